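"""Published combination-frequency/effect rows used as identity-check fixtures.

Each entry is a reported gamete, allele-genotype, or genotype-genotype
combination table (frequencies and effects, printed to 3 significant
figures) from a family-based lipid GWAS.  Any valid combination table must
satisfy sum(f) = 1 and sum(f * effect) = 0 up to printing precision; the
rows serve as external data for checking those identities.
"""

REFERENCE_COMBINATION_ROWS = {
    "tc_aa_gamete": {
        "granularity": "gamete",
        "frequency": [0.0785, 0.413, 0.434, 0.0742],
        "effect": [0.103, 0.0195, -0.0186, -0.108],
    },
    "tc_ad_allele_genotype": {
        "granularity": "allele_genotype",
        "frequency": [0.0015, 0.0284, 0.557, 0.374, 0.0387, 0.001],
        "effect": [0.961, 0.0917, 0.00219, -0.00313, -0.0636, -1.42],
    },
    "hdl_aa_gamete_1": {
        "granularity": "gamete",
        "frequency": [0.0538, 0.593, 0.226, 0.127],
        "effect": [0.15, 0.0137, -0.0359, -0.0635],
    },
    "hdl_dd_genotype_1": {
        "granularity": "genotype_genotype",
        "frequency": [0.0817, 0.0887, 0.161, 0.169, 0.112, 0.0619, 0.24, 0.055, 0.0298],
        "effect": [0.137, 0.127, 0.0694, 0.066, -0.0495, -0.0908, -0.0932, -0.103, -0.189],
    },
    "hdl_aa_gamete_2": {
        "granularity": "gamete",
        "frequency": [0.106, 0.448, 0.241, 0.206],
        "effect": [0.0946, 0.0224, -0.0416, -0.0488],
    },
    "hdl_aa_gamete_3": {
        "granularity": "gamete",
        "frequency": [0.0751, 0.237, 0.661, 0.0272],
        "effect": [0.0801, 0.0253, -0.00908, -0.221],
    },
    "hdl_dd_genotype_2": {
        "granularity": "genotype_genotype",
        "frequency": [0.0501, 0.103, 0.115, 0.208, 0.131, 0.115, 0.215, 0.0344, 0.0279],
        "effect": [0.223, 0.109, 0.0979, 0.0535, -0.0433, -0.0494, -0.103, -0.167, -0.197],
    },
}
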