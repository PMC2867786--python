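"""Genotype containers, PED/MAP text I/O, allele-frequency summaries, and
scan-size arithmetic.

Genotypes are coded as counts of a designated reference allele (0, 1, 2) with
``MISSING`` (-1) as sentinel.  At load time the reference allele is the
*minor* allele (ties broken alphabetically), so effect signs downstream
always refer to the minor allele and ``p_ref`` equals the MAF for polymorphic
SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DegenerateDataError, FormatError, ParameterError

MISSING = -1

log = logging.getLogger("episcan.genodata")


@dataclass(frozen=True)
class SnpMeta:
    """Marker metadata: id, chromosome label, 1-based bp position, alleles."""

    snp_id: str
    chromosome: str
    position: int
    allele_ref: str
    allele_alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"{self.snp_id}: position must be >= 1, got {self.position}")
        if self.allele_ref == self.allele_alt:
            raise DataError(f"{self.snp_id}: reference and alternate alleles are identical")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of reference-allele counts.

    ``codes[i, j]`` is the number of copies of ``snps[j].allele_ref`` carried
    by ``individual_ids[i]``, or ``MISSING``.
    """

    individual_ids: list[str]
    snps: list[SnpMeta]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if n != len(self.individual_ids) or m != len(self.snps):
            raise DataError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals / {len(self.snps)} SNPs"
            )
        if len(set(self.individual_ids)) != n:
            raise DataError("duplicate individual ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise DataError("duplicate SNP ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        for k, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return k
        raise KeyError(snp_id)


@dataclass(frozen=True)
class FreqSummary:
    """Genotype/allele frequencies at one SNP over non-missing individuals.

    ``hwd_coefficient = f2 - p_ref**2`` measures departure from
    Hardy-Weinberg proportions (positive = homozygote excess for the
    reference allele).
    """

    n_obs: int
    counts: tuple[int, int, int]
    genotype_freqs: tuple[float, float, float]
    p_ref: float
    maf: float
    hwd_coefficient: float


def _read_map(map_path) -> list[tuple[str, str, int]]:
    out = []
    with open(map_path) as fh:
        for line_no, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) == 4:
                chrom, snp_id, _cm, bp = tok
            elif len(tok) == 3:
                chrom, snp_id, bp = tok
            else:
                raise FormatError(f"{map_path}:{line_no}: expected 3 or 4 columns, got {len(tok)}")
            out.append((chrom, snp_id, int(bp)))
    return out


def load_genotypes(ped_path, map_path) -> GenotypeMatrix:
    """Read whitespace-delimited PED/MAP files into a :class:`GenotypeMatrix`.

    The reference allele of each SNP is set to its minor allele (alphabetical
    tie-break at MAF 0.5); ``"0"`` alleles mark missing genotypes.  A locus
    with more than two observed alleles raises :class:`DataError` naming the
    SNP; PED rows whose genotype count disagrees with the MAP raise
    :class:`FormatError`.
    """
    snp_rows = _read_map(map_path)
    m = len(snp_rows)

    individual_ids: list[str] = []
    rows_a1: list[list[str]] = []
    rows_a2: list[list[str]] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{line_no}: expected {6 + 2 * m} fields for {m} SNPs, got {len(tok)}"
                )
            individual_ids.append(tok[1])
            rows_a1.append(tok[6::2])
            rows_a2.append(tok[7::2])

    n = len(individual_ids)
    if n == 0:
        raise FormatError(f"{ped_path}: no individuals")
    a1 = np.array(rows_a1, dtype="U8")
    a2 = np.array(rows_a2, dtype="U8")

    codes = np.full((n, m), MISSING, dtype=np.int8)
    snps: list[SnpMeta] = []
    for j, (chrom, snp_id, bp) in enumerate(snp_rows):
        c1, c2 = a1[:, j], a2[:, j]
        obs = (c1 != "0") & (c2 != "0")
        alleles, counts = np.unique(np.concatenate([c1[obs], c2[obs]]), return_counts=True)
        if len(alleles) > 2:
            raise DataError(f"SNP {snp_id}: more than two alleles observed: {sorted(alleles)}")
        if len(alleles) == 0:
            raise DataError(f"SNP {snp_id}: all genotypes missing")
        if len(alleles) == 1:
            ref, alt = str(alleles[0]), "N"
        else:
            # minor allele is the reference; alphabetical tie-break
            order = np.lexsort((alleles, counts))
            ref, alt = str(alleles[order[0]]), str(alleles[order[1]])
        snps.append(SnpMeta(snp_id, chrom, bp, ref, alt))
        col = (c1 == ref).astype(np.int8) + (c2 == ref).astype(np.int8)
        col[~obs] = MISSING
        codes[:, j] = col

    return GenotypeMatrix(individual_ids, snps, codes)


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path, family_of: dict[str, str] | None = None) -> None:
    """Write a :class:`GenotypeMatrix` back to PED/MAP text.

    ``family_of`` maps individual id -> family id for the first PED column
    (defaults to the individual id itself).  Parents/sex/phenotype columns
    are written as PLINK missing values.
    """
    with open(map_path, "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(gm.individual_ids):
            fam = family_of.get(ind, ind) if family_of else ind
            fields = [fam, ind, "0", "0", "0", "-9"]
            for j, s in enumerate(gm.snps):
                c = gm.codes[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 2:
                    fields += [s.allele_ref, s.allele_ref]
                elif c == 1:
                    fields += [s.allele_ref, s.allele_alt]
                else:
                    fields += [s.allele_alt, s.allele_alt]
            fh.write(" ".join(fields) + "\n")


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    """Debug dump: one row per individual, one 0/1/2/NA column per SNP."""
    with open(path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(s.snp_id for s in gm.snps) + "\n")
        for i, ind in enumerate(gm.individual_ids):
            vals = ["NA" if c == MISSING else str(int(c)) for c in gm.codes[i]]
            fh.write(ind + "\t" + "\t".join(vals) + "\n")


def summarize_snp(column: np.ndarray) -> FreqSummary:
    """Genotype counts/frequencies over non-missing entries of one SNP column."""
    col = np.asarray(column)
    obs = col[col != MISSING]
    n = obs.size
    if n == 0:
        raise DegenerateDataError("all genotypes missing at this SNP")
    cnt = np.bincount(obs, minlength=3)
    n0, n1, n2 = int(cnt[0]), int(cnt[1]), int(cnt[2])
    f0, f1, f2 = n0 / n, n1 / n, n2 / n
    p = f2 + f1 / 2.0
    return FreqSummary(
        n_obs=n,
        counts=(n0, n1, n2),
        genotype_freqs=(f0, f1, f2),
        p_ref=p,
        maf=min(p, 1.0 - p),
        hwd_coefficient=f2 - p * p,
    )


def filter_by_maf(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep SNPs whose MAF is >= ``min_maf`` (inclusive boundary), order preserved."""
    if not 0.0 <= min_maf <= 0.5:
        raise ParameterError(f"min_maf must be in [0, 0.5], got {min_maf}")
    keep = []
    for j in range(gm.n_snps):
        try:
            s = summarize_snp(gm.codes[:, j])
        except DegenerateDataError:
            continue
        # tiny slack so a MAF mathematically equal to the threshold survives
        # float rounding of the frequency arithmetic
        if s.maf >= min_maf - 1e-12:
            keep.append(j)
    log.info("MAF filter >= %g: %d of %d SNPs retained", min_maf, len(keep), gm.n_snps)
    if not keep:
        log.warning("MAF filter removed every SNP")
    return GenotypeMatrix(
        gm.individual_ids,
        [gm.snps[j] for j in keep],
        gm.codes[:, keep] if keep else np.empty((gm.n_individuals, 0), dtype=np.int8),
    )


def count_tests(n_snps: int, mode: str) -> int:
    """Exact test-count arithmetic for a scan of ``n_snps`` markers.

    ``single`` = 3 tests per SNP; ``pairs`` = n(n-1)/2 unordered pairs;
    ``pairwise_effects`` = 5 tests per pair.  Python integers, so no overflow
    at genome scale.
    """
    n = int(n_snps)
    if mode == "single":
        return 3 * n
    if mode in ("pairs", "pairwise_effects"):
        if n < 2:
            raise ParameterError("pair modes require n_snps >= 2")
        pairs = n * (n - 1) // 2
        return pairs if mode == "pairs" else 5 * pairs
    raise ParameterError(f"unknown mode {mode!r}")
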