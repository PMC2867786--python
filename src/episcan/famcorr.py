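"""Sib-correlation model: equicorrelated sibship covariance, ANOVA intraclass
correlation estimate, and the GLS whitening transform shared by all tests.

Within a sibship of size k the phenotype covariance is modelled as
V = (1 - rho) I + rho J (exchangeable).  Its inverse square root has the
closed form

    V^(-1/2) = (1 - rho)^(-1/2) (I - J/k) + (1 - rho + k rho)^(-1/2) (J/k),

so ordinary least squares on whitened response and design reproduces GLS
under V exactly.  rho is estimated once from covariate-adjusted residuals
and reused for every test; spousal and parent-offspring correlations are
outside the model (only sibs are observed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError


@dataclass
class SibshipStructure:
    """Partition of individuals into sibships (singletons allowed)."""

    individual_ids: list[str]
    labels: np.ndarray          # sibship label per individual (object/str)
    codes: np.ndarray           # dense 0..n_sibships-1 integer codes

    @classmethod
    def from_labels(cls, individual_ids, labels) -> "SibshipStructure":
        labels = np.asarray(labels, dtype=object)
        codes, _ = pd.factorize(labels)
        return cls(list(individual_ids), labels, codes.astype(np.int64))

    @classmethod
    def from_frame(cls, pheno: pd.DataFrame) -> "SibshipStructure":
        """Build from the phenotype table's family_id/sibship_id columns."""
        lab = (pheno["family_id"].astype(str) + "::" + pheno["sibship_id"].astype(str)).to_numpy()
        return cls.from_labels(pheno["individual_id"].tolist(), lab)

    @property
    def sizes(self) -> dict:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))

    def subset(self, mask: np.ndarray) -> "SibshipStructure":
        ids = [i for i, m in zip(self.individual_ids, mask) if m]
        return SibshipStructure.from_labels(ids, self.labels[mask])


@dataclass(frozen=True)
class IccEstimate:
    """One-way random-effects ANOVA intraclass correlation, truncated to [0, 0.99]."""

    rho: float
    ms_between: float
    ms_within: float
    n_sibships: int


def estimate_icc(residuals: np.ndarray, structure: SibshipStructure) -> IccEstimate:
    """ANOVA estimator of the intra-sibship correlation.

    rho = (MSB - MSW) / (MSB + (n0 - 1) MSW) with n0 the standard effective
    sibship size (N - sum k_i^2 / N) / (a - 1).  Requires at least two
    multi-member sibships; otherwise returns rho = 0 with a warning.
    """
    y = np.asarray(residuals, dtype=float)
    codes = structure.codes
    n_grp = int(codes.max()) + 1 if codes.size else 0
    counts = np.bincount(codes, minlength=n_grp).astype(float)
    multi = counts[counts >= 2]
    if multi.size < 2:
        warnings.warn("fewer than two multi-member sibships: rho set to 0")
        return IccEstimate(0.0, float("nan"), float("nan"), n_grp)

    N = y.size
    a = n_grp
    sums = np.bincount(codes, weights=y, minlength=n_grp)
    means = sums / counts
    gmean = y.mean()
    ssb = float(np.sum(counts * (means - gmean) ** 2))
    ssw = float(np.sum((y - means[codes]) ** 2))
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    n0 = (N - np.sum(counts**2) / N) / (a - 1)
    rho = (msb - msw) / (msb + (n0 - 1) * msw)
    rho = float(np.clip(rho, 0.0, 0.99))
    return IccEstimate(rho, msb, msw, a)


def whiten_by_codes(vectors: np.ndarray, codes: np.ndarray, rho: float) -> np.ndarray:
    """Apply the per-sibship V^(-1/2) to one vector or the columns of a matrix.

    ``codes`` are integer sibship codes aligned to rows.  Works for any
    subset of a sibship because a sub-block of an exchangeable matrix is
    itself exchangeable.
    """
    if not 0.0 <= rho < 1.0:
        raise ParameterError(f"rho must be in [0, 1), got {rho}")
    x = np.asarray(vectors, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if rho == 0.0:
        out = x.copy()
        return out[:, 0] if squeeze else out

    n_grp = int(codes.max()) + 1
    counts = np.bincount(codes, minlength=n_grp).astype(float)
    safe = np.maximum(counts, 1.0)
    a = (1.0 - rho) ** -0.5
    b = (1.0 - rho + counts * rho) ** -0.5

    out = np.empty_like(x)
    for jcol in range(x.shape[1]):
        col = x[:, jcol]
        mean = np.bincount(codes, weights=col, minlength=n_grp) / safe
        mrow = mean[codes]
        out[:, jcol] = a * (col - mrow) + b[codes] * mrow
    return out[:, 0] if squeeze else out


def whiten(vectors: np.ndarray, structure: SibshipStructure, rho: float) -> np.ndarray:
    """Whitening transform keyed by a :class:`SibshipStructure`."""
    return whiten_by_codes(vectors, structure.codes, rho)
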