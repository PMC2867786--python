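"""Phenotype preparation: Box-Cox transformation profiling, outlier policy,
covariate screening, and covariate adjustment.

The scans downstream test *residuals*: the trait is transformed once
(default: natural log, the lambda = 0 member of the Box-Cox family, which is
the usual choice for right-skewed lipid concentrations), screened covariates
are regressed out by ordinary least squares, and the mean-zero residual
vector is what every SNP test sees.  Family correlation is *not* absorbed
here; it is handled at test time by GLS whitening (see :mod:`episcan.famcorr`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, DegenerateDataError, InsufficientDataError

#: columns every phenotype table must provide
REQUIRED_COLUMNS = ("individual_id", "family_id", "sibship_id", "trait")


@dataclass(frozen=True)
class BoxCoxProfile:
    """Profile log-likelihood of the Box-Cox power parameter on a grid."""

    lambda_grid: np.ndarray
    loglik: np.ndarray
    lambda_hat: float


@dataclass
class AdjustedPhenotype:
    """Covariate-adjusted residual vector, aligned to ``individual_ids``."""

    individual_ids: list[str]
    residuals: np.ndarray
    model_spec: dict[str, float]
    removed_outliers: list[tuple[str, str]] = field(default_factory=list)


def read_phenotypes(path) -> pd.DataFrame:
    """Read the tab-separated phenotype/covariate table (missing coded NA)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={c: str for c in REQUIRED_COLUMNS[:3]})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"phenotype table lacks required columns: {missing}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise DataError(f"duplicate individual ids in phenotype table: {dup[:5]}")
    return df


def boxcox_profile(y, grid=None, individual_ids=None) -> BoxCoxProfile:
    """Profile the Box-Cox log-likelihood (normal errors after transform,
    Jacobian included) over ``grid`` and locate its maximum.

    The profile is advisory: the pipeline's default transform stays lambda = 0
    regardless, keeping runs deterministic.
    """
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 81)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DataError("empty lambda grid")
    if np.any(y <= 0):
        bad = np.nonzero(y <= 0)[0]
        ids = [individual_ids[i] for i in bad] if individual_ids is not None else bad.tolist()
        raise DataError(f"Box-Cox requires positive trait values; offending: {ids[:10]}")
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant trait: Box-Cox profile undefined")
    ll = np.array([stats.boxcox_llf(lam, y) for lam in grid])
    return BoxCoxProfile(grid, ll, float(grid[int(np.argmax(ll))]))


def apply_transform(y, lam: float) -> np.ndarray:
    """Box-Cox transform: log for lambda = 0, else (y**lambda - 1)/lambda."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise DataError("Box-Cox transform requires positive values")
    if lam == 0.0:
        return np.log(y)
    # expm1 form avoids cancellation for small |lambda|
    return np.expm1(lam * np.log(y)) / lam


def flag_outliers(y, individual_ids, method: str = "none", k: float = 3.0, explicit=None) -> list[str]:
    """Return ids flagged by the configured outlier policy.

    ``none`` flags nothing; ``zscore`` flags |y - mean|/sd > k (on whatever
    scale the caller passes, normally the transformed trait); ``explicit``
    passes a manual id list through after checking membership.  Flagging is
    report-only -- exclusion happens where the caller drops the rows.
    """
    ids = list(individual_ids)
    if method == "none":
        return []
    if method == "explicit":
        explicit = list(explicit or [])
        unknown = [i for i in explicit if i not in set(ids)]
        if unknown:
            raise DataError(f"explicit outlier ids not present: {unknown}")
        return explicit
    if method == "zscore":
        if k <= 0:
            raise DataError("zscore policy requires k > 0")
        y = np.asarray(y, dtype=float)
        sd = y.std(ddof=1)
        if sd == 0:
            return []
        z = np.abs(y - y.mean()) / sd
        return [ids[i] for i in np.nonzero(z > k)[0]]
    raise DataError(f"unknown outlier policy {method!r}")


def screen_covariates(y, candidates: pd.DataFrame, force_in=(), alpha: float = 0.05):
    """Joint-model covariate screen.

    Fits one OLS of ``y`` on all candidate columns plus intercept and retains
    the candidates whose coefficient p-value is below ``alpha``, together
    with everything in ``force_in`` (the mechanism for keeping a marginally
    insignificant covariate, e.g. age kept because age-squared nearly is).

    Returns ``(retained_names, pvalues)`` with column order preserved.
    """
    y = np.asarray(y, dtype=float)
    if candidates.isna().any().any():
        bad = candidates.columns[candidates.isna().any()].tolist()
        raise DataError(f"candidate covariates contain missing values: {bad}")
    X = sm.add_constant(candidates.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = [
            c for c in candidates.columns
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank
        ]
        raise DataError(f"collinear covariate set: {collinear}")
    fit = sm.OLS(y, X).fit()
    pvals = fit.pvalues.drop("const")
    force = set(force_in)
    unknown = force - set(candidates.columns)
    if unknown:
        raise DataError(f"force_in covariates not among candidates: {sorted(unknown)}")
    retained = [c for c in candidates.columns if pvals[c] < alpha or c in force]
    return retained, pvals


def adjust_phenotype(y, covariates: pd.DataFrame | None, individual_ids,
                     removed_outliers=()) -> AdjustedPhenotype:
    """OLS-residualize the transformed trait on the retained covariates.

    With no covariates this is plain mean-centering.  Residuals are exactly
    orthogonal to the intercept and every covariate column.
    """
    y = np.asarray(y, dtype=float)
    ids = list(individual_ids)
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((y.size, 1))
        names = ["const"]
    else:
        X = np.column_stack([np.ones(y.size), covariates.astype(float).to_numpy()])
        names = ["const"] + list(covariates.columns)
    if y.size <= X.shape[1]:
        raise InsufficientDataError(
            f"{y.size} observations cannot support {X.shape[1] - 1} covariates + intercept"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return AdjustedPhenotype(
        individual_ids=ids,
        residuals=resid,
        model_spec=dict(zip(names, beta.tolist())),
        removed_outliers=list(removed_outliers),
    )


def write_adjusted(adj: AdjustedPhenotype, path) -> None:
    """Write the residual vector as a two-column TSV (id, residual)."""
    with open(path, "w") as fh:
        fh.write("individual_id\tresidual\n")
        for ind, r in zip(adj.individual_ids, adj.residuals):
            fh.write(f"{ind}\t{r:.10g}\n")
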