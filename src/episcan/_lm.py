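"""Small dense least-squares helpers shared by the association modules."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class LsFit(NamedTuple):
    beta: np.ndarray
    rss: float
    rank: int
    xtx_inv: np.ndarray | None   # None when the design is rank-deficient


def ls_fit(X: np.ndarray, y: np.ndarray, need_cov: bool = False) -> LsFit:
    """Least-squares fit returning RSS, rank, and optionally (X'X)^-1."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    rss = float(r @ r)
    xtx_inv = None
    if need_cov:
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design: covariance undefined")
        xtx_inv = np.linalg.inv(X.T @ X)
    return LsFit(beta, rss, int(rank), xtx_inv)
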