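"""Shared statistical primitives: OLS with t-based inference and an exact
Fisher test for small r x c contingency tables (Freeman-Halton)."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats
from scipy.special import gammaln

# Smallest p-value reported by the OLS engine; a perfect fit yields this
# rather than an exact zero.
P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class OlsFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    n: int


def ols_fit(X: np.ndarray, y: np.ndarray) -> OlsFit:
    """Ordinary least squares with two-sided t p-values per coefficient.

    ``X`` must already include an intercept column if one is wanted.
    Raises on rank deficiency (the caller names the offending columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations for {k} parameters, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)
    return OlsFit(beta=beta, se=se, t=t, p=p, df_resid=df, n=n)


def check_collinearity(X: np.ndarray, names: list[str]) -> None:
    """Raise ``ValueError`` naming columns whose removal restores full rank."""
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank == k:
        return
    offenders = []
    for j in range(k):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            offenders.append(names[j])
    raise ValueError(f"collinear covariates: removal of any of {offenders} restores full rank")


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - gammaln(table + 1.0).sum()


def fisher_exact_rxc(table) -> float:
    """Two-sided Fisher exact p for an r x c table (Freeman-Halton).

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table.
    Intended for the small tables of a recall study (n of order tens).
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("empty table")
    # drop all-zero margins: they contribute nothing
    obs = obs[row > 0][:, col > 0]
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    r, c = obs.shape
    if r < 2 or c < 2:
        return 1.0
    log_const = gammaln(row + 1.0).sum() + gammaln(col + 1.0).sum() - gammaln(n + 1.0)
    log_p_obs = _log_table_prob(obs, log_const)

    # enumerate the free (r-1) x (c-1) block; the last row/column follow
    total = 0.0
    extreme = 0.0
    ranges = [range(min(row[i], col[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for cells in product(*ranges):
        t = np.zeros((r, c), dtype=int)
        t[: r - 1, : c - 1] = np.asarray(cells).reshape(r - 1, c - 1)
        t[: r - 1, c - 1] = row[: r - 1] - t[: r - 1, : c - 1].sum(axis=1)
        if (t[: r - 1, c - 1] < 0).any():
            continue
        t[r - 1, :] = col - t[: r - 1, :].sum(axis=0)
        if (t[r - 1, :] < 0).any():
            continue
        lp = _log_table_prob(t, log_const)
        pr = float(np.exp(lp))
        total += pr
        if lp <= log_p_obs + 1e-10:
            extreme += pr
    return min(extreme / total, 1.0)
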