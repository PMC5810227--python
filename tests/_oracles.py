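"""Independent brute-force oracles used only by the test suite.

Each oracle takes the most direct route available (direct log-factorial
evaluation, explicit enumeration, closed forms) and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln


def hwe_enumeration_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p by direct evaluation of every heterozygote configuration.

    P(het = h | allele counts) is computed term by term from log factorials
    and normalized by the explicit sum over all feasible h.
    """
    n = n_aa + n_ab + n_bb
    rare = 2 * n_aa + n_ab
    rare = min(rare, 2 * n - rare)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.empty(len(hets))
    for i, h in enumerate(hets):
        aa = (rare - h) // 2
        bb = n - aa - h
        logp[i] = (
            gammaln(n + 1) - gammaln(aa + 1) - gammaln(h + 1) - gammaln(bb + 1)
            + h * math.log(2.0)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
        )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(hets, min(n_ab, rare)))]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


def fisher_2x2_pvalue(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x):
        return (
            gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {x: math.exp(log_prob(x)) for x in xs}
    p_obs = probs[a]
    return min(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)), 1.0)


def ols_normal_equations(X, y):
    """Closed-form OLS coefficients via the normal equations."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def piecewise_linear_integral(times, values, upper):
    """Integral of the piecewise-linear interpolant on [times[0], upper]."""
    total = 0.0
    for (t0, v0), (t1, v1) in zip(zip(times, values), zip(times[1:], values[1:])):
        if t1 <= upper:
            total += 0.5 * (v0 + v1) * (t1 - t0)
        elif t0 < upper:
            v_up = v0 + (v1 - v0) * (upper - t0) / (t1 - t0)
            total += 0.5 * (v0 + v_up) * (upper - t0)
    return total
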