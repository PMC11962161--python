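"""Two-sample tests used for condensate and particle comparisons.

The Brunner-Munzel test compares two samples through the relative effect
p = P(X < Y) + 1/2 P(X = Y), estimated with midranks; the studentized
statistic is referred to a t distribution with Satterthwaite-type degrees of
freedom (the standard small-sample recommendation), with an optional
permutation variant. Welch's unequal-variance t test is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "brunner_munzel", "welch_t"]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float                  # two-sided
    n_x: int
    n_y: int
    relative_effect: float | None = None   # Brunner-Munzel only


def _bm_relative_effect(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    r2bar = ranks[len(x):].mean()
    return float((r2bar - (len(y) + 1) / 2.0) / len(x))


def brunner_munzel(x, y, method: str = "t", n_permutations: int = 10000,
                   rng: np.random.Generator | int | None = None) -> TestResult:
    """Brunner-Munzel nonparametric two-sample test.

    Parameters
    ----------
    x, y:
        Samples with at least two observations each; at least one must be
        non-degenerate.
    method:
        ``"t"`` (default): studentized statistic with Satterthwaite-type
        degrees of freedom and a two-sided p from the t distribution.
        ``"permutation"``: two-sided p from ``n_permutations`` random
        relabellings, using |relative effect - 1/2| as the statistic.

    Returns a :class:`TestResult` whose ``relative_effect`` estimates
    P(X < Y) + 1/2 P(X = Y); it satisfies
    ``relative_effect(x, y) + relative_effect(y, x) == 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need >= 2 observations")
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx, ry = ranks[:nx], ranks[nx:]
    rxbar, rybar = rx.mean(), ry.mean()
    phat = float((rybar - (ny + 1) / 2.0) / nx)
    qx = sps.rankdata(x)
    qy = sps.rankdata(y)
    sx2 = np.sum((rx - qx - rxbar + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((ry - qy - rybar + (ny + 1) / 2.0) ** 2) / (ny - 1)
    denom2 = nx * sx2 + ny * sy2
    if denom2 <= 0:
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            raise ValueError("degenerate samples: both constant and equal")
        stat = np.inf if rybar > rxbar else -np.inf
        return TestResult(statistic=float(stat), df=np.nan, p_value=0.0,
                          n_x=nx, n_y=ny, relative_effect=phat)
    stat = nx * ny * (rybar - rxbar) / ((nx + ny) * np.sqrt(denom2))
    df = denom2 ** 2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    if method == "t":
        p = 2.0 * sps.t.sf(abs(stat), df)
    elif method == "permutation":
        gen = rng if isinstance(rng, np.random.Generator) \
            else np.random.default_rng(rng)
        pooled = np.concatenate([x, y])
        obs = abs(phat - 0.5)
        count = 0
        for _ in range(n_permutations):
            perm = gen.permutation(pooled)
            count += abs(_bm_relative_effect(perm[:nx], perm[nx:]) - 0.5) \
                >= obs - 1e-12
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError("method must be 't' or 'permutation'")
    return TestResult(statistic=float(stat), df=float(df),
                      p_value=float(min(p, 1.0)), n_x=nx, n_y=ny,
                      relative_effect=phat)


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance two-sample t test (two-tailed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need >= 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(statistic=float(res.statistic), df=float(res.df),
                      p_value=float(res.pvalue), n_x=len(x), n_y=len(y))
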