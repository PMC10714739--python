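"""Degree-preserving null models: curveball randomization, metric null
distributions, and distribution comparison.

The curveball algorithm repeatedly picks two rows of the binary
adjacency matrix and randomly reallocates the entries held by exactly
one of the two rows, leaving every row and column sum (each species'
number of predators and of prey) untouched. A chain of such trades gives
an ensemble of degree-matched random webs against which the empirical
metric values are placed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .io import FoodWeb
from . import metrics as _metrics
from . import stability as _stability

__all__ = [
    "curveball",
    "curveball_matrix",
    "NullEnsemble",
    "null_distribution",
    "NULL_METRICS",
    "ks_compare",
]


def curveball_matrix(
    A: np.ndarray,
    n_trades: int,
    rng: np.random.Generator,
    pin_diagonal: bool = False,
) -> np.ndarray:
    """Apply ``n_trades`` curveball trades to a binary matrix.

    Rows keep their sums and columns keep theirs. With ``pin_diagonal``
    the two diagonal cells of a traded row pair are held fixed, so a
    square trophic matrix never acquires a self-loop; leave it off for
    bipartite incidence matrices. A degenerate trade (nothing tradeable)
    counts as a trade, which keeps the runtime bounded.
    """
    if n_trades < 1:
        raise ValueError("n_trades must be >= 1")
    A = np.array(A, dtype=np.int8, copy=True)
    n = A.shape[0]
    if n < 2:
        return A
    rows = [set(np.flatnonzero(A[i]).tolist()) for i in range(n)]
    for _ in range(n_trades):
        i, k = rng.choice(n, size=2, replace=False)
        pinned = {i, k} if pin_diagonal else set()
        only_i = list((rows[i] - rows[k]) - pinned)
        only_k = list((rows[k] - rows[i]) - pinned)
        if not only_i or not only_k:
            continue
        pool = only_i + only_k
        perm = rng.permutation(len(pool))
        new_i = {pool[p] for p in perm[: len(only_i)]}
        new_k = set(pool) - new_i
        rows[i] = (rows[i] - set(only_i)) | new_i
        rows[k] = (rows[k] - set(only_k)) | new_k
    out = np.zeros_like(A)
    for i in range(n):
        cols = sorted(rows[i])
        out[i, cols] = 1
    return out


def curveball(web: FoodWeb, n_trades: Optional[int] = None, rng=None, seed: int = 0) -> FoodWeb:
    """One degree-preserving randomization of a web.

    ``n_trades`` defaults to 5*S. The result keeps every node's number of
    prey and of predators exactly.
    """
    if web.L < 2:
        raise ValueError("curveball needs at least two links")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_trades is None:
        n_trades = 5 * web.S
    A = curveball_matrix(web.adjacency, n_trades, rng, pin_diagonal=True)
    return FoodWeb(web.nodes, A, label=web.label)


# Registered null-ensemble metrics. Trophic-level based metrics fall back
# to a least-squares solution when a shuffled web contains a basal-free
# feeding loop (rare but possible under degree-preserving trades).
NULL_METRICS: dict = {
    "L": lambda web, rng, p: float(web.L),
    "meanTL": lambda web, rng, p: _metrics.trophic_levels(web, on_singular="lstsq")[1],
    "omnivory": lambda web, rng, p: _metrics.omnivory(web, on_singular="lstsq"),
    "modularity": lambda web, rng, p: _metrics.modularity(web)[0],
    "qss_prop_stable": lambda web, rng, p: _stability.qss(
        web, n_draws=p["qss_draws"], rng=rng
    ).prop_stable,
    "qss_mean_max_eig": lambda web, rng, p: _stability.qss(
        web, n_draws=p["qss_draws"], rng=rng
    ).mean_max_eig,
}


@dataclass
class NullEnsemble:
    """Null distribution of one metric over curveball-randomized webs."""

    metric_name: str
    n_random: int
    values: np.ndarray
    empirical: float
    ci95: tuple
    within: bool  # empirical value inside the simulated range
    seed: int

    def summary(self) -> dict:
        return {
            "metric": self.metric_name,
            "n_random": self.n_random,
            "empirical": self.empirical,
            "null_mean": float(np.mean(self.values)),
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            "within": bool(self.within),
            "seed": self.seed,
        }


def null_distribution(
    web: FoodWeb,
    metric: str | Callable,
    n_random: int = 1000,
    seed: int = 0,
    n_trades: Optional[int] = None,
    qss_draws: int = 100,
) -> NullEnsemble:
    """Null distribution of a metric over curveball-randomized webs.

    Runs a single Markov chain from the empirical web, retaining a
    snapshot every ``n_trades`` trades (default 5*S, used both as burn-in
    and thinning). ``metric`` is a registered name from
    :data:`NULL_METRICS` or any callable ``f(web) -> float``.

    The 95% band is the empirical 2.5/97.5 percentile of the ensemble;
    ``within`` records whether the observed value falls inside the full
    simulated range, the criterion used to accept the null ensemble as a
    reference for between-web comparison.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    params = {"qss_draws": qss_draws}
    if callable(metric):
        fn = lambda w, rng, p: float(metric(w))
        name = getattr(metric, "__name__", "metric")
    else:
        if metric not in NULL_METRICS:
            raise ValueError(
                f"unknown metric {metric!r}; known: {sorted(NULL_METRICS)}"
            )
        fn = NULL_METRICS[metric]
        name = metric
    rng = np.random.default_rng(seed)
    if n_trades is None:
        n_trades = max(1, 5 * web.S)
    empirical = fn(web, np.random.default_rng(rng.integers(2**31)), params)
    values = np.empty(n_random)
    A = web.adjacency
    for r in range(n_random):
        A = curveball_matrix(A, n_trades, rng, pin_diagonal=True)
        rweb = FoodWeb(web.nodes, A, label=web.label)
        values[r] = fn(rweb, np.random.default_rng(rng.integers(2**31)), params)
    lo, hi = np.percentile(values, [2.5, 97.5])
    within = bool(values.min() <= empirical <= values.max())
    return NullEnsemble(
        metric_name=name,
        n_random=n_random,
        values=values,
        empirical=float(empirical),
        ci95=(float(lo), float(hi)),
        within=within,
        seed=seed,
    )


def ks_compare(a, b):
    """Two-sample two-sided Kolmogorov-Smirnov test.

    Returns ``(D, p)`` with D the supremum ECDF distance and an asymptotic
    p value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_compare needs non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
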