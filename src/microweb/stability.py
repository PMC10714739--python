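"""Quasi sign-stability (QSS) by Monte-Carlo sampling of community matrices.

The web's sign structure fixes which Jacobian entries are negative
(predation loss for prey), positive (predator gain) and zero; magnitudes
are drawn at random draw after draw. The fraction of draws whose largest
eigenvalue real part is negative estimates how often that sign pattern is
locally stable; the mean largest real part is an effect-size style
companion where lower means more stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FoodWeb

__all__ = ["QSSResult", "sample_community_matrix", "qss", "wilson_ci"]


def sample_community_matrix(
    web: FoodWeb,
    rng: np.random.Generator,
    interaction_max: float = 10.0,
    efficiency: float = 0.1,
    self_limitation_max: float = 1.0,
    self_limit_all: bool = True,
) -> np.ndarray:
    """One random community matrix consistent with the web's sign pattern.

    For every trophic link prey *i* -> predator *j* a single magnitude
    ``u ~ Uniform(0, interaction_max)`` is drawn: the prey loses at rate
    ``M[i, j] = -u`` and the predator gains the trophically converted
    ``M[j, i] = +efficiency * u``. Diagonal self-limitation is
    ``-d`` with ``d ~ Uniform(0, self_limitation_max)`` on every node
    (or on basal nodes only when ``self_limit_all`` is false). The sign
    pattern is identical across draws.
    """
    S = web.S
    M = np.zeros((S, S), dtype=float)
    prey_idx, pred_idx = np.nonzero(web.adjacency)
    u = rng.uniform(0.0, interaction_max, size=len(prey_idx))
    M[prey_idx, pred_idx] = -u
    M[pred_idx, prey_idx] = efficiency * u
    d = rng.uniform(0.0, self_limitation_max, size=S)
    if not self_limit_all:
        d = np.where(web.basal_mask(), d, 0.0)
    M[np.arange(S), np.arange(S)] = -d
    return M


@dataclass
class QSSResult:
    """Monte-Carlo stability summary of one web's sign pattern."""

    label: str
    n_draws: int
    prop_stable: float
    mean_max_eig: float
    max_eig_draws: np.ndarray
    seed: int

    def ci95(self):
        """Wilson 95% interval on the stable-draw proportion."""
        k = int(round(self.prop_stable * self.n_draws))
        return wilson_ci(k, self.n_draws)


def qss(
    web: FoodWeb,
    n_draws: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    **matrix_params,
) -> QSSResult:
    """Quasi sign-stability of a web.

    Draws ``n_draws`` community matrices, records each draw's largest
    eigenvalue real part, and reports the proportion of draws that are
    locally stable (all real parts strictly negative) together with the
    mean largest real part. Reproducible given ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    max_re = np.empty(n_draws)
    for k in range(n_draws):
        M = sample_community_matrix(web, rng, **matrix_params)
        if web.S == 0:
            max_re[k] = -np.inf
            continue
        max_re[k] = np.max(np.linalg.eigvals(M).real)
    stable = max_re < 0.0  # exactly-zero real part counts unstable
    return QSSResult(
        label=web.label,
        n_draws=n_draws,
        prop_stable=float(stable.mean()),
        mean_max_eig=float(max_re.mean()) if web.S else float("-inf"),
        max_eig_draws=max_re,
        seed=seed,
    )


def wilson_ci(k: int, n: int, z: float = 1.959963984540054):
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)
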