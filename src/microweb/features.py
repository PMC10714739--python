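"""Per-sample diversity and sub-network features.

Each water sample induces a sub-network of the seasonal web on the taxa
present in that sample (aggregate compartments always retained). From it
we take the average degree AD = 2L/S and ``Int`` — the proportion of the
sub-network's trophic links that run from a bacterivorous protist to a
bacterial node — plus the Shannon diversity of the sample's community.
Simple OLS regressions and rank correlations relate these features to
web complexity and stability metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .io import FoodWeb

__all__ = [
    "shannon",
    "sample_subweb",
    "interaction_proportion",
    "SampleFeatures",
    "RegressionResult",
    "regress_feature",
    "metric_correlations",
]


def shannon(counts) -> float:
    """Shannon diversity H (natural log) of an abundance vector."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if x.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    return float(stats.entropy(x))  # normalizes and uses natural log


def sample_subweb(web: FoodWeb, sample_taxa: Set[str], label: str = ""):
    """Induced sub-network on a sample's taxa plus the standing aggregates.

    The five compartment nodes (algae, bacteria, fungi, detritus, DOC)
    are always retained; phylum-level bacterial nodes follow the sample's
    own detections like any taxon. Taxa absent from the web are ignored
    and returned for reporting. Raises when nothing at all is retained.
    """
    present = [t for t in sample_taxa if t in web]
    missing = sorted(t for t in sample_taxa if t not in web)
    keep = set(present) | {
        n.node_id
        for n in web.nodes
        if n.kind == "aggregate" and n.node_id == n.compartment
    }
    if not keep:
        raise ValueError("sample induces an empty sub-network")
    sub = web.subweb(keep, label=label or web.label)
    return sub, missing


def interaction_proportion(
    subweb: FoodWeb,
    bacterial_nodes: Optional[Set[str]] = None,
    denominator: str = "all",
) -> float:
    """Proportion of links from bacterivorous predators to bacterial prey.

    ``bacterial_nodes`` defaults to every node in the bacteria
    compartment (the aggregate plus any phylum-level nodes).
    ``denominator="all"`` divides by every link of the sub-network;
    ``"protist"`` divides by links whose predator is a protist genus.
    """
    if subweb.L == 0:
        raise ValueError("interaction proportion undefined for a linkless web")
    if denominator not in ("all", "protist"):
        raise ValueError("denominator must be 'all' or 'protist'")
    if bacterial_nodes is None:
        bacterial_nodes = {
            n.node_id for n in subweb.nodes if n.compartment == "bacteria"
        }
    n_qualifying = 0
    n_denom = 0
    for prey_id, pred_id in subweb.trophic_links():
        pred = subweb.node(pred_id)
        is_protist_pred = pred.compartment == "protist"
        if denominator == "all" or is_protist_pred:
            n_denom += 1
        if is_protist_pred and "B" in pred.guilds and prey_id in bacterial_nodes:
            n_qualifying += 1
    if n_denom == 0:
        raise ValueError("no qualifying links in denominator")
    return n_qualifying / n_denom


@dataclass
class SampleFeatures:
    """One sample's diversity and sub-network numbers."""

    sample_id: str
    season: str
    shannon_H: float
    sub_S: int
    sub_L: int
    AD: float
    Int: float


class RegressionResult:
    """Simple linear regression y = a + b*x with a t-test on the slope."""

    def __init__(self, slope, intercept, r_squared, pvalue, n):
        self.slope = slope
        self.intercept = intercept
        self.r_squared = r_squared
        self.pvalue = pvalue
        self.n = n

    def __repr__(self):
        return (
            f"RegressionResult(slope={self.slope:.4g}, "
            f"R2={self.r_squared:.4g}, p={self.pvalue:.4g}, n={self.n})"
        )


def regress_feature(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rvalue**2)
    p = 1.0 if np.ptp(y) == 0 else float(res.pvalue)
    return RegressionResult(float(res.slope), float(res.intercept), r2, p, int(x.size))


def metric_correlations(
    table: pd.DataFrame,
    complexity_cols: Sequence[str] = ("L", "LD", "C"),
    stability_cols: Sequence[str] = ("meanTL", "O", "Mod", "QSS"),
):
    """Spearman rank correlations between complexity and stability columns.

    Returns ``(rho, p)`` DataFrames indexed by complexity column. Ties are
    rank-averaged; a constant column yields NaN for its pairs.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 rows for rank correlation")
    for c in list(complexity_cols) + list(stability_cols):
        if c not in table.columns:
            raise KeyError(f"column {c!r} missing from metrics table")
    rho = pd.DataFrame(index=list(complexity_cols), columns=list(stability_cols), dtype=float)
    pval = rho.copy()
    for a in complexity_cols:
        for b in stability_cols:
            x, y = table[a].to_numpy(float), table[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho.loc[a, b] = np.nan
                pval.loc[a, b] = np.nan
                continue
            r = stats.spearmanr(x, y)
            rho.loc[a, b] = float(r.statistic)
            pval.loc[a, b] = float(r.pvalue)
    return rho, pval
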