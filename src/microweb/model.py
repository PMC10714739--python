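"""Study-level modelling surface: :class:`FoodWebStudy` and its results.

`FoodWebStudy` holds the study inputs (community tables, guild
annotation, interaction catalog); :meth:`FoodWebStudy.fit` runs the whole
analysis — seasonal web construction, complexity/topology/structure
metrics, quasi sign-stability, curveball null ensembles with KS
comparisons, and per-sample sub-network features with their regressions —
and returns a :class:`FoodWebStudyResults` carrying every estimate, its
uncertainty, and a ``summary()`` table.

The fit is a pure function of (inputs, options, seed): one global seed
fans out to per-stage child seeds through a counter-based spawn scheme so
any stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import build as _build
from . import features as _features
from . import metrics as _metrics
from . import nullmodels as _null
from . import stability as _stability
from .io import (
    CommunityTable,
    InteractionCatalog,
    read_annotation,
    read_community_table,
    read_interaction_catalog,
)

__all__ = ["FoodWebStudy", "FoodWebStudyResults", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"

logger = logging.getLogger("microweb")

ALL_STAGES = ("metrics", "qss", "null", "features")
DEFAULT_NULL_METRICS = ("meanTL", "omnivory", "modularity")


def _stage_seed(seed: int, k: int) -> int:
    """Counter-based child seed: stage k of global seed, below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(k,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = _sps.false_discovery_control(p[mask], method="bh")
    return out


class FoodWebStudy:
    """A seasonal microbial food-web study, ready to fit.

    Parameters
    ----------
    protist_table : CommunityTable
        Genus-level protist counts, all samples, with season labels.
    bacteria_table : CommunityTable or None
        Phylum-level bacterial counts for the same samples; required for
        the per-sample bacterivory feature ``Int``.
    annotation : dict
        ``taxon_id -> TaxonAnnotation`` covering every community taxon.
    catalog : InteractionCatalog
        Literature-style predator-prey edge list.
    aggregates : iterable of str
        Standing compartments added to every web.
    min_count : int
        Season-level detection threshold (summed counts), default 1.
    """

    def __init__(
        self,
        protist_table: CommunityTable,
        bacteria_table: Optional[CommunityTable],
        annotation: dict,
        catalog: InteractionCatalog,
        aggregates: Iterable[str] = _build.DEFAULT_AGGREGATES,
        min_count: int = 1,
    ):
        self.protist_table = protist_table
        self.bacteria_table = bacteria_table
        self.annotation = dict(annotation)
        self.catalog = catalog
        self.aggregates = tuple(aggregates)
        self.min_count = min_count
        self.seasons = protist_table.season_labels()
        self._webs: Optional[dict] = None
        self._reports: Optional[dict] = None

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_synthetic(cls, seed: int, config=None) -> "FoodWebStudy":
        """Build a study from the synthetic generator at one seed."""
        from .simulate import generate_seasonal_dataset

        ds = generate_seasonal_dataset(seed, config)
        return cls.from_dataset(ds)

    @classmethod
    def from_dataset(cls, dataset) -> "FoodWebStudy":
        study = cls(
            dataset.protist_table(),
            dataset.bacteria_table(),
            dataset.annotation,
            dataset.catalog,
            aggregates=dataset.config.aggregates,
        )
        study.dataset = dataset
        return study

    @classmethod
    def from_directory(cls, path) -> "FoodWebStudy":
        """Load the TSV bundle written by ``SyntheticDataset.write`` / the CLI."""
        p = Path(path)
        bacteria = None
        if (p / "bacteria_counts.tsv").exists():
            bacteria = read_community_table(p / "bacteria_counts.tsv")
        return cls(
            read_community_table(p / "protist_counts.tsv"),
            bacteria,
            read_annotation(p / "annotation.tsv"),
            read_interaction_catalog(p / "catalog.tsv"),
        )

    # -- construction ----------------------------------------------------
    def validate_inputs(self) -> list:
        """Referential-integrity problems across the input files."""
        tables = [self.protist_table]
        if self.bacteria_table is not None:
            tables.append(self.bacteria_table)
        return _build.validate_bundle(
            tables, self.annotation, self.catalog, self.aggregates
        )

    def webs(self) -> Dict[str, object]:
        """One built web per season (cached; construction is deterministic)."""
        if self._webs is None:
            self._webs, self._reports = {}, {}
            for season in self.seasons:
                taxa = _build.detected_taxa(
                    self.protist_table, season, self.min_count
                )
                web, report = _build.build_web(
                    taxa,
                    self.annotation,
                    self.catalog,
                    aggregates=self.aggregates,
                    label=season,
                )
                self._webs[season] = web
                self._reports[season] = report
        return self._webs

    def build_reports(self) -> dict:
        self.webs()
        return self._reports

    def expanded_web(self, season: str):
        """Season web with bacteria resolved to phylum-level nodes.

        Used for the per-sample ``Int`` feature: bacterivore-to-phylum
        catalog edges resolve only in this view, and the bulk-bacteria
        compartment is dropped in favour of its phyla so the bacterial
        side carries real phylum structure. The season-level web keeps
        bacteria as one aggregate compartment.
        """
        taxa = _build.detected_taxa(self.protist_table, season, self.min_count)
        aggregates = tuple(self.aggregates)
        if self.bacteria_table is not None:
            taxa |= _build.detected_taxa(self.bacteria_table, season, self.min_count)
            aggregates = tuple(a for a in aggregates if a != "bacteria")
        web, _ = _build.build_web(
            taxa, self.annotation, self.catalog, aggregates=aggregates,
            label=f"{season}+bacteria",
        )
        return web

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        n_random: int = 1000,
        n_draws: int = 1000,
        null_metrics: Sequence[str] = DEFAULT_NULL_METRICS,
        null_qss_draws: int = 100,
        sample_qss_draws: int = 200,
        stages: Sequence[str] = ALL_STAGES,
    ) -> "FoodWebStudyResults":
        """Run the full analysis and return a results object.

        ``stages`` may drop any of ``metrics``/``qss``/``null``/
        ``features``; dependent outputs (e.g. QSS columns) simply vanish
        from the report. ``n_random`` is the number of curveball
        randomizations per null ensemble, ``n_draws`` the number of QSS
        community-matrix draws per season web.
        """
        stages = tuple(stages)
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        t0 = time.time()
        webs = self.webs()
        res = FoodWebStudyResults(self, seed=seed, stages=stages)
        res.build_reports = self.build_reports()

        if "metrics" in stages:
            rows = []
            for season in self.seasons:
                m = _metrics.compute_all(webs[season], on_singular="lstsq")
                rows.append(m.as_dict())
                res.web_metrics[season] = m
            res.metrics = pd.DataFrame(rows).set_index("label")
            logger.info("metrics stage done in %.1fs", time.time() - t0)

        if "qss" in stages:
            t = time.time()
            for k, season in enumerate(self.seasons):
                res.qss[season] = _stability.qss(
                    webs[season], n_draws=n_draws, seed=_stage_seed(seed, 100 + k)
                )
            logger.info("qss stage done in %.1fs", time.time() - t)

        if "null" in stages:
            t = time.time()
            counter = 200
            for metric in null_metrics:
                for season in self.seasons:
                    res.null[(season, metric)] = _null.null_distribution(
                        webs[season],
                        metric,
                        n_random=n_random,
                        seed=_stage_seed(seed, counter),
                        qss_draws=null_qss_draws,
                    )
                    counter += 1
            res.ks = self._ks_table(res.null, null_metrics)
            logger.info("null stage done in %.1fs", time.time() - t)

        if "features" in stages:
            t = time.time()
            res.samples = self._sample_table(
                seed=_stage_seed(seed, 300), qss_draws=sample_qss_draws
            )
            res.regressions = self._regression_table(res.samples)
            stab_cols = [
                c for c in ("meanTL", "O", "Mod", "QSS") if c in res.samples.columns
            ]
            if len(res.samples) >= 4 and stab_cols:
                res.correlations = _features.metric_correlations(
                    res.samples, ("L", "LD", "C"), stab_cols
                )
            logger.info("features stage done in %.1fs", time.time() - t)

        logger.info("fit complete in %.1fs", time.time() - t0)
        return res

    # -- stage helpers ---------------------------------------------------
    def _ks_table(self, ensembles: dict, metrics: Sequence[str]) -> pd.DataFrame:
        rows = []
        for metric in metrics:
            for i, sa in enumerate(self.seasons):
                for sb in self.seasons[i + 1:]:
                    a = ensembles[(sa, metric)].values
                    b = ensembles[(sb, metric)].values
                    try:
                        d, p = _null.ks_compare(a, b)
                    except ValueError:
                        continue
                    rows.append(
                        {"metric": metric, "season_a": sa, "season_b": sb,
                         "D": d, "p": p}
                    )
        df = pd.DataFrame(rows)
        if len(df):
            df["p_adj"] = _bh_adjust(df["p"])
        return df

    def _sample_table(self, seed: int, qss_draws: int = 200) -> pd.DataFrame:
        rows = []
        k = 0
        for season in self.seasons:
            web = self.expanded_web(season)
            bact_nodes = {
                n.node_id for n in web.nodes if n.compartment == "bacteria"
            }
            for sid in self.protist_table.samples_in(season):
                pcounts = self.protist_table.counts_for_sample(sid)
                present = {
                    t
                    for t, v in zip(self.protist_table.taxon_ids, pcounts)
                    if v > 0
                }
                if self.bacteria_table is not None:
                    bcounts = self.bacteria_table.counts_for_sample(sid)
                    present |= {
                        t
                        for t, v in zip(self.bacteria_table.taxon_ids, bcounts)
                        if v > 0
                    }
                sub, _missing = _features.sample_subweb(web, present, label=sid)
                row = {
                    "sample_id": sid,
                    "season": season,
                    "shannon_H": _features.shannon(pcounts),
                    "sub_S": sub.S,
                    "sub_L": sub.L,
                }
                deg = _metrics.degree_stats(sub)
                row["AD"] = deg.AD
                row["Int"] = (
                    _features.interaction_proportion(sub, bact_nodes)
                    if sub.L
                    else float("nan")
                )
                comp = _metrics.complexity(sub)
                row["L"], row["LD"], row["C"] = comp.L, comp.LD, comp.C
                tl, mean_tl = _metrics.trophic_levels(sub, on_singular="lstsq")
                row["meanTL"] = mean_tl
                row["O"] = _metrics.omnivory(sub, tl=tl)
                row["Mod"] = _metrics.modularity(sub)[0] if sub.S >= 2 else np.nan
                if qss_draws:
                    row["QSS"] = _stability.qss(
                        sub, n_draws=qss_draws, seed=_stage_seed(seed, k)
                    ).prop_stable
                k += 1
                rows.append(row)
        return pd.DataFrame(rows)

    def _regression_table(self, samples: pd.DataFrame) -> pd.DataFrame:
        rows = []
        targets = [c for c in ("Mod", "L", "LD", "C", "meanTL", "QSS")
                   if c in samples.columns]
        x = samples["Int"].to_numpy(float)
        ok = np.isfinite(x)
        for target in targets:
            y = samples[target].to_numpy(float)
            m = ok & np.isfinite(y)
            if m.sum() < 3 or np.ptp(x[m]) == 0:
                continue
            r = _features.regress_feature(x[m], y[m])
            rows.append(
                {"feature": "Int", "metric": target, "slope": r.slope,
                 "intercept": r.intercept, "r_squared": r.r_squared,
                 "p": r.pvalue, "n": r.n}
            )
        df = pd.DataFrame(rows)
        if len(df):
            df["p_adj"] = _bh_adjust(df["p"])
        return df


class FoodWebStudyResults:
    """Everything one :meth:`FoodWebStudy.fit` produced.

    Attributes
    ----------
    metrics : DataFrame
        One row per season: S, L, LD, C, CC, CPL, Mod, meanTL, O.
    qss : dict
        ``season -> QSSResult`` (stable-draw proportion, mean leading
        eigenvalue real part, Wilson CI).
    null : dict
        ``(season, metric) -> NullEnsemble``.
    ks : DataFrame
        Pairwise two-sided KS tests between seasonal null ensembles,
        BH-adjusted within the family.
    samples : DataFrame
        Per-sample sub-network features (shannon_H, AD, Int, sub-metrics).
    regressions : DataFrame
        OLS of each sub-metric on Int across samples.
    correlations : (DataFrame, DataFrame)
        Spearman rho and p, complexity rows x stability columns.
    """

    def __init__(self, study: FoodWebStudy, seed: int, stages: Tuple[str, ...]):
        self.study = study
        self.seed = seed
        self.stages = stages
        self.schema_version = SCHEMA_VERSION
        self.web_metrics: dict = {}
        self.metrics: Optional[pd.DataFrame] = None
        self.qss: dict = {}
        self.null: dict = {}
        self.ks: Optional[pd.DataFrame] = None
        self.samples: Optional[pd.DataFrame] = None
        self.regressions: Optional[pd.DataFrame] = None
        self.correlations = None
        self.build_reports: dict = {}

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        """Human-readable study summary."""
        lines = []
        lines.append("Microbial food-web study")
        lines.append("=" * 64)
        lines.append(f"seasons: {', '.join(self.study.seasons)}   seed: {self.seed}")
        if self.metrics is not None:
            lines.append("")
            lines.append("Seasonal web metrics")
            lines.append("-" * 64)
            df = self.metrics.copy()
            lines.append(df.to_string(float_format=lambda v: f"{v:.3f}"))
        if self.qss:
            lines.append("")
            lines.append("Quasi sign-stability (prop. stable draws, mean max Re(lambda))")
            lines.append("-" * 64)
            for season, q in self.qss.items():
                lo, hi = q.ci95()
                lines.append(
                    f"{season:>10}: prop_stable={q.prop_stable:.3f} "
                    f"[{lo:.3f}, {hi:.3f}]  mean_max_eig={q.mean_max_eig:.3f} "
                    f"(n={q.n_draws})"
                )
        if self.null:
            lines.append("")
            lines.append("Null-model placement (curveball ensembles)")
            lines.append("-" * 64)
            for (season, metric), ens in self.null.items():
                lines.append(
                    f"{season:>10} {metric:>12}: empirical={ens.empirical:.3f} "
                    f"null 95% [{ens.ci95[0]:.3f}, {ens.ci95[1]:.3f}] "
                    f"within={'yes' if ens.within else 'NO'}"
                )
        if self.regressions is not None and len(self.regressions):
            lines.append("")
            lines.append("Int regressions across samples")
            lines.append("-" * 64)
            lines.append(
                self.regressions.to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                )
            )
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Machine-readable report bundle (JSON-serializable)."""
        report = {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "stages": list(self.stages),
            "seasons": list(self.study.seasons),
            "build_reports": {
                s: json.loads(r.to_json()) for s, r in self.build_reports.items()
            },
        }
        if self.metrics is not None:
            report["metrics"] = json.loads(
                self.metrics.reset_index().to_json(orient="records")
            )
        if self.qss:
            report["qss"] = {
                s: {
                    "n_draws": q.n_draws,
                    "prop_stable": q.prop_stable,
                    "mean_max_eig": q.mean_max_eig,
                    "ci95": list(q.ci95()),
                    "seed": q.seed,
                }
                for s, q in self.qss.items()
            }
        if self.null:
            report["null"] = [
                dict(ens.summary(), season=season)
                for (season, _m), ens in self.null.items()
            ]
        if self.ks is not None and len(self.ks):
            report["ks"] = json.loads(self.ks.to_json(orient="records"))
        if self.samples is not None:
            report["samples"] = json.loads(self.samples.to_json(orient="records"))
        if self.regressions is not None and len(self.regressions):
            report["regressions"] = json.loads(
                self.regressions.to_json(orient="records")
            )
        if self.correlations is not None:
            rho, p = self.correlations
            report["correlations"] = {
                "rho": json.loads(rho.to_json()),
                "p": json.loads(p.to_json()),
            }
        return report

    def save(self, outdir) -> None:
        """Write the report bundle: TSV tables plus one report.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.6g"
        if self.metrics is not None:
            self.metrics.to_csv(out / "metrics.tsv", sep="\t", float_format=fmt)
        if self.qss:
            rows = []
            for season, q in self.qss.items():
                lo, hi = q.ci95()
                rows.append(
                    {"label": season, "n_draws": q.n_draws,
                     "prop_stable": q.prop_stable, "mean_max_eig": q.mean_max_eig,
                     "ci95_low": lo, "ci95_high": hi, "seed": q.seed}
                )
            pd.DataFrame(rows).to_csv(
                out / "qss.tsv", sep="\t", index=False, float_format=fmt
            )
        for (season, metric), ens in self.null.items():
            pd.Series(ens.values, name=metric).to_csv(
                out / f"null_{season}_{metric}.tsv", sep="\t",
                index=False, float_format=fmt,
            )
        if self.ks is not None and len(self.ks):
            self.ks.to_csv(out / "ks.tsv", sep="\t", index=False, float_format=fmt)
        if self.samples is not None:
            self.samples.to_csv(
                out / "samples.tsv", sep="\t", index=False, float_format=fmt
            )
        if self.regressions is not None and len(self.regressions):
            self.regressions.to_csv(
                out / "regressions.tsv", sep="\t", index=False, float_format=fmt
            )
        if self.correlations is not None:
            rho, p = self.correlations
            rho.to_csv(out / "correlations_rho.tsv", sep="\t", float_format=fmt)
            p.to_csv(out / "correlations_p.tsv", sep="\t", float_format=fmt)
        (out / "report.json").write_text(
            json.dumps(self.to_report(), indent=2, sort_keys=True), encoding="utf-8"
        )

    # -- plotting --------------------------------------------------------
    def plot_null(self, season: str, metric: str, ax=None):
        """Histogram of a null ensemble with the empirical value marked."""
        import matplotlib.pyplot as plt

        ens = self.null[(season, metric)]
        if ax is None:
            _fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(ens.values, bins=30, color="steelblue", alpha=0.8)
        ax.axvline(ens.empirical, color="firebrick", lw=2)
        ax.annotate(
            f"{ens.empirical:.3g}",
            xy=(ens.empirical, ax.get_ylim()[1] * 0.9),
            color="firebrick",
        )
        ax.set_xlabel(metric)
        ax.set_ylabel("count")
        ax.set_title(f"{season}: {metric} null distribution")
        return ax

    def plot_regression(self, metric: str = "Mod", ax=None):
        """Scatter of a sub-network metric against Int with the OLS line."""
        import matplotlib.pyplot as plt

        if self.samples is None:
            raise ValueError("features stage was not run")
        if ax is None:
            _fig, ax = plt.subplots(figsize=(4, 3))
        x = self.samples["Int"].to_numpy(float)
        y = self.samples[metric].to_numpy(float)
        ax.scatter(x, y, s=18, color="steelblue")
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() >= 3 and np.ptp(x[m]) > 0:
            r = _features.regress_feature(x[m], y[m])
            xs = np.linspace(x[m].min(), x[m].max(), 20)
            ax.plot(xs, r.intercept + r.slope * xs, color="firebrick")
            ax.set_title(f"{metric} ~ Int (R$^2$={r.r_squared:.2f}, p={r.pvalue:.3g})")
        ax.set_xlabel("Int")
        ax.set_ylabel(metric)
        return ax
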