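"""Synthetic subalpine-lake community generator.

Emulates the processed level of a four-season survey: 9 water samples per
season, genus-level protist tables (18S-like), phylum-level bacterial
tables (16S-like), a guild annotation, and a literature-style
predator-prey catalog. Defaults are set so that the seasonal webs built
from the output land in the study's regime: 59-70 interacting nodes per
season, connectance roughly 0.12-0.19, a phototroph-dominated community
with bacterivores as the leading predator guild (45-78% of predators),
and standing aggregate compartments for algae, bacteria, fungi, detritus
and dissolved organic carbon.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .build import DEFAULT_AGGREGATES
from .io import (
    CommunityTable,
    InteractionCatalog,
    TaxonAnnotation,
    write_annotation,
    write_community_table,
    write_interaction_catalog,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "BACTERIAL_PHYLA",
    "generate_catalog",
    "generate_seasonal_dataset",
    "plant_association",
]

#: Phylum-level bacterial compartments resolved by the 16S table.
BACTERIAL_PHYLA = (
    "Proteobacteria",
    "Actinobacteriota",
    "Bacteroidota",
    "Cyanobacteria",
    "Verrucomicrobiota",
    "Planctomycetota",
    "Chloroflexi",
    "Acidobacteriota",
    "Firmicutes",
    "Patescibacteria",
    "Gemmatimonadota",
    "Myxococcota",
    "Bdellovibrionota",
    "Nitrospirota",
    "Desulfobacterota",
    "Armatimonadota",
    "Deinococcota",
)

_PHYLUM_BY_GUILD = {
    "P": ("Chlorophyta", "Ochrophyta", "Cryptophyta", "Haptophyta", "Dinoflagellata"),
    "B": ("Ciliophora", "Cercozoa"),
    "A": ("Ciliophora", "Dinoflagellata"),
    "N": ("Ciliophora", "Amoebozoa"),
    "R": ("Cercozoa", "Ciliophora"),
    "M": ("Cercozoa",),
    "S": ("Amoebozoa",),
    "H-P": ("Apicomplexa", "Perkinsea"),
    "U": ("Unclassified_Eukaryota",),
}

_CONSUMER_GUILDS = ("B", "A", "N", "R", "M", "S", "H-P")


@dataclass
class SyntheticConfig:
    """Tunable study conditions of the generator.

    ``richness`` counts detected protist genera per season; the built web
    additionally carries the five aggregate compartments, so the default
    targets give seasonal webs of 69/70/61/59 nodes. ``mean_prey`` sets
    the per-guild mean of the truncated-geometric prey-count draw;
    ``prey_count_fixed`` overrides it with an exact count per guild.
    """

    seasons: tuple = ("spring", "summer", "autumn", "winter")
    richness: tuple = (64, 65, 56, 54)
    samples_per_season: int = 9
    pool_size: int = 75
    bacterial_phyla: tuple = BACTERIAL_PHYLA
    guild_props: Dict[str, float] = field(
        default_factory=lambda: {
            "P": 0.34,
            "B": 0.32,
            "H-P": 0.06,
            "A": 0.09,
            "N": 0.08,
            "R": 0.05,
            "M": 0.02,
            "S": 0.02,
            "U": 0.02,
        }
    )
    secondary_guild_prob: float = 1.0
    mean_prey: Dict[str, float] = field(
        default_factory=lambda: {
            "B": 3.5,
            "A": 38.0,
            "N": 78.0,
            "R": 62.0,
            "M": 1.0,
            "S": 1.0,
            "H-P": 3.0,
        }
    )
    truncation_factor: float = 1.5
    prey_count_fixed: Dict[str, int] = field(default_factory=dict)
    presence_prob: float = 0.85
    effort_sd: float = 0.08
    bacterivore_effort_mult: float = 1.0
    bacteria_presence_prob: float = 0.9  # bulk phyla are near-ubiquitous
    lognormal_mu: float = 5.0
    lognormal_sigma: float = 1.2
    bacterivore_band: tuple = (0.45, 0.78)
    aggregates: tuple = DEFAULT_AGGREGATES

    def validate(self):
        if len(self.richness) != len(self.seasons):
            raise ValueError("one richness target per season required")
        if max(self.richness) > self.pool_size:
            raise ValueError("richness target exceeds genus pool size")
        if abs(sum(self.guild_props.values()) - 1.0) > 1e-9:
            raise ValueError("guild proportions must sum to 1")
        n_b = round(self.guild_props.get("B", 0) * self.pool_size)
        if n_b > self.pool_size:
            raise ValueError("more bacterivore genera than genus budget")


def _apportion(total: int, props: Mapping[str, float]) -> Dict[str, int]:
    """Largest-remainder apportionment of ``total`` by proportions."""
    keys = list(props)
    raw = np.array([props[k] * total for k in keys])
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def _trunc_geometric(
    rng: np.random.Generator, mean: float, max_k: int, factor: float = 1.5
) -> int:
    """Truncated geometric prey-count draw.

    Geometric with the given untruncated mean, truncated both at the prey
    class size and at ``factor * mean`` — generalist diets vary, but no
    predator's diet explodes to several times the guild norm.
    """
    if max_k < 1:
        raise ValueError("no available prey")
    p = min(1.0, 1.0 / max(mean, 1.0))
    cap = min(max_k, max(1, int(np.ceil(factor * mean))))
    return int(min(rng.geometric(p), cap))


def generate_catalog(
    guild_table: Mapping[str, frozenset],
    bacterial_phyla: Sequence[str],
    rng: np.random.Generator,
    mean_prey: Optional[Mapping[str, float]] = None,
    prey_count_fixed: Optional[Mapping[str, int]] = None,
    truncation_factor: float = 1.5,
) -> InteractionCatalog:
    """Draw a predator-prey catalog from guild semantics.

    Prey classes per guild: bacterivores (B) graze bacterial phyla and the
    bulk bacteria compartment; algivores (A) eat phototroph genera and the
    algae compartment; mycophagous (M) eat fungi; saprotrophs (S) feed on
    detritus; raptors (R) prey on other protist genera; nonselective
    omnivores (N) may take any node class; heterotrophic parasites (H-P)
    attach to host genera as predators; phototrophs (P) and unknowns (U)
    consume nothing. The bacteria compartment takes up dissolved organic
    carbon. Per-predator prey counts follow a truncated geometric law; a
    ``mean_prey`` entry below 1 is read as a fraction of the guild's prey
    class size, so diet breadth scales with the richness on offer.
    """
    cfg_mean = dict(SyntheticConfig().mean_prey)
    if mean_prey:
        cfg_mean.update(mean_prey)
    fixed = dict(prey_count_fixed or {})
    genera = list(guild_table)
    phototrophs = [g for g in genera if "P" in guild_table[g]]
    edges = [("bacteria", "DOC", "guild-rule")]

    def prey_class(g: str, guild: str) -> list:
        if guild == "B":
            return list(bacterial_phyla) + ["bacteria"]
        if guild == "A":
            return [x for x in phototrophs if x != g] + ["algae"]
        if guild == "M":
            return ["fungi"]
        if guild == "S":
            return ["detritus"]
        if guild == "R":
            return [x for x in genera if x != g]
        if guild == "N":
            return [x for x in genera if x != g] + [
                "algae",
                "bacteria",
                "fungi",
                "detritus",
            ]
        if guild == "H-P":
            return [x for x in genera if x != g and "H-P" not in guild_table[x]]
        return []

    for g in genera:
        for guild in _CONSUMER_GUILDS:
            if guild not in guild_table[g]:
                continue
            cls = prey_class(g, guild)
            if not cls:
                raise ValueError(
                    f"guild {guild!r} of genus {g!r} has no available prey class"
                )
            if guild in fixed:
                k = min(int(fixed[guild]), len(cls))
            else:
                mean = cfg_mean.get(guild, 2.0)
                if mean < 1.0:
                    mean = max(1.0, mean * len(cls))
                k = _trunc_geometric(rng, mean, len(cls), truncation_factor)
            if guild == "B":
                # every bacterivore grazes the bulk pool; the remaining
                # diet picks out its preferred phyla
                rest = [c for c in cls if c != "bacteria"]
                picks = rng.choice(len(rest), size=min(k - 1, len(rest)), replace=False)
                chosen = ["bacteria"] + [rest[int(c)] for c in picks]
            else:
                chosen = [cls[int(c)] for c in rng.choice(len(cls), size=k, replace=False)]
            for c in chosen:
                edges.append((g, c, f"guild-rule:{guild}"))
    return InteractionCatalog(edges)


@dataclass
class SyntheticDataset:
    """All artifacts of one synthetic study, plus provenance."""

    protist_tables: Dict[str, CommunityTable]
    bacteria_tables: Dict[str, CommunityTable]
    annotation: Dict[str, TaxonAnnotation]
    catalog: InteractionCatalog
    environment: pd.DataFrame
    config: SyntheticConfig
    seed: int

    @property
    def seasons(self) -> tuple:
        return self.config.seasons

    def protist_table(self) -> CommunityTable:
        """All 36 samples merged into one community table."""
        tables = [self.protist_tables[s] for s in self.seasons]
        return CommunityTable(
            sum((t.sample_ids for t in tables), []),
            list(tables[0].taxon_ids),
            np.vstack([t.counts for t in tables]),
            sum((t.seasons for t in tables), []),
        )

    def bacteria_table(self) -> CommunityTable:
        tables = [self.bacteria_tables[s] for s in self.seasons]
        return CommunityTable(
            sum((t.sample_ids for t in tables), []),
            list(tables[0].taxon_ids),
            np.vstack([t.counts for t in tables]),
            sum((t.seasons for t in tables), []),
        )

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        return {"seed": self.seed, "config": cfg, "seasons": list(self.seasons)}

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_community_table(self.protist_table(), out / "protist_counts.tsv")
        write_community_table(self.bacteria_table(), out / "bacteria_counts.tsv")
        write_annotation(self.annotation, out / "annotation.tsv")
        write_interaction_catalog(self.catalog, out / "catalog.tsv")
        self.environment.to_csv(out / "environment.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True), encoding="utf-8"
        )


def _assign_guilds(cfg: SyntheticConfig, rng: np.random.Generator):
    """Genus pool with primary + optional secondary guild memberships."""
    counts = _apportion(cfg.pool_size, cfg.guild_props)
    genera, primary = [], []
    i = 0
    for guild, n in counts.items():
        for _ in range(n):
            genera.append(f"g{i:03d}")
            primary.append(guild)
            i += 1
    guilds = {}
    for g, pg in zip(genera, primary):
        gs = {pg}
        # eukaryvorous consumers often hold a second broad feeding mode;
        # bacterivores stay specialist grazers of the bacterial pool
        if pg in ("A", "N", "R") and rng.random() < cfg.secondary_guild_prob:
            extra = [x for x in ("A", "N", "R") if x != pg]
            gs.add(extra[int(rng.integers(len(extra)))])
        guilds[g] = frozenset(gs)
    return genera, dict(zip(genera, primary)), guilds


def _season_subsets(cfg, genera, primary, rng):
    """Stratified per-season genus subsets hitting richness targets exactly."""
    by_guild: Dict[str, list] = {}
    for g in genera:
        by_guild.setdefault(primary[g], []).append(g)
    subsets = {}
    for season, target in zip(cfg.seasons, cfg.richness):
        quota = _apportion(target, {k: len(v) / len(genera) for k, v in by_guild.items()})
        chosen = []
        for guild, members in by_guild.items():
            k = min(quota.get(guild, 0), len(members))
            picks = rng.choice(len(members), size=k, replace=False)
            chosen.extend(members[int(p)] for p in picks)
        # top up if rounding or capping left us short
        short = target - len(chosen)
        if short > 0:
            rest = [g for g in genera if g not in chosen]
            picks = rng.choice(len(rest), size=short, replace=False)
            chosen.extend(rest[int(p)] for p in picks)
        subsets[season] = sorted(chosen)
    return subsets


def _patch_isolates(cfg, catalog, guilds, subsets, rng) -> InteractionCatalog:
    """Guarantee every detected genus has an in-season trophic partner."""
    edges = list(catalog.edges)
    pairs = {(p, q) for p, q, _ in edges}

    def add(pred, prey):
        if (pred, prey) not in pairs and pred != prey:
            edges.append((pred, prey, "patch"))
            pairs.add((pred, prey))

    agg = set(cfg.aggregates)
    for season, detected in subsets.items():
        dset = set(detected) | agg
        linked = set()
        for p, q in pairs:
            if p in dset and q in dset:
                linked.add(p)
                linked.add(q)
        for g in detected:
            if g in linked:
                continue
            gset = guilds[g]
            if "B" in gset:
                add(g, "bacteria")
            elif "A" in gset:
                add(g, "algae")
            elif "M" in gset:
                add(g, "fungi")
            elif "S" in gset:
                add(g, "detritus")
            elif "N" in gset:
                add(g, "bacteria")
            elif "R" in gset or "H-P" in gset:
                others = [x for x in detected if x != g]
                add(g, others[int(rng.integers(len(others)))])
            else:  # pure phototroph or unknown: give it an in-season grazer
                eaters = [
                    x
                    for x in detected
                    if x != g and (guilds[x] & {"A", "N", "R"})
                ]
                if not eaters:
                    raise ValueError(
                        f"season {season!r}: no consumer available to link {g!r}"
                    )
                add(eaters[int(rng.integers(len(eaters)))], g)
    return InteractionCatalog(edges)


def _abundance_table(
    cfg, season, sample_ids, columns, detected, rng, groups=None,
    effort=None, effort_mult=None,
) -> CommunityTable:
    """Presence-stratified log-normal abundances.

    ``groups`` maps each detected taxon to a stratum (here: primary guild
    crossed with a bin of catalog-degree neighbours), and presence is
    drawn per stratum so each sample's guild mix and link budget stay
    balanced. A per-sample detection-effort multiplier ``effort`` moves
    every stratum's retention up or down together — emulating uneven
    sequencing depth — and ``effort_mult`` lets a stratum respond more
    strongly to that shared gradient.
    """
    n, m = len(sample_ids), len(columns)
    col_index = {c: j for j, c in enumerate(columns)}
    detected = list(detected)
    if groups is None:
        strata = {"": detected}
    else:
        strata = {}
        for taxon in detected:
            strata.setdefault(groups.get(taxon, ""), []).append(taxon)
    if effort is None:
        effort = np.ones(n)
    presence = np.zeros((n, m), dtype=bool)
    for key, members in strata.items():
        mult = 1.0 if effort_mult is None else effort_mult.get(key, 1.0)
        jcols = [col_index[t] for t in members]
        for i in range(n):
            p_i = float(np.clip(
                cfg.presence_prob * (1.0 - mult * (1.0 - effort[i])), 0.05, 1.0
            ))
            target = p_i * len(jcols)
            k = int(target) + (1 if rng.random() < target - int(target) else 0)
            k = min(max(k, 0), len(jcols))
            if k == 0:
                continue
            picks = rng.choice(len(jcols), size=k, replace=False)
            for p in picks:
                presence[i, jcols[int(p)]] = True
    # every detected taxon must surface in at least one sample
    for taxon in detected:
        j = col_index[taxon]
        if not presence[:, j].any():
            presence[int(rng.integers(n)), j] = True
    vals = np.round(
        np.exp(rng.normal(cfg.lognormal_mu, cfg.lognormal_sigma, size=(n, m)))
    )
    counts = np.where(presence, np.maximum(vals, 1.0), 0.0)
    return CommunityTable(list(sample_ids), list(columns), counts, [season] * n)


def generate_seasonal_dataset(
    seed: int, config: Optional[SyntheticConfig] = None
) -> SyntheticDataset:
    """Generate the full four-season study from one seed.

    Per-season detected-genus counts hit the configured richness targets
    exactly; the guild mix follows the configured proportions with
    phototrophs dominant and bacterivores the leading predator guild; a
    single global catalog covers all genera, patched so no detected genus
    is trophically isolated in its season.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    genera, primary, guilds = _assign_guilds(cfg, rng)
    subsets = _season_subsets(cfg, genera, primary, rng)
    catalog = generate_catalog(
        guilds,
        cfg.bacterial_phyla,
        rng,
        mean_prey=cfg.mean_prey,
        prey_count_fixed=cfg.prey_count_fixed,
        truncation_factor=cfg.truncation_factor,
    )
    catalog = _patch_isolates(cfg, catalog, guilds, subsets, rng)

    annotation: Dict[str, TaxonAnnotation] = {}
    for g in genera:
        pool = _PHYLUM_BY_GUILD.get(primary[g], ("Unclassified_Eukaryota",))
        phylum = pool[int(rng.integers(len(pool)))]
        annotation[g] = TaxonAnnotation("protist", phylum, guilds[g])
    for ph in cfg.bacterial_phyla:
        annotation[ph] = TaxonAnnotation("bacteria", ph, frozenset())

    # stratify per-sample presence by guild x catalog-degree tercile so a
    # sample's guild mix and link budget stay balanced across samples
    degree: Dict[str, int] = {g: 0 for g in genera}
    for p, q, _ in catalog:
        for end in (p, q):
            if end in degree:
                degree[end] += 1

    protist_tables, bacteria_tables, env_rows = {}, {}, []
    season_temp = dict(zip(cfg.seasons, (12.0, 22.0, 10.0, 2.0)))
    for season in cfg.seasons:
        sample_ids = [
            f"{season}_{k+1:02d}" for k in range(cfg.samples_per_season)
        ]
        by_guild: Dict[str, list] = {}
        for g in subsets[season]:
            by_guild.setdefault(primary[g], []).append(g)
        strata = {}
        effort_mult = {}
        for guild, members in by_guild.items():
            ranked = sorted(members, key=lambda g: (degree[g], g))
            n_bins = max(1, len(ranked) // 2)
            for b in range(n_bins):
                key = f"{guild}:{b}"
                for g in ranked[b::n_bins]:
                    strata[g] = key
                # bacterivore detection responds more steeply to effort:
                # their counts fall faster in shallow samples, which keeps
                # the bacterivory share orthogonal to the effort gradient
                effort_mult[key] = (
                    cfg.bacterivore_effort_mult if guild == "B" else 1.0
                )
        effort = np.clip(
            1.0 + cfg.effort_sd * rng.standard_normal(len(sample_ids)), 0.7, 1.15
        )
        protist_tables[season] = _abundance_table(
            cfg, season, sample_ids, genera, subsets[season], rng,
            groups=strata, effort=effort, effort_mult=effort_mult,
        )
        # bacterial phyla are broadly present in every season
        det_phyla = list(cfg.bacterial_phyla)
        bcfg = copy.copy(cfg)
        bcfg.presence_prob = cfg.bacteria_presence_prob
        bacteria_tables[season] = _abundance_table(
            bcfg, season, sample_ids, list(cfg.bacterial_phyla), det_phyla, rng
        )
        base_t = season_temp.get(season, 10.0)
        for sid in sample_ids:
            env_rows.append(
                {
                    "sample_id": sid,
                    "season": season,
                    "temperature": round(base_t + rng.normal(0, 1.5), 2),
                    "pH": round(8.0 + rng.normal(0, 0.2), 2),
                    "DO": round(9.0 + rng.normal(0, 1.0), 2),
                    "NH4": round(max(0.01, 0.2 + rng.normal(0, 0.05)), 3),
                }
            )
    return SyntheticDataset(
        protist_tables=protist_tables,
        bacteria_tables=bacteria_tables,
        annotation=annotation,
        catalog=catalog,
        environment=pd.DataFrame(env_rows),
        config=cfg,
        seed=seed,
    )


@dataclass
class PlantedEffect:
    """A per-sample feature-metric association to plant into a dataset."""

    feature: str = "Int"
    metric: str = "Mod"
    sign: int = 1
    strength: float = 0.6


def plant_association(
    dataset: SyntheticDataset,
    effect: PlantedEffect,
    rng: np.random.Generator,
) -> SyntheticDataset:
    """Perturb per-sample presence so feature and metric co-vary as requested.

    A latent gradient ``t`` per sample tilts each sample's guild balance:
    high-``t`` samples keep their bacterivores and shed broad-diet
    generalists (nonselective omnivores and raptors), raising the sample
    sub-network's bacterivory share ``Int`` while thinning its link count
    and letting its modules separate; low-``t`` samples do the opposite.
    The ``sign``/``metric`` pair only chooses the orientation of the
    gradient; ``strength`` in [0, 1] scales the presence perturbation,
    with 0 leaving the dataset untouched. No genus is ever removed from
    all samples of its season, so detected richness is preserved.
    """
    if effect.feature != "Int":
        raise ValueError(f"unknown feature {effect.feature!r}")
    if effect.metric not in ("Mod", "L", "LD", "C"):
        raise ValueError(f"unknown metric {effect.metric!r}")
    if effect.sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    if effect.strength < 0:
        raise ValueError("strength must be nonnegative")
    out = copy.deepcopy(dataset)
    if effect.strength == 0:
        return out
    # guild-count channels: more bacterivores raise Int and knit the dense
    # bacterivore-bacteria block (Mod up); more generalists add links
    # across the whole web (L, LD, C up, Mod down)
    natural = 1 if effect.metric == "Mod" else -1
    flip = effect.sign * natural  # +1: use t as drawn, -1: reverse it
    ann = out.annotation
    beta = 0.9  # maximal drop fraction at strength 1
    for season, table in out.protist_tables.items():
        n = len(table.sample_ids)
        t = rng.random(n)
        if flip < 0:
            t = 1.0 - t
        bacteriv = [
            j
            for j, g in enumerate(table.taxon_ids)
            if g in ann and "B" in ann[g].guilds
        ]
        generalists = [
            j
            for j, g in enumerate(table.taxon_ids)
            if g in ann and (ann[g].guilds & {"N", "R"}) and "B" not in ann[g].guilds
        ]
        counts = table.counts
        # one protected sample per genus keeps season-level detection intact
        protected = {}
        for j in set(bacteriv) | set(generalists):
            present = np.flatnonzero(counts[:, j] > 0)
            if len(present):
                protected[j] = int(present[int(rng.integers(len(present)))])
        for cols, frac_drop in (
            (bacteriv, beta * effect.strength * (1.0 - t)),
            (generalists, beta * effect.strength * t),
        ):
            for i in range(n):
                present = [j for j in cols if counts[i, j] > 0 and protected.get(j) != i]
                n_drop = int(round(frac_drop[i] * len(present)))
                if n_drop <= 0:
                    continue
                picks = rng.choice(len(present), size=n_drop, replace=False)
                for p in picks:
                    counts[i, present[int(p)]] = 0.0
    return out
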