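"""Seasonal food-web construction from detected taxa, annotations and a catalog.

One web per season: the genera detected in that season's samples become
genus nodes, the requested aggregate compartments (algae, bacteria, fungi,
detritus, DOC) become standing nodes, and every catalog edge whose two
endpoints are present is kept. Aggregate nodes stay even when isolated;
genus nodes without a single trophic link are dropped so that the species
count S is a count of interacting trophic species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Set

import numpy as np

from .io import (
    AGGREGATE_COMPARTMENTS,
    CommunityTable,
    FoodWeb,
    InteractionCatalog,
    TaxonAnnotation,
    TaxonNode,
)

__all__ = [
    "DEFAULT_AGGREGATES",
    "BuildReport",
    "detected_taxa",
    "make_aggregate_node",
    "build_web",
    "GuildPartition",
    "guild_partition",
    "validate_bundle",
]

DEFAULT_AGGREGATES = ("algae", "bacteria", "fungi", "detritus", "DOC")


def detected_taxa(table: CommunityTable, season: str, min_count: int = 1) -> set:
    """Taxa whose summed counts over the season's samples reach ``min_count``.

    ``min_count`` defaults to 1, i.e. presence anywhere in the season.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    samples = table.samples_in(season)  # raises KeyError on unknown season
    rows = [table.sample_ids.index(s) for s in samples]
    totals = table.counts[rows].sum(axis=0)
    return {t for t, v in zip(table.taxon_ids, totals) if v >= min_count}


def make_aggregate_node(compartment: str) -> TaxonNode:
    """Standing single-node compartment (algae, bacteria, fungi, detritus, DOC)."""
    if compartment not in AGGREGATE_COMPARTMENTS:
        raise ValueError(f"not an aggregate compartment: {compartment!r}")
    return TaxonNode(
        node_id=compartment,
        name=compartment,
        kind="aggregate",
        compartment=compartment,
    )


@dataclass
class BuildReport:
    """Provenance of one web construction."""

    label: str
    n_nodes: int              # total S, aggregates included
    n_genus_nodes: int        # S counting genus nodes only
    n_links: int
    n_excluded_edges: int
    excluded_edges: list = field(default_factory=list)
    dropped_isolated_genera: list = field(default_factory=list)
    guild_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d, indent=2, sort_keys=True)


def build_web(
    taxa: Set[str],
    annotation: Mapping[str, TaxonAnnotation],
    catalog: InteractionCatalog,
    aggregates: Iterable[str] = DEFAULT_AGGREGATES,
    label: str = "",
):
    """Assemble a :class:`FoodWeb` from detected taxa and the catalog.

    Returns ``(web, report)``. Catalog edges with an endpoint neither
    detected nor a requested aggregate are excluded and tallied in the
    report — literature catalogs routinely reference taxa absent from a
    given season. A zero-node result raises ``ValueError``.
    """
    aggregates = list(dict.fromkeys(aggregates))
    for a in aggregates:
        if a not in AGGREGATE_COMPARTMENTS:
            raise ValueError(f"unknown aggregate compartment {a!r}")
    nodes: dict = {}
    for a in aggregates:
        nodes[a] = make_aggregate_node(a)
    unannotated = sorted(t for t in taxa if t not in annotation and t not in nodes)
    if unannotated:
        raise ValueError(f"detected taxa missing from annotation: {unannotated[:5]}")
    for t in sorted(taxa):
        if t in nodes:
            continue
        ann = annotation[t]
        kind = "genus" if ann.compartment == "protist" else "aggregate"
        nodes[t] = TaxonNode(
            node_id=t,
            name=t,
            kind=kind,
            compartment=ann.compartment,
            phylum=ann.phylum,
            guilds=ann.guilds,
        )
    present = set(nodes)
    kept, excluded = [], []
    for pred, prey, prov in catalog:
        if pred in present and prey in present:
            kept.append((pred, prey))
        else:
            excluded.append((pred, prey))
    # drop genus nodes with no trophic link at all; aggregates always stay
    linked = {e for pair in kept for e in pair}
    ordered = [
        n
        for n in nodes.values()
        if n.kind == "aggregate" or n.node_id in linked
    ]
    dropped = sorted(
        n.node_id for n in nodes.values() if n.kind != "aggregate" and n.node_id not in linked
    )
    if not ordered:
        raise ValueError(f"web {label!r}: construction produced zero nodes")
    index = {n.node_id: k for k, n in enumerate(ordered)}
    S = len(ordered)
    A = np.zeros((S, S), dtype=np.int8)
    for pred, prey in kept:
        A[index[prey], index[pred]] = 1  # prey row, predator column
    web = FoodWeb(ordered, A, label=label)
    guild_counts: dict = {}
    for n in ordered:
        for g in n.guilds:
            guild_counts[g] = guild_counts.get(g, 0) + 1
    n_agg = sum(1 for n in ordered if n.kind == "aggregate")
    report = BuildReport(
        label=label,
        n_nodes=S,
        n_genus_nodes=S - n_agg,
        n_links=web.L,
        n_excluded_edges=len(excluded),
        excluded_edges=excluded,
        dropped_isolated_genera=dropped,
        guild_counts=guild_counts,
    )
    return web, report


@dataclass
class GuildPartition:
    """Web nodes grouped by trophic guild, with predator bookkeeping.

    ``predator_share[g]`` is the fraction of distinct predators (nodes with
    at least one prey) carrying guild ``g``; a multi-guild predator counts
    once in each of its guilds, so shares need not sum to one.
    """

    by_guild: dict
    predators: set
    predator_share: dict


def guild_partition(web: FoodWeb) -> GuildPartition:
    by_guild: dict = {}
    for n in web.nodes:
        for g in n.guilds:
            by_guild.setdefault(g, set()).add(n.node_id)
    n_prey = web.n_prey()
    predators = {n.node_id for n, k in zip(web.nodes, n_prey) if k > 0}
    share = {}
    if predators:
        for g, members in by_guild.items():
            share[g] = len(members & predators) / len(predators)
    return GuildPartition(by_guild=by_guild, predators=predators, predator_share=share)


def validate_bundle(
    tables: Iterable[CommunityTable],
    annotation: Mapping[str, TaxonAnnotation],
    catalog: InteractionCatalog,
    aggregates: Iterable[str] = DEFAULT_AGGREGATES,
) -> list:
    """Cross-file referential integrity check before any computation.

    Returns a list of human-readable problem strings (empty when the
    bundle is consistent).
    """
    problems = []
    agg = set(aggregates)
    known = set(annotation) | agg
    for ti, table in enumerate(tables):
        for t in table.taxon_ids:
            if t not in known:
                problems.append(f"community table {ti}: taxon {t!r} not annotated")
    for pred, prey, _ in catalog:
        for end in (pred, prey):
            if end not in known:
                problems.append(f"catalog: endpoint {end!r} not annotated")
    for tid, ann in annotation.items():
        if ann.compartment == "protist" and not ann.guilds:
            problems.append(f"annotation: protist {tid!r} has no guild")
    return problems
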