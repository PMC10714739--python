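"""Domain types and tab-separated readers/writers for food-web inputs.

The package exchanges four kinds of flat files, all UTF-8 TSV with
``#``-prefixed comment lines ignored:

* community tables (samples x taxa counts, with a per-sample season label),
* taxon annotations (compartment, phylum, trophic guilds),
* predator-prey interaction catalogs (edge lists),
* food-web serializations (a node-table / edge-list file pair).

Adjacency convention
--------------------
A :class:`FoodWeb` stores a binary matrix ``a`` where ``a[i, j] = 1`` means
taxon *j* preys on taxon *i* — prey on the rows, predators on the columns.
Energy flows from row to column. Every routine that reads the matrix
documents which direction it walks.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GUILD_CODES",
    "AGGREGATE_COMPARTMENTS",
    "COMPARTMENTS",
    "TaxonNode",
    "TaxonAnnotation",
    "InteractionCatalog",
    "FoodWeb",
    "CommunityTable",
    "ParseError",
    "read_community_table",
    "write_community_table",
    "read_annotation",
    "write_annotation",
    "read_interaction_catalog",
    "write_interaction_catalog",
    "read_web",
    "write_web",
]

#: Trophic guild codes: algivore, bacterivore, mycophagous, nonselective
#: omnivore, heterotrophic parasite, phototroph, raptor, saprotroph, unknown.
GUILD_CODES = frozenset({"A", "B", "M", "N", "H-P", "P", "R", "S", "U"})

#: Compartments that enter a web as a single aggregate node.
AGGREGATE_COMPARTMENTS = frozenset({"algae", "bacteria", "fungi", "detritus", "DOC"})

COMPARTMENTS = frozenset({"protist"}) | AGGREGATE_COMPARTMENTS

#: Non-living compartments; their nodes carry no guild.
_NONLIVING = frozenset({"detritus", "DOC"})


class ParseError(ValueError):
    """Raised when an input file violates its documented format."""


def _check_guilds(guilds: Iterable[str], where: str) -> frozenset:
    gset = frozenset(guilds)
    bad = gset - GUILD_CODES
    if bad:
        raise ParseError(
            f"{where}: unknown guild code(s) {sorted(bad)}; "
            f"expected codes among {sorted(GUILD_CODES)}"
        )
    return gset


@dataclass(frozen=True)
class TaxonNode:
    """One web node: a genus-level taxon or an aggregate compartment.

    Parameters
    ----------
    node_id : str
        Short unique identifier within a web.
    name : str
        Free-text display name.
    kind : {"genus", "aggregate"}
        Aggregate nodes stand for a whole compartment (algae, bacteria,
        fungi, detritus, DOC); genus nodes are individual protist genera.
    compartment : str
        One of ``protist``, ``algae``, ``bacteria``, ``fungi``,
        ``detritus``, ``DOC``.
    phylum : str
        Phylum lineage, empty when unknown or meaningless.
    guilds : frozenset of str
        Trophic guild codes; a genus may belong to several guilds.
    """

    node_id: str
    name: str = ""
    kind: str = "genus"
    compartment: str = "protist"
    phylum: str = ""
    guilds: frozenset = frozenset()

    def __post_init__(self):
        if not self.node_id:
            raise ValueError("node_id must be non-empty")
        if self.kind not in ("genus", "aggregate"):
            raise ValueError(f"node {self.node_id!r}: bad kind {self.kind!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"node {self.node_id!r}: bad compartment {self.compartment!r}"
            )
        # aggregate <=> non-protist compartment
        if (self.kind == "aggregate") != (self.compartment in AGGREGATE_COMPARTMENTS):
            raise ValueError(
                f"node {self.node_id!r}: kind {self.kind!r} inconsistent with "
                f"compartment {self.compartment!r}"
            )
        object.__setattr__(self, "guilds", _check_guilds(self.guilds, f"node {self.node_id!r}"))
        if self.compartment in _NONLIVING and self.guilds:
            raise ValueError(f"node {self.node_id!r}: {self.compartment} nodes carry no guild")


class TaxonAnnotation(NamedTuple):
    """Annotation record: compartment, phylum and guild set for one taxon."""

    compartment: str
    phylum: str
    guilds: frozenset


@dataclass
class InteractionCatalog:
    """Literature-compiled predator-prey edge list.

    Edges are ``(predator_id, prey_id, provenance)`` triples, deduplicated
    on the (predator, prey) pair. Cannibalistic self-loops are rejected.
    """

    edges: list = field(default_factory=list)

    def __post_init__(self):
        seen = {}
        cleaned = []
        for edge in self.edges:
            pred, prey = edge[0], edge[1]
            prov = edge[2] if len(edge) > 2 else ""
            if pred == prey:
                raise ValueError(f"self-loop {pred!r} -> {prey!r} not allowed")
            if (pred, prey) in seen:
                continue
            seen[(pred, prey)] = True
            cleaned.append((pred, prey, prov))
        self.edges = cleaned

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator:
        return iter(self.edges)

    def pairs(self) -> set:
        """Set of (predator_id, prey_id) pairs, order-independent identity."""
        return {(p, q) for p, q, _ in self.edges}

    def taxa(self) -> set:
        """All endpoint ids appearing in the catalog."""
        out = set()
        for p, q, _ in self.edges:
            out.add(p)
            out.add(q)
        return out

    def merged(self, other: "InteractionCatalog") -> "InteractionCatalog":
        return InteractionCatalog(self.edges + list(other.edges))


class FoodWeb:
    """Binary directed trophic network with an ordered node registry.

    ``adjacency[i, j] = 1`` means node ``j`` preys on node ``i``: each
    node's prey are found down its *column*, its predators along its *row*.
    """

    def __init__(self, nodes: Sequence[TaxonNode], adjacency, label: str = ""):
        nodes = list(nodes)
        A = np.asarray(adjacency, dtype=np.int8)
        S = len(nodes)
        if A.shape != (S, S):
            raise ValueError(f"adjacency shape {A.shape} != ({S}, {S})")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if S and np.diagonal(A).any():
            raise ValueError("adjacency diagonal must be zero (no cannibalism)")
        ids = [n.node_id for n in nodes]
        if len(set(ids)) != S:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate node ids: {dupes}")
        if A.sum() > 0 and not (A.sum(axis=0) == 0).any():
            raise ValueError("web with links must contain at least one basal node")
        self.nodes = nodes
        self.adjacency = A
        self.label = label
        self._index = {nid: k for k, nid in enumerate(ids)}

    # -- basic protocol -------------------------------------------------
    @property
    def S(self) -> int:
        return len(self.nodes)

    @property
    def L(self) -> int:
        return int(self.adjacency.sum())

    @property
    def node_ids(self) -> list:
        return [n.node_id for n in self.nodes]

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def node(self, node_id: str) -> TaxonNode:
        return self.nodes[self._index[node_id]]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __eq__(self, other) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return (
            self.label == other.label
            and self.nodes == other.nodes
            and np.array_equal(self.adjacency, other.adjacency)
        )

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<FoodWeb{lab} S={self.S} L={self.L}>"

    # -- trophic views ---------------------------------------------------
    def n_prey(self) -> np.ndarray:
        """Per-node prey counts (column sums: what each predator eats)."""
        return np.asarray(self.adjacency.sum(axis=0)).ravel()

    def n_predators(self) -> np.ndarray:
        """Per-node predator counts (row sums: who eats each node)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def basal_mask(self) -> np.ndarray:
        """True for nodes with no prey (primary resources)."""
        return self.n_prey() == 0

    def prey_of(self, node_id: str) -> list:
        j = self._index[node_id]
        return [self.nodes[i].node_id for i in np.flatnonzero(self.adjacency[:, j])]

    def predators_of(self, node_id: str) -> list:
        i = self._index[node_id]
        return [self.nodes[j].node_id for j in np.flatnonzero(self.adjacency[i, :])]

    def trophic_links(self) -> Iterator:
        """Yield (prey_id, predator_id) pairs, energy-flow direction."""
        for i, j in zip(*np.nonzero(self.adjacency)):
            yield self.nodes[i].node_id, self.nodes[j].node_id

    def to_networkx(self):
        """Directed graph with prey -> predator arcs (energy flow)."""
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.node_ids)
        G.add_edges_from(self.trophic_links())
        return G

    def to_undirected(self):
        """Symmetrized simple graph; trophic direction discarded."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.node_ids)
        G.add_edges_from(self.trophic_links())
        return G

    def subweb(self, node_ids: Iterable[str], label: str = "") -> "FoodWeb":
        """Induced sub-network on the given nodes (order preserved)."""
        keep = [self._index[n] for n in node_ids if n in self._index]
        keep.sort()
        idx = np.asarray(keep, dtype=int)
        nodes = [self.nodes[k] for k in keep]
        A = self.adjacency[np.ix_(idx, idx)] if len(keep) else np.zeros((0, 0), np.int8)
        return FoodWeb(nodes, A, label=label or self.label)

    def relabelled(self, order: Sequence[str]) -> "FoodWeb":
        """Same web with nodes permuted into the given id order."""
        if sorted(order) != sorted(self._index):
            raise ValueError("order must be a permutation of the node ids")
        idx = np.asarray([self._index[n] for n in order], dtype=int)
        return FoodWeb(
            [self.nodes[k] for k in idx],
            self.adjacency[np.ix_(idx, idx)],
            label=self.label,
        )


@dataclass
class CommunityTable:
    """Samples x taxa abundance table with a season label per sample."""

    sample_ids: list
    taxon_ids: list
    counts: np.ndarray
    seasons: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n, m = self.counts.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match counts rows")
        if len(self.taxon_ids) != m:
            raise ValueError("taxon_ids length does not match counts columns")
        if len(self.seasons) != n:
            raise ValueError("one season label required per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != m:
            raise ValueError("duplicate taxon ids")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )

    @property
    def shape(self):
        return self.counts.shape

    def season_labels(self) -> list:
        seen = []
        for s in self.seasons:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_in(self, season: str) -> list:
        if season not in self.seasons:
            raise KeyError(f"unknown season {season!r}; have {self.season_labels()}")
        return [sid for sid, s in zip(self.sample_ids, self.seasons) if s == season]

    def counts_for_sample(self, sample_id: str) -> np.ndarray:
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return self.counts[i]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)
        df.insert(0, "season", self.seasons)
        df.index.name = "sample_id"
        return df

    def restrict_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityTable(
            [self.sample_ids[i] for i in idx],
            list(self.taxon_ids),
            self.counts[idx],
            [self.seasons[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _read_tsv_lines(path) -> list:
    text = Path(path).read_text(encoding="utf-8")
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append((lineno, line.split("\t")))
    return rows


def _fmt(x) -> str:
    """Numeric formatting: integers verbatim, reals at 6 significant digits."""
    xf = float(x)
    if xf == int(xf) and abs(xf) < 1e15:
        return str(int(xf))
    return format(xf, ".6g")


def read_community_table(path) -> CommunityTable:
    """Read a samples x taxa TSV.

    Layout: header ``sample_id<TAB>season<TAB><taxon ids...>`` (the season
    column is optional), then one row per sample. Cells must be nonnegative
    numbers; empty cells are rejected.
    """
    rows = _read_tsv_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty community table")
    _, header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: header must name at least one taxon column")
    has_season = len(header) > 1 and header[1] == "season"
    taxa = header[2:] if has_season else header[1:]
    if not taxa:
        raise ParseError(f"{path}: no taxon columns in header")
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ParseError(f"{path}: duplicate taxon column(s) {dupes}")
    sample_ids, seasons, data = [], [], []
    for lineno, cells in rows[1:]:
        expected = len(taxa) + (2 if has_season else 1)
        if len(cells) != expected:
            raise ParseError(
                f"{path}:{lineno}: expected {expected} columns, got {len(cells)}"
            )
        sid = cells[0]
        season = cells[1] if has_season else ""
        values = cells[2:] if has_season else cells[1:]
        row = []
        for taxon, cell in zip(taxa, values):
            if cell == "":
                raise ParseError(f"{path}:{lineno}: empty cell in column {taxon!r}")
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {taxon!r}"
                ) from None
            if v < 0:
                raise ParseError(
                    f"{path}:{lineno}: negative count {cell} for sample {sid!r}, "
                    f"taxon {taxon!r}"
                )
            row.append(v)
        sample_ids.append(sid)
        seasons.append(season)
        data.append(row)
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample id(s) {dupes}")
    return CommunityTable(sample_ids, list(taxa), np.asarray(data, float), seasons)


def write_community_table(table: CommunityTable, path) -> None:
    buf = _io.StringIO()
    buf.write("sample_id\tseason\t" + "\t".join(table.taxon_ids) + "\n")
    for sid, season, row in zip(table.sample_ids, table.seasons, table.counts):
        buf.write(sid + "\t" + season + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_annotation(path) -> dict:
    """Read a taxon annotation TSV into ``{taxon_id: TaxonAnnotation}``.

    Columns: ``taxon_id``, ``compartment``, ``phylum``, ``guilds`` with
    guilds as semicolon-joined codes (empty allowed).
    """
    rows = _read_tsv_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty annotation table")
    start = 0
    if rows[0][1][0] == "taxon_id":
        start = 1
    out = {}
    for lineno, cells in rows[start:]:
        if len(cells) < 3 or len(cells) > 4:
            raise ParseError(f"{path}:{lineno}: expected 3-4 columns, got {len(cells)}")
        tid, compartment, phylum = cells[0], cells[1], cells[2]
        guilds_field = cells[3] if len(cells) == 4 else ""
        if tid in out:
            raise ParseError(f"{path}:{lineno}: duplicate taxon id {tid!r}")
        if compartment not in COMPARTMENTS:
            raise ParseError(
                f"{path}:{lineno}: unknown compartment {compartment!r} for {tid!r}"
            )
        codes = [g for g in guilds_field.split(";") if g]
        guilds = _check_guilds(codes, f"{path}:{lineno} taxon {tid!r}")
        out[tid] = TaxonAnnotation(compartment, phylum, guilds)
    return out


def write_annotation(annotation: Mapping[str, TaxonAnnotation], path) -> None:
    buf = _io.StringIO()
    buf.write("taxon_id\tcompartment\tphylum\tguilds\n")
    for tid, ann in annotation.items():
        buf.write(
            f"{tid}\t{ann.compartment}\t{ann.phylum}\t"
            + ";".join(sorted(ann.guilds))
            + "\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_interaction_catalog(path) -> InteractionCatalog:
    """Read a predator-prey edge list TSV.

    Columns: ``predator_id``, ``prey_id``, optional ``provenance``.
    Duplicate pairs are collapsed; a self-loop row is an error.
    """
    rows = _read_tsv_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty interaction catalog")
    start = 1 if rows[0][1][0] == "predator_id" else 0
    edges = []
    for lineno, cells in rows[start:]:
        if len(cells) < 2 or len(cells) > 3:
            raise ParseError(f"{path}:{lineno}: expected 2-3 columns, got {len(cells)}")
        pred, prey = cells[0], cells[1]
        prov = cells[2] if len(cells) == 3 else ""
        if pred == prey:
            raise ParseError(f"{path}:{lineno}: self-loop {pred!r} -> {prey!r}")
        edges.append((pred, prey, prov))
    return InteractionCatalog(edges)


def write_interaction_catalog(catalog: InteractionCatalog, path) -> None:
    buf = _io.StringIO()
    buf.write("predator_id\tprey_id\tprovenance\n")
    for pred, prey, prov in catalog.edges:
        buf.write(f"{pred}\t{prey}\t{prov}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _web_paths(path):
    base = Path(path)
    return base.with_suffix(base.suffix + ".nodes.tsv"), base.with_suffix(
        base.suffix + ".edges.tsv"
    )


def write_web(web: FoodWeb, path) -> None:
    """Serialize a web as a node-table / edge-list TSV pair.

    ``path`` is a base name: ``<path>.nodes.tsv`` and ``<path>.edges.tsv``
    are written. The web label is stored as a ``# label:`` comment.
    """
    nodes_path, edges_path = _web_paths(path)
    buf = _io.StringIO()
    buf.write(f"# label: {web.label}\n")
    buf.write("node_id\tname\tkind\tcompartment\tphylum\tguilds\n")
    for n in web.nodes:
        buf.write(
            f"{n.node_id}\t{n.name}\t{n.kind}\t{n.compartment}\t{n.phylum}\t"
            + ";".join(sorted(n.guilds))
            + "\n"
        )
    nodes_path.write_text(buf.getvalue(), encoding="utf-8")
    buf = _io.StringIO()
    buf.write("prey_id\tpredator_id\n")
    for prey, pred in web.trophic_links():
        buf.write(f"{prey}\t{pred}\n")
    edges_path.write_text(buf.getvalue(), encoding="utf-8")


def read_web(path) -> FoodWeb:
    """Inverse of :func:`write_web`; ``read_web(write_web(w)) == w``."""
    nodes_path, edges_path = _web_paths(path)
    label = ""
    for line in Path(nodes_path).read_text(encoding="utf-8").splitlines():
        if line.startswith("# label:"):
            label = line[len("# label:"):].strip()
            break
    rows = _read_tsv_lines(nodes_path)
    start = 1 if rows and rows[0][1][0] == "node_id" else 0
    nodes = []
    for lineno, cells in rows[start:]:
        if len(cells) != 6:
            raise ParseError(f"{nodes_path}:{lineno}: expected 6 columns")
        nid, name, kind, compartment, phylum, guilds_field = cells
        guilds = frozenset(g for g in guilds_field.split(";") if g)
        nodes.append(TaxonNode(nid, name, kind, compartment, phylum, guilds))
    index = {n.node_id: k for k, n in enumerate(nodes)}
    S = len(nodes)
    A = np.zeros((S, S), dtype=np.int8)
    erows = _read_tsv_lines(edges_path)
    estart = 1 if erows and erows[0][1][0] == "prey_id" else 0
    for lineno, cells in erows[estart:]:
        if len(cells) != 2:
            raise ParseError(f"{edges_path}:{lineno}: expected 2 columns")
        prey, pred = cells
        if prey not in index or pred not in index:
            missing = prey if prey not in index else pred
            raise ParseError(
                f"{edges_path}:{lineno}: edge endpoint {missing!r} not in node table"
            )
        A[index[prey], index[pred]] = 1
    return FoodWeb(nodes, A, label=label)
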