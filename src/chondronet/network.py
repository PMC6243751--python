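"""Signed regulatory-network data model, file I/O and edge-list utilities.

A :class:`RegulatoryNetwork` is a signed, weighted, directed graph over
genes/transcription factors.  The same object serves as simulator topology
(for the additive logical model), as gold standard (for ROC/PR evaluation)
and as the source of a prior sign matrix (for prior-weighted inference).
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NODE_CATEGORIES = ("growth_factor", "transcription_factor", "other")
SIGN_TO_RELATION = {1: "activates", -1: "inhibits"}
RELATION_TO_SIGN = {"activates": 1, "inhibits": -1}


# ---------------------------------------------------------------------------
# Name canonicalization
# ---------------------------------------------------------------------------

def _normalize(name: str) -> str:
    """Spelling-insensitive key: NFC-fold, lowercase, strip separators."""
    key = unicodedata.normalize("NFC", name).strip().lower()
    return key.replace("-", "").replace("_", "").replace(" ", "")


class NodeAliasTable:
    """Maps alternative gene-name spellings onto one canonical spelling.

    The growth-plate literature mixes spellings for the same factor
    (NF-κB/NFκB/NFkB, HIF-2α/HIF-α2/HIF-2a, δ-EF1/dEF1); the default table
    resolves all of them.  Alias sets must be pairwise disjoint and the
    mapping is idempotent: canonical names map to themselves.
    """

    def __init__(self, aliases: Mapping[str, Iterable[str]] | None = None):
        self._canonical: dict[str, str] = {}
        seen: dict[str, str] = {}
        for canonical, names in (aliases or {}).items():
            for name in list(names) + [canonical]:
                key = _normalize(name)
                if key in seen and seen[key] != canonical:
                    raise ValueError(
                        f"alias {name!r} claimed by both {seen[key]!r} and {canonical!r}"
                    )
                seen[key] = canonical
                self._canonical[key] = canonical

    def canonicalize(self, name: str) -> str:
        return self._canonical.get(_normalize(name), name.strip())


#: Growth-plate gene names with the Greek-letter variants used in the field.
DEFAULT_ALIASES = NodeAliasTable(
    {
        "NFκB": ["NF-κB", "NFkB", "NF-kB", "NFKB"],
        "HIF-2α": ["HIF-α2", "HIF-2a", "HIF2A", "Hifα2", "Epas1"],
        "δ-EF1": ["dEF1", "d-EF1", "delta-EF1", "deltaEF1", "δEF1", "Zeb1"],
        "ATF2": ["Atf2"],
        "STAT1": ["Stat1"],
        "MEF2C": ["Mef2c"],
        "CCND1": ["Ccnd1"],
        "Gli2": [],
        "Tcf7": [],
        "Runx2": [],
        "Sox9": [],
        "Dlx5": [],
        "Ets1": [],
    }
)


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Node:
    name: str
    category: str = "other"

    def __post_init__(self):
        if self.category not in NODE_CATEGORIES:
            object.__setattr__(self, "category", "other")


@dataclass(frozen=True)
class Edge:
    """One signed regulatory interaction source → target.

    ``kinetics`` partitions interactions into priority classes: *fast*
    reactions model protein-activity changes, *slow* ones transcription.
    """

    source: str
    target: str
    sign: int
    weight: float = 1.0
    kinetics: str = "slow"

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError(f"edge {self.source}->{self.target}: sign must be +1 or -1")
        if self.weight < 0:
            raise ValueError(f"edge {self.source}->{self.target}: weight must be >= 0")
        if self.kinetics not in ("fast", "slow"):
            raise ValueError(f"edge {self.source}->{self.target}: kinetics must be fast|slow")


@dataclass
class RegulatoryNetwork:
    """Validated signed directed graph with node categories.

    Node names are canonicalized through ``aliases`` at construction; at
    most one edge is allowed per ordered (source, target) pair and every
    edge endpoint must be a declared node.
    """

    nodes: list[Node]
    edges: list[Edge]
    aliases: NodeAliasTable = field(
        default_factory=lambda: DEFAULT_ALIASES, repr=False, compare=False
    )

    def __post_init__(self):
        canon = self.aliases.canonicalize
        self.nodes = [Node(canon(n.name), n.category) for n in self.nodes]
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate node names after canonicalization: {dupes}")
        known = set(names)
        new_edges: list[Edge] = []
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            e = replace(e, source=canon(e.source), target=canon(e.target))
            if e.source not in known or e.target not in known:
                missing = e.source if e.source not in known else e.target
                raise ValueError(f"edge {e.source}->{e.target}: undeclared node {missing!r}")
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise ValueError(f"duplicate edge for pair {e.source}->{e.target}")
            seen_pairs.add(pair)
            new_edges.append(e)
        self.edges = new_edges

    # -- accessors ---------------------------------------------------------
    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def category(self, name: str) -> str:
        name = self.aliases.canonicalize(name)
        for n in self.nodes:
            if n.name == name:
                return n.category
        raise KeyError(name)

    def edge_dict(self) -> dict[tuple[str, str], Edge]:
        return {(e.source, e.target): e for e in self.edges}

    def has_edge(self, source: str, target: str) -> bool:
        c = self.aliases.canonicalize
        return (c(source), c(target)) in self.edge_dict()

    def undirected_pairs(self) -> set[tuple[str, str]]:
        """Unordered non-self pairs covered by at least one edge."""
        return {
            canonical_pair(e.source, e.target)
            for e in self.edges
            if e.source != e.target
        }

    def to_adjacency(self, node_order: Sequence[str] | None = None) -> pd.DataFrame:
        """Signed weighted adjacency: entry (i, j) = sign·weight of edge i→j."""
        order = list(node_order) if node_order is not None else self.node_names
        adj = pd.DataFrame(0.0, index=order, columns=order)
        for e in self.edges:
            if e.source in adj.index and e.target in adj.columns:
                adj.loc[e.source, e.target] = e.sign * e.weight
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.name, category=n.category)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, weight=e.weight, kinetics=e.kinetics)
        return g


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Deterministic unordered-pair key: lexicographic order of the names."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Ranked edge lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedEdge:
    pair: tuple[str, str]
    direction: str  # "undirected" | "source_to_target"
    score: float
    rank: float


@dataclass
class RankedEdgeList:
    """Interactions sorted from most to least likely, with average-rank ties.

    ``pair`` is the canonical (lexicographic) node pair; for directed
    entries the regulator is ``pair[0]`` when direction is
    ``source_to_target`` on the ordered pair as stored in ``pair``.
    """

    entries: list[RankedEdge]

    def __post_init__(self):
        scores = [e.score for e in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("scores must be non-increasing with rank")
        keys = [(e.pair, e.direction) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("each (pair, direction) may appear at most once")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.pair[0],
                    "target": e.pair[1],
                    "direction": e.direction,
                    "score": e.score,
                    "rank": e.rank,
                }
                for e in self.entries
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RankedEdgeList":
        df = pd.read_csv(path, sep="\t")
        entries = [
            RankedEdge(
                (str(r.source), str(r.target)), str(r.direction), float(r.score), float(r.rank)
            )
            for r in df.itertuples()
        ]
        return cls(entries)


def average_ranks(scores: Sequence[float]) -> np.ndarray:
    """Competition-free ranks of descending scores; ties share the mean position."""
    from scipy.stats import rankdata

    return rankdata([-s for s in scores], method="average")


def ranked_list_from_scores(
    scored: Mapping[tuple[str, str], float], direction: str
) -> RankedEdgeList:
    """Build a RankedEdgeList: sort descending by score, lexicographic tie order."""
    items = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks = average_ranks([s for _, s in items])
    return RankedEdgeList(
        [RankedEdge(pair, direction, float(s), float(r)) for (pair, s), r in zip(items, ranks)]
    )


def collapse_undirected(ranking: RankedEdgeList) -> RankedEdgeList:
    """Collapse directed scores to undirected pairs, keeping the max score.

    An inferred interaction is read as an existence claim between the two
    components, so the stronger of the two directed scores represents the
    evidence for the pair.  Idempotent on already-undirected lists.
    """
    best: dict[tuple[str, str], float] = {}
    for e in ranking.entries:
        pair = canonical_pair(*e.pair)
        if pair not in best or e.score > best[pair]:
            best[pair] = e.score
    return ranked_list_from_scores(best, "undirected")


# ---------------------------------------------------------------------------
# Prior sign matrix
# ---------------------------------------------------------------------------

@dataclass
class PriorMatrix:
    """Square sign matrix: entry (i, j) ∈ {−1, 0, +1} is the known sign of
    regulation of column gene j by row gene i."""

    node_order: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        n = len(self.node_order)
        if self.values.shape != (n, n):
            raise ValueError("prior matrix must be square over node_order")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("prior entries must be in {-1, 0, +1}")

    def sign(self, source: str, target: str) -> int:
        i = self.node_order.index(source)
        j = self.node_order.index(target)
        return int(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_order, columns=self.node_order)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PriorMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("prior TSV must have identical row and column gene names")
        return cls(list(df.index), df.to_numpy())

    def to_network(self, aliases: NodeAliasTable | None = None) -> RegulatoryNetwork:
        """Interpret nonzero prior entries as a signed network (weight 1)."""
        nodes = [Node(n, "transcription_factor") for n in self.node_order]
        edges = []
        for i, src in enumerate(self.node_order):
            for j, tgt in enumerate(self.node_order):
                if self.values[i, j] != 0:
                    edges.append(Edge(src, tgt, int(self.values[i, j])))
        return RegulatoryNetwork(nodes, edges, aliases or NodeAliasTable())


def prior_from_network(
    net: RegulatoryNetwork, node_order: Sequence[str]
) -> PriorMatrix:
    """Sign matrix of the network restricted to ``node_order``."""
    canon = net.aliases.canonicalize
    order = [canon(n) for n in node_order]
    known = set(net.node_names)
    for name in order:
        if name not in known:
            raise ValueError(f"node {name!r} in node_order is absent from the network")
    values = np.zeros((len(order), len(order)), dtype=int)
    idx = {n: i for i, n in enumerate(order)}
    for e in net.edges:
        if e.source in idx and e.target in idx:
            values[idx[e.source], idx[e.target]] = e.sign
    return PriorMatrix(order, values)


def select_inference_nodes(net: RegulatoryNetwork) -> list[str]:
    """Transcription factors only, in declaration order.

    TFs are the nodes whose regulatory action is most directly reflected in
    transcript measurements, so inference is restricted to them.
    """
    tfs = [n.name for n in net.nodes if n.category == "transcription_factor"]
    if not tfs:
        raise ValueError("network contains no transcription-factor nodes; nothing to infer")
    return tfs


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_network(
    path: str | Path,
    format: str = "sif",
    aliases: NodeAliasTable | None = None,
    return_report: bool = False,
):
    """Read a network from SIF or TSV-adjacency text.

    SIF dialect: tab-separated ``source<TAB>relation<TAB>target`` with
    relation ∈ {activates, inhibits}; optional 4th/5th columns carry weight
    and kinetics.  Lines ``#node<TAB>name<TAB>category`` declare categories.
    The parse report (JSON-able dict) flags self-loops and counts records.
    """
    path = Path(path)
    aliases = aliases if aliases is not None else DEFAULT_ALIASES
    report: dict = {"path": str(path), "format": format, "n_records": 0, "self_loops": []}
    if format == "sif":
        nodes: dict[str, str] = {}
        edges: list[Edge] = []
        seen: set[tuple[str, str]] = set()
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#node":
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: malformed #node record")
                nodes[aliases.canonicalize(fields[1])] = fields[2]
                continue
            if fields[0].startswith("#"):
                continue
            if len(fields) not in (3, 4, 5):
                raise ValueError(f"{path}:{lineno}: expected 3-5 tab-separated fields")
            src, relation, tgt = fields[0], fields[1], fields[2]
            if relation not in RELATION_TO_SIGN:
                raise ValueError(
                    f"{path}:{lineno}: unknown sign tag {relation!r} (use activates|inhibits)"
                )
            src, tgt = aliases.canonicalize(src), aliases.canonicalize(tgt)
            if (src, tgt) in seen:
                raise ValueError(f"{path}: duplicate edge for pair {src}->{tgt}")
            seen.add((src, tgt))
            weight = float(fields[3]) if len(fields) >= 4 else 1.0
            kinetics = fields[4] if len(fields) == 5 else "slow"
            nodes.setdefault(src, "other")
            nodes.setdefault(tgt, "other")
            if src == tgt:
                report["self_loops"].append(src)
            edges.append(Edge(src, tgt, RELATION_TO_SIGN[relation], weight, kinetics))
            report["n_records"] += 1
        net = RegulatoryNetwork(
            [Node(n, c) for n, c in nodes.items()], edges, aliases
        )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [aliases.canonicalize(str(g)) for g in df.index]
        cols = [aliases.canonicalize(str(g)) for g in df.columns]
        if genes != cols:
            raise ValueError(f"{path}: adjacency row and column names differ")
        edges = []
        vals = df.to_numpy(dtype=float)
        for i, src in enumerate(genes):
            for j, tgt in enumerate(cols):
                v = vals[i, j]
                if v != 0.0:
                    if src == tgt:
                        report["self_loops"].append(src)
                    edges.append(Edge(src, tgt, 1 if v > 0 else -1, abs(v)))
                    report["n_records"] += 1
        net = RegulatoryNetwork([Node(g) for g in genes], edges, aliases)
    else:
        raise ValueError(f"unknown network format {format!r}")
    report["n_nodes"] = len(net.nodes)
    report["n_edges"] = len(net.edges)
    if return_report:
        return net, report
    return net


def write_network(net: RegulatoryNetwork, path: str | Path, format: str = "sif") -> None:
    path = Path(path)
    if format == "sif":
        lines = [
            f"#node\t{n.name}\t{n.category}" for n in net.nodes
        ] + [
            f"{e.source}\t{SIGN_TO_RELATION[e.sign]}\t{e.target}\t{e.weight:g}\t{e.kinetics}"
            for e in net.edges
        ]
        path.write_text("\n".join(lines) + "\n")
    elif format == "tsv":
        net.to_adjacency().to_csv(path, sep="\t", float_format="%.6g")
    else:
        raise ValueError(f"unknown network format {format!r}")


def write_parse_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, ensure_ascii=False) + "\n")
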