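"""Mass-difference reaction networks over molecular formulas.

Nodes are molecular formulas; an undirected edge links two formulas whose
elemental difference equals one of a predefined set of biochemical
transformations (phosphorylation = +HPO3, hexosylation = +C6H10O5, ...).
The network is first built from a *seed* universe of known metabolite
formulas; experimental formula candidates are then connected to it and
their connection degree serves as an evidence count for plausibility.

A default reaction table of common biochemical formula differences
(small-group transfers, conjugations and amino-acid residue additions)
ships with the package as an editable CSV; every network operation is
parameterized by the table actually supplied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np

from .formula import ElementRules, Formula

# Packed-integer encoding of count vectors for vectorized set membership:
# per-element bases comfortably exceed the largest count reachable below
# 800 Da (C<=66, H<=793, N<=57, O<=50, P<=25, S<=25).
_BASES = (128, 1024, 64, 64, 32, 32)


def _encode_counts(counts: np.ndarray) -> np.ndarray:
    """Pack (n, 6) non-negative count rows into unique int64 keys."""
    key = np.zeros(counts.shape[:-1], dtype=np.int64)
    for i, base in enumerate(_BASES):
        key = key * base + counts[..., i]
    return key


class ReactionTableError(ValueError):
    pass


class ReactionTable:
    """Named elemental differences used as network edge species.

    Matching is undirected: a pair of formulas matches a reaction if their
    componentwise difference equals the reaction difference up to overall
    sign. Differences must be non-zero and pairwise distinct (again up to
    sign).
    """

    def __init__(self, entries: list[tuple[str, Formula]]):
        self.entries: list[tuple[str, Formula]] = []
        self._by_diff: dict[tuple[int, ...], str] = {}
        for name, diff in entries:
            if not diff:
                raise ReactionTableError(f"reaction {name!r} has a zero difference")
            key = diff.canonical_difference()
            if key in self._by_diff:
                raise ReactionTableError(
                    f"duplicate reaction difference {diff} ({name!r} vs "
                    f"{self._by_diff[key]!r})"
                )
            self._by_diff[key] = name
            self.entries.append((name, Formula(key)))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def match(self, diff: Formula) -> str | None:
        """Name of the reaction matching a signed difference, else None."""
        return self._by_diff.get(diff.canonical_difference())

    @property
    def differences(self) -> list[Formula]:
        return [d for _, d in self.entries]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReactionTable":
        """Load a two-column CSV with header ``name,difference``."""
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append((row["name"].strip(), Formula.parse(row["difference"])))
        return cls(entries)

    @classmethod
    def default(cls) -> "ReactionTable":
        """The packaged default table of common biochemical differences."""
        ref = resources.files("formulanet.data").joinpath("reactions.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass
class ReactionNetwork:
    """Undirected formula network with an O(1) composition index.

    ``graph`` is a networkx Graph whose nodes are :class:`Formula` objects
    (node attribute ``origin`` records whether the node is an initial seed
    or was added in assignment round k; edge attribute ``reaction`` names
    the matching transformation).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    _keys: np.ndarray | None = field(default=None, repr=False)
    _by_key: dict = field(default_factory=dict, repr=False)

    def __contains__(self, f: Formula) -> bool:
        return self.graph.has_node(f)

    def _key_index(self) -> np.ndarray:
        """Sorted packed-key array of all nodes (built lazily)."""
        if self._keys is None or len(self._keys) != self.node_count:
            counts = np.array(
                [n.counts for n in self.graph.nodes], dtype=np.int64
            ).reshape(-1, 6)
            keys = _encode_counts(counts)
            self._by_key = dict(zip(keys.tolist(), self.graph.nodes))
            self._keys = np.sort(keys)
        return self._keys

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, f: Formula) -> int:
        return self.graph.degree(f) if f in self else 0

    def add_formulas(
        self, formulas, reactions: ReactionTable, origin: str = "seed"
    ) -> int:
        """Add formulas as nodes and wire every matching reaction edge.

        Edges are found by composition lookup (node + difference present?)
        rather than all-pairs comparison, so adding n nodes against a table
        of r reactions costs O(n.r). Returns the number of nodes added.
        Existing nodes keep their original ``origin``.
        """
        new_nodes = []
        for f in formulas:
            if f not in self:
                self.graph.add_node(f, origin=origin)
                new_nodes.append(f)
        for f in new_nodes:
            for name, diff in reactions:
                for neighbor in (f + diff, f - diff):
                    if neighbor != f and neighbor in self:
                        self.graph.add_edge(f, neighbor, reaction=name)
        return len(new_nodes)

    def reaction_neighbors(
        self, f: Formula, reactions: ReactionTable
    ) -> list[tuple[Formula, str]]:
        """Network nodes one reaction step from a formula (which itself need
        not be a node)."""
        seen: dict[Formula, str] = {}
        for name, diff in reactions:
            for neighbor in (f + diff, f - diff):
                if neighbor != f and neighbor in self and neighbor not in seen:
                    seen[neighbor] = name
        return list(seen.items())

    def to_graphml(self, path: str | Path) -> None:
        g = nx.relabel_nodes(self.graph, {n: str(n) for n in self.graph.nodes})
        nx.write_graphml(g, str(path))

    def to_sif(self, path: str | Path) -> None:
        """Cytoscape simple-interaction format: one edge per line."""
        with open(path, "w") as fh:
            for a, b, data in self.graph.edges(data=True):
                name = data.get("reaction", "edge").replace(" ", "_")
                fh.write(f"{a}\t{name}\t{b}\n")
            for n in nx.isolates(self.graph):
                fh.write(f"{n}\n")


def filter_seeds(seeds, rules: ElementRules) -> list[Formula]:
    """Deduplicate seed formulas and restrict them to the allowed elements
    and neutral mass range (the H/C plausibility rule is not applied to
    seeds: they are known metabolites, not hypotheses)."""
    out, seen = [], set()
    for f in seeds:
        if f in seen or f.is_difference or not f:
            continue
        seen.add(f)
        if any(c > 0 and el not in rules.allowed_elements
               for el, c in f.as_dict().items()):
            continue
        m = f.monoisotopic_mass()
        if not (rules.mass_range[0] <= m <= rules.mass_range[1]):
            continue
        out.append(f)
    return out


def build_initial_network(
    seeds, reactions: ReactionTable, rules: ElementRules | None = None
) -> ReactionNetwork:
    """Construct the initial reaction network from known metabolite formulas.

    Seeds are deduplicated and constrained to the allowed elements and the
    configured mass range; an edge is placed between every pair of retained
    seeds whose elemental difference matches a reaction (up to sign).
    """
    rules = rules or ElementRules()
    kept = filter_seeds(seeds, rules)
    if not kept:
        raise ValueError("no seed formulas survive element/mass filtering")
    net = ReactionNetwork()
    net.add_formulas(kept, reactions, origin="seed")
    return net


@dataclass(frozen=True)
class ConnectedCandidate:
    """A candidate formula hypothesis with its evidence in the network."""

    feature_id: object
    adduct: str
    formula: Formula
    mz_theo: float
    ppm_error: float
    degree: int
    neighbors: tuple[tuple[Formula, str], ...]
    identity_match: bool


def connect_candidates(
    net: ReactionNetwork, candidate_set, reactions: ReactionTable
) -> tuple[list[ConnectedCandidate], list]:
    """Connect each candidate of a feature to the network.

    A candidate's degree is the number of network nodes one reaction step
    away. A candidate whose formula is itself already a node is flagged as
    an identity match (its degree is then that node's degree); such
    candidates are never treated as unconnected even when the node is
    isolated. Returns (connected, unconnected) lists; the latter holds the
    raw candidates with zero network evidence.
    """
    cands = candidate_set.candidates
    if not cands:
        return [], []
    node_keys = net._key_index()
    counts = np.array([c.formula.counts for c in cands], dtype=np.int64)
    diffs = np.array(
        [d.counts for d in reactions.differences], dtype=np.int64
    )
    signed = np.concatenate([diffs, -diffs])  # (2R, 6)
    shifted = counts[:, None, :] + signed[None, :, :]  # (n, 2R, 6)
    valid = (shifted >= 0).all(axis=2)
    keys = np.where(valid, _encode_counts(np.abs(shifted)), -1)
    pos = np.searchsorted(node_keys, keys)
    pos[pos == len(node_keys)] = 0
    hit = valid & (node_keys[pos] == keys) if len(node_keys) else np.zeros_like(valid)
    # a zero difference cannot occur (reaction differences are non-zero) and
    # two distinct reactions cannot reach the same node from one candidate,
    # so the row sum counts distinct neighbor nodes
    degrees = hit.sum(axis=1)
    self_keys = _encode_counts(counts)
    spos = np.searchsorted(node_keys, self_keys)
    spos[spos == len(node_keys)] = 0
    identity = (
        (node_keys[spos] == self_keys)
        if len(node_keys)
        else np.zeros(len(cands), dtype=bool)
    )
    names = [name for name, _ in reactions.entries] * 2
    connected, unconnected = [], []
    for i, cand in enumerate(cands):
        if degrees[i] == 0 and not identity[i]:
            unconnected.append(cand)
            continue
        neighbors = tuple(
            (net._by_key[int(keys[i, j])], names[j]) for j in np.nonzero(hit[i])[0]
        )
        connected.append(
            ConnectedCandidate(
                feature_id=candidate_set.feature_id,
                adduct=cand.adduct,
                formula=cand.formula,
                mz_theo=cand.mz_theo,
                ppm_error=cand.ppm_error,
                degree=int(degrees[i]),
                neighbors=neighbors,
                identity_match=bool(identity[i]),
            )
        )
    return connected, unconnected


def degree_filter(
    connected: list[ConnectedCandidate], cutoff: int, inclusive: bool = True
) -> list[ConnectedCandidate]:
    """Retain candidates with sufficient network evidence.

    With ``inclusive`` (default) a candidate survives when degree >= cutoff;
    the alternative strict reading (degree > cutoff) is available via the
    flag. Identity matches (candidate formula already a network node)
    always survive: a known metabolite must not be penalized for sitting in
    a sparse corner of the seed network.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    if inclusive:
        return [c for c in connected if c.identity_match or c.degree >= cutoff]
    return [c for c in connected if c.identity_match or c.degree > cutoff]


def network_stats(net: ReactionNetwork) -> dict:
    """Node/edge counts, degree histogram and mean degree (2|E|/|V|)."""
    degrees = [d for _, d in net.graph.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    n, e = net.node_count, net.edge_count
    return {
        "nodes": n,
        "edges": e,
        "mean_degree": (2 * e / n) if n else 0.0,
        "degree_histogram": dict(sorted(hist.items())),
        "fraction_degree_lt_3": (sum(v for k, v in hist.items() if k < 3) / n)
        if n
        else 0.0,
    }


def load_seed_list(path: str | Path) -> list[Formula]:
    """Read a seed formula list: one formula per line, or a CSV whose last
    column is the formula (a header line containing 'formula' is skipped)."""
    seeds = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split(",")[-1].strip()
            if token.lower() == "formula":
                continue
            seeds.append(Formula.parse(token))
    return seeds
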