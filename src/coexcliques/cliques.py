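"""Top-K co-regulation network and greedy clique separation.

The network connects every gene to its K strongest co-expression partners
(directed); the undirected projection keeps, per gene pair, the strongest
of the two directional correlations as edge strength and remembers whether
the pair was hit from one side or both (multiplicity 1 or 2).

Cliques — disjoint groups of co-expressed genes, not graph-theoretic
cliques — are excised from the network by a greedy pass over the unique
edges sorted strongest-first:

1. both genes unassigned  -> a new 2-gene clique;
2. exactly one assigned   -> the other gene joins that clique;
3. different cliques, at least one of size <= T -> the cliques are fused;
4. different cliques, both larger than T        -> both stay put.

T is the *protection threshold*: once a clique has grown past T genes it
can no longer be absorbed.  With K >= T+1 every final clique has more than
T genes (each gene touches K distinct partners, so an undersized clique
always has an outgoing edge that would have merged it).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterator, Mapping

import networkx as nx
import numpy as np

from .coexpression import CoexpressionRankDB

DEFAULT_K = 10
DEFAULT_T = 5


class CliqueSet(Mapping):
    """Disjoint, named gene cliques (an ordered ``name -> frozenset`` map).

    ``k`` and ``t`` record the network/separation parameters when known.
    """

    def __init__(self, cliques: Mapping[str, frozenset], k=None, t=None):
        self._cliques = {str(n): frozenset(g) for n, g in cliques.items()}
        seen: set[str] = set()
        for name, genes in self._cliques.items():
            if not genes:
                raise ValueError(f"clique {name!r} is empty")
            overlap = seen & genes
            if overlap:
                raise ValueError(
                    f"gene {sorted(overlap)[0]!r} appears in more than one clique"
                )
            seen |= genes
        self.k = k
        self.t = t

    def __getitem__(self, name: str) -> frozenset:
        return self._cliques[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._cliques)

    def __len__(self) -> int:
        return len(self._cliques)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CliqueSet):
            return NotImplemented
        return (
            self._cliques == other._cliques
            and self.k == other.k
            and self.t == other.t
        )

    @property
    def genes(self) -> frozenset:
        """Union of all cliques (the clique-set universe)."""
        return frozenset().union(*self._cliques.values())

    @property
    def sizes(self) -> dict[str, int]:
        return {n: len(g) for n, g in self._cliques.items()}

    def membership(self) -> dict[str, str]:
        """gene -> clique name."""
        return {g: n for n, genes in self._cliques.items() for g in genes}

    def renamed(self, mapping: Mapping[str, str]) -> "CliqueSet":
        return CliqueSet(
            {mapping.get(n, n): genes for n, genes in self._cliques.items()},
            k=self.k,
            t=self.t,
        )


@dataclass
class CoexprNetwork:
    """Top-K co-regulation network.

    ``top`` keeps the directed connection lists (gene -> its K database
    partners, strongest first); ``graph`` is the undirected projection
    with per-edge ``strength`` (pair-maximum correlation) and
    ``multiplicity`` (1 if only one gene listed the other, 2 if mutual).
    """

    top: dict[str, tuple[str, ...]]
    graph: nx.Graph
    k: int

    @property
    def genes(self) -> list[str]:
        return list(self.top)

    @property
    def n_directed(self) -> int:
        return sum(len(v) for v in self.top.values())

    @property
    def n_unique(self) -> int:
        return self.graph.number_of_edges()

    def stats(self) -> dict[str, float]:
        return connection_stats(len(self.top), self.n_directed, self.n_unique)


def connection_stats(n_genes: int, directed: int, unique: int) -> dict[str, float]:
    """Self-consistency arithmetic for a co-regulation network.

    ``possible`` is C(n, 2); ``average_edge_count`` is directed/unique
    (how often the average unique pair was listed); ``density_pct`` is the
    share of realised pairs.
    """
    possible = comb(n_genes, 2)
    return {
        "n_genes": n_genes,
        "directed_connections": directed,
        "unique_edges": unique,
        "possible_connections": possible,
        "average_edge_count": directed / unique if unique else float("nan"),
        "density_pct": 100.0 * unique / possible if possible else float("nan"),
    }


def build_topk_network(db: CoexpressionRankDB, k: int = DEFAULT_K) -> CoexprNetwork:
    """Connect every gene to its rank-1..K database partners."""
    n = len(db)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the gene count {n}")
    if db.corr is None:
        raise ValueError(
            "network construction needs stored correlation values "
            "(edge strength is the pair-maximum correlation)"
        )
    top: dict[str, tuple[str, ...]] = {}
    graph = nx.Graph()
    graph.add_nodes_from(db.genes)
    for g in db.genes:
        partners = tuple(db.top(g, k))
        top[g] = partners
        for h in partners:
            if graph.has_edge(g, h):
                graph[g][h]["multiplicity"] = 2
            else:
                r_gh = db.correlation(g, h)
                r_hg = db.correlation(h, g)
                strength = max(r_gh, r_hg)  # symmetric r: equal in practice
                graph.add_edge(g, h, strength=strength, multiplicity=1)
    return CoexprNetwork(top=top, graph=graph, k=k)


def _sorted_edges(net: CoexprNetwork) -> list[tuple[str, str, float]]:
    """Unique edges, strongest first; ties by lexicographic gene pair.

    Undefined strengths (possible only in degenerate hand-built networks)
    sort last.
    """
    edges = []
    for u, v, s in net.graph.edges(data="strength"):
        a, b = sorted((u, v))
        edges.append((a, b, float(s)))
    edges.sort(key=lambda e: (np.isnan(e[2]), -e[2] if not np.isnan(e[2]) else 0.0, e[0], e[1]))
    return edges


def separate_cliques(net: CoexprNetwork, t: int = DEFAULT_T) -> CliqueSet:
    """Separate the network into disjoint cliques by the four greedy rules.

    Returns a clique set with provisional names (``C001``, ...) in order
    of decreasing size; :func:`name_cliques` assigns the final names.
    """
    if t < 1:
        raise ValueError("protection threshold must be >= 1")
    assign: dict[str, int] = {}
    members: dict[int, set[str]] = {}
    next_id = 0
    for u, v, _ in _sorted_edges(net):
        cu, cv = assign.get(u), assign.get(v)
        if cu is None and cv is None:  # rule 1: new clique
            members[next_id] = {u, v}
            assign[u] = assign[v] = next_id
            next_id += 1
        elif cu is None:  # rule 2: u joins v's clique
            members[cv].add(u)
            assign[u] = cv
        elif cv is None:
            members[cu].add(v)
            assign[v] = cu
        elif cu != cv:
            small, large = sorted((cu, cv), key=lambda c: len(members[c]))
            if len(members[small]) <= t:  # rule 3: fuse while one is small
                for g in members[small]:
                    assign[g] = large
                members[large] |= members.pop(small)
            # rule 4: both protected -> nothing happens
    unassigned = [g for g in net.top if g not in assign]
    if unassigned:  # isolated genes cannot occur for top-K nets; be safe
        raise ValueError(f"gene {unassigned[0]!r} appears in no edge")
    ordered = sorted(members.values(), key=lambda s: (-len(s), min(s)))
    width = max(3, len(str(len(ordered))))
    return CliqueSet(
        {f"C{i + 1:0{width}d}": frozenset(s) for i, s in enumerate(ordered)},
        k=net.k,
        t=t,
    )


def name_cliques(cliques: CliqueSet, net: CoexprNetwork) -> CliqueSet:
    """Name every clique ``G1-G2`` after its two best-connected genes.

    Connectivity counts unique intra-clique edges; ties are broken
    lexicographically, the higher-degree gene comes first.  On the rare
    name collision a ``#2`` style suffix keeps names unique.
    """
    mapping: dict[str, str] = {}
    used: dict[str, int] = {}
    for name, genes in cliques.items():
        sub = net.graph.subgraph(genes)
        ranked = sorted(genes, key=lambda g: (-sub.degree(g), g))
        new = f"{ranked[0]}-{ranked[1]}"
        if new in used:
            used[new] += 1
            new = f"{new}#{used[new]}"
        else:
            used[new] = 1
        mapping[name] = new
    return cliques.renamed(mapping)


def eval_clique_rankings(
    cliques: CliqueSet, db: CoexpressionRankDB
) -> dict[str, tuple[float, float | None]]:
    """Average intra- vs inter-clique co-expression rank per clique.

    For each clique the intra value is the mean database rank over ordered
    pairs (g, h) of distinct clique members, the inter value the mean rank
    from clique members towards all non-members.  Smaller rank = stronger
    co-expression, so a good separation shows intra far below inter.  With
    a single clique the inter mean does not exist and is returned as
    ``None``.
    """
    missing = cliques.genes - set(db.genes)
    if missing:
        raise ValueError(f"clique gene {sorted(missing)[0]!r} absent from the rank database")
    ranks = db.rank_matrix().astype(float)
    index = {g: i for i, g in enumerate(db.genes)}
    all_idx = np.arange(len(db.genes))
    universe = np.array(sorted(index[g] for g in cliques.genes))
    out: dict[str, tuple[float, float | None]] = {}
    single = len(cliques) == 1
    for name, genes in cliques.items():
        idx = np.array(sorted(index[g] for g in genes))
        block = ranks[np.ix_(idx, idx)]
        intra = float(block.sum() / (len(idx) * (len(idx) - 1)))
        if single:
            out[name] = (intra, None)
        else:
            others = np.setdiff1d(universe, idx, assume_unique=True)
            inter = float(ranks[np.ix_(idx, others)].mean())
            out[name] = (intra, inter)
    return out


def scramble_cliques(cliques: CliqueSet, seed) -> CliqueSet:
    """Same clique sizes and names (suffixed), randomly permuted genes.

    ``seed`` may be an integer or a ``numpy.random.Generator`` so a caller
    drawing many scrambles can stream them from one generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.array(sorted(cliques.genes), dtype=object)
    rng.shuffle(pool)
    scrambled: dict[str, frozenset] = {}
    start = 0
    for name, genes in cliques.items():
        stop = start + len(genes)
        scrambled[f"{name}~scrambled"] = frozenset(pool[start:stop])
        start = stop
    return CliqueSet(scrambled, k=cliques.k, t=cliques.t)
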