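"""Positive co-occurrence network inference and weighted module detection.

The network is built by conditional-independence screening: an edge between
two OTUs survives only if their partial correlation stays significant
(Fisher z-test) given every conditioning subset of current neighbors up to a
configurable size. Edge weight is the minimal-magnitude surviving partial
correlation; negative associations are discarded, so weights lie in (0, 1].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import ClrMatrix

logger = logging.getLogger(__name__)


@dataclass
class CoNetwork:
    """Undirected, positively weighted OTU graph."""

    nodes: list[str]
    # keys are (u, v) node-id pairs with u < v; values strictly positive
    edges: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if not (0 < w <= 1):
                raise ValueError(f"edge weight {w} for ({u}, {v}) not in (0, 1]")
            if u > v:
                raise ValueError("edge keys must be ordered (u < v)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_weight(self) -> float:
        """S: sum of edge weights, each unordered edge counted once."""
        return float(sum(self.edges.values()))

    def weighted_degrees(self) -> dict[str, float]:
        k = {u: 0.0 for u in self.nodes}
        for (u, v), w in self.edges.items():
            k[u] += w
            k[v] += w
        return k

    def to_edgelist_tsv(self, path) -> None:
        import pandas as pd

        rows = [(u, v, w) for (u, v), w in sorted(self.edges.items())]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_edgelist_tsv(cls, path) -> "CoNetwork":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        edges = {}
        nodes = set()
        for u, v, w in frame.itertuples(index=False):
            u, v = sorted((str(u), str(v)))
            edges[(u, v)] = float(w)
            nodes.update((u, v))
        return cls(nodes=sorted(nodes), edges=edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


@dataclass
class ModulePartition:
    """Node -> module-id map with its modularity score."""

    assignment: dict[str, int]
    Q: float

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, m in self.assignment.items():
            out.setdefault(m, []).append(node)
        return out

    def min_module_size(self) -> int:
        return min(len(v) for v in self.modules().values())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            sorted(self.assignment.items()), columns=["otu_id", "module"]
        ).to_csv(path, index=False)


def _fisher_z_pvalue(r: float, n: int, n_cond: int) -> float:
    r = float(np.clip(r, -0.9999999, 0.9999999))
    df = n - n_cond - 3
    if df <= 0:
        return 1.0
    z = 0.5 * np.log((1 + r) / (1 - r)) * np.sqrt(df)
    return float(2 * stats.norm.sf(abs(z)))


def _partial_corr(corr: np.ndarray, i: int, j: int, cond: tuple[int, ...]) -> float:
    if not cond:
        return float(corr[i, j])
    idx = [i, j, *cond]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub)
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        return 0.0
    return float(-prec[0, 1] / np.sqrt(denom))


def infer_network(
    clr: ClrMatrix,
    alpha: float = 0.05,
    max_conditioning: int = 3,
) -> CoNetwork:
    """Infer direct positive associations between OTUs from clr data.

    A PC-stable-style screen: level-0 keeps pairs with a significant Pearson
    correlation; each higher level re-tests every surviving edge against all
    conditioning subsets (drawn from either endpoint's current neighbors) of
    that size, removing edges whose partial correlation becomes
    non-significant. Removals within a level are applied at the end of the
    level, making the result invariant to OTU column order. The edge weight
    is the minimal-magnitude partial correlation seen among surviving tests;
    edges whose minimal association is negative are discarded.
    """
    X = np.asarray(clr.values, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples for network inference")
    if p < 3:
        raise ValueError("need at least 3 OTUs for network inference")

    sd = X.std(axis=0)
    active = sd > 0
    if not active.all():
        skipped = [o for o, a in zip(clr.otu_ids, active) if not a]
        logger.warning("infer_network: excluding constant OTUs: %s", skipped)
    cols = np.flatnonzero(active)
    ids = [clr.otu_ids[c] for c in cols]
    Z = (X[:, cols] - X[:, cols].mean(axis=0)) / X[:, cols].std(axis=0)
    corr = np.clip((Z.T @ Z) / n, -1.0, 1.0)
    m = len(cols)

    # adjacency over local indices; minweight[key] = signed pcor of minimal |pcor|
    adj: dict[int, set[int]] = {i: set() for i in range(m)}
    minweight: dict[tuple[int, int], float] = {}
    for i in range(m):
        for j in range(i + 1, m):
            r = float(corr[i, j])
            if _fisher_z_pvalue(r, n, 0) < alpha:
                adj[i].add(j)
                adj[j].add(i)
                minweight[(i, j)] = r

    for level in range(1, max_conditioning + 1):
        frozen = {i: sorted(neigh) for i, neigh in adj.items()}
        to_remove = []
        for (i, j) in sorted(minweight):
            cand_sets = set()
            for base, other in ((i, j), (j, i)):
                pool = [x for x in frozen[base] if x != other]
                if len(pool) >= level:
                    cand_sets.update(itertools.combinations(pool, level))
            removed = False
            for cond in sorted(cand_sets):
                r = _partial_corr(corr, i, j, cond)
                if _fisher_z_pvalue(r, n, len(cond)) >= alpha:
                    removed = True
                    break
                if abs(r) < abs(minweight[(i, j)]):
                    minweight[(i, j)] = r
            if removed:
                to_remove.append((i, j))
        for (i, j) in to_remove:
            del minweight[(i, j)]
            adj[i].discard(j)
            adj[j].discard(i)

    edges = {}
    for (i, j), w in minweight.items():
        if w <= 0:
            continue  # negative associations discarded
        u, v = sorted((ids[i], ids[j]))
        edges[(u, v)] = min(float(w), 1.0)
    logger.info(
        "infer_network: %d nodes, %d positive edges (alpha=%g, max_cond=%d)",
        m, len(edges), alpha, max_conditioning,
    )
    return CoNetwork(nodes=list(ids), edges=edges)


def modularity(net: CoNetwork, part: ModulePartition) -> float:
    """Weighted modularity Q of a partition.

    Q = (1/2S) * sum over ordered node pairs (u, v) of
    (sigma(u,v) - k_u k_v / 2S) * [M_u == M_v],
    where S is the total edge weight and k_u the weighted degree.
    """
    missing = [u for u in net.nodes if u not in part.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    S = net.total_weight
    if S == 0:
        raise ValueError("modularity undefined for an empty network")
    k = net.weighted_degrees()
    # per-module aggregate form, algebraically equal to the ordered-pair sum
    w_in: dict[int, float] = {}
    k_mod: dict[int, float] = {}
    for node in net.nodes:
        mod = part.assignment[node]
        k_mod[mod] = k_mod.get(mod, 0.0) + k[node]
        w_in.setdefault(mod, 0.0)
    for (u, v), w in net.edges.items():
        if part.assignment[u] == part.assignment[v]:
            w_in[part.assignment[u]] += w
    q = 0.0
    for mod in k_mod:
        q += w_in[mod] / S - (k_mod[mod] / (2 * S)) ** 2
    return q


_ALGORITHMS = ("leiden", "louvain", "greedy", "label_propagation")


def detect_modules(net: CoNetwork, algorithm: str = "leiden", seed: int = 0) -> ModulePartition:
    """Detect a modularity-maximizing partition of the network.

    Algorithms: ``leiden`` (refinement-based, default), ``louvain``,
    ``greedy`` (agglomerative modularity), ``label_propagation``. Connected
    components are handled independently by all of them. Module ids are
    renumbered 1..K by descending module size (ties by sorted member ids).
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {_ALGORITHMS}")
    if net.n_edges == 0:
        raise ValueError("cannot detect modules in an empty network")

    if algorithm == "leiden":
        import igraph
        import leidenalg

        g = igraph.Graph()
        g.add_vertices(net.n_nodes)
        index = {u: i for i, u in enumerate(net.nodes)}
        pairs = sorted(net.edges.items())
        g.add_edges([(index[u], index[v]) for (u, v), _ in pairs])
        weights = [w for _, w in pairs]
        partition = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights=weights,
            seed=seed,
            n_iterations=-1,
        )
        groups = [[net.nodes[i] for i in block] for block in partition]
    else:
        import networkx as nx

        g = net.to_networkx()
        if algorithm == "louvain":
            communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
        elif algorithm == "greedy":
            communities = nx.community.greedy_modularity_communities(g, weight="weight")
        else:
            communities = nx.community.asyn_lpa_communities(g, weight="weight", seed=seed)
        groups = [sorted(c) for c in communities]

    groups = sorted(groups, key=lambda grp: (-len(grp), sorted(grp)))
    assignment = {}
    for mod_id, members in enumerate(groups, start=1):
        for node in members:
            assignment[node] = mod_id
    part = ModulePartition(assignment=assignment, Q=0.0)
    part.Q = modularity(net, part)
    return part


def select_partition(
    candidates: list[ModulePartition], min_module_size: int = 3
) -> ModulePartition:
    """Highest-Q candidate among those whose smallest module has at least
    ``min_module_size`` members; falls back to highest-Q overall with a
    warning if none qualifies."""
    if not candidates:
        raise ValueError("no candidate partitions")
    eligible = [c for c in candidates if c.min_module_size() >= min_module_size]
    if not eligible:
        logger.warning(
            "select_partition: no candidate meets min module size %d; "
            "returning best Q overall", min_module_size,
        )
        eligible = candidates
    return max(eligible, key=lambda c: c.Q)
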