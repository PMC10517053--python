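"""Edge-satisfaction index and community-type assignment.

For a module M and sample i, the edge-satisfaction index is the
edge-weight-weighted mean of min(p_i(u), p_i(v)) over M's internal edges,
where p_i(u) is the logistic transform of the clr abundance of OTU u in
sample i. A sample's community type is the module with the highest index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CoNetwork, ModulePartition
from .preprocess import ClrMatrix

logger = logging.getLogger(__name__)


@dataclass
class NodeWeights:
    """Per-sample node weights in (0, 1)."""

    sample_ids: list[str]
    otu_ids: list[str]
    p: np.ndarray  # (n_samples, n_otus)


@dataclass
class EdgeSatisfactionMatrix:
    sample_ids: list[str]
    module_ids: list[int]
    ES: np.ndarray  # (n_samples, n_modules), entries in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ES,
            index=self.sample_ids,
            columns=[f"module_{m}" for m in self.module_ids],
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "sample_id"
        frame.to_csv(path)

    def to_long_frame(self) -> pd.DataFrame:
        """Heatmap-ready long format: sample_id, module, es."""
        frame = self.to_frame().reset_index(names="sample_id")
        long = frame.melt(id_vars="sample_id", var_name="module", value_name="es")
        long["module"] = long["module"].str.removeprefix("module_").astype(int)
        return long


def node_weights(clr: ClrMatrix, scale: float = 1.0, offset: float = 0.0) -> NodeWeights:
    """Logistic transform of clr values: p = 1 / (1 + exp(-(clr - offset) / scale)).

    Defaults give the standard logistic, so an OTU at its sample's geometric
    mean abundance (clr = 0) has weight 0.5.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    z = (np.asarray(clr.values, dtype=float) - offset) / scale
    p = 1.0 / (1.0 + np.exp(-z))
    return NodeWeights(sample_ids=list(clr.sample_ids), otu_ids=list(clr.otu_ids), p=p)


def edge_satisfaction(
    net: CoNetwork, part: ModulePartition, w: NodeWeights
) -> EdgeSatisfactionMatrix:
    """Edge-satisfaction index for every (sample, module) pair.

    ES_{M,i} = sum over edges (u,v) inside M of sigma(u,v) * min(p_i(u), p_i(v)),
    divided by the sum of sigma(u,v) over the same edges. Modules without any
    internal edge are omitted with a warning.
    """
    col = {o: j for j, o in enumerate(w.otu_ids)}
    missing = [u for u in net.nodes if u not in col]
    if missing:
        raise ValueError(f"node weights missing for network nodes: {missing[:5]}")

    internal: dict[int, list[tuple[int, int, float]]] = {}
    for (u, v), weight in sorted(net.edges.items()):
        mu, mv = part.assignment[u], part.assignment[v]
        if mu == mv:
            internal.setdefault(mu, []).append((col[u], col[v], weight))

    module_ids = []
    columns = []
    for mod in sorted(set(part.assignment.values())):
        edges = internal.get(mod)
        if not edges:
            logger.warning("edge_satisfaction: module %d has no internal edge; omitted", mod)
            continue
        iu = np.array([e[0] for e in edges])
        iv = np.array([e[1] for e in edges])
        sigma = np.array([e[2] for e in edges])
        num = np.minimum(w.p[:, iu], w.p[:, iv]) @ sigma
        columns.append(num / sigma.sum())
        module_ids.append(mod)
    if not module_ids:
        raise ValueError("no module has an internal edge")
    ES = np.column_stack(columns)
    return EdgeSatisfactionMatrix(
        sample_ids=list(w.sample_ids), module_ids=module_ids, ES=ES
    )


def assign_types(es: EdgeSatisfactionMatrix) -> pd.DataFrame:
    """Assign each sample the module with the highest edge satisfaction.

    Returns a frame with columns ``sample_id, community_type, tie_flag``;
    ties (including all-zero rows) go to the lowest module id and are
    flagged.
    """
    if es.ES.shape[1] < 1:
        raise ValueError("need at least one module column")
    modules = np.asarray(es.module_ids)
    best = es.ES.max(axis=1, keepdims=True)
    is_best = es.ES >= best  # exact comparison: argmax ties only
    first_best = is_best.argmax(axis=1)
    tie = is_best.sum(axis=1) > 1
    return pd.DataFrame(
        {
            "sample_id": es.sample_ids,
            "community_type": modules[first_best],
            "tie_flag": tie,
        }
    )
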