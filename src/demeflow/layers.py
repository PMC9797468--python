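"""Per-layer weighted social networks from nest-box co-occupancy.

The edge weight between two individuals in a layer is the total time (in
seconds) their visit intervals overlap in the same box, irrespective of any
other individuals present — a triple co-stay credits all three pairs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from demeflow.preprocess import TimeLayer, Visit


@dataclasses.dataclass
class LayerNetwork:
    """Symmetric weighted co-occupancy graph for one time layer.

    Nodes are the individuals with at least one visit in the layer; ``A`` is
    the symmetric nonnegative matrix of pairwise co-occupancy seconds with a
    zero diagonal.
    """

    layer_index: int
    node_ids: list[str]
    A: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, tag_id: str) -> int:
        return self.node_ids.index(tag_id)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(layer_index=self.layer_index)
        g.add_nodes_from(self.node_ids)
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if self.A[i, j] > 0:
                    g.add_edge(self.node_ids[i], self.node_ids[j], weight=float(self.A[i, j]))
        return g


def _overlap(iv_a: Sequence[tuple[float, float]], iv_b: Sequence[tuple[float, float]]) -> float:
    total = 0.0
    for a0, a1 in iv_a:
        for b0, b1 in iv_b:
            lo, hi = max(a0, b0), min(a1, b1)
            if hi > lo:
                total += hi - lo
    return total


def contact_time(visits_i: Iterable[Visit], visits_j: Iterable[Visit]) -> float:
    """Total co-occupancy seconds of two distinct individuals across boxes."""
    visits_i, visits_j = list(visits_i), list(visits_j)
    tags_i = {v.tag_id for v in visits_i}
    tags_j = {v.tag_id for v in visits_j}
    if tags_i and tags_i == tags_j:
        raise ValueError("contact_time requires two distinct individuals")
    by_box_i: dict[str, list[tuple[float, float]]] = {}
    for v in visits_i:
        by_box_i.setdefault(v.box_id, []).append((v.t_enter, v.t_exit))
    total = 0.0
    by_box_j: dict[str, list[tuple[float, float]]] = {}
    for v in visits_j:
        by_box_j.setdefault(v.box_id, []).append((v.t_enter, v.t_exit))
    for box, ivs in by_box_i.items():
        if box in by_box_j:
            total += _overlap(ivs, by_box_j[box])
    return total


def build_layer_network(layer: TimeLayer) -> LayerNetwork:
    """Fill the adjacency matrix of one layer from its visits.

    Individuals with visits but no contacts stay in the node set as isolated
    vertices; individuals with no visits in the layer are excluded.
    """
    node_ids = sorted({v.tag_id for v in layer.visits})
    idx = {t: i for i, t in enumerate(node_ids)}
    n = len(node_ids)
    A = np.zeros((n, n))
    # sweep per box: sort interval endpoints, accumulate pairwise overlaps
    by_box: dict[str, list[Visit]] = {}
    for v in layer.visits:
        by_box.setdefault(v.box_id, []).append(v)
    for box, vs in by_box.items():
        vs = sorted(vs, key=lambda v: v.t_enter)
        for a in range(len(vs)):
            va = vs[a]
            for b in range(a + 1, len(vs)):
                vb = vs[b]
                if vb.t_enter >= va.t_exit:
                    break  # sorted by start: no later visit can overlap va
                if va.tag_id == vb.tag_id:
                    continue
                ov = min(va.t_exit, vb.t_exit) - vb.t_enter
                i, j = idx[va.tag_id], idx[vb.tag_id]
                A[i, j] += ov
                A[j, i] += ov
    return LayerNetwork(layer_index=layer.index, node_ids=node_ids, A=A)


def build_all_layer_networks(layers: Sequence[TimeLayer]) -> list[LayerNetwork]:
    return [build_layer_network(ly) for ly in layers]
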