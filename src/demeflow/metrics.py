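"""Post-partition descriptives: distinctiveness, spatial separation, box
occupancy and period-summary networks."""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from demeflow.layers import LayerNetwork
from demeflow.mapeq import MultilayerPartition
from demeflow.preprocess import Visit


@dataclasses.dataclass
class SeparationIndex:
    """Usage-weighted mean of per-box usage exclusivities for one layer."""

    layer_index: int
    possession: dict[str, dict[int, float]]  # box -> module -> share of box time
    exclusivity: dict[str, float]  # box -> max module share
    usage: dict[str, float]  # box -> total seconds
    index: float


def distinctiveness(
    layer_network: LayerNetwork,
    partition: MultilayerPartition,
    time_pooled: bool = False,
) -> float:
    """Mean proportion of interaction time individuals spend with their own
    module's members; individuals with no interactions are excluded.

    With ``time_pooled`` the intramodular seconds are pooled over individuals
    before dividing (an alternative weighting); the default averages the
    per-individual proportions unweighted.  Returns NaN when nobody
    interacts.
    """
    A = layer_network.A
    li = layer_network.layer_index
    mods = [partition.assignment[(tag, li)] for tag in layer_network.node_ids]
    props = []
    intra_total = 0.0
    grand_total = 0.0
    for i in range(layer_network.n_nodes):
        total = float(A[i].sum())
        if total <= 0:
            continue
        intra = float(sum(A[i, j] for j in range(layer_network.n_nodes) if mods[j] == mods[i]))
        props.append(intra / total)
        intra_total += intra
        grand_total += total
    if not props:
        return float("nan")
    if time_pooled:
        return intra_total / grand_total
    return float(np.mean(props))


def spatial_separation(
    layer_visits: Iterable[Visit],
    partition: MultilayerPartition,
    layer_index: int,
) -> SeparationIndex:
    """Box-possession shares per module and the spatial-separation index.

    possession(m, b) = seconds spent by members of m in box b over total
    seconds anyone spent in b (solitary time included); exclusivity of b is
    the maximum share; the index is the usage-weighted mean of exclusivities
    over occupied boxes.  Index is NaN when no box is used.
    """
    time_by_box_mod: dict[str, dict[int, float]] = {}
    for v in layer_visits:
        m = partition.assignment[(v.tag_id, layer_index)]
        time_by_box_mod.setdefault(v.box_id, {}).setdefault(m, 0.0)
        time_by_box_mod[v.box_id][m] += v.duration
    possession: dict[str, dict[int, float]] = {}
    exclusivity: dict[str, float] = {}
    usage: dict[str, float] = {}
    for box, by_mod in time_by_box_mod.items():
        total = sum(by_mod.values())
        if total <= 0:
            continue
        usage[box] = total
        possession[box] = {m: t / total for m, t in by_mod.items()}
        exclusivity[box] = max(possession[box].values())
    if not usage:
        return SeparationIndex(layer_index, {}, {}, {}, float("nan"))
    total_usage = sum(usage.values())
    index = sum(usage[b] * exclusivity[b] for b in usage) / total_usage
    return SeparationIndex(layer_index, possession, exclusivity, usage, float(index))


def box_occupancy(
    layer_visits: Iterable[Visit],
    partition: MultilayerPartition,
    layer_index: int,
    all_boxes: Sequence[str] | None = None,
) -> dict[str, dict[int, float] | None]:
    """Per-box module occupancy proportions; unoccupied boxes map to None."""
    sep = spatial_separation(layer_visits, partition, layer_index)
    boxes = list(all_boxes) if all_boxes is not None else sorted(sep.possession)
    return {b: sep.possession.get(b) for b in boxes}


def summary_network(
    layer_networks: Sequence[LayerNetwork],
    window: Sequence[int],
    include_ids: Iterable[str],
    partition: MultilayerPartition | None = None,
    individuals: Mapping[str, object] | None = None,
):
    """Mean-strength network over a 10-layer (or any) window.

    Edge weight is the mean of A_ij over the window layers, layers where a
    pair is absent contributing zero.  Vertices carry the prevailing module
    (modal assignment over the window, ties to the earliest module label)
    and sex when metadata is given.  Only ``include_ids`` (founders and/or
    proven reproducers) enter the summary.
    """
    import networkx as nx

    by_index = {ln.layer_index: ln for ln in layer_networks}
    missing = [w for w in window if w not in by_index]
    if missing:
        raise ValueError(f"window layers {missing} not in the available record")
    include = sorted(set(include_ids))
    n_win = len(window)
    weight: dict[tuple[str, str], float] = {}
    present: set[str] = set()
    for w in window:
        ln = by_index[w]
        idx = {t: i for i, t in enumerate(ln.node_ids)}
        for a_pos, a in enumerate(include):
            if a not in idx:
                continue
            present.add(a)
            for b in include[a_pos + 1 :]:
                if b not in idx:
                    continue
                val = float(ln.A[idx[a], idx[b]])
                if val > 0:
                    weight[(a, b)] = weight.get((a, b), 0.0) + val
    g = nx.Graph()
    for tag in sorted(present):
        attrs = {}
        if partition is not None:
            mods = [
                partition.assignment[(tag, w)]
                for w in window
                if (tag, w) in partition.assignment
            ]
            if mods:
                counts: dict[int, int] = {}
                for m in mods:
                    counts[m] = counts.get(m, 0) + 1
                top = max(counts.values())
                attrs["module"] = min(m for m, c in counts.items() if c == top)
        if individuals is not None and tag in individuals:
            attrs["sex"] = individuals[tag].sex
        g.add_node(tag, **attrs)
    for (a, b), tot in weight.items():
        g.add_edge(a, b, weight=tot / n_win)
    return g
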