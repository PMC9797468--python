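"""Relax-rate selection by NMI consensus and the visit-reordering bootstrap.

The relax rate r is a free parameter of the multilayer clustering; it is
fixed, non-arbitrarily, at the value whose solutions agree most (by
normalized mutual information) with the solutions found under every other
value, with the median taken across experiments.  Robustness of the
modularity M to idiosyncrasies of the movement record is probed by a
bootstrap that reshuffles each individual's visits among its own visit start
slots, conserving the time it spends in each box while disturbing pairwise
synchrony.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from demeflow.mapeq import MultilayerPartition, build_multilayer, louvain_minimize
from demeflow.preprocess import TimeLayer, Visit, slice_visits_into_layers
from demeflow.layers import build_all_layer_networks


def nmi(partition_a: MultilayerPartition, partition_b: MultilayerPartition) -> float:
    """Normalized mutual information I(A;B)/sqrt(H(A)H(B)) over state nodes.

    1.0 for identical partitions up to relabeling; defined as 1 when both
    partitions are single-module (no uncertainty on either side), 0 when
    exactly one is.
    """
    nodes_a = set(partition_a.assignment)
    nodes_b = set(partition_b.assignment)
    if nodes_a != nodes_b:
        raise ValueError("partitions cover different state-node sets")
    nodes = sorted(nodes_a)
    n = len(nodes)
    labels_a = [partition_a.assignment[x] for x in nodes]
    labels_b = [partition_b.assignment[x] for x in nodes]
    joint: dict[tuple[int, int], int] = {}
    ca: dict[int, int] = {}
    cb: dict[int, int] = {}
    for a, b in zip(labels_a, labels_b):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        ca[a] = ca.get(a, 0) + 1
        cb[b] = cb.get(b, 0) + 1
    h_a = -sum((c / n) * math.log2(c / n) for c in ca.values())
    h_b = -sum((c / n) * math.log2(c / n) for c in cb.values())
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab * n * n / (ca[a] * cb[b]))
    return float(max(0.0, min(1.0, mi / math.sqrt(h_a * h_b))))


def relax_scan(
    layer_networks: Sequence,
    r_grid: Sequence[float],
    seed: int = 0,
    teleport: float = 0.01,
) -> tuple[list[MultilayerPartition], np.ndarray, np.ndarray]:
    """Cluster one experiment at every r; returns (partitions, NMI matrix, mean NMI per r)."""
    partitions = []
    for k, r in enumerate(r_grid):
        net = build_multilayer(layer_networks, r)
        part, _res = louvain_minimize(net, rng=seed * 1009 + k, teleport=teleport)
        partitions.append(part)
    n = len(r_grid)
    nmi_mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = nmi(partitions[i], partitions[j])
            nmi_mat[i, j] = nmi_mat[j, i] = v
    # mean similarity of each r's solution to every other r's solution
    mean_nmi = (nmi_mat.sum(axis=1) - 1.0) / (n - 1) if n > 1 else np.ones(1)
    return partitions, nmi_mat, mean_nmi


def select_relax_rate(
    experiments: Sequence[Sequence],
    r_grid: Sequence[float] | None = None,
    seed: int = 0,
    teleport: float = 0.01,
) -> tuple[float, np.ndarray]:
    """Consensual relax rate: maximize the median across experiments of the
    per-experiment mean NMI curves; ties resolve to the smaller r.

    Returns (r_star, curves) with curves of shape (n_experiments, len(grid)).
    """
    if r_grid is None:
        r_grid = np.round(np.linspace(0.0, 1.0, 21), 10)
    curves = []
    for e, layer_networks in enumerate(experiments):
        _parts, _mat, mean_nmi = relax_scan(
            layer_networks, r_grid, seed=seed + 7919 * e, teleport=teleport
        )
        curves.append(mean_nmi)
    curves = np.asarray(curves)
    med = np.median(curves, axis=0)
    best = int(np.argmax(med))  # argmax takes the first (= smallest r) on ties
    return float(r_grid[best]), curves


# ---------------------------------------------------------------------------
# visit-reordering bootstrap

def bootstrap_replicate(
    visits: Sequence[Visit], rng: np.random.Generator
) -> list[Visit]:
    """Randomly reorder each individual's visits among its own start slots.

    Per individual, the ordered sequence of visit start times stays fixed and
    the (box, duration) payloads are permuted among those slots.  Every
    individual therefore spends exactly the same total time in the same
    boxes, but pairwise synchrony is disturbed.
    """
    by_tag: dict[str, list[Visit]] = {}
    for v in visits:
        by_tag.setdefault(v.tag_id, []).append(v)
    out: list[Visit] = []
    for tag in sorted(by_tag):
        vs = sorted(by_tag[tag], key=lambda v: v.t_enter)
        starts = [v.t_enter for v in vs]
        payload = [(v.box_id, v.t_exit - v.t_enter) for v in vs]
        perm = rng.permutation(len(vs))
        for slot, k in enumerate(perm):
            box, dur = payload[k]
            out.append(Visit(tag, box, starts[slot], starts[slot] + dur))
    out.sort(key=lambda v: (v.t_enter, v.tag_id, v.box_id))
    return out


def bootstrap_replicate_gap_shuffle(
    visits: Sequence[Visit], rng: np.random.Generator
) -> list[Visit]:
    """Alternative reordering: permute visits and inter-visit gaps jointly,
    rebuilding each individual's timeline from its original first start."""
    by_tag: dict[str, list[Visit]] = {}
    for v in visits:
        by_tag.setdefault(v.tag_id, []).append(v)
    out: list[Visit] = []
    for tag in sorted(by_tag):
        vs = sorted(by_tag[tag], key=lambda v: v.t_enter)
        gaps = [vs[0].t_enter] + [
            b.t_enter - a.t_exit for a, b in zip(vs[:-1], vs[1:])
        ]
        perm = rng.permutation(len(vs))
        t = 0.0
        for k in perm:
            t += gaps[k]
            dur = vs[k].t_exit - vs[k].t_enter
            out.append(Visit(tag, vs[k].box_id, t, t + dur))
            t += dur
    out.sort(key=lambda v: (v.t_enter, v.tag_id, v.box_id))
    return out


def bootstrap_modularity(
    visits: Sequence[Visit],
    layers: Sequence[TimeLayer],
    r_grid: Sequence[float],
    reps: int,
    rng: np.random.Generator | int | None = None,
    teleport: float = 0.01,
) -> pd.DataFrame:
    """Distribution of M per relax rate over visit-reordering replicates.

    Runs the full pipeline (reorder -> layer networks -> cluster -> M) per
    replicate; returns a tidy frame (rep, r, M).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    records = []
    for rep in range(reps):
        perm_visits = bootstrap_replicate(visits, rng)
        lys = slice_visits_into_layers(
            [TimeLayer(ly.index, ly.t_start, ly.t_end) for ly in layers], perm_visits
        )
        nets = build_all_layer_networks([ly for ly in lys if ly.visits])
        for r in r_grid:
            net = build_multilayer(nets, r)
            _part, res = louvain_minimize(
                net, rng=int(rng.integers(2**31)), teleport=teleport
            )
            records.append({"rep": rep, "r": r, "M": res.M})
    return pd.DataFrame.from_records(records)


def bootstrap_summary(boot: pd.DataFrame) -> pd.DataFrame:
    """Min/max and 2.5/97.5% quantiles of bootstrap M per relax rate."""
    return (
        boot.groupby("r")["M"]
        .agg(
            minimum="min",
            maximum="max",
            q025=lambda s: s.quantile(0.025),
            q975=lambda s: s.quantile(0.975),
        )
        .reset_index()
    )
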