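"""Map-equation codelength, its Louvain minimization, and the multilayer
extension with a relax rate.

The description length of a random walk on the network under a two-level
partition is

    L = q * H(Q) + sum_m p_m * H(P_m)

where q is the total module-exit flow, H(Q) the entropy of normalized exit
flows (the index codebook), and each module codebook P_m covers the module's
node visit rates plus its exit flow.  Algebraically this reduces to

    L = plogp(q) - 2 * sum_m plogp(q_m) + sum_m plogp(p_m + q_m)
        - sum_a plogp(p_a)

(plogp(x) = x log2 x), the form used throughout.  Modularity is reported as
the compression rate M = L_before / L_after, the one-module codelength over
the partitioned one; M = 1 means no compressible structure.

Visit rates come from the stationary distribution of the row-normalized flow
with a small uniform teleportation (default tau = 0.01) that guarantees
ergodicity; teleportation flow is recorded in module transitions.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

StateNode = tuple[str, int]  # (tag_id, layer_index)


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 1e-15 else 0.0


@dataclasses.dataclass
class StateNetwork:
    """Directed weighted network over (individual, layer) state nodes."""

    nodes: list[StateNode]
    links: dict[int, dict[int, float]]  # out-adjacency on node indices
    r: float = 0.0

    def __post_init__(self) -> None:
        self._index = {node: i for i, node in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index_of(self, node: StateNode) -> int:
        return self._index[node]

    def out_strength(self) -> np.ndarray:
        s = np.zeros(self.n_nodes)
        for i, nbrs in self.links.items():
            s[i] = sum(nbrs.values())
        return s

    def total_weight(self) -> float:
        return float(sum(sum(nbrs.values()) for nbrs in self.links.values()))

    @classmethod
    def from_single_layer(cls, layer_network) -> "StateNetwork":
        """Wrap one undirected layer network as a (symmetric) state network."""
        nodes = [(tag, layer_network.layer_index) for tag in layer_network.node_ids]
        links: dict[int, dict[int, float]] = {}
        A = layer_network.A
        n = len(nodes)
        for i in range(n):
            for j in range(n):
                if A[i, j] > 0:
                    links.setdefault(i, {})[j] = float(A[i, j])
        return cls(nodes=nodes, links=links, r=0.0)


@dataclasses.dataclass
class MultilayerPartition:
    """Hard assignment of every (individual, layer) state node to a module."""

    assignment: dict[StateNode, int]

    def modules(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def module_lifespan(self) -> dict[int, set[int]]:
        """Module id -> set of layer indices where any member is assigned."""
        out: dict[int, set[int]] = {}
        for (_tag, layer), m in self.assignment.items():
            out.setdefault(m, set()).add(layer)
        return out

    def restrict(self, nodes: Iterable[StateNode]) -> "MultilayerPartition":
        return MultilayerPartition({n: self.assignment[n] for n in nodes})

    def relabel_by_first_appearance(self) -> "MultilayerPartition":
        """Renumber modules 0,1,... in order of first (layer, tag) appearance."""
        order = sorted(self.assignment, key=lambda n: (n[1], n[0]))
        mapping: dict[int, int] = {}
        for node in order:
            m = self.assignment[node]
            if m not in mapping:
                mapping[m] = len(mapping)
        return MultilayerPartition({n: mapping[m] for n, m in self.assignment.items()})


@dataclasses.dataclass
class CodelengthResult:
    L: float  # bits per step
    index_length: float  # q * H(Q) term
    module_length: float  # sum of module codebook terms
    visit_rates: dict[StateNode, float]


@dataclasses.dataclass
class ModularityResult:
    M: float
    r: float
    L_before: float
    L_after: float
    partition: MultilayerPartition


# ---------------------------------------------------------------------------
# stationary flow

def stationary_flow(
    state_network: StateNetwork,
    teleport: float = 0.01,
    tol: float = 1e-14,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Visit rates: stationary distribution of the teleported random walk.

    Dangling state nodes (zero out-strength) teleport uniformly.  For a
    single-layer undirected network the teleport-free limit is
    p proportional to node strength.  ``teleport=0`` is accepted for exact
    hand-checkable fixtures; the lazy (half-averaged) iteration keeps
    periodic structures convergent, without changing the fixed point.
    """
    n = state_network.n_nodes
    if n == 0:
        raise ValueError("empty state network")
    s = state_network.out_strength()
    if not np.any(s > 0):
        raise ValueError("all-zero network: stationary flow undefined")
    rows = []
    for i in range(n):
        if s[i] > 0:
            nbrs = state_network.links[i]
            idx = np.fromiter(nbrs.keys(), dtype=np.int64, count=len(nbrs))
            w = np.fromiter(nbrs.values(), dtype=float, count=len(nbrs)) / s[i]
            rows.append((idx, w))
        else:
            rows.append(None)
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = np.zeros(n)
        dangling_mass = 0.0
        for i in range(n):
            if rows[i] is None:
                dangling_mass += p[i]
            else:
                idx, w = rows[i]
                np.add.at(nxt, idx, (1.0 - teleport) * p[i] * w)
        nxt += (teleport * (1.0 - dangling_mass) + dangling_mass) / n
        nxt = 0.5 * (p + nxt)  # lazy walk: same fixed point, aperiodic
        if np.abs(nxt - p).sum() < tol:
            p = nxt
            break
        p = nxt
    return p / p.sum()


# ---------------------------------------------------------------------------
# codelength

def _flow_terms(
    state_network: StateNetwork, p: np.ndarray, teleport: float
) -> tuple[list[dict[int, float]], np.ndarray]:
    """Per-node link-flow adjacency F(a->b) and rank-one teleport coefficients.

    Node a emits p[a] of flow per step: a fraction follows links
    (row-normalized, damped by 1 - tau) and the rest teleports uniformly over
    nodes.  Returns (sparse link flows, pt) with pt[a] the mass node a sends
    through teleportation; teleport flow a->b is pt[a] / n.
    """
    n = state_network.n_nodes
    s = state_network.out_strength()
    flows: list[dict[int, float]] = [dict() for _ in range(n)]
    pt = np.empty(n)
    for i in range(n):
        if s[i] > 0:
            pt[i] = teleport * p[i]
            scale = (1.0 - teleport) * p[i] / s[i]
            for j, w in state_network.links[i].items():
                flows[i][j] = flows[i].get(j, 0.0) + scale * w
        else:
            pt[i] = p[i]
    return flows, pt


def codelength(
    state_network: StateNetwork,
    partition: MultilayerPartition,
    teleport: float = 0.01,
    visit_rates: np.ndarray | None = None,
) -> CodelengthResult:
    """Two-level map-equation description length of a partition, in bits."""
    n = state_network.n_nodes
    missing = [node for node in state_network.nodes if node not in partition.assignment]
    if missing:
        raise ValueError(f"partition missing state node(s), e.g. {missing[0]}")
    p = stationary_flow(state_network, teleport) if visit_rates is None else visit_rates
    flows, pt = _flow_terms(state_network, p, teleport)

    module_of = np.array(
        [partition.assignment[node] for node in state_network.nodes]
    )
    mods = np.unique(module_of)
    remap = {m: k for k, m in enumerate(mods)}
    midx = np.array([remap[m] for m in module_of])
    n_mod = len(mods)

    p_mod = np.zeros(n_mod)
    pt_mod = np.zeros(n_mod)
    size_mod = np.zeros(n_mod)
    w_mod = np.zeros(n_mod)  # internal link flow
    np.add.at(p_mod, midx, p)
    np.add.at(pt_mod, midx, pt)
    np.add.at(size_mod, midx, 1.0)
    for i in range(n):
        mi = midx[i]
        for j, f in flows[i].items():
            if midx[j] == mi:
                w_mod[mi] += f
    q_mod = p_mod - w_mod - pt_mod * size_mod / n
    q_mod = np.maximum(q_mod, 0.0)
    q = float(q_mod.sum())

    node_term = -sum(_plogp(float(x)) for x in p)
    index_length = _plogp(q) - sum(_plogp(float(x)) for x in q_mod)
    module_length = (
        -sum(_plogp(float(x)) for x in q_mod)
        + sum(_plogp(float(x)) for x in (p_mod + q_mod))
        + node_term
    )
    L = index_length + module_length
    rates = {node: float(p[i]) for i, node in enumerate(state_network.nodes)}
    return CodelengthResult(
        L=float(L),
        index_length=float(index_length),
        module_length=float(module_length),
        visit_rates=rates,
    )


# ---------------------------------------------------------------------------
# multilayer construction

def build_multilayer(layer_networks: Sequence, r: float) -> StateNetwork:
    """Couple per-layer networks into one directed state network.

    Intra-layer links carry (1 - r) of a state node's strength.  The
    remaining fraction r is spread over the node's neighborhoods in other
    layers, each layer l' weighted by the similarity of i's normalized
    neighbor-weight profile there to the profile in the current layer
    (overlap coefficient sigma = sum_j min(w_hat_ij^l, w_hat_ij^l'),
    normalized over candidate layers).  Disjoint neighborhoods get no
    cross-layer flow; a node absent from a layer has no state node there.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"relax rate must lie in [0, 1], got {r}")
    nodes: list[StateNode] = []
    for ln in layer_networks:
        nodes.extend((tag, ln.layer_index) for tag in ln.node_ids)
    index = {node: k for k, node in enumerate(nodes)}
    links: dict[int, dict[int, float]] = {}

    # per (tag, layer): normalized neighbor profile and strength
    profiles: dict[str, dict[int, dict[str, float]]] = {}
    strengths: dict[str, dict[int, float]] = {}
    for ln in layer_networks:
        A = ln.A
        for i, tag in enumerate(ln.node_ids):
            s = float(A[i].sum())
            strengths.setdefault(tag, {})[ln.layer_index] = s
            if s > 0:
                prof = {
                    ln.node_ids[j]: float(A[i, j]) / s
                    for j in range(len(ln.node_ids))
                    if A[i, j] > 0
                }
                profiles.setdefault(tag, {})[ln.layer_index] = prof

    def add(a: int, b: int, w: float) -> None:
        if w > 0:
            links.setdefault(a, {})[b] = links.setdefault(a, {}).get(b, 0.0) + w

    for ln in layer_networks:
        l = ln.layer_index
        A = ln.A
        for i, tag in enumerate(ln.node_ids):
            s_il = strengths[tag][l]
            if s_il <= 0:
                continue
            a = index[(tag, l)]
            # cross-layer targets, weighted by neighborhood-profile similarity
            sigmas: dict[int, float] = {}
            if r > 0.0:
                my_prof = profiles.get(tag, {}).get(l, {})
                for lp in profiles.get(tag, {}):
                    if lp == l:
                        continue
                    sig = sum(
                        min(my_prof.get(nb, 0.0), w)
                        for nb, w in profiles[tag][lp].items()
                    )
                    if sig > 0:
                        sigmas[lp] = sig
            total_sigma = sum(sigmas.values())
            # when nothing is similar the relaxed share has nowhere to go
            # and stays within the layer
            intra_scale = (1.0 - r) if total_sigma > 0 else 1.0
            for j in range(len(ln.node_ids)):
                if A[i, j] > 0:
                    add(a, index[(ln.node_ids[j], l)], intra_scale * float(A[i, j]))
            for lp, sig in sigmas.items():
                rho = sig / total_sigma
                for nb, w_hat in profiles[tag][lp].items():
                    add(a, index[(nb, lp)], r * rho * w_hat * s_il)
    return StateNetwork(nodes=nodes, links=links, r=r)


# ---------------------------------------------------------------------------
# Louvain minimization of L

class _FlowGraph:
    """Aggregatable flow graph for the Louvain passes.

    Each node carries its visit rate p, teleporting mass pt, and the number
    of original state nodes it stands for (teleport targets are uniform over
    original nodes, so aggregate nodes attract flow in proportion to size).
    """

    __slots__ = ("p", "pt", "size", "out", "inn", "selfflow", "n_orig")

    def __init__(
        self,
        p: np.ndarray,
        pt: np.ndarray,
        size: np.ndarray,
        flows: list[dict[int, float]],
        n_orig: int,
    ):
        n = len(p)
        self.p = p
        self.pt = pt
        self.size = size
        self.n_orig = n_orig
        self.out: list[dict[int, float]] = [dict() for _ in range(n)]
        self.inn: list[dict[int, float]] = [dict() for _ in range(n)]
        self.selfflow = np.zeros(n)
        for i, nbrs in enumerate(flows):
            for j, f in nbrs.items():
                if i == j:
                    self.selfflow[i] += f
                else:
                    self.out[i][j] = self.out[i].get(j, 0.0) + f
                    self.inn[j][i] = self.inn[j].get(i, 0.0) + f

    def __len__(self) -> int:
        return len(self.p)


def _partition_cost(
    q_mod: Mapping[int, float], p_mod: Mapping[int, float]
) -> float:
    """Partition-dependent part of L (node term excluded)."""
    q = sum(q_mod.values())
    return (
        _plogp(q)
        - 2.0 * sum(_plogp(x) for x in q_mod.values())
        + sum(_plogp(p_mod[m] + q_mod[m]) for m in q_mod)
    )


def _louvain_level(
    g: _FlowGraph,
    rng: np.random.Generator,
    tol: float,
    max_passes: int,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """One Louvain level: local moves until no move improves L by > tol.

    ``init`` seeds the starting assignment (default: all singletons).
    """
    n = len(g)
    module = np.arange(n) if init is None else np.asarray(init, dtype=np.int64).copy()
    # per-module aggregates
    p_m: dict[int, float] = {}
    pt_m: dict[int, float] = {}
    n_m: dict[int, float] = {}
    w_m: dict[int, float] = {}
    for i in range(n):
        m = int(module[i])
        p_m[m] = p_m.get(m, 0.0) + float(g.p[i])
        pt_m[m] = pt_m.get(m, 0.0) + float(g.pt[i])
        n_m[m] = n_m.get(m, 0.0) + float(g.size[i])
        w_m[m] = w_m.get(m, 0.0) + float(g.selfflow[i])
    for i in range(n):
        mi = int(module[i])
        for j, f in g.out[i].items():
            if int(module[j]) == mi:
                w_m[mi] += f
    N = float(g.n_orig)

    def q_of(m: int) -> float:
        return max(p_m[m] - w_m[m] - pt_m[m] * n_m[m] / N, 0.0)

    def mod_term(m: int) -> float:
        qm = q_of(m)
        return -2.0 * _plogp(qm) + _plogp(p_m[m] + qm)

    q_total = sum(q_of(m) for m in p_m)

    improved_any = True
    for _pass in range(max_passes):
        if not improved_any:
            break
        improved_any = False
        order = rng.permutation(n)
        for v in order:
            a = int(module[v])
            # flow between v and each touched module
            conn: dict[int, list[float]] = {}
            for j, f in g.out[v].items():
                conn.setdefault(int(module[j]), [0.0, 0.0])[0] += f
            for j, f in g.inn[v].items():
                conn.setdefault(int(module[j]), [0.0, 0.0])[1] += f
            conn.setdefault(a, [0.0, 0.0])
            if len(conn) == 1:
                continue
            pv, ptv, nv, sv = float(g.p[v]), float(g.pt[v]), float(g.size[v]), float(
                g.selfflow[v]
            )
            out_a, in_a = conn[a]
            # stats of module a without v
            pa = p_m[a] - pv
            pta = pt_m[a] - ptv
            na = n_m[a] - nv
            wa = w_m[a] - out_a - in_a - sv
            qa_old = q_of(a)
            qa_new = max(pa - wa - pta * na / N, 0.0) if na > 0 else 0.0
            term_a_old = mod_term(a)
            term_a_new = (-2.0 * _plogp(qa_new) + _plogp(pa + qa_new)) if na > 0 else 0.0

            best_b, best_delta = a, -1e-300
            base_q = q_total - qa_old + qa_new
            for b, (out_b, in_b) in conn.items():
                if b == a:
                    continue
                pb = p_m[b] + pv
                ptb = pt_m[b] + ptv
                nb = n_m[b] + nv
                wb = w_m[b] + out_b + in_b + sv
                qb_old = q_of(b)
                qb_new = max(pb - wb - ptb * nb / N, 0.0)
                term_b_old = mod_term(b)
                term_b_new = -2.0 * _plogp(qb_new) + _plogp(pb + qb_new)
                q_new = base_q - qb_old + qb_new
                delta = (
                    (_plogp(q_total) - _plogp(q_new))
                    + (term_a_old - term_a_new)
                    + (term_b_old - term_b_new)
                )  # positive delta = reduction of L
                if delta > best_delta + 1e-16:
                    best_delta = delta
                    best_b = b
            if best_b != a and best_delta > tol:
                b = best_b
                out_b, in_b = conn[b]
                module[v] = b
                p_m[a], pt_m[a], n_m[a], w_m[a] = pa, pta, na, wa
                p_m[b] += pv
                pt_m[b] += ptv
                n_m[b] += nv
                w_m[b] += out_b + in_b + sv
                if n_m[a] <= 0:
                    for d in (p_m, pt_m, n_m, w_m):
                        del d[a]
                q_total = sum(q_of(m) for m in p_m)
                improved_any = True
    return module


def _aggregate(g: _FlowGraph, module: np.ndarray) -> tuple[_FlowGraph, np.ndarray]:
    mods = np.unique(module)
    remap = {int(m): k for k, m in enumerate(mods)}
    midx = np.array([remap[int(m)] for m in module])
    k = len(mods)
    p = np.zeros(k)
    pt = np.zeros(k)
    size = np.zeros(k)
    np.add.at(p, midx, g.p)
    np.add.at(pt, midx, g.pt)
    np.add.at(size, midx, g.size)
    flows: list[dict[int, float]] = [dict() for _ in range(k)]
    for i in range(len(g)):
        mi = int(midx[i])
        flows[mi][mi] = flows[mi].get(mi, 0.0) + float(g.selfflow[i])
        for j, f in g.out[i].items():
            mj = int(midx[j])
            flows[mi][mj] = flows[mi].get(mj, 0.0) + f
    return _FlowGraph(p, pt, size, flows, g.n_orig), midx


def louvain_minimize(
    state_network: StateNetwork,
    rng: np.random.Generator | int | None = None,
    teleport: float = 0.01,
    tol: float = 1e-10,
    max_passes: int = 100,
) -> tuple[MultilayerPartition, ModularityResult]:
    """Minimize the map-equation codelength by Louvain local moves.

    Starts from singletons, sweeps nodes in rng-shuffled order moving each to
    the first best-improving neighbouring module, aggregates, and repeats
    until no move reduces L by more than ``tol`` bits.  Returns the partition
    (module labels in order of first appearance) and M = L_before / L_after.
    The one-module solution is the fallback, so M >= 1 always.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = stationary_flow(state_network, teleport)
    flows, pt = _flow_terms(state_network, p, teleport)
    n = state_network.n_nodes

    def run(init: np.ndarray | None) -> np.ndarray:
        g = _FlowGraph(p.copy(), pt.copy(), np.ones(n), flows, n)
        membership = np.arange(n)
        level_init = init
        for _level in range(max_passes):
            local = _louvain_level(g, rng, tol, max_passes, init=level_init)
            level_init = None
            if len(np.unique(local)) == len(g):
                break
            g, midx = _aggregate(g, local)
            membership = midx[membership]
            if len(g) == 1:
                break
        return membership

    one_module = MultilayerPartition({node: 0 for node in state_network.nodes})
    L_before = codelength(state_network, one_module, teleport, visit_rates=p).L

    # Two starting points: all-singletons, and one module per individual.
    # The latter escapes the well-known barrier where per-layer blocks of a
    # persistent module cannot be merged by pairwise moves.
    tags = {node[0] for node in state_network.nodes}
    tag_index = {t: k for k, t in enumerate(sorted(tags))}
    by_individual = np.array(
        [tag_index[node[0]] for node in state_network.nodes], dtype=np.int64
    )
    best_partition = None
    L_after = np.inf
    for init in (None, by_individual):
        membership = run(init)
        assignment = {
            node: int(membership[i]) for i, node in enumerate(state_network.nodes)
        }
        cand = MultilayerPartition(assignment).relabel_by_first_appearance()
        L_cand = codelength(state_network, cand, teleport, visit_rates=p).L
        if L_cand < L_after:
            best_partition, L_after = cand, L_cand
    partition = best_partition
    if L_after >= L_before - tol:
        partition = one_module
        L_after = L_before
    M = L_before / L_after if L_after > 0 else 1.0
    return partition, ModularityResult(
        M=float(M), r=state_network.r, L_before=float(L_before),
        L_after=float(L_after), partition=partition,
    )


# ---------------------------------------------------------------------------
# sex-specific / filtered modularity under a fixed partition

def modularity_for_subgraph(
    layer_networks: Sequence,
    fixed_partition: MultilayerPartition,
    edge_filter: Callable[[str, str], bool],
    node_filter: Callable[[str, int], bool] | None = None,
    r: float = 0.6,
    teleport: float = 0.01,
) -> float:
    """Compression rate of the FIXED partition on a filtered network.

    Edges are kept when ``edge_filter(tag_i, tag_j)`` is true (e.g. only
    female-female interactions); ``node_filter(tag, layer_index)`` can drop
    nodes (e.g. non-adults).  The clustering itself is not re-optimized.
    """
    from demeflow.layers import LayerNetwork

    filtered = []
    any_edge = False
    for ln in layer_networks:
        keep = [
            i
            for i, tag in enumerate(ln.node_ids)
            if node_filter is None or node_filter(tag, ln.layer_index)
        ]
        ids = [ln.node_ids[i] for i in keep]
        A = ln.A[np.ix_(keep, keep)].copy()
        for a in range(len(ids)):
            for b in range(len(ids)):
                if a != b and A[a, b] > 0 and not edge_filter(ids[a], ids[b]):
                    A[a, b] = 0.0
        if np.any(A > 0):
            any_edge = True
        if ids:
            filtered.append(LayerNetwork(ln.layer_index, ids, A))
    if not any_edge:
        raise ValueError("no interactions of requested class")
    net = build_multilayer(filtered, r)
    p = stationary_flow(net, teleport)
    one = MultilayerPartition({node: 0 for node in net.nodes})
    fixed = fixed_partition.restrict(net.nodes)
    L_before = codelength(net, one, teleport, visit_rates=p).L
    L_after = codelength(net, fixed, teleport, visit_rates=p).L
    return float(L_before / L_after)


def sex_pair_filter(individuals: Mapping[str, object], kind: str) -> Callable[[str, str], bool]:
    """Edge filters for the sex-specific modularity: 'FF', 'MM', 'FM' or 'all'."""
    if kind == "all":
        return lambda a, b: True
    if kind not in ("FF", "MM", "FM"):
        raise ValueError(f"unknown interaction class {kind!r}")

    def fltr(a: str, b: str) -> bool:
        sexes = {individuals[a].sex, individuals[b].sex}
        if kind == "FM":
            return sexes == {"F", "M"}
        return sexes == {kind[0]}

    return fltr


def adult_node_filter(
    individuals: Mapping[str, object],
    mid_time_days: Mapping[int, float],
    adult_age_days: float = 50.0,
) -> Callable[[str, int], bool]:
    """Keep only individuals aged >= adult_age_days at the layer mid-time."""
    from demeflow.io_rfid import DAY

    def fltr(tag: str, layer_index: int) -> bool:
        rec = individuals[tag]
        return (mid_time_days[layer_index] * DAY - rec.birth_time) / DAY >= adult_age_days

    return fltr
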