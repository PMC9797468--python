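"""Synthetic enclosure simulator.

Emits RFID reader events, individual metadata, check schedules and a
pedigree with a planted module structure, so the whole pipeline can be
exercised and validated without external data.  The generator emulates the
study conditions it is meant to test: a six-box enclosure with dual-reader
entrances seeded with twelve adult founders (six of each sex), modules that
monopolize disjoint home-box sets, a tunable mixing rate, 20-day gestation,
litters of 3-7 pups, paternity skewed toward a module's dominant male,
50-day maturity, transpondering of pups at 14 days, and occasional
emigration.

Movement is a per-individual alternating renewal process (exponential
out-of-box and in-box durations, integer seconds); every visit emits the
outer/inner entry pair and the inner/outer exit pair with a 1-3 s antenna
lag.  Same seed, same bytes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from demeflow.io_rfid import DAY, IndividualRecord, ReaderEvent
from demeflow.mapeq import MultilayerPartition, StateNode
from demeflow.preprocess import TimeLayer, Visit


@dataclasses.dataclass
class SimConfig:
    n_boxes: int = 6
    n_founders: int = 12  # half F, half M
    duration_days: float = 60.0
    n_modules: int = 2
    mixing: float = 0.05  # probability a visit targets a box outside the home set
    # communal co-nesting: each module holds synchronized group visits that
    # members join; solo visits are short and independent
    communal_gap_mean_s: float = 3600.0
    communal_visit_mean_s: float = 7200.0
    join_prob: float = 0.85
    solo_gap_mean_s: float = 14400.0
    solo_visit_mean_s: float = 600.0
    conception_rate_per_day: float = 0.04  # per adult, non-pregnant female
    litter_size_min: int = 3
    litter_size_max: int = 7
    paternity_skew: float = 0.9  # probability the module's dominant male sires
    gestation_days: float = 20.0
    maturity_days: float = 50.0
    transponder_age_days: float = 14.0
    emigration_rate_per_day: float = 0.002
    minor_check_every_days: float = 3.0
    minor_check_hours: float = 1.0
    major_check_every_days: float = 35.0
    major_check_hours: float = 6.0
    check_start_hour: float = 9.0
    spurious_read_rate: float = 0.0  # per-visit probability of one stray lone read
    founder_age_days: float = 90.0

    def __post_init__(self) -> None:
        for name in ("mixing", "paternity_skew", "emigration_rate_per_day",
                     "spurious_read_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("communal_gap_mean_s", "communal_visit_mean_s",
                     "solo_gap_mean_s", "solo_visit_mean_s",
                     "conception_rate_per_day", "duration_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modules < 1 or self.n_modules > self.n_boxes:
            raise ValueError("need 1 <= n_modules <= n_boxes")


@dataclasses.dataclass
class SimResult:
    events: list[ReaderEvent]
    individuals: dict[str, IndividualRecord]
    checks: list[tuple[float, float, str]]
    pedigree: pd.DataFrame
    truth_modules: dict[str, int]  # tag -> planted module (constant over time)
    config: SimConfig

    def truth_partition(self, state_nodes: Sequence[StateNode]) -> MultilayerPartition:
        """Planted partition expanded onto a set of (tag, layer) state nodes."""
        return MultilayerPartition(
            {node: self.truth_modules[node[0]] for node in state_nodes}
        )


def _home_boxes(n_boxes: int, n_modules: int) -> list[list[str]]:
    """Partition boxes B1..Bn among modules as evenly as possible."""
    boxes = [f"B{k + 1}" for k in range(n_boxes)]
    sets: list[list[str]] = [[] for _ in range(n_modules)]
    for k, b in enumerate(boxes):
        sets[k % n_modules].append(b)
    return sets


def simulate_run(config: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Run the enclosure simulation; returns events, metadata and ground truth."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    n_f = cfg.n_founders // 2
    n_m = cfg.n_founders - n_f
    duration_s = cfg.duration_days * DAY

    homes = _home_boxes(cfg.n_boxes, cfg.n_modules)
    all_boxes = [b for hs in homes for b in hs]

    individuals: dict[str, IndividualRecord] = {}
    module_of: dict[str, int] = {}
    founders_f = [f"F{k + 1:02d}" for k in range(n_f)]
    founders_m = [f"M{k + 1:02d}" for k in range(n_m)]
    # deal founders to modules alternating within each sex, so every module
    # holds both breeding females and at least one male
    for k, tag in enumerate(founders_f):
        module_of[tag] = k % cfg.n_modules
        individuals[tag] = IndividualRecord(
            tag, "F", -cfg.founder_age_days * DAY, founder=True
        )
    for k, tag in enumerate(founders_m):
        module_of[tag] = k % cfg.n_modules
        individuals[tag] = IndividualRecord(
            tag, "M", -cfg.founder_age_days * DAY, founder=True
        )
    for m in range(cfg.n_modules):
        has_f = any(module_of[t] == m for t in founders_f)
        has_m = any(module_of[t] == m for t in founders_m)
        if has_f and not has_m:
            raise ValueError(f"module {m} has breeding females but no male")

    dominant = {
        m: next(t for t in founders_m if module_of[t] == m)
        for m in range(cfg.n_modules)
        if any(module_of[t] == m for t in founders_m)
    }

    # --- demography (day resolution) -------------------------------------
    removal: dict[str, float] = {}
    birth_day: dict[str, float] = {
        t: individuals[t].birth_time / DAY for t in individuals
    }
    pending: list[tuple[float, str, str, int]] = []  # (delivery_day, mother, father, module)
    pregnant: set[str] = set()
    ped_rows = []
    n_pups = 0
    n_litters = 0
    day = 0
    while day < cfg.duration_days:
        # deliveries due today
        due = [x for x in pending if x[0] <= day]
        pending = [x for x in pending if x[0] > day]
        for delivery_day, mother, father, mod in due:
            n_litters += 1
            lid = f"L{n_litters:03d}"
            size = int(rng.integers(cfg.litter_size_min, cfg.litter_size_max + 1))
            for _ in range(size):
                n_pups += 1
                tag = f"P{n_pups:03d}"
                sex = "F" if rng.random() < 0.5 else "M"
                individuals[tag] = IndividualRecord(tag, sex, delivery_day * DAY)
                module_of[tag] = mod
                birth_day[tag] = delivery_day
                ped_rows.append(
                    {
                        "offspring_id": tag,
                        "mother_id": mother,
                        "father_id": father,
                        "delivery_time": delivery_day * DAY,
                        "litter_id": lid,
                    }
                )
            pregnant.discard(mother)
        # conceptions
        for tag in sorted(individuals):
            rec = individuals[tag]
            if rec.sex != "F" or tag in pregnant or tag in removal:
                continue
            age = day - birth_day[tag]
            if age < cfg.maturity_days:
                continue
            if rng.random() < cfg.conception_rate_per_day:
                mod = module_of[tag]
                if mod not in dominant:
                    continue
                males = [
                    t
                    for t in sorted(individuals)
                    if individuals[t].sex == "M"
                    and module_of[t] == mod
                    and t not in removal
                    and day - birth_day[t] >= cfg.maturity_days
                ]
                if not males:
                    continue
                if rng.random() < cfg.paternity_skew and dominant[mod] in males:
                    father = dominant[mod]
                else:
                    father = males[int(rng.integers(len(males)))]
                pending.append((day + cfg.gestation_days, tag, father, mod))
                pregnant.add(tag)
        # emigration (transpondered adults only)
        for tag in sorted(individuals):
            if tag in removal or tag in pregnant:
                continue
            if day - birth_day[tag] < cfg.maturity_days:
                continue
            if rng.random() < cfg.emigration_rate_per_day:
                removal[tag] = float(day + 1)
        day += 1

    individuals = {
        t: dataclasses.replace(
            r, death_or_removal_time=removal[t] * DAY if t in removal else None
        )
        for t, r in individuals.items()
    }
    pedigree = pd.DataFrame(
        ped_rows,
        columns=["offspring_id", "mother_id", "father_id", "delivery_time", "litter_id"],
    )

    # --- movement (second resolution) ------------------------------------
    # Communal schedules first: each module alternates open time and a group
    # visit at one of its home boxes; members join with high probability and
    # small entry/exit jitter, which is what makes within-module edges rest
    # on many long synchronized overlaps.
    communal: list[list[tuple[float, float, str]]] = []
    for m in range(cfg.n_modules):
        sched = []
        t = 0.0
        while True:
            t += max(60.0, rng.exponential(cfg.communal_gap_mean_s))
            dur = max(600.0, rng.exponential(cfg.communal_visit_mean_s))
            if t + dur >= duration_s:
                break
            box = homes[m][int(rng.integers(len(homes[m])))]
            sched.append((t, t + dur, box))
            t += dur
        communal.append(sched)

    events: list[ReaderEvent] = []

    def pick_box(home: list[str], away: list[str]) -> str:
        if cfg.mixing > 0 and away and rng.random() < cfg.mixing:
            return away[int(rng.integers(len(away)))]
        return home[int(rng.integers(len(home)))]

    def emit_visit(tag: str, box: str, t_enter: float, t_exit: float) -> None:
        t_enter, t_exit = round(t_enter), round(t_exit)
        if t_exit - t_enter < 30:
            return
        lag_in = int(rng.integers(1, 4))
        lag_out = int(rng.integers(1, 4))
        events.append(ReaderEvent(t_enter - lag_in, tag, box, "outer"))
        events.append(ReaderEvent(float(t_enter), tag, box, "inner"))
        events.append(ReaderEvent(t_exit - lag_out, tag, box, "inner"))
        events.append(ReaderEvent(float(t_exit), tag, box, "outer"))
        if cfg.spurious_read_rate > 0 and rng.random() < cfg.spurious_read_rate:
            # one stray lone read shortly after the exit: an equivocal signal
            pos = "inner" if rng.random() < 0.5 else "outer"
            stray_box = box if rng.random() < 0.5 else "B1"
            events.append(ReaderEvent(float(t_exit + 4), tag, stray_box, pos))

    for tag in sorted(individuals):
        rec = individuals[tag]
        mod = module_of[tag]
        home = homes[mod]
        away = [b for b in all_boxes if b not in home]
        t_on = max(0.0, rec.birth_time + cfg.transponder_age_days * DAY)
        t_off = min(duration_s, removal.get(tag, np.inf) * DAY)
        t_free = t_on
        for start, end, box in communal[mod]:
            if end <= t_on or start >= t_off:
                continue
            # short solo excursions while the group is dispersed
            while True:
                gap = max(10.0, rng.exponential(cfg.solo_gap_mean_s))
                dur = max(60.0, rng.exponential(cfg.solo_visit_mean_s))
                if t_free + gap + dur + 60.0 >= min(start, t_off):
                    break
                emit_visit(tag, pick_box(home, away), t_free + gap, t_free + gap + dur)
                t_free = t_free + gap + dur
            if start < t_free or end >= t_off:
                continue
            if rng.random() < cfg.join_prob:
                jitter_in = rng.uniform(0.0, 60.0)
                jitter_out = rng.uniform(0.0, 60.0)
                visit_box = box
                if cfg.mixing > 0 and away and rng.random() < cfg.mixing:
                    visit_box = away[int(rng.integers(len(away)))]
                emit_visit(tag, visit_box, start + jitter_in, end - jitter_out)
                t_free = end
    events.sort(key=lambda e: e.timestamp)

    # --- checks -----------------------------------------------------------
    checks: list[tuple[float, float, str]] = []
    d = cfg.minor_check_every_days
    next_major = cfg.major_check_every_days
    while d < cfg.duration_days:
        start = d * DAY + cfg.check_start_hour * 3600.0
        if d >= next_major:
            checks.append((start, start + cfg.major_check_hours * 3600.0, "major"))
            next_major += cfg.major_check_every_days
        else:
            checks.append((start, start + cfg.minor_check_hours * 3600.0, "minor"))
        d += cfg.minor_check_every_days

    return SimResult(
        events=events,
        individuals=individuals,
        checks=checks,
        pedigree=pedigree,
        truth_modules=module_of,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# hand-built fixtures

def make_fixture(name: str) -> dict:
    """Tiny deterministic datasets embedding the worked examples.

    Names: 'toy_visits', 'two_triangles', 'nora_miro', 'occupancy_toy'.
    """
    if name == "toy_visits":
        visits = [
            Visit("a", "B1", 0.0, 100.0),
            Visit("b", "B1", 80.0, 180.0),
        ]
        return {"visits": visits, "overlap_s": 20.0}

    if name == "two_triangles":
        from demeflow.layers import LayerNetwork

        ids = list("abcdef")
        A = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            A[i, j] = A[j, i] = 1.0
        return {
            "network": LayerNetwork(0, ids, A),
            "components": {t: (0 if t in "abc" else 1) for t in ids},
        }

    if name == "nora_miro":
        # A mother conceives in layer 6 and delivers in layer 15; the
        # 20-day gestation window spans exactly 10 layers (6..15).
        layers = []
        for i in range(15):
            layers.append(TimeLayer(i, i * 2 * DAY, (i + 1) * 2 * DAY))
        layers.append(TimeLayer(15, 30 * DAY, 33 * DAY))  # mid 31.5 d
        layers.append(TimeLayer(16, 33 * DAY, 35 * DAY))
        delivery = 32.5 * DAY  # conception at 12.5 d, inside layer 6
        pedigree = pd.DataFrame(
            {
                "offspring_id": ["p1", "p2", "p3"],
                "mother_id": ["nora"] * 3,
                "father_id": ["miro"] * 3,
                "delivery_time": [delivery] * 3,
                "litter_id": ["L1"] * 3,
            }
        )
        red, grey = 0, 1
        full = {}
        partial = {}
        window = list(range(6, 16))  # the 10 gestation-window layers
        for ly in layers:
            for tag in ("nora", "miro", "other"):
                full[(tag, ly.index)] = red if tag != "other" else grey
                partial[(tag, ly.index)] = red if tag != "other" else grey
        # partial association: Miro leaves the red module except in 2 window layers
        for i in window:
            if i not in (6, 7):
                partial[("miro", i)] = grey
        return {
            "layers": layers,
            "pedigree": pedigree,
            "partition_full": MultilayerPartition(full),
            "partition_partial": MultilayerPartition(partial),
            "window_layers": window,
            "red_module": red,
            "gestation_days": 20.0,
        }

    if name == "occupancy_toy":
        visits = [
            Visit("a", "B1", 0.0, 100.0),
            Visit("b", "B1", 0.0, 100.0),
            Visit("c", "B2", 0.0, 100.0),
            Visit("d", "B2", 0.0, 50.0),
        ]
        partition = MultilayerPartition(
            {("a", 0): 0, ("b", 0): 0, ("c", 0): 1, ("d", 0): 0}
        )
        return {"visits": visits, "partition": partition, "layer_index": 0}

    raise ValueError(f"unknown fixture name {name!r}")
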