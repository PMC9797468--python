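"""Pedigree-linked statistics: multiple paternity, persistence of family
bonds within modules, and the deme support of modules.

A module is called a deme when at least one parent pair conceived and
carried a litter while socially associated with it.  Each litter contributes
a support in [0, 1]: the fraction of the gestation-window layers in which
both parents were assigned to the module the mother belonged to at the
estimated conception time (delivery minus the gestation length).  Summed
over litters, the support becomes an effective number of parental pairs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import pandas as pd

from demeflow.io_rfid import DAY
from demeflow.mapeq import MultilayerPartition
from demeflow.preprocess import TimeLayer

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Litter:
    litter_id: str
    mother_id: str
    offspring: list[str]
    fathers: list[str | None]  # per offspring; None = unassigned
    delivery_time: float  # seconds
    gestation_days: float = 20.0

    @property
    def conception_time(self) -> float:
        return self.delivery_time - self.gestation_days * DAY

    @property
    def size(self) -> int:
        return len(self.offspring)

    def conception_layer(self, layers: Sequence[TimeLayer]) -> int:
        """Layer whose span contains the conception time, else the nearest."""
        t = self.conception_time
        for ly in layers:
            if ly.t_start <= t <= ly.t_end:
                return ly.index
        return min(
            layers,
            key=lambda ly: min(abs(ly.t_start - t), abs(ly.t_end - t)),
        ).index


@dataclasses.dataclass
class DemeSupport:
    module_id: int
    effective_pairs: float
    litter_supports: dict[str, float]  # litter_id -> support

    @property
    def is_deme(self) -> bool:
        return self.effective_pairs > 0


def build_litters(
    pedigree: pd.DataFrame, gestation_days: float = 20.0
) -> list[Litter]:
    """Group a pedigree table into litters (see io_rfid.read_pedigree)."""
    litters = []
    for lid, grp in pedigree.groupby("litter_id", sort=False):
        mothers = grp["mother_id"].unique()
        if len(mothers) != 1:
            raise ValueError(f"litter {lid!r} has multiple mothers: {list(mothers)}")
        deliveries = grp["delivery_time"].unique()
        if len(deliveries) != 1:
            raise ValueError(f"litter {lid!r} has multiple delivery times")
        fathers = [None if pd.isna(f) else str(f) for f in grp["father_id"]]
        litters.append(
            Litter(
                litter_id=str(lid),
                mother_id=str(mothers[0]),
                offspring=[str(o) for o in grp["offspring_id"]],
                fathers=fathers,
                delivery_time=float(deliveries[0]),
                gestation_days=gestation_days,
            )
        )
    litters.sort(key=lambda lt: (lt.delivery_time, lt.litter_id))
    return litters


def multiple_paternity(litters: Sequence[Litter]) -> float:
    """Mean probability that two distinct offspring of one litter have
    different fathers.

    Offspring with unassigned fathers are left out; litters with fewer than
    two remaining offspring do not qualify.  NaN when no litter qualifies.
    """
    probs = []
    for lt in litters:
        assigned = [f for f in lt.fathers if f is not None]
        n = len(assigned)
        if n < 2:
            continue
        counts: dict[str, int] = {}
        for f in assigned:
            counts[f] = counts.get(f, 0) + 1
        same = sum(c * (c - 1) for c in counts.values()) / (n * (n - 1))
        probs.append(1.0 - same)
    if not probs:
        return float("nan")
    return float(sum(probs) / len(probs))


def bond_persistence(
    pedigree: pd.DataFrame,
    partition: MultilayerPartition,
    layer_index: int,
    individuals: Mapping[str, object] | None = None,
    filter: str = "all",
) -> float:
    """Proportion of parent-to-offspring arrows lying within modules in a layer.

    Arrows run from each assigned parent to each offspring; both ends must be
    assigned in the layer to count.  ``filter`` restricts to 'mother-daughter'
    or 'father-son' arrows (offspring sex from metadata; offspring of unknown
    sex are excluded from the sex-specific variants only).  NaN when no arrow
    has both ends assigned.
    """
    if filter not in ("all", "mother-daughter", "father-son"):
        raise ValueError(f"unknown filter {filter!r}")
    within = 0
    total = 0
    for row in pedigree.itertuples(index=False):
        child = str(row.offspring_id)
        child_sex = None
        if individuals is not None and child in individuals:
            child_sex = individuals[child].sex
        parents = []
        if not pd.isna(row.mother_id):
            parents.append(("mother", str(row.mother_id)))
        if not pd.isna(row.father_id):
            parents.append(("father", str(row.father_id)))
        for role, parent in parents:
            if filter == "mother-daughter" and not (role == "mother" and child_sex == "F"):
                continue
            if filter == "father-son" and not (role == "father" and child_sex == "M"):
                continue
            pk = (parent, layer_index)
            ck = (child, layer_index)
            if pk not in partition.assignment or ck not in partition.assignment:
                continue
            total += 1
            if partition.assignment[pk] == partition.assignment[ck]:
                within += 1
    if total == 0:
        return float("nan")
    return within / total


def litter_support(
    litter: Litter,
    partition: MultilayerPartition,
    layers: Sequence[TimeLayer],
) -> tuple[int, float] | None:
    """(candidate module, support) for one litter, or None when the litter
    cannot be evaluated (unassigned father, mother unassigned at conception,
    or empty gestation window).

    The candidate module is the mother's assignment in the conception layer;
    the gestation window is the set of layers whose mid-times fall between
    conception and delivery.  Window layers where either parent is
    unassigned count against the support (the denominator is the full
    window).
    """
    fathers = {f for f in litter.fathers if f is not None}
    if len(fathers) != 1:
        logger.warning(
            "litter %s skipped: needs exactly one assigned father, got %d",
            litter.litter_id, len(fathers),
        )
        return None
    father = next(iter(fathers))
    c_layer = litter.conception_layer(layers)
    mother_key = (litter.mother_id, c_layer)
    if mother_key not in partition.assignment:
        logger.warning(
            "litter %s skipped: mother %s unassigned in conception layer %d",
            litter.litter_id, litter.mother_id, c_layer,
        )
        return None
    candidate = partition.assignment[mother_key]
    window = [
        ly.index
        for ly in layers
        if litter.conception_time <= ly.mid_time_days * DAY <= litter.delivery_time
    ]
    if not window:
        logger.warning("litter %s skipped: empty gestation window", litter.litter_id)
        return None
    supporting = 0
    for w in window:
        mk = (litter.mother_id, w)
        fk = (father, w)
        if (
            partition.assignment.get(mk) == candidate
            and partition.assignment.get(fk) == candidate
        ):
            supporting += 1
    return candidate, supporting / len(window)


def deme_support(
    litters: Sequence[Litter],
    partition: MultilayerPartition,
    layers: Sequence[TimeLayer],
) -> dict[int, DemeSupport]:
    """Effective number of parental pairs supporting each module as a deme.

    Litter supports are summed per candidate module: one pair carrying two
    litters in full association counts as two effective pairs; two pairs at
    half association count as one.  Modules never supported are not demes.
    """
    by_module: dict[int, DemeSupport] = {
        m: DemeSupport(m, 0.0, {}) for m in partition.modules()
    }
    for lt in litters:
        res = litter_support(lt, partition, layers)
        if res is None:
            continue
        module, support = res
        ds = by_module.setdefault(module, DemeSupport(module, 0.0, {}))
        ds.effective_pairs += support
        ds.litter_supports[lt.litter_id] = support
    return by_module
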