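"""File formats, domain records and run configuration.

All timestamps are held internally as seconds since the experiment start
(float).  Input files may give timestamps either as numeric seconds or as
ISO-8601 strings; in the latter case the earliest timestamp in the file
defines second zero unless an explicit origin is passed.  Time axes reported
downstream (layer mid-times) use days of 86 400 s.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAY = 86_400.0

#: box_id values that denote readers outside nest boxes
SPECIAL_BOXES = frozenset({"exit-tube", "connector-left", "connector-right"})

_POSITIONS = frozenset({"inner", "outer", "single"})


@dataclasses.dataclass(frozen=True)
class ReaderEvent:
    """One antenna detection: who, where, which antenna, when."""

    timestamp: float  # seconds since experiment start
    tag_id: str
    box_id: str
    position: str  # {inner, outer, single}
    enclosure_id: str = "E1"

    def __post_init__(self) -> None:
        if self.position not in _POSITIONS:
            raise ValueError(f"unknown position token: {self.position!r}")
        if self.position == "single" and self.box_id not in SPECIAL_BOXES:
            raise ValueError(
                f"position 'single' is reserved for tube/exit readers, got box {self.box_id!r}"
            )


@dataclasses.dataclass(frozen=True)
class IndividualRecord:
    """Metadata for one individual."""

    tag_id: str
    sex: str  # {F, M}
    birth_time: float  # seconds since experiment start; founders are negative (age ~90 d at start)
    founder: bool = False
    death_or_removal_time: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.death_or_removal_time is not None and not (
            self.birth_time < self.death_or_removal_time
        ):
            raise ValueError(
                f"{self.tag_id}: birth_time must precede death_or_removal_time"
            )

    def age_days(self, t: float) -> float:
        return (t - self.birth_time) / DAY


@dataclasses.dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the study protocol."""

    layer_max_hours: float = 48.0
    gap_max_hours: float = 1.0
    layer_min_hours_for_merge: float = 24.0
    gestation_days: float = 20.0
    adult_age_days: float = 50.0
    relax_rates: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 21), 10))
    bootstrap_reps: int = 100
    teleport_rate: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("layer_max_hours", "gap_max_hours", "layer_min_hours_for_merge",
                     "gestation_days", "adult_age_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(r < 0 or r > 1 for r in self.relax_rates):
            raise ValueError("relax rates must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "relax_rates" in raw:
            raw["relax_rates"] = tuple(raw["relax_rates"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# timestamp handling

def _parse_times(col: pd.Series, origin: float | str | None) -> np.ndarray:
    """Return seconds-since-start as float64.

    Numeric columns pass through (origin subtracted if numeric); string
    columns are parsed as ISO-8601 and referenced to `origin` (ISO string) or
    to the earliest time present.
    """
    numeric = pd.to_numeric(col, errors="coerce")
    if not numeric.isna().any():
        values = numeric.to_numpy(dtype=float)
        if origin is not None and not isinstance(origin, str):
            values = values - float(origin)
        return values
    stamps = pd.to_datetime(col, format="ISO8601")
    t0 = pd.to_datetime(origin) if isinstance(origin, str) else stamps.min()
    return (stamps - t0).dt.total_seconds().to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers

def read_events(path: str | Path, origin: float | str | None = None) -> list[ReaderEvent]:
    """Read a reader-event log (CSV: timestamp, tag_id, box_id, position, enclosure_id).

    Events are returned sorted by timestamp with a stable sort, so rows that
    share a timestamp keep their file order.  Malformed rows raise with the
    offending line number.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["timestamp", "tag_id", "box_id", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "enclosure_id" not in df.columns:
        df["enclosure_id"] = "E1"
    bad = df[required].isna().any(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")
    try:
        times = _parse_times(df["timestamp"], origin)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp ({exc})") from exc
    events = []
    for i, t in enumerate(times):
        try:
            events.append(
                ReaderEvent(
                    timestamp=float(t),
                    tag_id=df["tag_id"].iat[i],
                    box_id=df["box_id"].iat[i],
                    position=df["position"].iat[i],
                    enclosure_id=df["enclosure_id"].iat[i],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    events.sort(key=lambda e: e.timestamp)  # Timsort is stable
    return events


def write_events(events: Iterable[ReaderEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.timestamp, e.tag_id, e.box_id, e.position, e.enclosure_id) for e in events],
        columns=["timestamp", "tag_id", "box_id", "position", "enclosure_id"],
    )
    df.to_csv(path, index=False)


def read_individuals(path: str | Path) -> dict[str, IndividualRecord]:
    df = pd.read_csv(path, dtype={"tag_id": str, "sex": str})
    out: dict[str, IndividualRecord] = {}
    for i, row in df.iterrows():
        tag = str(row["tag_id"])
        if tag in out:
            raise ValueError(f"{path}: duplicate tag_id {tag!r}")
        death = row.get("death_or_removal_time", np.nan)
        out[tag] = IndividualRecord(
            tag_id=tag,
            sex=str(row["sex"]),
            birth_time=float(row["birth_time"]),
            founder=bool(row.get("founder", False)),
            death_or_removal_time=None if pd.isna(death) else float(death),
        )
    return out


def write_individuals(records: dict[str, IndividualRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.tag_id, r.sex, r.birth_time, r.founder,
             "" if r.death_or_removal_time is None else r.death_or_removal_time)
            for r in records.values()
        ],
        columns=["tag_id", "sex", "birth_time", "founder", "death_or_removal_time"],
    )
    df.to_csv(path, index=False)


def read_checks(path: str | Path, origin: float | str | None = None) -> list[tuple[float, float, str]]:
    """Read the enclosure-check schedule: one (start, end, kind) interval per row."""
    df = pd.read_csv(path, dtype={"kind": str})
    out = []
    starts = _parse_times(df["start"], origin)
    ends = _parse_times(df["end"], origin)
    for i in range(len(df)):
        kind = df["kind"].iat[i] if "kind" in df.columns else "minor"
        if kind not in ("minor", "major"):
            raise ValueError(f"{path}: line {i + 2}: unknown check kind {kind!r}")
        out.append((float(starts[i]), float(ends[i]), kind))
    return out


def read_pedigree(path: str | Path, origin: float | str | None = None) -> pd.DataFrame:
    """Read a pedigree table grouped into litters.

    Columns: offspring_id, mother_id, father_id, delivery_time, litter_id.
    father_id may be empty (unassigned paternity).  Returns a DataFrame sorted
    by (delivery_time, litter_id) with father_id as NaN where unassigned.
    """
    df = pd.read_csv(
        path,
        dtype={"offspring_id": str, "mother_id": str, "father_id": str, "litter_id": str},
    )
    required = ["offspring_id", "mother_id", "father_id", "delivery_time", "litter_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df["offspring_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate offspring_id {df['offspring_id'][dup].iloc[0]!r}"
        )
    self_parent = (df["offspring_id"] == df["mother_id"]) | (
        df["offspring_id"] == df["father_id"]
    )
    if self_parent.any():
        raise ValueError(
            f"{path}: offspring {df['offspring_id'][self_parent].iloc[0]!r} listed as its own parent"
        )
    df["delivery_time"] = _parse_times(df["delivery_time"], origin)
    return df.sort_values(["delivery_time", "litter_id"], kind="stable").reset_index(drop=True)


def write_pedigree(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# partitions and networks

def write_partition(assignment: dict[tuple[str, int], int], path: str | Path) -> None:
    """Write a multilayer partition as CSV (tag_id, layer_index, module_id)."""
    rows = sorted(assignment.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    df = pd.DataFrame(
        [(tag, layer, module) for (tag, layer), module in rows],
        columns=["tag_id", "layer_index", "module_id"],
    )
    df.to_csv(path, index=False)


def read_partition(path: str | Path) -> dict[tuple[str, int], int]:
    df = pd.read_csv(path, dtype={"tag_id": str})
    return {
        (str(r.tag_id), int(r.layer_index)): int(r.module_id)
        for r in df.itertuples(index=False)
    }


def write_layer_graphml(layer_network, path: str | Path) -> None:
    """Export one layer's co-occupancy network as GraphML."""
    import networkx as nx

    g = layer_network.to_networkx()
    nx.write_graphml(g, path)


def write_layer_matrix(layer_network, path: str | Path) -> None:
    """Export one layer's adjacency as a dense matrix CSV (labelled rows/cols)."""
    df = pd.DataFrame(
        layer_network.A, index=layer_network.node_ids, columns=layer_network.node_ids
    )
    df.to_csv(path)


def write_layers_json(layers: Sequence, path: str | Path) -> None:
    payload = [
        {
            "index": ly.index,
            "t_start": ly.t_start,
            "t_end": ly.t_end,
            "mid_time_days": ly.mid_time_days,
        }
        for ly in layers
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
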