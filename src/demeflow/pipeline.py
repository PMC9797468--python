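"""End-to-end convenience wrappers around the processing stages."""

from __future__ import annotations

import dataclasses
from typing import Sequence

from demeflow.io_rfid import ReaderEvent, RunConfig
from demeflow.layers import LayerNetwork, build_all_layer_networks
from demeflow.mapeq import (
    ModularityResult,
    MultilayerPartition,
    build_multilayer,
    louvain_minimize,
)
from demeflow.preprocess import (
    TimeLayer,
    Visit,
    build_time_layers,
    censor_checks,
    censor_windows,
    clip_visits,
    extract_visits,
    slice_visits_into_layers,
)


@dataclasses.dataclass
class Preprocessed:
    visits: list[Visit]
    layers: list[TimeLayer]
    networks: list[LayerNetwork]
    n_equivocal: int


def preprocess_events(
    events: Sequence[ReaderEvent],
    checks: Sequence[tuple[float, float, str]] = (),
    config: RunConfig | None = None,
) -> Preprocessed:
    """events -> censoring -> visits -> layers -> per-layer networks."""
    config = config or RunConfig()
    censored = censor_checks(events, checks) if checks else list(events)
    visits, n_equivocal = extract_visits(censored)
    if checks:
        visits = clip_visits(visits, censor_windows(checks))
    layers = build_time_layers(censored, config)
    layers = slice_visits_into_layers(layers, visits)
    networks = build_all_layer_networks([ly for ly in layers if ly.visits])
    return Preprocessed(visits, layers, networks, n_equivocal)


def cluster(
    networks: Sequence[LayerNetwork],
    r: float = 0.6,
    seed: int = 0,
    teleport: float = 0.01,
) -> tuple[MultilayerPartition, ModularityResult]:
    """Multilayer coupling at relax rate r followed by codelength minimization."""
    net = build_multilayer(networks, r)
    return louvain_minimize(net, rng=seed, teleport=teleport)
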