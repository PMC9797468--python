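import numpy as np
import pytest

import demeflow as dm
from demeflow.pipeline import preprocess_events


@pytest.fixture(scope="session")
def small_sim():
    """One short planted-2-module enclosure run, preprocessed."""
    cfg = dm.SimConfig(duration_days=15, mixing=0.05)
    sim = dm.simulate_run(cfg, seed=42)
    pre = preprocess_events(sim.events, sim.checks)
    return sim, pre


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def enumerate_set_partitions(items):
    """All partitions of a sequence (restricted-growth strings)."""
    items = list(items)
    if not items:
        yield []
        return

    def rec(k, groups):
        if k == len(items):
            yield [list(g) for g in groups]
            return
        for g in groups:
            g.append(items[k])
            yield from rec(k + 1, groups)
            g.pop()
        groups.append([items[k]])
        yield from rec(k + 1, groups)
        groups.pop()

    yield from rec(1, [[items[0]]])
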