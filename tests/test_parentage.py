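import math

import numpy as np
import pandas as pd
import pytest

import demeflow as dm
from demeflow.io_rfid import DAY
from demeflow.mapeq import MultilayerPartition
from demeflow.parentage import (
    Litter,
    bond_persistence,
    build_litters,
    deme_support,
    litter_support,
    multiple_paternity,
)


def litter(fathers, lid="L1", mother="mom", delivery=30 * DAY):
    return Litter(
        litter_id=lid,
        mother_id=mother,
        offspring=[f"p{i}" for i in range(len(fathers))],
        fathers=list(fathers),
        delivery_time=delivery,
    )


class TestMultiplePaternity:
    def test_single_sire_everywhere_is_zero(self):
        assert multiple_paternity([litter("AAA"), litter("BB", lid="L2")]) == 0.0

    def test_two_pups_different_fathers_is_one(self):
        assert multiple_paternity([litter("AB")]) == 1.0

    def test_mixed_litters_closed_form(self):
        # {A,A,B}: 1 - (2*1)/(3*2) = 2/3; {A,A}: 0; mean = 1/3
        val = multiple_paternity([litter("AAB"), litter("AA", lid="L2")])
        assert val == pytest.approx(1 / 3)

    def test_unassigned_fathers_excluded(self):
        # only the two assigned-father pups qualify
        val = multiple_paternity([litter(["A", None, "B"])])
        assert val == 1.0
        assert math.isnan(multiple_paternity([litter(["A", None])]))

    def test_matches_monte_carlo_sibling_pair_oracle(self, rng):
        # independent oracle: sample unordered sibling pairs without
        # replacement and count discordant fathers
        litters = []
        for k in range(12):
            n = int(rng.integers(2, 8))
            fathers = [f"M{rng.integers(1, 4)}" for _ in range(n)]
            litters.append(litter(fathers, lid=f"L{k}"))
        exact = multiple_paternity(litters)
        draws = 100_000
        hits = 0
        for _ in range(draws):
            lt = litters[int(rng.integers(len(litters)))]
            i, j = rng.choice(len(lt.fathers), size=2, replace=False)
            hits += lt.fathers[i] != lt.fathers[j]
        mc = hits / draws
        se = math.sqrt(mc * (1 - mc) / draws)
        assert abs(exact - mc) < 3 * se + 1e-12


class TestBondPersistence:
    def _setup(self):
        ped = pd.DataFrame(
            {
                "offspring_id": ["d1", "s1", "d2", "s2"],
                "mother_id": ["momA", "momA", "momB", "momB"],
                "father_id": ["dadA", "dadA", "dadB", "dadB"],
                "delivery_time": [10.0 * DAY] * 4,
                "litter_id": ["L1", "L1", "L2", "L2"],
            }
        )
        sexes = {"d1": "F", "s1": "M", "d2": "F", "s2": "M",
                 "momA": "F", "dadA": "M", "momB": "F", "dadB": "M"}

        class R:
            def __init__(self, s):
                self.sex = s

        individuals = {t: R(s) for t, s in sexes.items()}
        return ped, individuals

    def test_all_arrows_within_modules(self):
        ped, ind = self._setup()
        assignment = {(t, 0): 0 for t in ["d1", "s1", "momA", "dadA"]}
        assignment.update({(t, 0): 1 for t in ["d2", "s2", "momB", "dadB"]})
        part = MultilayerPartition(assignment)
        assert bond_persistence(ped, part, 0) == 1.0

    def test_split_family_counts_fractional(self):
        ped, ind = self._setup()
        # d1 leaves its parents' module: 2 of 8 arrows cross
        assignment = {(t, 0): 0 for t in ["s1", "momA", "dadA"]}
        assignment[("d1", 0)] = 9
        assignment.update({(t, 0): 1 for t in ["d2", "s2", "momB", "dadB"]})
        part = MultilayerPartition(assignment)
        assert bond_persistence(ped, part, 0) == pytest.approx(6 / 8)

    def test_sex_specific_filters(self):
        ped, ind = self._setup()
        assignment = {(t, 0): 0 for t in ["s1", "momA", "dadA"]}
        assignment[("d1", 0)] = 9
        assignment.update({(t, 0): 1 for t in ["d2", "s2", "momB", "dadB"]})
        part = MultilayerPartition(assignment)
        # mother-daughter arrows: momA->d1 (cross), momB->d2 (within)
        assert bond_persistence(ped, part, 0, ind, filter="mother-daughter") == 0.5
        # father-son arrows: dadA->s1, dadB->s2, both within
        assert bond_persistence(ped, part, 0, ind, filter="father-son") == 1.0

    def test_unassigned_members_excluded(self):
        ped, _ = self._setup()
        part = MultilayerPartition({("momA", 0): 0, ("d1", 0): 0})
        assert bond_persistence(ped, part, 0) == 1.0  # only momA->d1 counts

    def test_no_assigned_arrows_gives_nan(self):
        ped, _ = self._setup()
        part = MultilayerPartition({("zzz", 0): 0})
        assert math.isnan(bond_persistence(ped, part, 0))


class TestDemeSupport:
    def test_full_association_worked_example(self):
        fx = dm.make_fixture("nora_miro")
        litters = build_litters(fx["pedigree"], fx["gestation_days"])
        (lt,) = litters
        assert lt.conception_layer(fx["layers"]) == 6
        module, support = litter_support(lt, fx["partition_full"], fx["layers"])
        assert module == fx["red_module"]
        assert support == 1.0

    def test_two_layer_association_worked_example(self):
        fx = dm.make_fixture("nora_miro")
        (lt,) = build_litters(fx["pedigree"], fx["gestation_days"])
        module, support = litter_support(lt, fx["partition_partial"], fx["layers"])
        assert module == fx["red_module"]
        assert support == pytest.approx(0.2)

    def test_gestation_window_is_ten_layers(self):
        fx = dm.make_fixture("nora_miro")
        (lt,) = build_litters(fx["pedigree"], fx["gestation_days"])
        window = [
            ly.index
            for ly in fx["layers"]
            if lt.conception_time <= ly.mid_time_days * DAY <= lt.delivery_time
        ]
        assert window == fx["window_layers"]
        assert len(window) == 10

    def test_effective_pairs_sum_over_litters(self):
        # one pair, two fully associated litters -> 2 effective pairs;
        # two pairs at half association -> 1
        fx = dm.make_fixture("nora_miro")
        ped = fx["pedigree"]
        second = ped.copy()
        second["offspring_id"] = ["q1", "q2", "q3"]
        second["litter_id"] = "L2"
        litters = build_litters(pd.concat([ped, second]), fx["gestation_days"])
        support = deme_support(litters, fx["partition_full"], fx["layers"])
        assert support[fx["red_module"]].effective_pairs == pytest.approx(2.0)

        half = {}
        for (tag, ly), m in fx["partition_full"].assignment.items():
            half[(tag, ly)] = m
        for i in fx["window_layers"][: len(fx["window_layers"]) // 2]:
            half[("miro", i)] = 1  # half the window outside the module
        two_pairs = ped.copy()
        two_pairs_b = ped.copy()
        two_pairs_b["offspring_id"] = ["r1", "r2", "r3"]
        two_pairs_b["litter_id"] = "L9"
        litters2 = build_litters(pd.concat([two_pairs, two_pairs_b]), fx["gestation_days"])
        sup2 = deme_support(litters2, MultilayerPartition(half), fx["layers"])
        assert sup2[fx["red_module"]].effective_pairs == pytest.approx(1.0)

    def test_unsupported_module_is_not_a_deme(self):
        fx = dm.make_fixture("nora_miro")
        litters = build_litters(fx["pedigree"], fx["gestation_days"])
        support = deme_support(litters, fx["partition_full"], fx["layers"])
        grey = 1
        assert support[grey].effective_pairs == 0.0
        assert not support[grey].is_deme
        assert support[fx["red_module"]].is_deme

    def test_unassigned_father_skips_litter(self):
        fx = dm.make_fixture("nora_miro")
        ped = fx["pedigree"].copy()
        ped["father_id"] = np.nan
        (lt,) = build_litters(ped, fx["gestation_days"])
        assert litter_support(lt, fx["partition_full"], fx["layers"]) is None

    def test_simulated_dominant_male_control(self):
        # complete paternity control and no mixing: multiple paternity is 0
        # and each planted module with a litter draws positive support
        from demeflow.pipeline import preprocess_events, cluster

        cfg = dm.SimConfig(
            duration_days=45, mixing=0.02, paternity_skew=1.0,
            conception_rate_per_day=0.2,
        )
        sim = dm.simulate_run(cfg, seed=9)
        assert len(sim.pedigree) > 0
        litters = build_litters(sim.pedigree, cfg.gestation_days)
        assert multiple_paternity(litters) == 0.0
        pre = preprocess_events(sim.events, sim.checks)
        part, _ = cluster(pre.networks, r=0.6, seed=9)
        support = deme_support(litters, part, pre.layers)
        assert any(ds.is_deme for ds in support.values())
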