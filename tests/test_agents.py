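import math

import numpy as np
import pytest

from lobulesim import agents as ag
from lobulesim.fields import CytokineField

EXTENT = (0.0, 0.0, 10.0, 10.0)


def make_fields(tgf_level=0.0):
    flds = {}
    for name in ("tnf", "tgf", "hmgb1"):
        flds[name] = CytokineField(name, EXTENT, 1.0, 0.0, 0.0, 1.0)
    if tgf_level:
        flds["tgf"].grid[:] = tgf_level
    return flds


class TestHepatocyteStep:
    def test_quiet_cell_does_nothing(self, rng):
        cell = ag.Hepatocyte(site=0, age=10, lifespan=100)
        event = ag.hepatocyte_step(cell, False, [], False, rng,
                                   ag.HepatocyteParams())
        assert event == ("none",)
        assert cell.age == 11

    def test_senescence_cap_blocks_replication(self, rng):
        params = ag.HepatocyteParams(replication_prob=1.0)
        cell = ag.Hepatocyte(site=0, age=1, lifespan=100, replication_count=2)
        event = ag.hepatocyte_step(cell, False, [5], True, rng, params)
        assert event == ("none",)

    def test_below_cap_replicates_near_collagen(self, rng):
        params = ag.HepatocyteParams(replication_prob=1.0)
        cell = ag.Hepatocyte(site=0, age=1, lifespan=100, replication_count=1)
        event = ag.hepatocyte_step(cell, False, [5], True, rng, params)
        assert event == ("replicate", 5)
        assert cell.replication_count == 2

    def test_lifespan_expiry(self, rng):
        cell = ag.Hepatocyte(site=0, age=100, lifespan=100)
        assert ag.hepatocyte_step(cell, False, [], False, rng,
                                  ag.HepatocyteParams()) == ("die",)

    def test_replication_count_never_decreases(self, rng):
        params = ag.HepatocyteParams(replication_prob=1.0)
        cell = ag.Hepatocyte(site=0, age=1, lifespan=10_000)
        counts = []
        for _ in range(6):
            ag.hepatocyte_step(cell, False, [1, 2, 3], False, rng, params)
            counts.append(cell.replication_count)
        assert counts == sorted(counts)

    def test_tnf_death_fraction_matches_binomial(self):
        # binomial oracle over 10,000 independent trials
        p = 0.3
        params = ag.HepatocyteParams(tnf_death_prob=p)
        rng = np.random.default_rng(123)
        n = 10_000
        deaths = 0
        for _ in range(n):
            cell = ag.Hepatocyte(site=0, age=1, lifespan=10_000)
            if ag.hepatocyte_step(cell, True, [], False, rng, params) == ("die",):
                deaths += 1
        sd = math.sqrt(n * p * (1 - p))
        assert abs(deaths - n * p) < 3 * sd


class TestKupfferStep:
    def test_quiescent_no_dead_is_silent(self, rng):
        flds = make_fields()
        kc = ag.KupfferCell(5.0, 5.0)
        events = ag.kupffer_step(kc, [], flds, rng, ag.KupfferParams())
        assert events == [("none",)]
        assert kc.state == ag.QUIESCENT
        assert all(f.total_mass() == 0 for f in flds.values())

    def test_phagocytosis_activates(self, rng):
        flds = make_fields()
        kc = ag.KupfferCell(5.0, 5.0)
        events = ag.kupffer_step(kc, [17], flds, rng, ag.KupfferParams())
        assert ("phagocytize", 17) in events
        assert kc.state == ag.ACTIVATED
        assert kc.phagocytosis_count == 1

    def test_pure_m1_secretes_only_tnf(self, rng):
        flds = make_fields()
        kc = ag.KupfferCell(5.0, 5.0, state=ag.ACTIVATED, m=0.0)
        ag.kupffer_step(kc, [], flds, rng, ag.KupfferParams())
        assert flds["tnf"].total_mass() > 0
        assert flds["tgf"].total_mass() == 0

    def test_pure_m2_secretes_only_tgf(self, rng):
        flds = make_fields()
        kc = ag.KupfferCell(5.0, 5.0, state=ag.ACTIVATED, m=1.0)
        ag.kupffer_step(kc, [], flds, rng, ag.KupfferParams())
        assert flds["tnf"].total_mass() == 0
        assert flds["tgf"].total_mass() > 0

    def test_tgf_suppresses_tnf_secretion(self):
        params = ag.KupfferParams(tnf_production=(1.0, 1.0),
                                  tnf_suppression_factor=0.25)
        amounts = {}
        for level in (0.0, 5.0):
            flds = make_fields(tgf_level=level)
            kc = ag.KupfferCell(5.0, 5.0, state=ag.ACTIVATED, m=0.0)
            ag.kupffer_step(kc, [], flds, np.random.default_rng(0), params)
            amounts[level] = flds["tnf"].total_mass()
        assert amounts[5.0] == pytest.approx(0.25 * amounts[0.0])

    def test_polarization_composition_matches_sequential_oracle(self, rng):
        inc = 0.17
        params = ag.KupfferParams(polarization_increment=inc)
        flds = make_fields()
        kc = ag.KupfferCell(5.0, 5.0)
        oracle_m = 0.0
        for k in range(9):
            ag.kupffer_step(kc, [k], flds, rng, params)
            oracle_m = min(1.0, oracle_m + inc)  # hand-rolled composition
            assert kc.m == pytest.approx(oracle_m)
            assert kc.phagocytosis_count == k + 1

    def test_m_is_nondecreasing_in_phagocytosis(self, rng):
        flds = make_fields()
        kc = ag.KupfferCell(5.0, 5.0)
        history = []
        for k in range(30):
            ag.kupffer_step(kc, [k], flds, rng, ag.KupfferParams())
            history.append(kc.m)
        assert history == sorted(history)
        assert history[-1] <= 1.0


class TestRecruitMonocytes:
    def test_zero_hmgb1_no_recruits(self, rng):
        hmgb1 = CytokineField("hmgb1", EXTENT, 1.0, 0.0, 0.0, 1.0)
        assert ag.recruit_monocytes(hmgb1, rng, ag.KupfferParams()) == []

    def test_probability_one_recruits_each_hot_cell(self, rng):
        hmgb1 = CytokineField("hmgb1", EXTENT, 1.0, 0.0, 0.0, 1.0)
        hmgb1.grid[3, 4] = 2.0
        params = ag.KupfferParams(recruit_prob=1.0)
        recruits = ag.recruit_monocytes(hmgb1, rng, params)
        assert len(recruits) == 1
        kc = recruits[0]
        assert kc.state == ag.ACTIVATED
        assert kc.m == 0.0
        assert (kc.x, kc.y) == (4.5, 3.5)

    def test_recruit_count_matches_binomial(self):
        hmgb1 = CytokineField("hmgb1", EXTENT, 1.0, 0.0, 0.0, 1.0)
        hmgb1.grid[:5, :4] = 2.0  # N = 20 hot cells
        p = 0.1
        params = ag.KupfferParams(recruit_prob=p)
        rng = np.random.default_rng(99)
        steps = 1000
        total = sum(len(ag.recruit_monocytes(hmgb1, rng, params))
                    for _ in range(steps))
        n = 20 * steps
        sd = math.sqrt(n * p * (1 - p))
        assert abs(total - n * p) < 3 * sd


class TestFibrogenicStep:
    def test_quiet_hsc_unchanged(self, rng):
        cell = ag.FibrogenicCell(1.0, 1.0, ag.HSC)
        events = ag.fibrogenic_step(cell, False, False, False, rng,
                                    ag.FibrogenicParams())
        assert events == [("none",)]
        assert cell.kind == ag.HSC

    @pytest.mark.parametrize("kind", [ag.HSC, ag.PORTAL_FIBROBLAST])
    def test_tnf_transforms_irreversibly(self, rng, kind):
        cell = ag.FibrogenicCell(1.0, 1.0, kind)
        events = ag.fibrogenic_step(cell, True, False, False, rng,
                                    ag.FibrogenicParams())
        assert ("transform",) in events
        assert cell.kind == ag.MYOFIBROBLAST
        # a second TNF exposure does not "re-transform"
        events = ag.fibrogenic_step(cell, True, False, False, rng,
                                    ag.FibrogenicParams())
        assert ("transform",) not in events

    def test_hmgb1_transformation_flag(self, rng):
        on = ag.FibrogenicParams(hmgb1_transforms=True)
        off = ag.FibrogenicParams(hmgb1_transforms=False)
        a = ag.FibrogenicCell(0, 0, ag.HSC)
        b = ag.FibrogenicCell(0, 0, ag.HSC)
        ag.fibrogenic_step(a, False, True, False, rng, on)
        ag.fibrogenic_step(b, False, True, False, rng, off)
        assert a.kind == ag.MYOFIBROBLAST
        assert b.kind == ag.HSC

    def test_forced_deposition_hits_anchor_site(self, rng):
        params = ag.FibrogenicParams(deposit_prob=1.0, proliferation_prob=0.0)
        cell = ag.FibrogenicCell(1.0, 1.0, ag.MYOFIBROBLAST)
        events = ag.fibrogenic_step(cell, False, False, True, rng, params,
                                    find_deposit_site=lambda: 42)
        assert ("deposit", 42) in events

    def test_no_anchor_in_reach_skips_deposition(self, rng):
        params = ag.FibrogenicParams(deposit_prob=1.0, proliferation_prob=0.0)
        cell = ag.FibrogenicCell(1.0, 1.0, ag.MYOFIBROBLAST)
        events = ag.fibrogenic_step(cell, False, False, True, rng, params,
                                    find_deposit_site=lambda: None)
        assert events == [("none",)]

    def test_myofibroblast_needs_tgf(self, rng):
        params = ag.FibrogenicParams(deposit_prob=1.0, proliferation_prob=1.0)
        cell = ag.FibrogenicCell(1.0, 1.0, ag.MYOFIBROBLAST)
        events = ag.fibrogenic_step(cell, True, True, False, rng, params,
                                    find_deposit_site=lambda: 1)
        assert events == [("none",)]


class TestInitializePopulations:
    def test_paper_counts(self):
        assert ag.initialize_populations(3857) == (964, 321)

    def test_zero(self):
        assert ag.initialize_populations(0) == (0, 0)

    def test_exact_ratio(self):
        # 120 * 15/60 = 30; 120 * 5/60 = 10, both exact
        assert ag.initialize_populations(120) == (30, 10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ag.initialize_populations(-1)
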