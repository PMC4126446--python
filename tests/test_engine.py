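import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest

from lobulesim import agents as ag
from lobulesim import engine


class TestConfig:
    def test_default_config_validates(self):
        engine.validate_config(engine.SimulationConfig())

    def test_errors_are_aggregated(self):
        cfg = engine.SimulationConfig(
            injury=engine.InjuryConfig(kill_prob=1.5, period=0),
            field_tnf=engine.FieldParams(diffusion_coeff=0.9),
        )
        with pytest.raises(engine.ConfigError) as exc:
            engine.validate_config(cfg)
        msgs = "\n".join(exc.value.errors)
        assert "injury.kill_prob" in msgs
        assert "injury.period" in msgs
        assert "field_tnf.diffusion_coeff" in msgs

    def test_roundtrip_dict(self):
        cfg = engine.SimulationConfig()
        clone = engine.SimulationConfig.from_dict(cfg.to_dict())
        assert clone == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(engine.ConfigError):
            engine.SimulationConfig.from_dict({"geometry": {"bogus": 1}})


class TestApplyTherapy:
    def test_none_unchanged(self):
        cfg = engine.SimulationConfig()
        assert engine.apply_therapy(cfg) == cfg

    def test_anti_tnf_scales_only_tnf_degradation(self):
        cfg = engine.SimulationConfig(
            therapy=engine.TherapyConfig(kind="anti_tnf", anti_tnf_factor=2.0))
        out = engine.apply_therapy(cfg)
        assert out.field_tnf.degradation_rate == pytest.approx(
            2.0 * cfg.field_tnf.degradation_rate)
        assert out.field_tgf == cfg.field_tgf
        assert out.kupffer == cfg.kupffer
        assert out.therapy.applied

    def test_m2_scales_only_tgf_production(self):
        cfg = engine.SimulationConfig(
            therapy=engine.TherapyConfig(kind="m2_enhance", m2_factor=3.0))
        out = engine.apply_therapy(cfg)
        assert out.kupffer.tgf_production_factor == pytest.approx(3.0)
        assert out.field_tnf == cfg.field_tnf
        assert out.hepatocyte == cfg.hepatocyte

    def test_factor_below_one_rejected(self):
        cfg = engine.SimulationConfig(
            therapy=engine.TherapyConfig(kind="anti_tnf", anti_tnf_factor=0.5))
        with pytest.raises(engine.ConfigError):
            engine.apply_therapy(cfg)

    def test_apply_twice_does_not_compound(self):
        cfg = engine.SimulationConfig(
            therapy=engine.TherapyConfig(kind="anti_tnf", anti_tnf_factor=2.0))
        once = engine.apply_therapy(cfg)
        twice = engine.apply_therapy(once)
        assert twice == once


class TestInitialize:
    def test_population_ratios_from_fill(self, small_state):
        n_hep = len(small_state.hepatocytes)
        n_k, n_h = ag.initialize_populations(n_hep)
        counts = small_state.counts()
        assert counts["kc_quiescent"] == n_k
        assert counts["hsc"] == n_h
        assert counts["pf"] == (small_state.lattice.n_nodes
                                * small_state.config.run.portal_fibroblasts_per_triad)

    def test_fields_start_empty(self, small_state):
        assert all(f.total_mass() == 0 for f in small_state.fields.values())
        assert small_state.step_index == 0

    def test_same_seed_same_serialized_state(self, small_config):
        a = engine.serialize_state(engine.initialize(small_config, seed=3))
        b = engine.serialize_state(engine.initialize(small_config, seed=3))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_hsc_inside_lobules(self, small_state):
        centers = small_state.lattice.lobule_centers()
        side = small_state.lattice.hex_side
        for cell in small_state.fibrogenic:
            if cell.kind == ag.HSC:
                assert engine._in_any_lobule(cell.x, cell.y, centers, side)


class TestInjuryPulse:
    def test_kill_prob_zero_is_noop(self, small_state):
        before = small_state.counts()
        engine.injury_pulse(small_state, 2.5, 0.0, small_state.rng["injury"])
        assert small_state.counts() == before

    def test_kill_prob_one_kills_every_cell_in_radius(self, small_state):
        radius = 2.0
        in_radius = int(((small_state.occupancy == engine.OCC_HEPATOCYTE)
                         & (small_state.site_center_dist <= radius)).sum())
        total_before = (len(small_state.hepatocytes) + len(small_state.dead))
        engine.injury_pulse(small_state, radius, 1.0, small_state.rng["injury"])
        counts = small_state.counts()
        assert counts["dead"] == in_radius
        assert counts["hepatocytes"] + counts["dead"] == total_before

    def test_kill_count_matches_binomial(self, small_config):
        p = 0.5
        radius = 2.0
        state = engine.initialize(small_config, seed=0)
        n_in = int(((state.occupancy == engine.OCC_HEPATOCYTE)
                    & (state.site_center_dist <= radius)).sum())
        rng = np.random.default_rng(11)
        pulses = 400
        kills = 0
        occ_backup = state.occupancy.copy()
        hep_backup = dict(state.hepatocytes)
        for _ in range(pulses):
            engine.injury_pulse(state, radius, p, rng)
            kills += len(state.dead)
            state.occupancy = occ_backup.copy()
            state.hepatocytes = dict(hep_backup)
            state.dead = {}
        mean = pulses * n_in * p
        sd = math.sqrt(pulses * n_in * p * (1 - p))
        assert abs(kills - mean) < 3 * sd


class TestStep:
    def test_injury_produces_dead_within_one_period(self, small_config):
        state = engine.initialize(small_config, seed=1)
        for _ in range(small_config.injury.period):
            engine.step(state)
        # dead agents were created (they may already have been phagocytized)
        assert state.cumulative_deaths > 0

    def test_determinism_same_seed_identical_output(self, small_config):
        df_a = engine.run_replicate(small_config, seed=5)
        df_b = engine.run_replicate(small_config, seed=5)
        pd.testing.assert_frame_equal(df_a, df_b)

    def test_census_identity(self, small_config):
        state = engine.initialize(small_config, seed=2)
        n0 = len(state.hepatocytes)
        for _ in range(60):
            engine.step(state)
        assert (len(state.hepatocytes) + state.cumulative_deaths
                - state.cumulative_replications) == n0

    def test_collagen_count_nondecreasing(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            injury=dataclasses.replace(small_config.injury, kill_prob=0.3))
        state = engine.initialize(cfg, seed=3)
        prev = 0
        for _ in range(80):
            engine.step(state)
            cur = state.counts()["collagen"]
            assert cur >= prev
            prev = cur

    def test_no_collider_overlaps_after_steps(self, small_config):
        state = engine.initialize(small_config, seed=4)
        for _ in range(30):
            engine.step(state)
        assert state.mechanical_view().max_overlap() < 1e-3

    def test_baseline_homeostasis(self, seven_lobule_config):
        cfg = dataclasses.replace(
            seven_lobule_config,
            injury=dataclasses.replace(seven_lobule_config.injury,
                                       enabled=False))
        state = engine.initialize(cfg, seed=1)
        initial = state.counts()
        for _ in range(500):
            engine.step(state)
        final = state.counts()
        for key, start in initial.items():
            if start == 0:
                assert final[key] == 0, key
            else:
                assert abs(final[key] - start) <= 0.05 * start, key


class TestRunAggregation:
    def test_single_replicate_sd_is_zero(self, small_config):
        cfg = dataclasses.replace(
            small_config, run=dataclasses.replace(small_config.run,
                                                  n_steps=10, replicates=1))
        res = engine.run(cfg)
        sd = res.sd.drop(columns="step").fillna(0.0)
        assert (sd.to_numpy() == 0).all()

    def test_mean_sd_match_recomputation(self, small_config):
        cfg = dataclasses.replace(
            small_config, run=dataclasses.replace(small_config.run,
                                                  n_steps=15, replicates=3))
        res = engine.run(cfg)
        stacked = np.stack([df.drop(columns="step").to_numpy()
                            for df in res.replicates])
        np.testing.assert_allclose(res.mean.drop(columns="step").to_numpy(),
                                   np.nanmean(stacked, axis=0), rtol=1e-12)
        np.testing.assert_allclose(res.sd.drop(columns="step").to_numpy(),
                                   np.nanstd(stacked, axis=0), rtol=1e-9,
                                   atol=1e-12)

    def test_paired_seeds_across_scenarios(self, small_config):
        cfg = dataclasses.replace(
            small_config, run=dataclasses.replace(small_config.run,
                                                  n_steps=5, replicates=2))
        results = engine.run_scenarios(cfg, kinds=("none", "anti_tnf"))
        for res in results.values():
            assert res.config.run.seed == cfg.run.seed
            assert res.n_replicates == 2


class TestSerialization:
    def test_roundtrip_bit_identical(self, small_config):
        state = engine.initialize(small_config, seed=9)
        for _ in range(25):
            engine.step(state)
        payload = json.dumps(engine.serialize_state(state), sort_keys=True)
        clone = engine.deserialize_state(json.loads(payload))
        payload2 = json.dumps(engine.serialize_state(clone), sort_keys=True)
        assert payload == payload2
        assert engine.state_hash(state) == engine.state_hash(clone)

    def test_restored_state_continues_identically(self, small_config):
        state = engine.initialize(small_config, seed=9)
        for _ in range(10):
            engine.step(state)
        clone = engine.deserialize_state(engine.serialize_state(state))
        for _ in range(10):
            engine.step(state)
            engine.step(clone)
        assert engine.state_hash(state) == engine.state_hash(clone)

    def test_unknown_schema_rejected(self, small_state):
        data = engine.serialize_state(small_state)
        data["schema_version"] = 99
        with pytest.raises(ValueError):
            engine.deserialize_state(data)


class TestElastographyNonPerturbation:
    def test_hash_unchanged_by_measurement(self, seven_lobule_config):
        state = engine.initialize(seven_lobule_config, seed=2)
        for _ in range(15):
            engine.step(state)
        before = engine.state_hash(state)
        engine.measure_state_elasticity(state)
        assert engine.state_hash(state) == before
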