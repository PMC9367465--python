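"""Synthetic cohorts: archetype shapes, fate bookkeeping, determinism."""

import numpy as np
import pandas as pd
import pytest

from mpcva import ARCHETYPES, DyeModelParams, ScenarioConfig
from mpcva.simulate import (
    generate_cohort,
    generate_cytometry_sample,
    generate_timelapse_cohort,
    simulate_vm_track,
    tracks_to_frames,
)

DENSE_TIMES = np.linspace(0.0, 80.0, 401)


class TestVmTrack:
    def test_control_rests_at_resting_potential(self, params):
        tr = simulate_vm_track("control", None, sample_times=DENSE_TIMES, noise_cv=0)
        assert np.all(tr.vm == params.resting_potential)
        assert np.all(tr.raw_intensity == params.baseline_fluorescence)
        assert tr.lysis_time is None

    @pytest.mark.parametrize("onset,duration", [(4.0, 12.0), (10.0, 40.0), (20.0, 48.0)])
    def test_apoptotic_spike_then_fall(self, params, onset, duration):
        """Intensity rises above baseline and drops below it before lysis."""
        tr = simulate_vm_track(
            "apoptotic", onset, duration, sample_times=DENSE_TIMES, noise_cv=0
        )
        base = params.baseline_fluorescence
        assert tr.raw_intensity.max() > base
        assert tr.raw_intensity[-1] < base
        # no measurement at or past the lysis instant
        assert np.all(tr.sample_times < onset + duration)

    @pytest.mark.parametrize("onset,duration", [(2.0, 10.0), (10.0, 40.0)])
    def test_necrotic_monotone_decline_from_onset(self, onset, duration):
        tr = simulate_vm_track(
            "necrotic", onset, duration, sample_times=DENSE_TIMES, noise_cv=0
        )
        after = tr.raw_intensity[tr.sample_times >= onset]
        assert np.all(np.diff(after) <= 1e-9)

    def test_death_vm_monotone_toward_zero(self, params):
        for name in ("apoptotic", "necrotic", "ferroptotic"):
            tr = simulate_vm_track(name, 10.0, 40.0, sample_times=DENSE_TIMES, noise_cv=0)
            vm = tr.vm[tr.sample_times >= 10.0]
            assert np.all(np.diff(vm) >= -1e-12)
            assert vm[-1] <= params.dead_potential + 1e-12

    def test_archetype_factor_invariants(self):
        u = np.linspace(0, 1, 101)
        for arch in ARCHETYPES.values():
            assert np.all(arch.surface_at(u) >= 1.0)
            r = arch.retention_at(u)
            assert np.all((r > 0) & (r <= 1.0))


class TestTimelapseCohort:
    def test_no_toxin_no_division_means_no_events(self):
        cfg = ScenarioConfig(seed=3, n_cells=50, toxin_effect=0.0, division_rate=0.0)
        tracks = generate_timelapse_cohort(cfg)
        assert len(tracks) == 50
        assert all(t.lysis_time is None and not t.division_times for t in tracks)

    def test_seed_determinism_bitwise(self, mixed_config):
        f1 = tracks_to_frames(generate_timelapse_cohort(mixed_config))
        f2 = tracks_to_frames(generate_timelapse_cohort(mixed_config))
        for a, b in zip(f1, f2):
            pd.testing.assert_frame_equal(a, b)

    def test_full_toxin_all_tracks_lyse_within_horizon(self):
        """Onset <= 24 h and duration <= 48 h imply lysis before 80 h."""
        cfg = ScenarioConfig(seed=4, n_cells=300, toxin_effect=1.0)
        tracks = generate_timelapse_cohort(cfg)
        lysed = sum(t.lysis_time is not None for t in tracks)
        assert lysed == len(tracks)

    def test_death_durations_within_configured_window(self, mixed_config):
        tracks = generate_timelapse_cohort(mixed_config)
        durs = [
            t.true_lysis - t.onset for t in tracks if t.true_lysis is not None
        ]
        assert len(durs) > 20
        assert all(2.0 <= d <= 48.0 for d in durs)

    def test_archetype_shape_contracts_hold_cohort_wide(self):
        """Spike-then-fall / monotone-fall checked on every zero-noise track."""
        p = DyeModelParams(noise_cv=0.0)
        cfg = ScenarioConfig(
            seed=5, n_cells=300, toxin_effect=1.0, division_rate=0.0,
            sample_times=tuple(np.arange(0.0, 80.5, 1.0)),
        )
        tracks = generate_timelapse_cohort(cfg, params=p)
        assert len(tracks) >= 200
        base = p.baseline_fluorescence
        for t in tracks:
            mask = t.sample_times >= t.onset
            post = t.raw_intensity[mask]
            if len(post) < 2:
                continue
            u = (t.sample_times[mask] - t.onset) / (t.true_lysis - t.onset)
            if t.archetype == "apoptotic":
                # spike visible once the bleb phase is sampled ...
                if np.any((u >= 0.25) & (u <= 0.6)):
                    assert post.max() > base
                # ... and the pre-lysis collapse ends below baseline
                if u[-1] >= 0.9:
                    assert post[-1] < base
            elif t.archetype == "necrotic":
                assert np.all(np.diff(post) <= 1e-9)

    def test_division_produces_two_daughter_tracks(self):
        cfg = ScenarioConfig(seed=6, n_cells=80, toxin_effect=0.0, division_rate=0.9)
        tracks = generate_timelapse_cohort(cfg)
        by_id = {t.cell_id: t for t in tracks}
        dividers = [t for t in tracks if t.division_times]
        assert dividers
        for t in dividers:
            assert f"{t.cell_id}.1" in by_id and f"{t.cell_id}.2" in by_id
            for child in (by_id[f"{t.cell_id}.1"], by_id[f"{t.cell_id}.2"]):
                assert child.parent_id == t.cell_id
                if len(child.sample_times):
                    assert child.sample_times[0] > t.division_times[0]

    def test_measured_times_strictly_increasing_and_pre_lysis(self, mixed_config):
        for t in generate_timelapse_cohort(mixed_config):
            if len(t.sample_times) > 1:
                assert np.all(np.diff(t.sample_times) > 0)
            if t.lysis_time is not None:
                assert np.all(t.sample_times < t.lysis_time)


def _expected_lysed_fraction(measure_time, exposure_window, dur_lo, dur_hi, n=200_000):
    """Independent numerical oracle for P(onset + duration < t)."""
    rng = np.random.default_rng(99)
    onset = rng.uniform(0, exposure_window, n)
    dur = rng.uniform(dur_lo, dur_hi, n)
    return float((onset + dur < measure_time).mean())


class TestCytometrySample:
    def test_clean_control_sample_counts(self):
        cfg = ScenarioConfig(seed=7, n_cells=120, toxin_effect=0.0, division_rate=0.0)
        events = generate_cytometry_sample(cfg)
        for dup in (1, 2):
            sub = events[events["duplicate_index"] == dup]
            assert len(sub) == 120
            assert (sub["true_state"] == "alive").all()

    def test_all_lysed_sample_is_empty(self):
        cfg = ScenarioConfig(
            seed=8, n_cells=60, toxin_effect=1.0, duration_range=(2.0, 5.0)
        )
        events = generate_cytometry_sample(cfg, measure_time=40.0)
        assert len(events) == 0

    def test_missing_fraction_matches_lysis_probability(self):
        """Absent events = dying cells whose onset+duration precedes acquisition."""
        cfg = ScenarioConfig(seed=9, n_cells=20_000, toxin_effect=0.3)
        events = generate_cytometry_sample(cfg, measure_time=24.0)
        n_dup1 = (events["duplicate_index"] == 1).sum()
        missing = 1.0 - n_dup1 / cfg.n_cells
        expected = 0.3 * _expected_lysed_fraction(24.0, 24.0, 2.0, 48.0)
        se = np.sqrt(expected * (1 - expected) / cfg.n_cells)
        assert missing == pytest.approx(expected, abs=4 * se)

    def test_event_table_invariants(self, mixed_config):
        events = generate_cytometry_sample(mixed_config)
        assert (events["total_intensity"] >= 0).all()
        assert (events["dye_area"] > 0).all()
        assert (events["dye_area"] <= events["cell_area"] * 1.2 + 1e-9).all()
        assert set(events["duplicate_index"]) == {1, 2}
        assert set(events["true_state"]) <= {"alive", "dying"}

    def test_determinism(self, mixed_config):
        e1 = generate_cytometry_sample(mixed_config)
        e2 = generate_cytometry_sample(mixed_config)
        pd.testing.assert_frame_equal(e1, e2)

    def test_cohort_truth_columns(self, mixed_config):
        cohort = generate_cohort(mixed_config)
        assert len(cohort) == mixed_config.n_cells
        dying = cohort[cohort["dying"]]
        assert (dying["true_lysis"] == dying["onset"] + dying["duration"]).all()
        assert dying["archetype"].isin(["apoptotic", "necrotic"]).all()
        alive = cohort[~cohort["dying"]]
        assert (alive["archetype"] == "control").all()


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_cells": 0},
            {"toxin_effect": 1.5},
            {"division_rate": -0.1},
            {"confluency_label": 60},
            {"pathway_mix": {"apoptotic": 0.5}},
            {"pathway_mix": {"control": 1.0}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig(seed=1, **kwargs)
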