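"""Cytometry arm: compensation, DNA exclusion, gating, permanence, scoring."""

import numpy as np
import pandas as pd
import pytest

from mpcva import (
    CytometryViabilityModel,
    GateConfig,
    SampleScore,
    ScenarioConfig,
    ViableRange,
    compensate_intensity,
    control_range,
    count_adjusted_viability,
    exclude_dividing,
    generate_cytometry_sample,
    permanence_check,
    score_sample,
)
from mpcva.cytometry import MIN_PERMANENCE_EVENTS
from mpcva.timelapse import classify_values


def make_events(comp_values, dna=100.0, sample_id="S", duplicate=1):
    comp = np.asarray(comp_values, dtype=float)
    n = len(comp)
    dye_area = np.full(n, 200.0)
    return pd.DataFrame(
        {
            "event_id": [f"{sample_id}-{i}" for i in range(n)],
            "sample_id": sample_id,
            "duplicate_index": duplicate,
            "total_intensity": comp * dye_area,
            "dye_area": dye_area,
            "cell_area": dye_area,
            "dna_intensity": np.broadcast_to(np.asarray(dna, float), (n,)).copy(),
            "dna_area": np.full(n, 50.0),
        }
    )


class TestCompensation:
    def test_ratio(self):
        assert compensate_intensity(1200.0, 300.0) == 4.0

    def test_zero_intensity_allowed(self):
        assert compensate_intensity(0.0, 123.0) == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="dye_area"):
            compensate_intensity(10.0, 0.0)

    def test_removes_shared_size_scaling(self, rng):
        """Scaling intensity and area by a shared per-cell factor leaves the
        compensated value untouched, shrinking the control spread."""
        base_comp = rng.normal(0.5, 0.015, 3000)
        size = rng.lognormal(0, 0.2, 3000)
        total = base_comp * 200.0 * size
        area = 200.0 * size
        comp = compensate_intensity(total, area)
        assert np.std(comp) / np.mean(comp) < 0.5 * (
            np.std(total) / np.mean(total)
        )
        # and the k=2 gate keeps its ~4.55% false-positive calibration
        ev = make_events(comp[:1500])
        vr = control_range(make_events(base_comp[1500:]), GateConfig())
        frac = (
            classify_values(
                compensate_intensity(ev["total_intensity"], ev["dye_area"]), vr
            )
            == "dead"
        ).mean()
        se = np.sqrt(0.0455 * 0.9545 / 1500)
        assert abs(frac - 0.0455) < 3 * se


class TestDnaExclusion:
    def test_uniform_dna_keeps_everything(self):
        ev = make_events([0.5] * 10, dna=100.0)
        kept, excluded = exclude_dividing(ev)
        assert len(kept) == 10 and len(excluded) == 0

    def test_single_high_dna_event_excluded(self):
        dna = [100.0] * 9 + [220.0]
        ev = make_events([0.5] * 10, dna=dna)
        kept, excluded = exclude_dividing(ev)
        assert len(excluded) == 1
        assert excluded["dna_intensity"].iloc[0] == 220.0

    def test_empty_input_passes_through(self):
        ev = make_events([])
        kept, excluded = exclude_dividing(ev)
        assert len(kept) == 0 and len(excluded) == 0

    def test_reduces_control_false_positives_with_dividing_cells(self, params):
        """Excluding high-DNA (G2/M, transiently depolarized) events never
        raises the control death ratio."""
        for seed in (0, 1, 2):
            cfg = ScenarioConfig(
                seed=seed, n_cells=4000, toxin_effect=0.0, division_rate=0.5
            )
            events = generate_cytometry_sample(cfg, params=params)
            vr = control_range(events, GateConfig())
            with_excl = score_sample(exclude_dividing(events)[0], vr).death_ratio
            without = score_sample(events, vr).death_ratio
            assert with_excl <= without


class TestControlRange:
    def test_constant_controls_collapse_range(self):
        vr = control_range(make_events([0.5] * 20))
        assert (vr.low, vr.high) == (0.5, 0.5)

    def test_insufficient_controls_error_names_group(self):
        with pytest.raises(ValueError, match="CONF50"):
            control_range(make_events([0.5]), group="CONF50")

    def test_per_group_ranges_have_no_crosstalk(self):
        ev_a = make_events(np.linspace(0.4, 0.6, 50), sample_id="ctrlA")
        ev_b = make_events(np.linspace(4.0, 6.0, 50), sample_id="ctrlB")
        events = pd.concat([ev_a, ev_b], ignore_index=True)
        model = CytometryViabilityModel(
            events,
            control_samples=["ctrlA", "ctrlB"],
            group_of={"ctrlA": "A", "ctrlB": "B"},
        )
        res = model.fit()
        assert res.ranges["A"].high < res.ranges["B"].low

    def test_self_classification_near_95_percent(self, rng):
        comp = rng.normal(0.5, 0.02, 10_000)
        vr = control_range(make_events(comp))
        frac = (classify_values(comp, vr) == "viable").mean()
        assert frac == pytest.approx(0.9545, abs=0.01)


class TestScoring:
    def test_counts_and_ratio(self):
        vr = ViableRange(center=0.5, spread=0.05, k=2.0)
        values = [0.5] * 95 + [0.9] * 5
        score = score_sample(make_events(values), vr)
        assert score.n_events == 100
        assert score.n_dead_classified == 5
        assert score.death_ratio == pytest.approx(0.05)
        assert score.gate_viability == pytest.approx(0.95)

    def test_dead_count_sums_both_tails(self):
        """Hand-built 10-event fixture straddling both gate bounds."""
        vr = ViableRange(center=0.5, spread=0.05, k=2.0)  # gate [0.4, 0.6]
        values = [0.10, 0.20, 0.39, 0.40, 0.50, 0.55, 0.60, 0.61, 0.80, 0.95]
        score = score_sample(make_events(values), vr)
        # below the gate: 0.10, 0.20, 0.39; above: 0.61, 0.80, 0.95;
        # the boundary values 0.40 and 0.60 are inclusive, hence viable
        assert score.n_dead_classified == 3 + 3

    def test_all_inside_gives_zero(self):
        vr = ViableRange(center=0.5, spread=0.05, k=2.0)
        assert score_sample(make_events([0.5] * 10), vr).death_ratio == 0.0


class TestPermanence:
    def _score(self, n, dead, sid="S"):
        return SampleScore(sample_id=sid, n_events=n, n_dead_classified=dead)

    def test_identical_duplicates_permanent(self):
        assert permanence_check(self._score(500, 25), self._score(500, 25)) == "permanent"

    def test_strongly_differing_duplicates_transient(self):
        # 5% vs 40% dead at n = 1000: Chi-squared p is astronomically small
        assert (
            permanence_check(self._score(1000, 50), self._score(1000, 400))
            == "transient"
        )

    def test_small_duplicates_untestable(self):
        assert (
            permanence_check(self._score(10, 1), self._score(10, 2)) == "untestable"
        )
        assert MIN_PERMANENCE_EVENTS == 20

    def test_mismatched_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            permanence_check(self._score(100, 5, "A"), self._score(100, 5, "B"))


class TestCountAdjustment:
    @pytest.mark.parametrize(
        "gate_v, n_s, n_c, expected",
        [(0.9, 1000, 1000, 0.9), (1.0, 500, 1000, 0.5), (1.0, 1500, 1000, 1.0)],
    )
    def test_formula_and_clamp(self, gate_v, n_s, n_c, expected):
        assert count_adjusted_viability(gate_v, n_s, n_c) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            count_adjusted_viability(0.9, 100, 0)


class TestDoseResponse:
    def test_death_ratio_monotone_in_toxin_effect(self, params):
        """Dose monotonicity across the toxin grid, per seed."""
        for seed in (11, 12, 13):
            ctrl = generate_cytometry_sample(
                ScenarioConfig(seed=seed + 1000, n_cells=1500), params=params,
                sample_id="control",
            )
            ratios = []
            for tox in (0.0, 0.1, 0.25, 0.5, 0.9):
                cfg = ScenarioConfig(seed=seed, n_cells=1500, toxin_effect=tox)
                events = generate_cytometry_sample(cfg, params=params, sample_id="t")
                all_events = pd.concat([ctrl, events], ignore_index=True)
                res = CytometryViabilityModel(all_events, ["control"]).fit()
                ratios.append(res.score("t").death_ratio)
            assert all(b >= a for a, b in zip(ratios, ratios[1:]))
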