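"""Simulated reference viability assays for benchmarking.

Three standard readouts are simulated from the same ground-truth
cohorts the membrane-potential assay sees, each with its documented
error mode:

* **cell count** (48 h): survivors are counted from a subsampled volume
  and scaled to the full sample; the most accurate but slowest readout.
* **propidium iodide** (24 h): a membrane-impermeant DNA dye marks
  cells whose membrane integrity is lost — but cells already lysed by
  24 h are invisible, and actively dividing cells admit the dye at a
  small rate (increased membrane fluidity), so PI tends to
  *overestimate* viability under fast-lysing insults.
* **MTT** (24 h): metabolic reduction of a tetrazolium salt to
  formazan; dying cells retain partial metabolic activity (modeled as a
  linear ramp to zero over the death duration) and the response
  saturates above ~25,000 active cells, both biasing viability upward.

All viability estimates are expressed relative to the untreated
control, as viability percentages conventionally are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cytometry import CytometryViabilityModel, GateConfig
from .dye import DyeModelParams
from .simulate import (
    ScenarioConfig,
    generate_cohort,
    generate_cytometry_sample,
)

__all__ = [
    "ComparatorResult",
    "cell_count_viability",
    "pi_readout",
    "mtt_readout",
    "mpcva_viability",
    "benchmark",
]

#: Total sample volume the counted subsample is scaled to, microliters.
TOTAL_VOLUME_UL = 50.0
#: Number of active cells above which formazan production saturates.
MTT_SATURATION_COUNT = 25_000.0
#: Optical density contributed per fully active cell at 570 nm.
MTT_OD_PER_CELL = 4e-5
MTT_BLANK_OD = 0.04


@dataclass(frozen=True)
class ComparatorResult:
    """One assay's readout and its control-relative viability estimate."""

    method: str
    raw_readout: float
    viability_estimate: float

    def __post_init__(self) -> None:
        if self.viability_estimate < 0:
            raise ValueError("viability_estimate must be >= 0")


def _survivors(cohort: pd.DataFrame, at_time: float) -> np.ndarray:
    """Boolean mask of cells not yet lysed at ``at_time``."""
    lysed = cohort["dying"].to_numpy() & (
        cohort["true_lysis"].to_numpy() <= at_time
    )
    return ~lysed


def cell_count_viability(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    subsample_volume: float = 20.0,
    total_volume: float = TOTAL_VOLUME_UL,
    rng: np.random.Generator | None = None,
    at_time: float = 72.0,
) -> ComparatorResult:
    """Cell-count viability, 48 h after the exposure window closes.

    Death pathways last at most 48 h, so by 48 h after the end of a
    24 h exposure (t = 72 h) every committed cell has lysed and the
    survivor count reflects true viability.  Surviving cells are
    counted from ``subsample_volume`` of the ``total_volume`` sample —
    each survivor lands in the counted volume independently — and the
    count is scaled back to the full volume.  Viability is the
    treated/control ratio of scaled counts.
    """
    if not 0 < subsample_volume <= total_volume:
        raise ValueError("subsample_volume must lie in (0, total_volume]")
    if rng is None:
        rng = np.random.default_rng()
    p = subsample_volume / total_volume
    counts = {}
    for name, cohort in (("treated", treated), ("control", control)):
        n_surv = int(_survivors(cohort, at_time).sum())
        counted = n_surv if p == 1.0 else int(rng.binomial(n_surv, p))
        counts[name] = counted / p
    if counts["control"] == 0:
        raise ValueError("control survivor count is zero")
    return ComparatorResult(
        method="cell_count",
        raw_readout=counts["treated"],
        viability_estimate=counts["treated"] / counts["control"],
    )


def _pi_positive_fraction(
    cohort: pd.DataFrame,
    at_time: float,
    division_permeability_prob: float,
    rng: np.random.Generator,
) -> float:
    present = cohort[_survivors(cohort, at_time)]
    if len(present) == 0:
        return 1.0
    compromised = present["dying"].to_numpy() & (
        present["onset"].to_numpy() <= at_time
    )
    # dividing (G2/M-content) cells admit the dye at a small rate
    dividing = (~compromised) & (present["dna_content"].to_numpy() >= 2.0)
    leaky = dividing & (rng.random(len(present)) < division_permeability_prob)
    return float((compromised | leaky).mean())


def pi_readout(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    division_permeability_prob: float = 0.1,
    rng: np.random.Generator | None = None,
    at_time: float = 24.0,
) -> ComparatorResult:
    """Propidium-iodide viability at 24 h.

    A cell is PI-positive iff its membrane integrity is lost by
    ``at_time``, or — the false-positive channel — it is dividing and
    admits the dye with probability ``division_permeability_prob``.
    Lysed cells contribute no signal.  Viability is the PI-negative
    fraction, normalized to the control.
    """
    if rng is None:
        rng = np.random.default_rng()
    f_treated = _pi_positive_fraction(
        treated, at_time, division_permeability_prob, rng
    )
    f_control = _pi_positive_fraction(
        control, at_time, division_permeability_prob, rng
    )
    if f_control >= 1.0:
        raise ValueError("every control cell is PI-positive")
    return ComparatorResult(
        method="PI",
        raw_readout=f_treated,
        viability_estimate=(1.0 - f_treated) / (1.0 - f_control),
    )


def _soft_saturation(total_activity: float, saturation: float) -> float:
    """Linear below ``saturation``; smooth exponential plateau above."""
    if total_activity <= saturation:
        return total_activity
    scale = saturation / 2.0
    return saturation + scale * (1.0 - np.exp(-(total_activity - saturation) / scale))


def _metabolic_activity(cohort: pd.DataFrame, at_time: float) -> float:
    dying = cohort["dying"].to_numpy()
    onset = cohort["onset"].to_numpy()
    duration = cohort["duration"].to_numpy()
    u = np.zeros(len(cohort))
    committed = dying & (onset <= at_time)
    u[committed] = (at_time - onset[committed]) / duration[committed]
    activity = np.clip(1.0 - u, 0.0, 1.0)
    return float(activity.sum())


def mtt_readout(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    od_per_active_cell: float = MTT_OD_PER_CELL,
    saturation_count: float = MTT_SATURATION_COUNT,
    rng: np.random.Generator | None = None,
    at_time: float = 24.0,
    blank_od: float = MTT_BLANK_OD,
) -> ComparatorResult:
    """MTT (formazan absorbance) viability at 24 h.

    Each unlysed cell contributes its metabolic activity — 1 when
    alive, ramping linearly to 0 over the death duration once committed
    — and the summed activity passes through a saturating response
    (linear below ``saturation_count`` active-cell equivalents,
    sub-linear above).  Viability is the blank-subtracted treated/control
    OD ratio.
    """
    ods = {}
    for name, cohort in (("treated", treated), ("control", control)):
        effective = _soft_saturation(
            _metabolic_activity(cohort, at_time), saturation_count
        )
        ods[name] = blank_od + od_per_active_cell * effective
    if ods["control"] <= blank_od:
        raise ValueError("control OD does not exceed the blank")
    return ComparatorResult(
        method="MTT",
        raw_readout=ods["treated"],
        viability_estimate=(ods["treated"] - blank_od)
        / (ods["control"] - blank_od),
    )


def mpcva_viability(
    treated_events: pd.DataFrame,
    control_events: pd.DataFrame,
    gate: GateConfig | None = None,
) -> ComparatorResult:
    """Membrane-potential assay viability, relative to control.

    Runs the cytometry pipeline (DNA exclusion, control-derived gate,
    duplicate scoring, count adjustment) on the treated and control
    event tables and reports the treated count-adjusted viability
    normalized to the control's.
    """
    events = pd.concat([control_events, treated_events], ignore_index=True)
    control_id = str(control_events["sample_id"].iloc[0])
    treated_id = str(treated_events["sample_id"].iloc[0])
    res = CytometryViabilityModel(events, [control_id], config=gate).fit()
    v_treated = res.score(treated_id).count_adjusted_viability
    v_control = res.score(control_id).count_adjusted_viability
    if v_control == 0:
        raise ValueError("control viability is zero")
    return ComparatorResult(
        method="MPCVA",
        raw_readout=v_treated,
        viability_estimate=v_treated / v_control,
    )


DEFAULT_TOXIN_GRID = (0.0, 0.1, 0.25, 0.5, 0.9)


def benchmark(
    toxin_levels=DEFAULT_TOXIN_GRID,
    n_cells: int = 1500,
    seed: int = 0,
    params: DyeModelParams | None = None,
    include_early_lysis: bool = True,
    measure_time: float = 24.0,
    gate: GateConfig | None = None,
) -> pd.DataFrame:
    """Run all four assays across a scenario grid and tabulate agreement.

    For each scenario a control and a treated cohort are simulated; the
    membrane-potential assay is run on cytometry event tables while the
    comparators read the shared ground-truth cohorts.  The default grid
    spans the toxin-effect levels under standard 2-48 h death durations,
    plus an early-lysis scenario (2-8 h durations, as after UV or
    peroxide insults) in which most dying cells are gone before the
    24 h readouts.

    Returns one row per scenario with each method's control-relative
    viability estimate, the ground-truth viability (fraction of cells
    never committing to death), absolute errors, and the per-scenario
    rank of each method by error (1 = closest).
    """
    if params is None:
        params = DyeModelParams()
    master = np.random.default_rng(seed)
    scenarios: list[tuple[str, float, tuple | None]] = [
        ("standard", float(tox), None) for tox in toxin_levels
    ]
    if include_early_lysis:
        scenarios.append(("early_lysis", 0.5, (2.0, 8.0)))

    rows = []
    for label, toxin, dur_range in scenarios:
        seeds = master.integers(0, 2**31 - 1, size=3)
        common = dict(
            n_cells=n_cells,
            division_rate=0.3,
            duration_range=dur_range,
        )
        cfg_control = ScenarioConfig(seed=int(seeds[0]), toxin_effect=0.0, **common)
        cfg_treated = ScenarioConfig(seed=int(seeds[1]), toxin_effect=toxin, **common)
        rng = np.random.default_rng(int(seeds[2]))

        control = generate_cohort(cfg_control, rng)
        treated = generate_cohort(cfg_treated, rng)
        control_events = generate_cytometry_sample(
            cfg_control, measure_time, params, rng, sample_id="control",
            cohort=control,
        )
        treated_events = generate_cytometry_sample(
            cfg_treated, measure_time, params, rng, sample_id="treated",
            cohort=treated,
        )

        truth = 1.0 - float(treated["dying"].mean())
        results = {
            "MPCVA": mpcva_viability(treated_events, control_events, gate),
            "cell_count": cell_count_viability(treated, control, rng=rng),
            "PI": pi_readout(treated, control, rng=rng, at_time=measure_time),
            "MTT": mtt_readout(treated, control, rng=rng, at_time=measure_time),
        }
        row = {
            "scenario": label,
            "toxin_effect": toxin,
            "truth_viability": truth,
        }
        for name, res in results.items():
            row[f"{name}_viability"] = res.viability_estimate
            row[f"{name}_abs_error"] = abs(res.viability_estimate - truth)
        errs = {name: row[f"{name}_abs_error"] for name in results}
        order = sorted(errs, key=errs.get)
        for rank, name in enumerate(order, start=1):
            row[f"{name}_rank"] = rank
        rows.append(row)
    return pd.DataFrame(rows)
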