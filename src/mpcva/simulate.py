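"""Synthetic cohorts of dye-stained cells with ground-truth fates.

The generator emulates the assay's two acquisition modes from one
underlying cell model:

* time-lapse microscopy — per-cell intensity tracks sampled every 12 h
  over an 80 h horizon, with division and lysis events;
* imaging flow cytometry — endpoint event tables (total dye intensity,
  dye area, cell area, DNA-stain channel) acquired as duplicate samples
  1 h apart.

Cells rest near -40 mV and depolarize to 0 mV when they pass the point
of no return of a death pathway; the pathway archetypes then shape the
surface-area and dye-retention dynamics until lysis, 2-48 h after
commitment.  Cells that have lysed before an acquisition are simply
absent from it.  All randomness flows through a single
``numpy.random.Generator``, so identical configurations and seeds give
bitwise-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .archetypes import ARCHETYPES, DEFAULT_PATHWAY_MIX, PathwayArchetype
from .dye import DyeModelParams, fluorescence, k_to_vm

__all__ = [
    "ScenarioConfig",
    "CellTrack",
    "simulate_vm_track",
    "generate_timelapse_cohort",
    "tracks_to_frames",
    "generate_cohort",
    "generate_cytometry_sample",
    "events_from_cohort",
    "generate_k_titration",
    "generate_gaussian_control_intensities",
    "DEFAULT_SAMPLE_TIMES",
]

#: Default microscope sampling grid: every 12 h, closing at the 80 h horizon.
DEFAULT_SAMPLE_TIMES: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 80.0)

#: Mean projected cell footprint, arbitrary area units.
BASE_CELL_AREA = 200.0
#: Coefficient of variation of per-cell size.
SIZE_CV = 0.2
#: DNA-stain scale for one genome copy (G1 content), arbitrary units.
DNA_SCALE = 100.0
DNA_BASE_AREA = 50.0
DNA_NOISE_CV = 0.05
#: Cell-cycle occupancy (G1, S, G2/M) of an asynchronously growing culture.
CYCLE_FRACTIONS = (0.60, 0.25, 0.15)
#: Duration of the mitotic (transiently depolarized) window, hours.
M_PHASE_HOURS = 1.0
#: Additive Gaussian background noise, as a fraction of the background level.
BACKGROUND_NOISE_FRAC = 0.02


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated experimental condition.

    Parameters
    ----------
    seed : int
        Mandatory RNG seed.
    n_cells : int
        Cells seeded per sample (founder cells for time-lapse cohorts).
    toxin_effect : float
        Probability that a cell commits to a death pathway during the
        exposure window.
    pathway_mix : dict
        Distribution over death archetypes; must sum to 1.
    division_rate : float
        Per-cell probability of dividing within 24 h.
    confluency_label : int
        Culture confluency group, one of 50, 75, 100.
    exposure_window : float
        Hours after treatment during which death commitment can occur.
    duration_range : (float, float), optional
        Overrides every death archetype's commitment-to-lysis duration
        range (hours); used e.g. for rapidly lysing insults.
    sample_times : tuple of float
        Microscope sampling grid, hours.
    """

    seed: int
    n_cells: int = 500
    toxin_effect: float = 0.0
    pathway_mix: dict = field(default_factory=lambda: dict(DEFAULT_PATHWAY_MIX))
    division_rate: float = 0.3
    confluency_label: int = 75
    exposure_window: float = 24.0
    duration_range: tuple[float, float] | None = None
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.toxin_effect <= 1.0:
            raise ValueError("toxin_effect must lie in [0, 1]")
        if not 0.0 <= self.division_rate <= 1.0:
            raise ValueError("division_rate must lie in [0, 1]")
        if self.confluency_label not in (50, 75, 100):
            raise ValueError("confluency_label must be one of 50, 75, 100")
        weights = np.array(list(self.pathway_mix.values()), dtype=float)
        if len(weights) == 0 or not np.isclose(weights.sum(), 1.0):
            raise ValueError("pathway_mix must be non-empty and sum to 1")
        if np.any(weights < 0):
            raise ValueError("pathway_mix probabilities must be >= 0")
        for name in self.pathway_mix:
            if name not in ARCHETYPES or not ARCHETYPES[name].is_death:
                raise ValueError(f"pathway_mix key {name!r} is not a death archetype")
        if len(self.sample_times) and np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")

    def archetype(self, name: str) -> PathwayArchetype:
        """Archetype instance, with the scenario's duration override applied."""
        arch = ARCHETYPES[name]
        if self.duration_range is not None:
            arch = replace(arch, duration_range=tuple(self.duration_range))
        return arch


@dataclass
class CellTrack:
    """Time-lapse record of one cell (or one lineage segment).

    A track ends either at the cell's division (daughters get their own
    tracks), at the first sampling time the cell is observed absent
    (``lysis_time``), or at the end of the observation horizon.
    ``raw_intensity`` carries no values at or after ``lysis_time``.
    """

    cell_id: str
    sample_times: np.ndarray
    vm: np.ndarray
    raw_intensity: np.ndarray
    background_intensity: np.ndarray
    division_times: tuple[float, ...] = ()
    lysis_time: float | None = None
    archetype: str = "control"
    onset: float | None = None
    true_lysis: float | None = None
    parent_id: str | None = None

    def true_state_at(self, t: float) -> str:
        if self.true_lysis is not None and t >= self.true_lysis:
            return "lysed"
        if self.onset is not None and t >= self.onset:
            return "dying"
        return "alive"


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean 1 and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _death_phase(t, onset: float, duration: float):
    return np.clip((np.asarray(t, dtype=float) - onset) / duration, 0.0, 1.0)


def simulate_vm_track(
    archetype: PathwayArchetype | str,
    onset: float | None,
    duration: float | None = None,
    params: DyeModelParams | None = None,
    sample_times=DEFAULT_SAMPLE_TIMES,
    rng: np.random.Generator | None = None,
    noise_cv: float | None = None,
    cell_id: str = "track",
) -> CellTrack:
    """Simulate one cell's membrane potential and intensity track.

    For a death archetype the cell commits at ``onset`` and lyses at
    ``onset + duration``; sampling times at or past lysis carry no
    measurement.  For the control/division archetypes ``onset`` is
    ignored and the cell rests for the whole horizon.  With
    ``noise_cv = 0`` (and a zero-noise background) the intensities are
    the exact forward-model values, so the archetype shape contracts
    (apoptotic spike-then-fall, necrotic monotone decline) hold sample
    by sample.
    """
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    if params is None:
        params = DyeModelParams()
    if noise_cv is None:
        noise_cv = params.noise_cv
    times = np.asarray(sample_times, dtype=float)

    true_lysis = None
    if archetype.is_death:
        if onset is None or duration is None:
            raise ValueError("death archetypes need onset and duration")
        if len(times) and onset > times[-1]:
            raise ValueError("onset must lie within the observation horizon")
        true_lysis = onset + duration
        measured = times[times < true_lysis]
        u = _death_phase(measured, onset, duration)
        vm = archetype.vm_at(u, params)
        surface = archetype.surface_at(u)
        retention = archetype.retention_at(u)
        pre = measured < onset
        vm = np.where(pre, params.resting_potential, vm)
        surface = np.where(pre, 1.0, surface)
        retention = np.where(pre, 1.0, retention)
    else:
        measured = times
        vm = np.full_like(measured, params.resting_potential)
        surface = np.ones_like(measured)
        retention = np.ones_like(measured)

    clean = fluorescence(vm, surface, retention, params)
    if rng is not None and noise_cv > 0:
        raw = clean * _lognormal_factor(rng, noise_cv, size=len(measured))
        bg = params.background_level + rng.normal(
            0.0, BACKGROUND_NOISE_FRAC * params.background_level, size=len(measured)
        )
    else:
        raw = np.asarray(clean, dtype=float)
        bg = np.full_like(measured, params.background_level)
    bg = np.maximum(bg, 1e-9 + 0.5 * params.background_level)

    lysis_frame = None
    if true_lysis is not None:
        later = times[times >= true_lysis]
        if len(later):
            lysis_frame = float(later[0])

    return CellTrack(
        cell_id=cell_id,
        sample_times=measured,
        vm=np.asarray(vm, dtype=float),
        raw_intensity=raw,
        background_intensity=bg,
        lysis_time=lysis_frame,
        archetype=archetype.name,
        onset=onset if archetype.is_death else None,
        true_lysis=true_lysis,
    )


def _division_times(
    rng: np.random.Generator, start: float, horizon: float, rate_per_24h: float
) -> float | None:
    """First division time after ``start``, or None within the horizon."""
    if rate_per_24h <= 0:
        return None
    lam = -np.log1p(-min(rate_per_24h, 1 - 1e-12)) / 24.0
    wait = rng.exponential(1.0 / lam)
    t = start + wait
    return float(t) if t <= horizon else None


def generate_timelapse_cohort(
    config: ScenarioConfig,
    params: DyeModelParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[CellTrack]:
    """Simulate a cohort of tracked cells under one scenario.

    Founder cells commit to a death pathway with probability
    ``toxin_effect`` (onset uniform over the exposure window, duration
    uniform over the archetype's range) or else live, divide at the
    configured rate, and pass the lineage on to daughter tracks.  A
    dividing cell shows a transient depolarization during the mitotic
    hour preceding the division.  Deterministic under a fixed seed.
    """
    if params is None:
        params = DyeModelParams()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sample_times, dtype=float)
    horizon = times[-1]
    mix_names = list(config.pathway_mix)
    mix_probs = np.array([config.pathway_mix[n] for n in mix_names])

    tracks: list[CellTrack] = []

    def spawn(cell_id: str, start: float, parent: str | None) -> None:
        my_times = times[times >= start] if parent is not None else times
        dying = (
            start < config.exposure_window
            and rng.random() < config.toxin_effect
        )
        if dying:
            arch = config.archetype(mix_names[rng.choice(len(mix_names), p=mix_probs)])
            onset = rng.uniform(start, config.exposure_window)
            lo, hi = arch.duration_range
            duration = rng.uniform(lo, hi)
            track = simulate_vm_track(
                arch, onset, duration, params, my_times, rng, cell_id=cell_id
            )
            track.parent_id = parent
            tracks.append(track)
            return

        division = _division_times(rng, start, horizon, config.division_rate)
        if division is not None:
            measured = my_times[my_times <= division]
        else:
            measured = my_times
        vm = np.full_like(measured, params.resting_potential)
        if division is not None:
            in_m = (measured >= division - M_PHASE_HOURS) & (measured <= division)
            vm = vm + np.where(in_m, ARCHETYPES["division"].division_vm_shift, 0.0)
        clean = fluorescence(vm, 1.0, 1.0, params)
        raw = clean * _lognormal_factor(rng, params.noise_cv, size=len(measured))
        bg = params.background_level + rng.normal(
            0.0, BACKGROUND_NOISE_FRAC * params.background_level, size=len(measured)
        )
        bg = np.maximum(bg, 1e-9 + 0.5 * params.background_level)
        tracks.append(
            CellTrack(
                cell_id=cell_id,
                sample_times=measured,
                vm=vm,
                raw_intensity=raw,
                background_intensity=bg,
                division_times=(division,) if division is not None else (),
                archetype="division" if division is not None else "control",
                parent_id=parent,
            )
        )
        if division is not None:
            for j in (1, 2):
                spawn(f"{cell_id}.{j}", division, cell_id)

    for i in range(config.n_cells):
        spawn(f"C{i + 1}", 0.0, None)
    return tracks


def tracks_to_frames(tracks: list[CellTrack]):
    """Flatten tracks into (measurements, events, truth) DataFrames.

    measurements: cell_id, time_h, raw_intensity, background_intensity, vm
    events:       cell_id, division_time, lysis_time (NaN when absent)
    truth:        cell_id, archetype, onset, true_lysis, parent_id
    """
    meas_rows, event_rows, truth_rows = [], [], []
    for tr in tracks:
        for t, v, r, b in zip(
            tr.sample_times, tr.vm, tr.raw_intensity, tr.background_intensity
        ):
            meas_rows.append((tr.cell_id, t, r, b, v))
        event_rows.append(
            (
                tr.cell_id,
                tr.division_times[0] if tr.division_times else np.nan,
                tr.lysis_time if tr.lysis_time is not None else np.nan,
            )
        )
        truth_rows.append(
            (
                tr.cell_id,
                tr.archetype,
                tr.onset if tr.onset is not None else np.nan,
                tr.true_lysis if tr.true_lysis is not None else np.nan,
                tr.parent_id if tr.parent_id is not None else "",
            )
        )
    measurements = pd.DataFrame(
        meas_rows,
        columns=["cell_id", "time_h", "raw_intensity", "background_intensity", "vm"],
    )
    events = pd.DataFrame(
        event_rows, columns=["cell_id", "division_time", "lysis_time"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "archetype", "onset", "true_lysis", "parent_id"]
    )
    return measurements, events, truth


# ---------------------------------------------------------------------------
# endpoint (cytometry) cohorts


def generate_cohort(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the per-cell ground truth of one endpoint sample.

    Returns one row per seeded cell with its fate (death archetype,
    commitment onset, lysis time), size factor, cell-cycle DNA content
    and archetype DNA-signal factor.  This table is the shared substrate
    for the cytometry event generator and the comparator assays.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    dying = rng.random(n) < config.toxin_effect
    mix_names = list(config.pathway_mix)
    mix_probs = np.array([config.pathway_mix[m] for m in mix_names])
    arch_idx = rng.choice(len(mix_names), size=n, p=mix_probs)
    archetype = np.where(dying, np.array(mix_names)[arch_idx], "control")

    onset = rng.uniform(0.0, config.exposure_window, size=n)
    durations = np.empty(n)
    for i, name in enumerate(mix_names):
        arch = config.archetype(name)
        lo, hi = arch.duration_range
        sel = arch_idx == i
        durations[sel] = rng.uniform(lo, hi, size=sel.sum())
    onset = np.where(dying, onset, np.nan)
    durations = np.where(dying, durations, np.nan)
    true_lysis = onset + durations

    size_factor = _lognormal_factor(rng, SIZE_CV, size=n)
    # asynchronous cell-cycle DNA content: G1 = 1, S uniform(1, 2), G2/M = 2
    phase = rng.choice(3, size=n, p=CYCLE_FRACTIONS)
    content = np.where(phase == 0, 1.0, np.where(phase == 1, rng.uniform(1, 2, n), 2.0))
    dna_factor = np.array(
        [config.archetype(a).dna_signal_factor if a != "control" else 1.0
         for a in archetype]
    )

    return pd.DataFrame(
        {
            "cell_id": [f"cell{i + 1}" for i in range(n)],
            "dying": dying,
            "archetype": archetype,
            "onset": onset,
            "duration": durations,
            "true_lysis": true_lysis,
            "size_factor": size_factor,
            "dna_content": content,
            "dna_factor": dna_factor,
        }
    )


def events_from_cohort(
    cohort: pd.DataFrame,
    measure_time: float,
    config: ScenarioConfig,
    params: DyeModelParams,
    rng: np.random.Generator,
    sample_id: str,
    duplicate_index: int,
) -> pd.DataFrame:
    """Acquire one cytometry duplicate from a cohort at ``measure_time``.

    Cells lysed before acquisition emit no event.  Committed, unlysed
    cells carry archetype-consistent intensity and morphology; alive
    cells in the ~1 h mitotic window carry the transient division
    depolarization and a 2x DNA content.  The mitotic draw is made
    independently per duplicate, so a division-linked depolarization
    seen in duplicate 1 has resolved by duplicate 2 one hour later.
    """
    present = ~(cohort["dying"] & (cohort["true_lysis"] <= measure_time))
    sub = cohort[present].reset_index(drop=True)
    n = len(sub)

    in_death = sub["dying"].to_numpy() & (sub["onset"].to_numpy() <= measure_time)
    u = np.zeros(n)
    dy = in_death
    u[dy] = (measure_time - sub.loc[dy, "onset"]) / sub.loc[dy, "duration"]

    vm = np.full(n, params.resting_potential)
    surface = np.ones(n)
    retention = np.ones(n)
    for name in sub.loc[dy, "archetype"].unique():
        arch = config.archetype(name)
        sel = dy & (sub["archetype"] == name).to_numpy()
        vm[sel] = arch.vm_at(u[sel], params)
        surface[sel] = arch.surface_at(u[sel])
        retention[sel] = arch.retention_at(u[sel])

    # transient division depolarization among non-committed cells
    m_prob = config.division_rate * M_PHASE_HOURS / 24.0
    dividing = (~dy) & (rng.random(n) < m_prob)
    vm[dividing] += ARCHETYPES["division"].division_vm_shift

    cell_area = BASE_CELL_AREA * sub["size_factor"].to_numpy()
    # the dye's projected footprint follows cell size; bleb-folded membrane
    # adds molecules to the optical plane without growing the footprint
    dye_area = cell_area

    density = fluorescence(vm, surface, retention, params)
    total_intensity = (
        density
        * (dye_area / BASE_CELL_AREA)
        * _lognormal_factor(rng, params.noise_cv, size=n)
    )

    content = np.where(dividing, 2.0, sub["dna_content"].to_numpy())
    dna_factor = sub["dna_factor"].to_numpy()
    dna_intensity = (
        content * DNA_SCALE * dna_factor * _lognormal_factor(rng, DNA_NOISE_CV, size=n)
    )
    dna_area = (
        content
        * DNA_BASE_AREA
        * np.where(dna_factor > 0.01, 1.0, dna_factor)
        * _lognormal_factor(rng, DNA_NOISE_CV, size=n)
    )

    return pd.DataFrame(
        {
            "event_id": [
                f"{sample_id}-d{duplicate_index}-{cid}" for cid in sub["cell_id"]
            ],
            "cell_id": sub["cell_id"],
            "sample_id": sample_id,
            "duplicate_index": duplicate_index,
            "total_intensity": total_intensity,
            "dye_area": dye_area,
            "cell_area": cell_area,
            "dna_intensity": dna_intensity,
            "dna_area": dna_area,
            "true_state": np.where(dy, "dying", "alive"),
            "dividing": dividing,
        }
    )


def generate_cytometry_sample(
    config: ScenarioConfig,
    measure_time: float = 24.0,
    params: DyeModelParams | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "S1",
    cohort: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate the duplicate pair of cytometry event tables.

    Duplicate 1 is acquired at ``measure_time`` and duplicate 2 one hour
    later, from the same underlying cohort, to let the analysis check
    that depolarizations are permanent rather than transient.
    """
    if params is None:
        params = DyeModelParams()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if cohort is None:
        cohort = generate_cohort(config, rng)
    dup1 = events_from_cohort(cohort, measure_time, config, params, rng, sample_id, 1)
    dup2 = events_from_cohort(
        cohort, measure_time + 1.0, config, params, rng, sample_id, 2
    )
    return pd.concat([dup1, dup2], ignore_index=True)


# ---------------------------------------------------------------------------
# calibration


def generate_k_titration(
    params: DyeModelParams | None = None,
    k_levels=(15.0, 30.0, 50.0),
    anchors=None,
) -> pd.DataFrame:
    """Noise-free K+ titration table (K+, Vm, intensity).

    Maps each external-K+ level through the calibration anchors to a
    membrane potential and then through the dye model with unit surface
    and retention factors.  Regressing the fractional intensity change
    against the voltage change on this table recovers the dye
    sensitivity exactly.
    """
    if params is None:
        params = DyeModelParams()
    k = np.asarray(k_levels, dtype=float)
    if k.size == 0 or np.any(k <= 0):
        raise ValueError("k_levels must be non-empty and positive")
    vm = np.atleast_1d(k_to_vm(k, anchors=anchors, params=params))
    intensity = np.atleast_1d(fluorescence(vm, 1.0, 1.0, params))
    return pd.DataFrame({"k_mM": k, "vm_mV": vm, "intensity": intensity})


def generate_gaussian_control_intensities(
    n: int,
    params: DyeModelParams | None = None,
    rng: np.random.Generator | None = None,
    cv: float | None = None,
) -> np.ndarray:
    """Gaussian compensated intensities of an untreated control sample.

    Convenience generator for gate-calibration studies: resting cells'
    compensated intensities drawn from a normal distribution centred on
    the baseline fluorescence with the configured measurement CV.
    """
    if params is None:
        params = DyeModelParams()
    if rng is None:
        rng = np.random.default_rng()
    if cv is None:
        cv = params.noise_cv
    center = params.baseline_fluorescence
    return rng.normal(center, cv * center, size=int(n))
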