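"""Imaging-flow-cytometry analysis arm.

Each acquired event (one cell) carries a total dye intensity and the
membrane area covered by the dye; dividing total intensity by dye area
compensates for cell-size and dye-loading differences.  The viable
intensity range is the mean +/- k*SD (k = 2) of the compensated
intensities of the *untreated* cells of the same replicate group;
events above or below the range are classified dead.

Refinements of the improved protocol are included: cells with a
DNA-stain signal above a threshold multiple of the sample median are in
G2/M or mitosis — transiently depolarized, a known false-positive
source — and are excluded before gating; each sample is acquired as two
duplicates 1 h apart, and a Chi-squared comparison of their viable/dead
counts distinguishes permanent depolarization (death) from transient
excursions; and the acquired-cell count relative to the untreated
control rescales viability to account for cells that lysed before
acquisition and therefore emit no event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import chi_squared
from .timelapse import ViableRange, build_viable_range, classify_values

__all__ = [
    "GateConfig",
    "SampleScore",
    "compensate_intensity",
    "exclude_dividing",
    "control_range",
    "score_sample",
    "permanence_check",
    "count_adjusted_viability",
    "CytometryViabilityModel",
    "CytometryViabilityResults",
]

#: Minimum events per duplicate for the permanence check to be meaningful.
MIN_PERMANENCE_EVENTS = 20


@dataclass(frozen=True)
class GateConfig:
    """Gating parameters of the cytometry arm.

    k : SD multiplier of the viable range (default 2).
    dna_exclusion_threshold : multiple of the sample-median DNA-stain
        intensity above which an event is excluded as dividing (default
        1.5, separating G1 content 1x from G2/M content 2x with margin).
        ``None`` disables the exclusion.
    duplicate_alpha : significance level of the duplicate permanence
        Chi-squared test (default 0.01).
    count_adjustment : whether sample viability is rescaled by the
        acquired-cell count relative to the control.
    """

    k: float = 2.0
    dna_exclusion_threshold: float | None = 1.5
    duplicate_alpha: float = 0.01
    count_adjustment: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.dna_exclusion_threshold is not None and not (
            self.dna_exclusion_threshold > 1
        ):
            raise ValueError("dna_exclusion_threshold must exceed 1")
        if not 0 < self.duplicate_alpha < 1:
            raise ValueError("duplicate_alpha must lie in (0, 1)")


@dataclass
class SampleScore:
    """Viability score of one sample (or one duplicate)."""

    sample_id: str
    n_events: int
    n_dead_classified: int
    permanence_flag: str = "untestable"
    count_adjusted_viability: float = float("nan")

    @property
    def death_ratio(self) -> float:
        return self.n_dead_classified / self.n_events

    @property
    def gate_viability(self) -> float:
        return 1.0 - self.death_ratio


def compensate_intensity(total_intensity, dye_area):
    """Compensated intensity: total dye intensity / dye-covered area.

    Removes the influence of cell size and dye loading on the raw total
    intensity; accepts scalars or arrays.
    """
    total = np.asarray(total_intensity, dtype=float)
    area = np.asarray(dye_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("invalid event: dye_area must be positive")
    out = total / area
    return float(out) if out.ndim == 0 else out


def exclude_dividing(
    events: pd.DataFrame, cfg: GateConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition events into (kept, excluded-as-dividing) by DNA content.

    Events whose DNA-stain intensity exceeds ``threshold x median`` of
    the sample are excluded before range building and scoring; both
    partitions are returned for audit.
    """
    if cfg is None:
        cfg = GateConfig()
    if len(events) == 0:
        return events, events
    if cfg.dna_exclusion_threshold is None:
        return events, events.iloc[0:0]
    median = float(events["dna_intensity"].median())
    mask = events["dna_intensity"].to_numpy() > cfg.dna_exclusion_threshold * median
    kept, excluded = events[~mask], events[mask]
    if len(kept) == 0:
        raise ValueError("empty sample: every event excluded by the DNA gate")
    return kept, excluded


def control_range(
    control_events: pd.DataFrame,
    cfg: GateConfig | None = None,
    group: str | None = None,
    apply_dna_exclusion: bool = True,
) -> ViableRange:
    """Viable range from the compensated intensities of untreated events.

    Built per replicate group; raises (naming the group) when fewer than
    two control events survive the DNA exclusion.
    """
    if cfg is None:
        cfg = GateConfig()
    events = control_events
    if apply_dna_exclusion and len(events):
        events, _ = exclude_dividing(events, cfg)
    if len(events) < 2:
        label = f" for group {group!r}" if group else ""
        raise ValueError(f"insufficient control events{label}: need >= 2")
    comp = compensate_intensity(
        events["total_intensity"].to_numpy(), events["dye_area"].to_numpy()
    )
    return build_viable_range(comp, k=cfg.k)


def score_sample(
    events: pd.DataFrame, vrange: ViableRange, sample_id: str | None = None
) -> SampleScore:
    """Classify each event's compensated intensity against the range."""
    if len(events) == 0:
        raise ValueError("cannot score an empty event set")
    if sample_id is None:
        sample_id = str(events["sample_id"].iloc[0]) if "sample_id" in events else ""
    comp = compensate_intensity(
        events["total_intensity"].to_numpy(), events["dye_area"].to_numpy()
    )
    labels = classify_values(comp, vrange)
    return SampleScore(
        sample_id=sample_id,
        n_events=len(events),
        n_dead_classified=int((labels == "dead").sum()),
    )


def permanence_check(
    dup1: SampleScore, dup2: SampleScore, cfg: GateConfig | None = None
) -> str:
    """Classify a duplicate pair as permanent / transient / untestable.

    The two duplicates of a sample, acquired 1 h apart and scored
    against the same group range, should classify indistinguishably if
    the depolarizations they see are permanent.  A Chi-squared test on
    the 2x2 duplicate x classification table decides: ``permanent`` if
    p >= duplicate_alpha, ``transient`` otherwise, ``untestable`` when
    either duplicate has fewer than 20 events.
    """
    if cfg is None:
        cfg = GateConfig()
    if dup1.sample_id != dup2.sample_id:
        raise ValueError(
            f"duplicate mismatch: {dup1.sample_id!r} vs {dup2.sample_id!r}"
        )
    if dup1.n_events < MIN_PERMANENCE_EVENTS or dup2.n_events < MIN_PERMANENCE_EVENTS:
        return "untestable"
    table = [
        [dup1.n_events - dup1.n_dead_classified, dup1.n_dead_classified],
        [dup2.n_events - dup2.n_dead_classified, dup2.n_dead_classified],
    ]
    if dup1.n_dead_classified == 0 and dup2.n_dead_classified == 0:
        return "permanent"  # identical all-viable duplicates; test degenerate
    if (
        dup1.n_dead_classified == dup1.n_events
        and dup2.n_dead_classified == dup2.n_events
    ):
        return "permanent"
    _, p = chi_squared(table)
    return "permanent" if p >= cfg.duplicate_alpha else "transient"


def count_adjusted_viability(
    gate_viability: float, n_sample: int, n_control: int
) -> float:
    """Rescale gate viability by the acquired-cell count ratio.

    Cells that lysed before acquisition emit no event, so the gate alone
    overestimates viability; multiplying by n_sample / n_control folds
    the missing cells back in.  Clamped to [0, 1].
    """
    if n_control <= 0:
        raise ValueError("control count must be positive")
    return float(np.clip(gate_viability * n_sample / n_control, 0.0, 1.0))


class CytometryViabilityModel:
    """Control-gated viability model of a cytometry event table.

    Parameters
    ----------
    events : DataFrame
        One row per event with columns ``event_id, sample_id,
        duplicate_index, total_intensity, dye_area, cell_area,
        dna_intensity, dna_area``.
    control_samples : sequence of str
        ``sample_id`` values of the untreated samples the ranges are
        built from.
    config : GateConfig
    group_of : mapping, optional
        ``sample_id -> replicate group`` (e.g. cell line x confluency).
        Ranges are built per group from that group's controls; default
        is a single group.

    Fitting builds the per-group viable ranges from the pooled control
    duplicates (falling back to duplicate 1 with a warning if the
    control duplicates fail the permanence check), scores every sample,
    flags duplicate permanence, applies the count adjustment, and tests
    each treated sample against its group control with a Chi-squared on
    the 2x2 viable/dead table.
    """

    def __init__(
        self,
        events: pd.DataFrame,
        control_samples,
        config: GateConfig | None = None,
        group_of: dict | None = None,
    ):
        required = {
            "sample_id", "duplicate_index", "total_intensity", "dye_area",
            "dna_intensity",
        }
        missing = required - set(events.columns)
        if missing:
            raise ValueError(f"events table lacks columns: {sorted(missing)}")
        self.events = events
        self.control_samples = list(control_samples)
        self.config = config if config is not None else GateConfig()
        sample_ids = list(pd.unique(events["sample_id"]))
        self.group_of = dict(group_of) if group_of else {s: "all" for s in sample_ids}
        for s in sample_ids:
            self.group_of.setdefault(s, "all")

    def _group_controls(self, group: str) -> pd.DataFrame:
        ids = [
            s for s in self.control_samples if self.group_of.get(s, "all") == group
        ]
        return self.events[self.events["sample_id"].isin(ids)]

    def fit(self) -> "CytometryViabilityResults":
        cfg = self.config
        groups = sorted({self.group_of[s] for s in pd.unique(self.events["sample_id"])})
        ranges: dict[str, ViableRange] = {}
        for group in groups:
            controls = self._group_controls(group)
            if len(controls) == 0:
                raise ValueError(f"no control events for group {group!r}")
            kept, _ = exclude_dividing(controls, cfg)
            pooled = control_range(kept, cfg, group=group, apply_dna_exclusion=False)
            d1 = kept[kept["duplicate_index"] == 1]
            d2 = kept[kept["duplicate_index"] == 2]
            if len(d1) and len(d2):
                s1 = score_sample(d1, pooled, sample_id="control")
                s2 = score_sample(d2, pooled, sample_id="control")
                if permanence_check(s1, s2, cfg) == "transient":
                    warnings.warn(
                        f"control duplicates of group {group!r} differ "
                        "(transient depolarization?); range rebuilt from "
                        "duplicate 1 only",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    pooled = control_range(
                        d1, cfg, group=group, apply_dna_exclusion=False
                    )
            ranges[group] = pooled

        rows = []
        scores: dict[str, SampleScore] = {}
        for sample_id, sample_events in self.events.groupby("sample_id", sort=False):
            group = self.group_of[sample_id]
            vrange = ranges[group]
            kept, excluded = exclude_dividing(sample_events, cfg)
            pooled_score = score_sample(kept, vrange, sample_id=str(sample_id))
            dup_scores = []
            for dup in (1, 2):
                d = kept[kept["duplicate_index"] == dup]
                if len(d):
                    dup_scores.append(score_sample(d, vrange, sample_id=str(sample_id)))
            if len(dup_scores) == 2:
                flag = permanence_check(dup_scores[0], dup_scores[1], cfg)
            else:
                flag = "untestable"
            pooled_score.permanence_flag = flag

            controls = self._group_controls(group)
            n_control = int(
                (controls.groupby("duplicate_index").size()).mean()
            ) if len(controls) else 0
            n_sample = int(
                sample_events.groupby("duplicate_index").size().mean()
            )
            if cfg.count_adjustment and n_control > 0:
                adjusted = count_adjusted_viability(
                    pooled_score.gate_viability, n_sample, n_control
                )
            else:
                adjusted = pooled_score.gate_viability
            pooled_score.count_adjusted_viability = adjusted
            scores[str(sample_id)] = pooled_score

            is_control = sample_id in self.control_samples
            chi_stat, chi_p = np.nan, np.nan
            if not is_control:
                ctrl_kept, _ = exclude_dividing(controls, cfg)
                ctrl_score = score_sample(ctrl_kept, vrange, sample_id="control")
                table = [
                    [
                        ctrl_score.n_events - ctrl_score.n_dead_classified,
                        ctrl_score.n_dead_classified,
                    ],
                    [
                        pooled_score.n_events - pooled_score.n_dead_classified,
                        pooled_score.n_dead_classified,
                    ],
                ]
                try:
                    chi_stat, chi_p = chi_squared(table)
                except ValueError:
                    pass
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "is_control": is_control,
                    "n_events": pooled_score.n_events,
                    "n_excluded_dividing": len(excluded),
                    "n_dead_classified": pooled_score.n_dead_classified,
                    "death_ratio": pooled_score.death_ratio,
                    "gate_viability": pooled_score.gate_viability,
                    "count_adjusted_viability": adjusted,
                    "permanence": flag,
                    "chi2_vs_control": chi_stat,
                    "p_vs_control": chi_p,
                }
            )
        table = pd.DataFrame(rows)
        return CytometryViabilityResults(self, table, ranges, scores)


class CytometryViabilityResults:
    """Fit results of :class:`CytometryViabilityModel`."""

    def __init__(self, model, sample_table, ranges, scores):
        self.model = model
        self.sample_table = sample_table
        self.ranges = ranges
        self.scores = scores

    def score(self, sample_id: str) -> SampleScore:
        return self.scores[str(sample_id)]

    def summary(self) -> str:
        lines = [
            "Cytometry viability analysis",
            "============================",
        ]
        for group, r in self.ranges.items():
            lines.append(
                f"group {group}: viable range [{r.low:.4f}, {r.high:.4f}] "
                f"(center {r.center:.4f}, SD {r.spread:.4f}, k={r.k:g})"
            )
        with pd.option_context("display.width", 120):
            lines.append(
                self.sample_table[
                    [
                        "sample_id", "group", "is_control", "n_events",
                        "death_ratio", "gate_viability",
                        "count_adjusted_viability", "permanence", "p_vs_control",
                    ]
                ].to_string(index=False, float_format=lambda x: f"{x:.4f}")
            )
        return "\n".join(lines)
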