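"""Time-lapse (fluorescence microscope) analysis arm.

Per-cell dye intensities, sampled every 12 h, are normalized to the
background of the surrounding region of interest.  Cell fates observed
in the time-lapse assign each measured value a label:

* a cell that divides proves it was viable, so all of its values up to
  the division are *viable* (the same rule applies to each daughter
  that itself divides);
* a cell that lyses was committed to death beforehand, so values within
  the 48 h preceding the lysis are *dead* (death pathways take 2-48 h,
  so the commitment happened somewhere in that window) and earlier
  values are discarded as unknowable;
* values of cells that neither divide nor lyse during the observation
  are discarded.

The pooled viable values define the viable intensity range
(mean +/- k standard deviations, k = 2 by default, bounds inclusive);
values outside it are classified dead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney

__all__ = [
    "ViableRange",
    "normalize_intensity",
    "assign_labels",
    "build_viable_range",
    "classify_value",
    "classify_values",
    "TimelapseViabilityModel",
    "TimelapseViabilityResults",
]


@dataclass(frozen=True)
class ViableRange:
    """Control-derived viable intensity gate: [center - k*spread, center + k*spread].

    ``spread`` is the sample standard deviation (n-1 denominator);
    both bounds are inclusive.
    """

    center: float
    spread: float
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")

    @property
    def low(self) -> float:
        return self.center - self.k * self.spread

    @property
    def high(self) -> float:
        return self.center + self.k * self.spread


def normalize_intensity(cell_intensity, background_intensity):
    """Normalize a cell's dye intensity to its background ROI intensity.

    Dimensionless ratio cell / background; accepts scalars or arrays.
    """
    cell = np.asarray(cell_intensity, dtype=float)
    bg = np.asarray(background_intensity, dtype=float)
    if np.any(bg <= 0):
        bad = np.atleast_1d(bg <= 0)
        raise ValueError(
            f"invalid measurement: background ROI intensity must be positive "
            f"({int(bad.sum())} offending ROI value(s))"
        )
    out = cell / bg
    return float(out) if out.ndim == 0 else out


def assign_labels(
    measurements: pd.DataFrame,
    events: pd.DataFrame,
    dead_window: float = 48.0,
) -> pd.DataFrame:
    """Label every normalized intensity viable / dead / discarded.

    Parameters
    ----------
    measurements : DataFrame
        Columns ``cell_id, time_h, raw_intensity, background_intensity``.
    events : DataFrame
        Columns ``cell_id, division_time, lysis_time`` (NaN when the
        event was not observed).  ``lysis_time`` is the first sampling
        time at which the cell was observed absent.
    dead_window : float
        Hours before lysis within which values are labeled dead.

    Returns
    -------
    DataFrame with ``cell_id, time_h, normalized_intensity, label``;
    every measured value receives exactly one label.
    """
    ev = events.set_index("cell_id")
    out = measurements.reset_index(drop=True).copy()
    out["normalized_intensity"] = normalize_intensity(
        out["raw_intensity"].to_numpy(), out["background_intensity"].to_numpy()
    )

    labels = np.full(len(out), "discarded", dtype=object)
    for cell_id, grp in out.groupby("cell_id", sort=False):
        if cell_id not in ev.index:
            continue
        division = ev.at[cell_id, "division_time"]
        lysis = ev.at[cell_id, "lysis_time"]
        has_div = np.isfinite(division)
        has_lys = np.isfinite(lysis)
        if has_div and has_lys and division == lysis:
            raise ValueError(
                f"track {cell_id!r} has a division and a lysis at the same "
                "timestamp; inconsistent events"
            )
        t = grp["time_h"].to_numpy()
        lab = np.full(len(grp), "discarded", dtype=object)
        if has_div:
            lab[t <= division] = "viable"
        if has_lys:
            dead = (t >= lysis - dead_window) & (t < lysis)
            if has_div:
                dead &= t > division
            lab[dead] = "dead"
        labels[grp.index] = lab

    out["label"] = labels
    return out[["cell_id", "time_h", "normalized_intensity", "label"]]


def build_viable_range(values, k: float = 2.0) -> ViableRange:
    """Viable range from control/viable normalized intensities.

    Center is the arithmetic mean, spread the sample standard deviation
    (n-1 denominator).  Requires at least two values.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if len(vals) < 2:
        raise ValueError(
            "insufficient control values: need >= 2 to build a viable range"
        )
    return ViableRange(
        center=float(np.mean(vals)), spread=float(np.std(vals, ddof=1)), k=float(k)
    )


def classify_value(value: float, vrange: ViableRange) -> str:
    """Classify one value against the viable range (bounds inclusive)."""
    return "viable" if vrange.low <= value <= vrange.high else "dead"


def classify_values(values, vrange: ViableRange) -> np.ndarray:
    """Vectorized :func:`classify_value`."""
    vals = np.asarray(values, dtype=float)
    inside = (vals >= vrange.low) & (vals <= vrange.high)
    return np.where(inside, "viable", "dead")


class TimelapseViabilityModel:
    """Viable-range model of time-lapse dye intensities.

    Built from a measurement table and a fate-event table; fitting
    normalizes the intensities, labels them by fate, pools the viable
    values into the mean +/- k*SD viable range, classifies every labeled
    value against it, and compares viable vs dead values with the
    Mann-Whitney test.

    Parameters
    ----------
    measurements, events : DataFrame
        See :func:`assign_labels`.
    k : float
        SD multiplier of the viable range.
    dead_window : float
        Hours before lysis labeled dead.
    """

    def __init__(
        self,
        measurements: pd.DataFrame,
        events: pd.DataFrame,
        k: float = 2.0,
        dead_window: float = 48.0,
    ):
        if k < 0:
            raise ValueError("k must be >= 0")
        self.measurements = measurements
        self.events = events
        self.k = float(k)
        self.dead_window = float(dead_window)

    @classmethod
    def from_tracks(cls, tracks, **kwargs) -> "TimelapseViabilityModel":
        """Build directly from simulated :class:`~mpcva.simulate.CellTrack`s."""
        from .simulate import tracks_to_frames

        measurements, events, _ = tracks_to_frames(tracks)
        return cls(measurements, events, **kwargs)

    def fit(self) -> "TimelapseViabilityResults":
        labeled = assign_labels(self.measurements, self.events, self.dead_window)
        viable = labeled.loc[labeled["label"] == "viable", "normalized_intensity"]
        dead = labeled.loc[labeled["label"] == "dead", "normalized_intensity"]
        vrange = build_viable_range(viable.to_numpy(), k=self.k)
        used = labeled[labeled["label"] != "discarded"].copy()
        used["classified"] = classify_values(
            used["normalized_intensity"].to_numpy(), vrange
        )
        if len(dead):
            u_stat, p = mann_whitney(viable.to_numpy(), dead.to_numpy())
        else:
            u_stat, p = np.nan, np.nan
        return TimelapseViabilityResults(self, labeled, used, vrange, u_stat, p)


class TimelapseViabilityResults:
    """Fit results of :class:`TimelapseViabilityModel`."""

    def __init__(self, model, labeled, classified, viable_range, u_statistic, p_value):
        self.model = model
        self.labeled = labeled
        self.classified = classified
        self.viable_range = viable_range
        self.u_statistic = u_statistic
        self.p_value = p_value

    @property
    def n_viable(self) -> int:
        return int((self.labeled["label"] == "viable").sum())

    @property
    def n_dead(self) -> int:
        return int((self.labeled["label"] == "dead").sum())

    @property
    def n_discarded(self) -> int:
        return int((self.labeled["label"] == "discarded").sum())

    def summary(self) -> str:
        r = self.viable_range
        lines = [
            "Time-lapse viability analysis",
            "=============================",
            f"measurements: {len(self.labeled)}  "
            f"(viable {self.n_viable}, dead {self.n_dead}, "
            f"discarded {self.n_discarded})",
            f"viable range (k={r.k:g}): [{r.low:.4f}, {r.high:.4f}]  "
            f"center {r.center:.4f}, SD {r.spread:.4f}",
        ]
        if np.isfinite(self.p_value):
            lines.append(
                f"Mann-Whitney viable vs dead: U = {self.u_statistic:.1f}, "
                f"p = {self.p_value:.3g}"
            )
        else:
            lines.append("Mann-Whitney viable vs dead: not testable (no dead values)")
        return "\n".join(lines)
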