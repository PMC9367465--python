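"""Forward model of the voltage-sensitive dye signal.

The dye (a FluoVolt-class PeT probe) sits in the outer leaflet of the
plasma membrane and brightens as the membrane depolarizes: its emission
changes by a fixed fraction of the baseline per 100 mV of depolarization
(25 %/100 mV for the dye modelled here).  A healthy cell rests near
-40 mV; a cell that has permanently lost membrane integrity drifts to
0 mV (bulk electroneutrality), so death shows up as a sustained
brightness increase — later compounded by morphology (bleb formation
folds extra labelled membrane into the optical plane) and eventually
reversed by dye loss when the membrane disintegrates.

The model is deliberately linear in voltage; everything beyond the
stated linear sensitivity (photochemistry, bleaching) is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DyeModelParams",
    "NEURON_K_ANCHORS",
    "default_anchor_table",
    "k_to_vm",
    "fluorescence",
]


@dataclass(frozen=True)
class DyeModelParams:
    """Constants of the dye forward model.

    Parameters
    ----------
    baseline_fluorescence : float
        Emission (arbitrary units) of a resting cell with unit surface
        and retention factors.
    sensitivity : float
        Fractional fluorescence change per 100 mV of depolarization.
        Default 0.25 (25 %/100 mV).
    resting_potential : float
        Resting membrane potential in mV.  Default -40 mV.
    dead_potential : float
        Membrane potential of a cell that has lost membrane integrity,
        in mV.  Default 0 mV.
    noise_cv : float
        Coefficient of variation of the multiplicative (lognormal)
        measurement noise applied to intensities.
    background_level : float
        Mean background intensity of an empty region of interest
        (arbitrary units).
    """

    baseline_fluorescence: float = 100.0
    sensitivity: float = 0.25
    resting_potential: float = -40.0
    dead_potential: float = 0.0
    noise_cv: float = 0.03
    background_level: float = 50.0

    def __post_init__(self) -> None:
        if not self.baseline_fluorescence > 0:
            raise ValueError("baseline_fluorescence must be positive")
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be positive")
        if not self.resting_potential < self.dead_potential:
            raise ValueError("resting_potential must lie below dead_potential")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not self.background_level > 0:
            raise ValueError("background_level must be positive")


#: External-K+ depolarization anchors measured in rat neurons:
#: (K+ concentration in mM, membrane potential in mV).
NEURON_K_ANCHORS: tuple[tuple[float, float], ...] = (
    (15.0, -56.0),
    (30.0, -26.0),
    (40.0, -19.0),
)

#: Physiological external K+ of the standard culture medium (mM).
BASELINE_K = 5.0


def default_anchor_table(params: DyeModelParams | None = None) -> np.ndarray:
    """Default K+ -> Vm calibration anchors as an (n, 2) array.

    The table is the published neuron anchor set.  A baseline anchor
    (5 mM, resting_potential) is prepended only when the configured
    resting potential lies below the first neuron anchor's -56 mV, so
    the table always satisfies the strict-monotonicity requirement of
    :func:`k_to_vm`.  The -40 mV cell lines the assay was developed on
    therefore use the neuron anchors alone.
    """
    anchors = list(NEURON_K_ANCHORS)
    if params is not None and params.resting_potential < anchors[0][1]:
        anchors.insert(0, (BASELINE_K, params.resting_potential))
    return np.asarray(anchors, dtype=float)


def _validate_anchors(anchors: np.ndarray) -> np.ndarray:
    anchors = np.asarray(anchors, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 2 or anchors.shape[0] < 2:
        raise ValueError(
            "calibration anchors must be an (n >= 2, 2) table of (K+, Vm)"
        )
    k, vm = anchors[:, 0], anchors[:, 1]
    if not (np.all(np.diff(k) > 0) and np.all(np.diff(vm) > 0)):
        raise ValueError(
            "calibration anchors must be strictly increasing in both "
            "K+ concentration and membrane potential"
        )
    return anchors


def k_to_vm(
    k_out,
    anchors: np.ndarray | None = None,
    params: DyeModelParams | None = None,
):
    """Map external K+ concentration (mM) to membrane potential (mV).

    Monotone piecewise-linear interpolation through the calibration
    anchors; values beyond the anchor range are linearly extrapolated
    from the nearest segment and clamped from above at the dead-cell
    potential (a fully depolarized membrane cannot exceed bulk
    electroneutrality).

    Parameters
    ----------
    k_out : float or array_like
        External K+ concentration(s), mM.  Must be positive.
    anchors : array_like, optional
        (n, 2) anchor table of (K+, Vm), strictly increasing in both
        columns.  Defaults to :func:`default_anchor_table`.
    params : DyeModelParams, optional
        Supplies the dead-potential clamp (default parameters if omitted).
    """
    if params is None:
        params = DyeModelParams()
    if anchors is None:
        anchors = default_anchor_table(params)
    anchors = _validate_anchors(anchors)

    k_arr = np.asarray(k_out, dtype=float)
    if np.any(k_arr <= 0):
        raise ValueError("K+ concentration must be positive")

    k_nodes, vm_nodes = anchors[:, 0], anchors[:, 1]
    vm = np.interp(k_arr, k_nodes, vm_nodes)
    # np.interp clips beyond the range; replace with linear extrapolation.
    lo = k_arr < k_nodes[0]
    hi = k_arr > k_nodes[-1]
    if np.any(lo):
        slope = (vm_nodes[1] - vm_nodes[0]) / (k_nodes[1] - k_nodes[0])
        vm = np.where(lo, vm_nodes[0] + slope * (k_arr - k_nodes[0]), vm)
    if np.any(hi):
        slope = (vm_nodes[-1] - vm_nodes[-2]) / (k_nodes[-1] - k_nodes[-2])
        vm = np.where(hi, vm_nodes[-1] + slope * (k_arr - k_nodes[-1]), vm)
    vm = np.minimum(vm, params.dead_potential)
    return float(vm) if np.isscalar(k_out) else vm


def fluorescence(
    vm,
    surface_factor=1.0,
    retention=1.0,
    params: DyeModelParams | None = None,
):
    """Dye emission at membrane potential ``vm`` (mV).

    F = F0 * (1 + s * (Vm - Vrest) / 100) * surface_factor * retention

    where ``F0`` is the baseline fluorescence, ``s`` the fractional
    sensitivity per 100 mV, ``surface_factor`` (>= 1) the membrane
    surface-area amplification from blebbing, and ``retention``
    (0 < r <= 1) the fraction of dye still attached to the membrane.
    Strictly increasing in ``vm`` at fixed factors.  A voltage far below
    rest (outside the linear model's validity) would give a negative
    emission; the result is clamped at 0 with a warning.
    """
    if params is None:
        params = DyeModelParams()
    vm_arr = np.asarray(vm, dtype=float)
    sf = np.asarray(surface_factor, dtype=float)
    ret = np.asarray(retention, dtype=float)
    if np.any(sf < 1):
        raise ValueError("surface_factor must be >= 1")
    if np.any(ret <= 0) or np.any(ret > 1):
        raise ValueError("retention must lie in (0, 1]")

    voltage_term = 1.0 + params.sensitivity * (
        vm_arr - params.resting_potential
    ) / 100.0
    out = params.baseline_fluorescence * voltage_term * sf * ret
    if np.any(out < 0):
        warnings.warn(
            "membrane potential below the linear range of the dye model; "
            "fluorescence clamped at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out
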