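"""Specific membrane conductance from current-voltage recordings.

Planar-bilayer experiments report the total specific membrane conductance
G_m (nS/cm^2) as the slope of a linear fit to the I-U relation in a small
voltage window around 0 mV, normalised by membrane area.  The voltage
dependence of G_m over a wider range is captured by an exponential
G(psi) = G0 * exp(b * |psi|), and inhibitor titrations are expressed as
baseline-subtracted relative conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "IVTrace",
    "ConductanceResult",
    "VoltageDependenceFit",
    "RelativeConductance",
    "fit_ohmic_conductance",
    "fit_voltage_dependence",
    "activation_ratio",
    "relative_conductance",
]


@dataclass
class IVTrace:
    """One current-voltage recording plus membrane geometry.

    Parameters
    ----------
    voltage : array of mV
    current : array of pA, same length as ``voltage``
    area : membrane area in cm^2
    side_labels : (cis, trans) buffer descriptors
    temperature : K
    provenance : free-form metadata; synthetic traces carry their true
        generating parameters here
    """

    voltage: np.ndarray
    current: np.ndarray
    area: float
    side_labels: tuple[str, str] = ("cis pH 7.34", "trans pH 7.34")
    temperature: float = 306.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.size == 0:
            raise InvalidInputError("voltage grid is empty")
        if self.voltage.shape != self.current.shape:
            raise InvalidInputError("voltage and current must have equal length")
        if self.voltage.size < 3:
            raise InvalidInputError("an I-V trace needs at least 3 points")
        if np.unique(self.voltage).size != self.voltage.size:
            raise InvalidInputError("voltages must be unique")
        if not self.area > 0:
            raise InvalidInputError(f"membrane area must be positive, got {self.area}")


@dataclass
class ConductanceResult:
    """Specific conductance estimate with fit diagnostics.

    ``G_specific`` is in nS/cm^2 (slope in pA/mV equals nS; divided by area).
    ``intercept_U0`` is the zero-current potential in mV, ``None`` when the
    slope is below machine tolerance (flagged via ``intercept_defined``).
    """

    G_specific: float
    intercept_U0: float | None
    fit_window: tuple[float, float]
    r_squared: float
    n_points: int
    intercept_defined: bool = True
    slope_pA_per_mV: float = 0.0
    offset_pA: float = 0.0


@dataclass
class VoltageDependenceFit:
    """Exponential voltage dependence G(psi) = G0 * exp(b * |psi|)."""

    G0_amplitude: float  # nS/cm^2 at psi = 0
    slope_b: float  # per mV
    converged: bool = True
    residual_norm: float = 0.0
    message: str = ""

    def predict(self, psi_mV: np.ndarray) -> np.ndarray:
        psi_mV = np.asarray(psi_mV, dtype=float)
        return self.G0_amplitude * np.exp(self.slope_b * np.abs(psi_mV))


@dataclass
class RelativeConductance:
    """Baseline-subtracted normalised conductance, clipped at 0 when needed."""

    value: float
    clipped: bool = False

    def __float__(self) -> float:
        return float(self.value)


def fit_ohmic_conductance(
    trace: IVTrace, window: tuple[float, float] = (-50.0, 50.0)
) -> ConductanceResult:
    """Estimate specific conductance as the OLS slope of I vs U in ``window``.

    The slope of current (pA) against voltage (mV) is numerically the
    conductance in nS; dividing by the membrane area gives nS/cm^2.  The
    zero-current potential is ``-a/g`` for the fitted line ``I = a + g*U``.

    Raises
    ------
    InsufficientDataError
        if fewer than 3 trace points fall inside the window.
    """
    lo, hi = min(window), max(window)
    mask = (trace.voltage >= lo) & (trace.voltage <= hi)
    u = trace.voltage[mask]
    i = trace.current[mask]
    if u.size < 3:
        raise InsufficientDataError(
            f"only {u.size} points inside window [{lo}, {hi}] mV; need >= 3"
        )

    slope, offset = np.polyfit(u, i, 1)
    fitted = offset + slope * u
    ss_res = float(np.sum((i - fitted) ** 2))
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    # slope tolerance scaled to the data so a flat trace is flagged, not divided
    scale = max(1.0, float(np.max(np.abs(i))) / max(np.ptp(u), 1.0))
    defined = abs(slope) > 1e3 * np.finfo(float).eps * scale
    u0 = float(-offset / slope) if defined else None

    return ConductanceResult(
        G_specific=float(slope / trace.area),
        intercept_U0=u0,
        fit_window=(lo, hi),
        r_squared=r2,
        n_points=int(u.size),
        intercept_defined=defined,
        slope_pA_per_mV=float(slope),
        offset_pA=float(offset),
    )


def fit_voltage_dependence(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> VoltageDependenceFit:
    """Fit G(psi) = A * exp(b * |psi|) to (potential mV, conductance nS/cm^2) pairs.

    Initial values come from a log-linear regression of ln G on |psi|; the
    exponential is then refined by nonlinear least squares with relative
    (1/G) weighting, since conductance errors are multiplicative and the
    data span decades.  The conductance is modelled as symmetric in the
    sign of the potential.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be a sequence of (psi_mV, G) pairs")
    if pts.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (psi, G) points")
    psi = np.abs(pts[:, 0])
    g = pts[:, 1]
    if np.any(g <= 0):
        raise InvalidInputError("conductances must be positive for the exponential fit")

    # log-linear start values
    b0, lnA0 = np.polyfit(psi, np.log(g), 1)

    def model(x, a, b):
        return a * np.exp(b * x)

    try:
        with np.errstate(invalid="ignore"):
            popt, _ = curve_fit(
                model, psi, g, p0=[np.exp(lnA0), b0], sigma=g, maxfev=10000
            )
        a_hat, b_hat = float(popt[0]), float(popt[1])
        resid = float(np.linalg.norm(g - model(psi, a_hat, b_hat)))
        return VoltageDependenceFit(a_hat, b_hat, True, resid)
    except RuntimeError as exc:  # pragma: no cover - hard to trigger
        return VoltageDependenceFit(
            float(np.exp(lnA0)), float(b0), False, float("nan"), message=str(exc)
        )


def activation_ratio(G_protein_fa: float, G_fa: float) -> float:
    """Fold-activation of conductance by the carrier in the presence of fatty acid.

    Returns ``G_protein_fa / G_fa`` (e.g. 1750/440 ~ 4-fold for arachidonic
    acid plus reconstituted carrier vs fatty acid alone).
    """
    if not (G_protein_fa > 0 and G_fa > 0):
        raise InvalidInputError("both conductances must be positive")
    return G_protein_fa / G_fa


def relative_conductance(
    G_at_c: float, G_no_inhibitor: float, G_baseline: float
) -> RelativeConductance:
    """Express conductance under inhibitor as a fraction of the uninhibited span.

    rel = (G_at_c - G_baseline) / (G_no_inhibitor - G_baseline), so full
    inhibition maps to 0 and no inhibitor to 1.  Values below 0 (conductance
    under the protein-free baseline, possible with noise) are clipped and
    flagged.
    """
    denom = G_no_inhibitor - G_baseline
    if denom <= 0:
        raise InvalidInputError(
            "uninhibited conductance must exceed the baseline conductance"
        )
    raw = (G_at_c - G_baseline) / denom
    if raw < 0:
        return RelativeConductance(0.0, clipped=True)
    return RelativeConductance(float(raw), clipped=False)
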