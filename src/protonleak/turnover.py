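"""Per-protein H+ turnover from a pH-gradient-induced reversal-potential shift.

Imposing a transmembrane pH difference shifts the zero-current potential of
the I-U relation; the shift ΔU_rev times the small-signal proton conductance
G_H gives the proton flux density J = G_H * ΔU_rev / F (mol s^-1 cm^-2).
Dividing by the carrier surface density sigma (molecules cm^-2, from the
FCS-derived protein:lipid ratio) yields the turnover number

    k = J * N_A / sigma   [H+ per carrier per second].

The ideal (fully proton-selective) shift is the Nernst potential
U_N = (R T / F) ln(10) ΔpH, so ΔU_rev / U_N measures proton selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.constants import Avogadro, R as GAS_CONSTANT
from scipy.constants import physical_constants

from .conductance import IVTrace, fit_ohmic_conductance
from .exceptions import InvalidInputError

FARADAY = physical_constants["Faraday constant"][0]  # C/mol

__all__ = [
    "ShiftedIvPair",
    "TurnoverResult",
    "reversal_shift",
    "nernst_potential",
    "protein_surface_density",
    "turnover_number",
]


@dataclass
class ShiftedIvPair:
    """I-V traces with and without a transmembrane pH gradient.

    ``trace_ref`` is recorded at symmetric pH; ``trace_shifted`` after raising
    the cis-side pH by ``delta_pH`` units.  Both traces must share the same
    membrane area.
    """

    trace_ref: IVTrace
    trace_shifted: IVTrace
    delta_pH: float = 1.0
    temperature: float = 306.0

    def __post_init__(self) -> None:
        if self.trace_ref.area != self.trace_shifted.area:
            raise InvalidInputError("reference and shifted traces must share one membrane area")


@dataclass
class TurnoverResult:
    """Turnover number with every quantity and constant that entered it."""

    k_turnover: float  # s^-1, H+ per carrier per second
    flux_density: float  # mol s^-1 cm^-2
    sigma_protein: float  # molecules cm^-2
    G_H: float  # nS/cm^2, the conductance used (provenance says which)
    delta_U_rev: float  # mV
    U_nernst: float | None = None  # mV, ideal shift for the imposed delta_pH
    transference_ratio: float | None = None  # delta_U_rev / U_nernst
    transference_flag: bool = False  # True when the ratio falls outside [0, 1]
    F: float = FARADAY
    N_A: float = Avogadro
    R: float = GAS_CONSTANT
    provenance: dict = field(default_factory=dict)


def reversal_shift(pair: ShiftedIvPair, window: tuple[float, float] = (-50.0, 50.0)) -> float:
    """Zero-current potential shift (mV) between the shifted and reference traces.

    Both traces are fit with the linear small-signal conductance fit; the
    shift is the difference of their zero-current intercepts.  An undefined
    intercept (flat trace) propagates as an error.
    """
    ref = fit_ohmic_conductance(pair.trace_ref, window)
    shifted = fit_ohmic_conductance(pair.trace_shifted, window)
    if not (ref.intercept_defined and shifted.intercept_defined):
        raise InvalidInputError("zero-current potential undefined on a flat trace")
    return shifted.intercept_U0 - ref.intercept_U0


def nernst_potential(delta_pH: float, T: float = 306.0) -> float:
    """Ideal proton reversal potential (mV): (R T / F) ln(10) * delta_pH."""
    if not T > 0:
        raise InvalidInputError("temperature must be positive (kelvin)")
    import numpy as np

    return GAS_CONSTANT * T / FARADAY * np.log(10.0) * delta_pH * 1e3


def protein_surface_density(rho: float, A_L_nm2: float = 0.6) -> float:
    """Carriers per cm^2 of membrane from the protein:lipid ratio.

    A unit membrane area holds 2/A_L lipids (both leaflets), so
    sigma = rho * 2 / A_L, converted from nm^-2 to cm^-2 (x 1e14).
    """
    if not (rho > 0 and A_L_nm2 > 0):
        raise InvalidInputError("rho and area per lipid must be positive")
    return rho * 2.0 / A_L_nm2 * 1e14


def turnover_number(
    G_H: float,
    delta_U_rev: float,
    sigma: float,
    delta_pH: float | None = None,
    temperature: float = 306.0,
    g_mode: str = "protein",
) -> TurnoverResult:
    """Per-carrier H+ turnover from conductance, reversal shift and density.

    Parameters
    ----------
    G_H : proton-carrying specific conductance in nS/cm^2.  By convention
        this is the protein-mediated part (total with protein + fatty acid
        minus the fatty-acid-only control); pass ``g_mode='total'`` to record
        that the total membrane conductance was used instead.
    delta_U_rev : measured reversal-potential shift in mV.
    sigma : carrier surface density in molecules/cm^2.
    delta_pH, temperature : when given, the ideal Nernst shift and the
        transference ratio delta_U_rev/U_N are reported alongside; a ratio
        outside [0, 1] is flagged, never clipped.
    """
    if not (G_H > 0 and delta_U_rev > 0 and sigma > 0):
        raise InvalidInputError("conductance, shift and density must all be positive")
    # nS/cm^2 * mV -> (1e-9 S)(1e-3 V) = 1e-12 A/cm^2; / F -> mol s^-1 cm^-2
    flux = G_H * 1e-9 * delta_U_rev * 1e-3 / FARADAY
    k = flux * Avogadro / sigma

    u_n = ratio = None
    flagged = False
    if delta_pH is not None:
        u_n = nernst_potential(delta_pH, temperature)
        ratio = delta_U_rev / u_n if u_n != 0 else None
        flagged = ratio is not None and not (0.0 <= ratio <= 1.0)

    return TurnoverResult(
        k_turnover=k,
        flux_density=flux,
        sigma_protein=sigma,
        G_H=G_H,
        delta_U_rev=delta_U_rev,
        U_nernst=u_n,
        transference_ratio=ratio,
        transference_flag=flagged,
        provenance={"g_mode": g_mode, "temperature_K": temperature},
    )
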