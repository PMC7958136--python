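"""Sigmoidal inhibition fitting: EC50 and maximal inhibition with bootstrap CIs.

The relative conductance under an inhibitor at concentration c is modelled as

    rel(c) = 1 - (I_max/100) * c^h / (c^h + EC50^h)

with the Hill slope h fixed to 1 by default (a two-parameter sigmoid:
EC50 and I_max are the reported fit parameters).  The curve is constrained
to rel = 1 at c = 0; I_max < 100 % means partial inhibition at saturation.
Uncertainty comes from a seeded case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .exceptions import DegenerateFitError, InsufficientDataError, InvalidInputError

__all__ = [
    "DoseSeries",
    "DoseResponseFit",
    "inhibition_model",
    "fit_inhibition",
    "bootstrap_ci",
    "compare_compounds",
]


@dataclass
class DoseSeries:
    """Inhibitor concentration vs relative conductance for one compound."""

    concentration: np.ndarray  # uM
    rel_conductance: np.ndarray
    compound: str = ""
    replicate_id: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.rel_conductance = np.asarray(self.rel_conductance, dtype=float)
        if self.concentration.shape != self.rel_conductance.shape:
            raise InvalidInputError("concentration and response must have equal length")
        if np.any(self.concentration < 0):
            raise InvalidInputError("concentrations must be non-negative")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id)
            if self.replicate_id.shape != self.concentration.shape:
                raise InvalidInputError("replicate_id must match data length")


@dataclass
class DoseResponseFit:
    """EC50 (uM), I_max (%), Hill slope and optional bootstrap 95% intervals."""

    ec50: float
    imax: float
    hill: float
    compound: str = ""
    ci_ec50: tuple[float, float] | None = None
    ci_imax: tuple[float, float] | None = None
    converged: bool = True
    sse: float = float("nan")
    n_points: int = 0
    message: str = ""

    @property
    def reliable(self) -> bool | None:
        """False when the I_max interval includes 0 (no reliable inhibition,
        the rule under which low-effect compounds are dropped from reporting);
        None when no interval has been computed."""
        if self.ci_imax is None:
            return None
        return self.ci_imax[0] > 0.0

    def predict(self, c: np.ndarray) -> np.ndarray:
        return inhibition_model(np.asarray(c, dtype=float), self.ec50, self.imax, self.hill)


def inhibition_model(c: np.ndarray, ec50: float, imax: float, hill: float = 1.0) -> np.ndarray:
    """rel(c) = 1 - (imax/100) * c^h / (c^h + ec50^h); rel(0) = 1 exactly."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ch = np.where(c > 0, c, 1.0) ** hill
        frac = np.where(c > 0, ch / (ch + ec50**hill), 0.0)
    return 1.0 - (imax / 100.0) * frac


def _check_series(series: DoseSeries) -> tuple[np.ndarray, np.ndarray]:
    c = series.concentration
    y = series.rel_conductance
    if np.unique(c).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations to fit, got {np.unique(c).size}"
        )
    if np.ptp(y) < 1e-12:
        raise DegenerateFitError("all responses equal; no dose dependence to fit")
    return c, y


def _occupancy(c: np.ndarray, log_ec50: np.ndarray, hill: float) -> np.ndarray:
    """Fractional occupancy c^h/(c^h + ec50^h), shape (n_points, n_grid)."""
    ch = np.where(c > 0, c, 1.0)[:, None] ** hill
    w = ch / (ch + np.exp(np.atleast_1d(log_ec50))[None, :] ** hill)
    return np.where((c > 0)[:, None], w, 0.0)


def _profile_imax(c: np.ndarray, y: np.ndarray, log_ec50, hill: float):
    """For fixed EC50 the model is linear in I_max: solve it in closed form.

    Vectorised over a grid of log-EC50 values; returns (imax_hat clipped to
    [0, 100], SSE at that imax), scalars for scalar input.
    """
    scalar = np.ndim(log_ec50) == 0
    w = _occupancy(c, log_ec50, hill)  # (n, g)
    num = w.T @ (1.0 - y)
    den = np.einsum("ig,ig->g", w, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        imax = np.clip(np.where(den > 0, 100.0 * num / den, 0.0), 0.0, 100.0)
    resid = (1.0 - y)[:, None] - w * (imax[None, :] / 100.0)
    sse = np.einsum("ig,ig->g", resid, resid)
    if scalar:
        return float(imax[0]), float(sse[0])
    return imax, sse


def fit_inhibition(series: DoseSeries, fix_hill: float | None = 1.0) -> DoseResponseFit:
    """Least-squares fit of the sigmoid to a dose series.

    With ``fix_hill`` given (default h = 1), the fit profiles I_max out
    analytically and minimises over log EC50 on a grid refined by bounded
    scalar search — robust and fast, with EC50 bounded to the positive
    concentration range times [0.01, 100] and I_max to [0, 100] %.
    With ``fix_hill=None`` the Hill slope is free (bounded nonlinear least
    squares in (log EC50, I_max, log h)).
    """
    c, y = _check_series(series)
    cpos = c[c > 0]
    if cpos.size == 0:
        raise InsufficientDataError("need positive concentrations to locate EC50")
    lo, hi = np.log(cpos.min() * 0.01), np.log(cpos.max() * 100.0)

    if fix_hill is not None:
        if not fix_hill > 0:
            raise InvalidInputError("fix_hill must be positive")
        h = float(fix_hill)
        grid = np.linspace(lo, hi, 80)
        _, sses = _profile_imax(c, y, grid, h)
        k = int(np.argmin(sses))
        a, b = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
        res = minimize_scalar(
            lambda t: _profile_imax(c, y, t, h)[1], bounds=(a, b), method="bounded",
            options={"xatol": 1e-10},
        )
        log_ec50 = float(res.x)
        imax, sse = _profile_imax(c, y, log_ec50, h)
        return DoseResponseFit(
            ec50=float(np.exp(log_ec50)), imax=imax, hill=h,
            compound=series.compound, converged=True, sse=sse, n_points=int(c.size),
        )

    # free Hill slope
    imax0 = min(max((1.0 - float(y.min())) * 100.0, 1.0), 100.0)
    x0 = np.array([np.log(np.median(cpos)), imax0, 0.0])

    def resid(x):
        return y - inhibition_model(c, np.exp(x[0]), x[1], np.exp(x[2]))

    sol = least_squares(
        resid, x0,
        bounds=([lo, 0.0, np.log(0.1)], [hi, 100.0, np.log(10.0)]),
    )
    return DoseResponseFit(
        ec50=float(np.exp(sol.x[0])), imax=float(sol.x[1]), hill=float(np.exp(sol.x[2])),
        compound=series.compound, converged=bool(sol.success),
        sse=float(2 * sol.cost), n_points=int(c.size), message=sol.message,
    )


def bootstrap_ci(
    series: DoseSeries,
    n_boot: int = 1000,
    seed: int = 0,
    fix_hill: float | None = 1.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile 95% bootstrap intervals for (EC50, I_max).

    Case-resampling over points; when ``replicate_id`` marks more than one
    replicate, whole replicates are resampled instead (the experimental unit
    is the independent titration).  Seeded and reproducible; resamples that
    are degenerate (too few distinct concentrations) are redrawn implicitly
    by being skipped.
    """
    if n_boot < 200:
        raise InvalidInputError("n_boot must be >= 200 for stable percentile intervals")
    c, y = _check_series(series)
    rng = np.random.default_rng(seed)

    blocks: list[np.ndarray]
    if series.replicate_id is not None and np.unique(series.replicate_id).size > 1:
        blocks = [np.flatnonzero(series.replicate_id == r) for r in np.unique(series.replicate_id)]
    else:
        blocks = [np.array([i]) for i in range(c.size)]
    if len(blocks) < 4:
        raise InsufficientDataError("need at least 4 resampling units")

    ec50s, imaxs = [], []
    for _ in range(n_boot):
        pick = rng.integers(0, len(blocks), size=len(blocks))
        idx = np.concatenate([blocks[j] for j in pick])
        sub = DoseSeries(c[idx], y[idx], compound=series.compound)
        try:
            f = fit_inhibition(sub, fix_hill=fix_hill)
        except (InsufficientDataError, DegenerateFitError):
            continue
        ec50s.append(f.ec50)
        imaxs.append(f.imax)
    if len(ec50s) < n_boot // 2:
        raise InsufficientDataError("too many degenerate bootstrap resamples")

    ci_ec50 = tuple(np.percentile(ec50s, [2.5, 97.5]))
    ci_imax = tuple(np.percentile(imaxs, [2.5, 97.5]))
    return (float(ci_ec50[0]), float(ci_ec50[1])), (float(ci_imax[0]), float(ci_imax[1]))


def compare_compounds(fits: list[DoseResponseFit]) -> pd.DataFrame:
    """Rank compounds by potency (ascending EC50, compound label as tie-break)."""
    if len(fits) < 2:
        raise InsufficientDataError("need at least 2 fits to compare")
    rows = [
        {
            "compound": f.compound,
            "ec50_uM": f.ec50,
            "imax_pct": f.imax,
            "hill": f.hill,
            "ci_ec50_lo": f.ci_ec50[0] if f.ci_ec50 else np.nan,
            "ci_ec50_hi": f.ci_ec50[1] if f.ci_ec50 else np.nan,
            "ci_imax_lo": f.ci_imax[0] if f.ci_imax else np.nan,
            "ci_imax_hi": f.ci_imax[1] if f.ci_imax else np.nan,
            "reliable": f.reliable,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["ec50_uM", "compound"], kind="stable").reset_index(drop=True)
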