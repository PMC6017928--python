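"""Enzyme kinetics: initial velocities, Michaelis-Menten fits, Hammett analysis.

Initial velocities come from linear fits to the early portion of an
absorbance-vs-time trace (NADH oxidation followed at 370 nm,
eps = 2660 M^-1 cm^-1), corrected for the uncoupled-oxidation baseline and
converted to molar rates by Beer-Lambert.

Saturation data are fit to the Michaelis-Menten equation

    v = kcat * [E]0 * [S] / (KM + [S])

by nonlinear least squares, initialized from a Hanes-Woolf linearization.

Substituent effects across a para-substituted substrate series are
quantified by the Hammett relation

    log10(Y_i / Y_0) = rho * sigma_i

where Y is kcat or kcat/KM, sigma the para substituent constant and rho the
reaction constant.  The normalized form has no intercept, so the default fit
is through the origin; a free-intercept mode on un-normalized log10(Y) is
also provided.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EPS370_NADH",
    "SIGMA_PARA",
    "AbsorbanceTrace",
    "RateMeasurement",
    "MMFit",
    "HammettPoint",
    "HammettFit",
    "HammettMode",
    "initial_velocity",
    "fit_michaelis_menten",
    "hammett_regression",
]

#: NADH molar extinction coefficient at 370 nm (M^-1 cm^-1).
EPS370_NADH = 2660.0

#: Literature para Hammett substituent constants (Hansch/Leo/Taft
#: compilation).  Reference values only; analyses accept arbitrary
#: user-supplied sigmas.
SIGMA_PARA: dict[str, float] = {
    "H": 0.00,
    "CH3": -0.17,
    "C2H5": -0.15,
    "OCH3": -0.27,
    "OH": -0.37,
    "NH2": -0.66,
    "F": 0.06,
    "Cl": 0.23,
    "Br": 0.23,
    "I": 0.18,
    "CF3": 0.54,
    "CN": 0.66,
    "NO2": 0.78,
    "COOH": 0.45,
    "COOCH3": 0.45,
    "COCH3": 0.50,
    "CHO": 0.42,
    "SO2NH2": 0.60,
    "SO2CH3": 0.72,
}


@dataclass
class AbsorbanceTrace:
    """An absorbance-vs-time trace at a stated wavelength.

    times in s (strictly increasing), absorbances in AU, pathlength in cm.
    """

    times: np.ndarray
    absorbances: np.ndarray
    pathlength: float = 1.0
    wavelength: float = 370.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.times.shape != self.absorbances.shape:
            raise ValueError("times and absorbances must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")


@dataclass(frozen=True)
class RateMeasurement:
    """One initial-rate point: substrate concentration [S] (M), velocity v
    (M/s), enzyme concentration [E]0 (M)."""

    substrate_conc: float
    velocity: float
    enzyme_conc: float

    def __post_init__(self) -> None:
        if self.substrate_conc < 0 or self.velocity < 0:
            raise ValueError("substrate_conc and velocity must be >= 0")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")


@dataclass
class MMFit:
    """Michaelis-Menten parameters with asymptotic standard errors."""

    kcat: float
    KM: float
    kcat_over_KM: float
    se_kcat: float
    se_KM: float
    se_kcat_over_KM: float
    r_squared: float
    n_points: int


class HammettMode(str, enum.Enum):
    NORMALIZED_THROUGH_ORIGIN = "normalized_through_origin"
    FREE_INTERCEPT = "free_intercept"


@dataclass(frozen=True)
class HammettPoint:
    """One substrate in a Hammett series: sigma_para and a positive rate
    quantity Y (kcat or kcat/KM).  The parent (unsubstituted) compound has
    sigma = 0 and is_parent = True."""

    compound_id: str
    sigma: float
    Y: float
    is_parent: bool = False


@dataclass
class HammettFit:
    """Reaction constant rho with fit diagnostics."""

    rho: float
    intercept: float
    r_squared: float
    se_rho: float
    mode: HammettMode
    n_points: int


# ---------------------------------------------------------------------------
# initial velocity from a trace
# ---------------------------------------------------------------------------

def initial_velocity(
    trace: AbsorbanceTrace,
    epsilon: float,
    baseline_slope: float = 0.0,
    window_fraction: float = 0.10,
    min_points: int = 4,
    curvature_tol: float = 0.05,
) -> float:
    """Initial rate (M/s) from the early linear portion of a trace.

    The fitted window is the first ``window_fraction`` of the points (at
    least ``min_points``); if the quadratic term of a 2nd-order fit
    contributes more than ``curvature_tol`` of the linear change across the
    window, the window is shrunk until the early region is linear.  The net
    chemical rate is

        v = (|slope| - |baseline_slope|) / (epsilon * pathlength)

    floored at zero; the baseline slope accounts for uncoupled NAD(P)H
    oxidation measured before substrate addition.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = trace.times.size
    if n < min_points:
        raise ValueError(f"trace has {n} points; at least {min_points} required")
    w = max(min_points, int(round(window_fraction * n)))
    w = min(w, n)
    while w > min_points:
        t = trace.times[:w]
        a = trace.absorbances[:w]
        c2, c1, _ = np.polyfit(t, a, 2)
        span = t[-1] - t[0]
        lin_change = abs(c1) * span
        quad_change = abs(c2) * span ** 2
        if lin_change == 0 or quad_change <= curvature_tol * lin_change:
            break
        w -= 1
    slope = np.polyfit(trace.times[:w], trace.absorbances[:w], 1)[0]
    v = (abs(slope) - abs(baseline_slope)) / (epsilon * trace.pathlength)
    return max(v, 0.0)


# ---------------------------------------------------------------------------
# Michaelis-Menten fitting
# ---------------------------------------------------------------------------

def _mm_curve(S, kcat, KM):
    return kcat * S / (KM + S)


def fit_michaelis_menten(
    data: Sequence[RateMeasurement],
    weight_inverse_v: bool = False,
) -> MMFit:
    """Nonlinear least-squares fit of v/[E]0 vs [S] to the Michaelis-Menten
    hyperbola.

    Initialization comes from a Hanes-Woolf linearization (S/v vs S);
    positivity of kcat and KM is enforced by bounds.  Standard errors are
    asymptotic (from the covariance of the fit); the error of kcat/KM
    propagates slope/intercept covariance.  Set ``weight_inverse_v`` for
    1/v-weighted residuals (relative-error weighting).
    """
    if len(data) < 2:
        raise ValueError("at least 2 rate measurements required")
    S = np.asarray([d.substrate_conc for d in data], dtype=float)
    v_norm = np.asarray([d.velocity / d.enzyme_conc for d in data], dtype=float)
    if np.ptp(S) == 0:
        raise ValueError("all substrate concentrations identical")

    # Hanes-Woolf: S/v = S/Vmax + KM/Vmax (only usable where v > 0)
    ok = v_norm > 0
    if ok.sum() >= 2 and np.ptp(S[ok]) > 0:
        b, a = np.polyfit(S[ok], S[ok] / v_norm[ok], 1)
        kcat0 = 1.0 / b if b > 0 else max(v_norm.max(), 1e-12)
        KM0 = a * kcat0 if a * kcat0 > 0 else np.median(S[S > 0]) or 1.0
    else:
        kcat0, KM0 = max(v_norm.max(), 1e-12), float(np.median(S[S > 0]) if (S > 0).any() else 1.0)

    sigma = 1.0 / np.clip(v_norm, 1e-30, None) if weight_inverse_v else None
    try:
        popt, pcov = curve_fit(
            _mm_curve, S, v_norm, p0=[kcat0, KM0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            sigma=sigma, maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    kcat, KM = popt
    if kcat <= 0 or KM <= 0:
        raise RuntimeError(
            f"Michaelis-Menten fit degenerate (kcat={kcat:g}, KM={KM:g}); "
            "check that the concentration range brackets KM"
        )
    fitted = _mm_curve(S, *popt)
    ss_res = float(np.sum((v_norm - fitted) ** 2))
    ss_tot = float(np.sum((v_norm - v_norm.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    se_kcat, se_KM = np.sqrt(np.clip(np.diag(pcov), 0, None))
    eff = kcat / KM
    # first-order propagation including covariance
    var_eff = (
        (se_kcat / KM) ** 2
        + (kcat * se_KM / KM**2) ** 2
        - 2 * kcat / KM**3 * pcov[0, 1]
    )
    se_eff = math.sqrt(max(var_eff, 0.0))
    return MMFit(
        kcat=float(kcat), KM=float(KM), kcat_over_KM=float(eff),
        se_kcat=float(se_kcat), se_KM=float(se_KM), se_kcat_over_KM=se_eff,
        r_squared=float(r2), n_points=len(data),
    )


# ---------------------------------------------------------------------------
# Hammett analysis
# ---------------------------------------------------------------------------

def hammett_regression(
    points: Sequence[HammettPoint],
    mode: HammettMode | str = HammettMode.NORMALIZED_THROUGH_ORIGIN,
) -> HammettFit:
    """Regress the Hammett log-rate quantity on sigma.

    In normalized mode each Y is divided by the parent's Y0 before taking
    log10, and the line is constrained through the origin (the relation has
    no intercept); rho is the through-origin slope and R² is the uncentered
    coefficient of determination.  In free-intercept mode log10(Y) is
    regressed on sigma with an intercept.
    """
    mode = HammettMode(mode)
    if len(points) < 2:
        raise ValueError("at least 2 points required")
    for p in points:
        if p.Y <= 0:
            raise ValueError(f"nonpositive rate quantity for {p.compound_id!r}")
    sig = np.asarray([p.sigma for p in points], dtype=float)
    Y = np.asarray([p.Y for p in points], dtype=float)

    if mode is HammettMode.NORMALIZED_THROUGH_ORIGIN:
        parents = [p for p in points if p.is_parent or p.sigma == 0.0]
        if not parents:
            raise ValueError("normalized mode requires a parent point (sigma = 0)")
        Y0 = parents[0].Y
        y = np.log10(Y / Y0)
        sxx = float(np.sum(sig**2))
        if sxx == 0:
            raise ValueError("all sigmas are zero; rho is unidentifiable")
        rho = float(np.sum(sig * y) / sxx)
        resid = y - rho * sig
        dof = max(len(points) - 1, 1)
        se_rho = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
        ss_tot = float(np.sum(y**2))  # uncentered: the model has no intercept
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        intercept = 0.0
    else:
        if np.ptp(sig) == 0:
            raise ValueError("all sigmas identical; slope is unidentifiable")
        y = np.log10(Y)
        rho_, intercept_ = np.polyfit(sig, y, 1)
        rho, intercept = float(rho_), float(intercept_)
        resid = y - (rho * sig + intercept)
        dof = max(len(points) - 2, 1)
        sxx = float(np.sum((sig - sig.mean()) ** 2))
        se_rho = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return HammettFit(
        rho=rho, intercept=intercept, r_squared=min(max(r2, 0.0), 1.0),
        se_rho=float(se_rho), mode=mode, n_points=len(points),
    )
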