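"""Dye-referenced equilibrium redox titration (Nernst log-log analysis).

A flavoenzyme is reduced slowly (xanthine / xanthine oxidase with a
mediator) in the presence of a reference dye of known midpoint potential, so
enzyme and dye stay at a common solution potential throughout.  At each
recorded point two absorbances are read:

* A521 reports the oxidized dye concentration (phenosafranine,
  eps521 = 44.7 mM^-1 cm^-1; the reduced dye is colorless at 521 nm);
* A454 reports the oxidized enzyme flavin, after subtracting the small
  oxidized-dye contribution at 454 nm (eps454 = 9.85 mM^-1 cm^-1).

Because both couples sit at the same potential, the Nernst equations
combine into the line

    log10(E_red/E_ox) = (n_e/n_d) * log10(D_red/D_ox)
                        + n_e * (E0_e - E0_d) / 0.0592

so a log-log plot is linear with slope n_e/n_d (= 1 for two two-electron
couples) and the enzyme midpoint potential follows from the intercept:

    E0_e = E0_d + intercept * 0.0592 / n_e.

Concentrations are in uM, extinction coefficients in mM^-1 cm^-1,
pathlengths in cm, potentials in V vs NHE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NERNST_SLOPE_V",
    "DyeSpec",
    "TitrationSeries",
    "TitrationResult",
    "dye_fractions",
    "enzyme_fractions",
    "nernst_fit",
]

#: Nernst slope constant 2.303*RT/F at 25 C, in volts.
NERNST_SLOPE_V = 0.0592


@dataclass
class DyeSpec:
    """Reference dye. Defaults describe phenosafranine: a two-electron
    indicator with E0 = -0.252 V vs NHE, eps521 = 44.7 and
    eps454 = 9.85 mM^-1 cm^-1, used at 18 uM."""

    name: str = "phenosafranine"
    E0_d: float = -0.252
    n_d: int = 2
    eps_521: float = 44.7
    eps_454: float = 9.85
    total_conc: float = 18.0

    def __post_init__(self) -> None:
        if self.eps_521 <= 0 or self.eps_454 <= 0:
            raise ValueError("extinction coefficients must be positive")
        if self.n_d < 1:
            raise ValueError("n_d must be >= 1")
        if self.total_conc <= 0:
            raise ValueError("total_conc must be positive")


@dataclass
class TitrationSeries:
    """Absorbance pairs recorded over the course of a reductive titration.

    ``A454_fully_ox`` / ``A454_fully_red`` are the enzyme-only (dye-corrected)
    454 nm endpoint absorbances, used to normalize the enzyme oxidized
    fraction.
    """

    A454: np.ndarray
    A521: np.ndarray
    enzyme_total: float
    A454_fully_ox: float
    A454_fully_red: float
    pathlength: float = 1.0

    def __post_init__(self) -> None:
        self.A454 = np.asarray(self.A454, dtype=float)
        self.A521 = np.asarray(self.A521, dtype=float)
        if self.A454.shape != self.A521.shape:
            raise ValueError("A454 and A521 must have equal length")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")


@dataclass
class TitrationResult:
    """Log-log Nernst fit and the derived enzyme midpoint potential."""

    slope: float
    intercept: float
    E0_e: float
    n_e: int
    r_squared: float
    n_used: int
    n_excluded: int


def dye_fractions(
    A521: float | np.ndarray, spec: DyeSpec, pathlength: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Oxidized and reduced dye concentrations (uM) from A521.

    D_ox = A521 / (eps521 * path) with eps in mM^-1 cm^-1, clipped to
    [0, total]; D_red is the remainder.
    """
    A521 = np.asarray(A521, dtype=float)
    d_ox = A521 / (spec.eps_521 * pathlength) * 1000.0  # mM -> uM
    d_ox = np.clip(d_ox, 0.0, spec.total_conc)
    return d_ox, spec.total_conc - d_ox


def enzyme_fractions(
    A454: float | np.ndarray,
    D_ox: float | np.ndarray,
    A454_fully_ox: float,
    A454_fully_red: float,
    spec: DyeSpec,
    pathlength: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Enzyme oxidized/reduced fractions from A454.

    The oxidized-dye contribution eps454 * D_ox * path is removed, then the
    enzyme absorbance is normalized between the fully-oxidized and
    fully-reduced endpoints and clipped to [0, 1].
    """
    if A454_fully_ox == A454_fully_red:
        raise ValueError("endpoint absorbances must differ")
    A454 = np.asarray(A454, dtype=float)
    D_ox = np.asarray(D_ox, dtype=float)
    a_enz = A454 - spec.eps_454 * (D_ox / 1000.0) * pathlength
    e_ox = (a_enz - A454_fully_red) / (A454_fully_ox - A454_fully_red)
    e_ox = np.clip(e_ox, 0.0, 1.0)
    return e_ox, 1.0 - e_ox


def nernst_fit(
    series: TitrationSeries,
    spec: DyeSpec | None = None,
    n_e: int = 2,
    interior: tuple[float, float] = (0.02, 0.98),
) -> TitrationResult:
    """Fit log10(E_red/E_ox) vs log10(D_red/D_ox) and derive E0_e.

    Points where either couple is nearly fully oxidized or reduced (fraction
    outside ``interior`` after clipping) are excluded before the OLS fit to
    avoid logarithmic blow-up; at least 3 usable points are required.
    """
    spec = spec or DyeSpec()
    d_ox, d_red = dye_fractions(series.A521, spec, series.pathlength)
    e_ox, e_red = enzyme_fractions(
        series.A454, d_ox, series.A454_fully_ox, series.A454_fully_red,
        spec, series.pathlength,
    )
    f_d = d_ox / spec.total_conc
    lo, hi = interior
    usable = (f_d > lo) & (f_d < hi) & (e_ox > lo) & (e_ox < hi)
    n_used = int(usable.sum())
    if n_used < 3:
        raise ValueError(
            f"only {n_used} interior titration points (need >= 3); "
            "the series may not bracket both midpoints"
        )
    x = np.log10(d_red[usable] / d_ox[usable])
    y = np.log10(e_red[usable] / e_ox[usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    E0_e = spec.E0_d + intercept * NERNST_SLOPE_V / n_e
    return TitrationResult(
        slope=float(slope), intercept=float(intercept), E0_e=float(E0_e),
        n_e=n_e, r_squared=float(r2), n_used=n_used,
        n_excluded=int(len(series.A454) - n_used),
    )
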