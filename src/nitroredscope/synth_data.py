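"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its consuming analysis
assumes — linearly related computed/experimental potential pairs, saturable
initial-rate data, Hammett-structured rate series, two-couple Nernst
titration traces, and toy multi-chain atom sets — so the whole pipeline is
testable without any external dataset.  All generators are pure functions of
(config, parameters): a fixed seed gives bit-identical output, and each
generator draws from its own independent RNG stream.

Noise models follow the character of the real measurements: additive
Gaussian noise for potentials and absorbances, multiplicative lognormal
noise for rates (which are strictly positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import HammettPoint, RateMeasurement
from .structure import AtomRecord, StructureModel, radius_for_element
from .titration import NERNST_SLOPE_V, DyeSpec, TitrationSeries

__all__ = [
    "SimConfig",
    "gen_calibration_pairs",
    "gen_mm_rates",
    "gen_hammett_series",
    "gen_titration_series",
    "gen_toy_dimer",
]


@dataclass(frozen=True)
class SimConfig:
    """Seed, sample size and stage-appropriate noise scale.

    ``noise`` is in volts for potential pairs, a relative fraction for rate
    data, and absorbance units for titration traces.
    """

    seed: int = 0
    n: int = 12
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_calibration_pairs(
    cfg: SimConfig,
    slope: float = 4.67,
    offset: float = 0.379,
    exp_range: tuple[float, float] = (-0.6, -0.2),
) -> list[tuple[float, float]]:
    """(E_exp, E_comp) pairs with E_comp = slope*(E_exp + offset) + Gaussian noise.

    Defaults reproduce the empirical calibration line of the gas-phase
    potential computation; ``cfg.noise`` is the Gaussian sigma in volts on
    the computed values.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if cfg.n < 2:
        raise ValueError("need n >= 2 pairs for a calibration")
    rng = cfg.rng()
    e_exp = rng.uniform(exp_range[0], exp_range[1], size=cfg.n)
    e_comp = slope * (e_exp + offset) + rng.normal(0.0, cfg.noise, size=cfg.n)
    return list(zip(e_exp.tolist(), e_comp.tolist()))


def gen_mm_rates(
    cfg: SimConfig,
    kcat: float = 10.0,
    KM: float = 1.0e-4,
    E0: float = 1.0e-7,
    S_grid: Sequence[float] | None = None,
) -> list[RateMeasurement]:
    """Michaelis-Menten rate data with multiplicative lognormal noise.

    The default substrate grid spans 13 uM to 0.5 mM (the NADH saturation
    range of the reference assay) with ``cfg.n`` log-spaced points; the
    default KM of 100 uM sits inside it.  ``cfg.noise`` is the lognormal
    sigma (relative noise; 0.05 means ~5%).
    """
    if S_grid is None:
        S = np.geomspace(1.3e-5, 5.0e-4, cfg.n)
    else:
        S = np.asarray(list(S_grid), dtype=float)
    if S.size == 0 or not np.any(S > 0):
        raise ValueError("substrate grid must contain positive concentrations")
    rng = cfg.rng()
    v = kcat * E0 * S / (KM + S)
    if cfg.noise > 0:
        v = v * rng.lognormal(mean=0.0, sigma=cfg.noise, size=S.size)
    return [RateMeasurement(float(s), float(vi), E0) for s, vi in zip(S, v)]


def gen_hammett_series(
    cfg: SimConfig,
    rho: float = 3.1,
    sigma_list: Sequence[float] = (-0.27, -0.17, 0.06, 0.23, 0.45, 0.66, 0.78),
    Y0: float = 1.0e4,
) -> list[HammettPoint]:
    """Hammett-structured rate series Y_i = Y0 * 10^(rho*sigma_i) with
    lognormal noise; the parent (sigma = 0) is always included.

    The default sigma grid covers common para substituents from methoxy to
    nitro; the default rho of 3.1 reflects a strongly electron-demand-
    sensitive nitro reduction.
    """
    sig = [float(s) for s in sigma_list]
    if not sig:
        raise ValueError("sigma_list must not be empty")
    if 0.0 not in sig:
        sig = [0.0] + sig
    rng = cfg.rng()
    pts = []
    for i, s in enumerate(sig):
        y = Y0 * 10.0 ** (rho * s)
        if cfg.noise > 0:
            y *= rng.lognormal(mean=0.0, sigma=cfg.noise)
        pts.append(HammettPoint(f"cmpd_{i}", s, float(y), is_parent=(s == 0.0)))
    return pts


def gen_titration_series(
    cfg: SimConfig,
    E0_e: float = -0.190,
    E0_d: float = -0.252,
    n_e: int = 2,
    n_d: int = 2,
    dye: DyeSpec | None = None,
    enzyme_total: float = 18.0,
    A454_fully_ox: float = 0.50,
    A454_fully_red: float = 0.05,
    potential_range: tuple[float, float] | None = None,
    pathlength: float = 1.0,
) -> TitrationSeries:
    """Equilibrium two-couple titration trace from the forward Nernst model.

    A solution-potential grid of ``cfg.n`` points sweeps a window bracketing
    both midpoints (default: 0.15 V beyond each); at each potential the
    oxidized fraction of each couple follows its Nernst equation, and the
    fractions are converted to A521 (oxidized dye) and A454 (oxidized-dye
    contribution plus enzyme absorbance interpolated between its endpoints).
    ``cfg.noise`` is the Gaussian sigma in AU added to both wavelengths.
    """
    dye = dye or DyeSpec()
    if potential_range is None:
        potential_range = (min(E0_e, E0_d) - 0.15, max(E0_e, E0_d) + 0.15)
    lo, hi = potential_range
    if hi <= lo:
        raise ValueError("potential_range must have positive width")
    rng = cfg.rng()
    E_sol = np.linspace(hi, lo, cfg.n)  # progressive reduction
    # frac oxidized = r/(1+r), r = [ox]/[red] = 10^(n (E_sol - E0)/0.0592)
    r_d = 10.0 ** (n_d * (E_sol - E0_d) / NERNST_SLOPE_V)
    r_e = 10.0 ** (n_e * (E_sol - E0_e) / NERNST_SLOPE_V)
    f_d_ox = r_d / (1.0 + r_d)
    f_e_ox = r_e / (1.0 + r_e)
    d_ox = f_d_ox * dye.total_conc  # uM
    A521 = dye.eps_521 * (d_ox / 1000.0) * pathlength
    A454 = (
        dye.eps_454 * (d_ox / 1000.0) * pathlength
        + A454_fully_red + f_e_ox * (A454_fully_ox - A454_fully_red)
    )
    if cfg.noise > 0:
        A521 = A521 + rng.normal(0.0, cfg.noise, size=cfg.n)
        A454 = A454 + rng.normal(0.0, cfg.noise, size=cfg.n)
    return TitrationSeries(
        A454=A454, A521=A521, enzyme_total=enzyme_total,
        A454_fully_ox=A454_fully_ox, A454_fully_red=A454_fully_red,
        pathlength=pathlength,
    )


def gen_toy_dimer(
    cfg: SimConfig,
    n_atoms_per_chain: int = 30,
    separation: float = 8.0,
    cluster_scale: float = 3.0,
    element: str = "C",
) -> StructureModel:
    """Toy two-chain atom set for surface-area tests.

    Chain A is a Gaussian cluster of ``n_atoms_per_chain`` atoms
    (sd ``cluster_scale`` A); chain B is its mirror image, with the two
    centroids ``separation`` A apart along x.  Coordinates are rounded to
    3 decimals (PDB precision) so serialized output is byte-stable.
    """
    if n_atoms_per_chain < 1:
        raise ValueError("n_atoms_per_chain must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = cfg.rng()
    pts = rng.normal(0.0, cluster_scale, size=(n_atoms_per_chain, 3))
    pts = np.round(pts, 3)
    radius = radius_for_element(element)
    atoms = []
    for i, p in enumerate(pts):
        atoms.append(AtomRecord(element, "A", "UNK", i + 1, element,
                                float(p[0] - separation / 2), float(p[1]), float(p[2]),
                                radius))
    for i, p in enumerate(pts):
        atoms.append(AtomRecord(element, "B", "UNK", i + 1, element,
                                float(-p[0] + separation / 2), float(p[1]), float(p[2]),
                                radius))
    return StructureModel(atoms)
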