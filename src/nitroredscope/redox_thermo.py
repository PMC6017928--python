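"""Calibrated one-electron reduction potentials of nitroaromatics.

The semi-empirical route implemented here turns gas-phase quantum-chemical
free energies of a nitroaromatic (ArNO2) and its radical anion (ArNO2^-.)
into an aqueous-scale reduction potential in three steps:

1. An isodesmic electron-exchange reaction against a reference couple
   (nitrobenzene by default),

       ArNO2 + BzNO2^-.  ->  ArNO2^-. + BzNO2,

   whose free-energy change cancels most of the systematic error of a
   modest level of theory.
2. Conversion of that free-energy change to a potential difference via the
   Nernst relation E = -dG/nF (n = 1 for the radical-anion couple), anchored
   to the experimental aqueous potential of the reference
   (E°'(nitrobenzene) = -0.486 V vs NHE at pH 7).
3. An empirical linear calibration against experimentally measured
   potentials, fitted in the parameterization

       E_comp = slope * (E_exp + offset),

   whose inverse E_cal = E_comp/slope - offset maps raw computed values onto
   the experimental scale.  The slope absorbs the missing aqueous dielectric
   stabilization of the anion; the offset absorbs basis-set incompleteness.

Free energies are consumed in hartree.  Working in eV per electron makes the
Faraday constant cancel, so the only physical constant needed is
1 hartree = 27.2114 eV.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HARTREE_TO_EV",
    "RedoxState",
    "FreeEnergyRecord",
    "ReferenceCouple",
    "ComputedPotential",
    "CalibrationModel",
    "CompoundRecord",
    "reaction_free_energy",
    "potential_from_dG",
    "fit_calibration",
    "apply_calibration",
    "predict_potentials",
    "assemble_compound_table",
    "read_free_energy_table",
    "read_experimental_table",
]

#: 1 hartree expressed in electron-volts (CODATA, 6 significant figures).
HARTREE_TO_EV = 27.2114


class RedoxState(str, enum.Enum):
    """Redox state of a species in the electron-exchange cycle."""

    OXIDIZED = "oxidized"
    REDUCED_ANION = "reduced_anion"


# accepted spellings in input tables
_STATE_ALIASES = {
    "ox": RedoxState.OXIDIZED,
    "oxidized": RedoxState.OXIDIZED,
    "red": RedoxState.REDUCED_ANION,
    "reduced": RedoxState.REDUCED_ANION,
    "reduced_anion": RedoxState.REDUCED_ANION,
}


@dataclass(frozen=True)
class FreeEnergyRecord:
    """Free energy of one species (compound in a given redox state).

    Parameters
    ----------
    compound_id:
        Identifier of the nitroaromatic compound.
    state:
        Either the neutral oxidized molecule or the one-electron radical
        anion.
    G:
        Gibbs free energy in hartree (electronic + thermal).
    conformer:
        Optional conformer label.  When several conformers of the same
        (compound, state) are supplied, only the lowest-G record is used —
        the retention rule of a minimum-energy conformer search.
    """

    compound_id: str
    state: RedoxState
    G: float
    conformer: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.G):
            raise ValueError(f"non-finite free energy for {self.compound_id!r}")
        object.__setattr__(self, "state", RedoxState(self.state))


@dataclass(frozen=True)
class ReferenceCouple:
    """Reference redox couple anchoring the computed potential scale.

    Defaults to the nitrobenzene / nitrobenzene radical-anion couple with
    E°' = -0.486 V vs NHE at pH 7.
    """

    compound_id: str = "nitrobenzene"
    E0_ref: float = -0.486
    n_electrons: int = 1

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")


@dataclass
class ComputedPotential:
    """A compound's raw computed potential and, once calibrated, E°_c."""

    compound_id: str
    E_comp: float
    E_cal: float | None = None


@dataclass
class CalibrationModel:
    """Linear calibration E_comp = slope * (E_exp + offset).

    ``mad_after`` is the mean absolute deviation of the back-calibrated
    values (E_comp/slope - offset) from experiment, i.e. the residual error
    on the experimental scale after calibration.
    """

    slope: float
    offset: float
    r_squared: float | None = None
    mad_after: float | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope": self.slope,
                    "offset": self.offset,
                    "r_squared": self.r_squared,
                    "mad_after": self.mad_after,
                    "n_points": self.n_points,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(**{k: d.get(k) for k in ("slope", "offset", "r_squared", "mad_after", "n_points")})


@dataclass
class CompoundRecord:
    """Per-compound physical properties for the substrate-property table.

    ``pi_system_size`` counts atoms bearing conjugated p-orbitals: aromatic
    ring atoms plus directly conjugated substituent atoms (nitro N and O,
    carbonyl C and O, nitrile C and N).  Nitrobenzene under this convention
    has 6 (ring) + 3 (NO2) = 9 such atoms; the field is user-supplied, so
    any consistent convention may be used instead.  ``amine_observed``
    records whether the fully reduced amine product was detected
    ("yes"/"no"/"unknown").
    """

    compound_id: str
    name: str = ""
    chemspider_id: str | None = None
    sigma_para: float | None = None
    pi_system_size: int | None = None
    volume: float | None = None
    logP: float | None = None
    E0_c: float | None = None
    amine_observed: str = "unknown"

    def __post_init__(self) -> None:
        if self.amine_observed not in ("yes", "no", "unknown"):
            raise ValueError("amine_observed must be 'yes', 'no' or 'unknown'")
        if self.volume is not None and self.volume <= 0:
            raise ValueError("volume must be positive when set")


# ---------------------------------------------------------------------------
# thermodynamic cycle
# ---------------------------------------------------------------------------

def _lookup_G(records: Iterable[FreeEnergyRecord], compound_id: str, state: RedoxState) -> float:
    """Lowest free energy among records matching (compound, state)."""
    hits = [r.G for r in records if r.compound_id == compound_id and r.state == state]
    if not hits:
        raise KeyError(f"missing free-energy record for ({compound_id!r}, {state.value!r})")
    return min(hits)


def reaction_free_energy(
    records: Iterable[FreeEnergyRecord],
    compound_id: str,
    reference: ReferenceCouple = ReferenceCouple(),
) -> float:
    """Free-energy change (hartree) of the electron exchange with the reference.

    dG = G(compound, anion) + G(reference, neutral)
       - G(compound, neutral) - G(reference, anion)

    Raises ``KeyError`` naming the first absent (compound, state) pair.
    """
    records = list(records)
    return (
        _lookup_G(records, compound_id, RedoxState.REDUCED_ANION)
        + _lookup_G(records, reference.compound_id, RedoxState.OXIDIZED)
        - _lookup_G(records, compound_id, RedoxState.OXIDIZED)
        - _lookup_G(records, reference.compound_id, RedoxState.REDUCED_ANION)
    )


def potential_from_dG(dG: float, reference: ReferenceCouple = ReferenceCouple()) -> float:
    """Convert an exchange free energy (hartree) to a raw computed potential (V).

    For a one-electron couple, -dG in eV equals the potential difference from
    the reference in volts, so E_comp = -dG * 27.2114 / n + E0_ref.
    """
    if not math.isfinite(dG):
        raise ValueError("dG must be finite")
    return -dG * HARTREE_TO_EV / reference.n_electrons + reference.E0_ref


# ---------------------------------------------------------------------------
# empirical calibration
# ---------------------------------------------------------------------------

def fit_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Fit E_comp = slope * (E_exp + offset) by OLS of E_comp on E_exp.

    Parameters
    ----------
    pairs:
        Sequence of (E_exp, E_comp) in volts.

    Returns
    -------
    CalibrationModel with slope, offset (= intercept/slope), the R² of the
    regression, and mad_after — the mean |E_comp/slope - offset - E_exp|.
    """
    if len(pairs) < 2:
        raise ValueError("at least 2 calibration pairs required")
    exp = np.asarray([p[0] for p in pairs], dtype=float)
    comp = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(exp) == 0:
        raise ValueError("experimental potentials are degenerate (zero variance)")
    slope, intercept = np.polyfit(exp, comp, 1)
    if slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    fitted = slope * exp + intercept
    ss_res = float(np.sum((comp - fitted) ** 2))
    ss_tot = float(np.sum((comp - comp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    offset = intercept / slope
    calc = comp / slope - offset
    mad = float(np.mean(np.abs(calc - exp)))
    return CalibrationModel(
        slope=float(slope), offset=float(offset), r_squared=float(r2),
        mad_after=mad, n_points=len(pairs),
    )


def apply_calibration(E_comp: float | np.ndarray, model: CalibrationModel):
    """Map a raw computed potential onto the experimental scale:
    E_cal = E_comp / slope - offset."""
    return E_comp / model.slope - model.offset


def predict_potentials(
    records: Iterable[FreeEnergyRecord],
    compound_ids: Sequence[str] | None = None,
    reference: ReferenceCouple = ReferenceCouple(),
    model: CalibrationModel | None = None,
) -> list[ComputedPotential]:
    """Run the full cycle for each compound: dG -> E_comp (-> E_cal).

    ``compound_ids`` defaults to every non-reference compound present in
    both redox states.
    """
    records = list(records)
    if compound_ids is None:
        by_compound: dict[str, set[RedoxState]] = {}
        for r in records:
            by_compound.setdefault(r.compound_id, set()).add(r.state)
        compound_ids = sorted(
            c for c, states in by_compound.items()
            if len(states) == 2 and c != reference.compound_id
        )
    out = []
    for cid in compound_ids:
        dG = reaction_free_energy(records, cid, reference)
        e_comp = potential_from_dG(dG, reference)
        e_cal = apply_calibration(e_comp, model) if model is not None else None
        out.append(ComputedPotential(cid, e_comp, e_cal))
    return out


# ---------------------------------------------------------------------------
# compound-property table
# ---------------------------------------------------------------------------

def assemble_compound_table(compounds: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Tidy per-compound table (E0_c, pi_system_size, volume, logP, amine_observed).

    Suitable for the calibrated-potential vs pi-system-size scatter that
    separates amine-producing substrates.  Missing optional fields are
    emitted as nulls; duplicate compound ids raise ``ValueError``.
    """
    columns = [
        "compound_id", "name", "chemspider_id", "sigma_para",
        "pi_system_size", "volume", "logP", "E0_c", "amine_observed",
    ]
    seen: set[str] = set()
    rows = []
    for c in compounds:
        if c.compound_id in seen:
            raise ValueError(f"duplicate compound_id {c.compound_id!r}")
        seen.add(c.compound_id)
        rows.append({k: getattr(c, k) for k in columns})
    df = pd.DataFrame(rows, columns=columns)
    return df.set_index("compound_id")


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------

def read_free_energy_table(path: str | Path) -> list[FreeEnergyRecord]:
    """Read a CSV/TSV with columns compound_id, state in {ox, red}, G_hartree
    (optional: conformer)."""
    df = pd.read_csv(path, sep=None, engine="python")
    recs = []
    for _, row in df.iterrows():
        state = _STATE_ALIASES.get(str(row["state"]).strip().lower())
        if state is None:
            raise ValueError(f"unrecognized redox state {row['state']!r}")
        recs.append(
            FreeEnergyRecord(
                compound_id=str(row["compound_id"]),
                state=state,
                G=float(row["G_hartree"]),
                conformer=str(row["conformer"]) if "conformer" in df.columns and pd.notna(row.get("conformer")) else None,
            )
        )
    return recs


def read_experimental_table(path: str | Path) -> list[tuple[str, float]]:
    """Read a CSV/TSV with columns compound_id, E_exp_V."""
    df = pd.read_csv(path, sep=None, engine="python")
    return [(str(r["compound_id"]), float(r["E_exp_V"])) for _, r in df.iterrows()]
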