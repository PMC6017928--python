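"""Reduction-product formulas and m/z for LC-MS identification.

Nitroaromatic groups are reduced enzymatically in sequential two-electron
steps:

    Ar-NO2  ->  Ar-NO (nitroso)  ->  Ar-NHOH (hydroxylamine)  ->  Ar-NH2 (amine)

Each stage has a fixed compositional delta from the parent nitro compound —
nitroso loses one oxygen (-16 Da nominal), the hydroxylamine loses one
oxygen and gains two hydrogens (-14 Da), the amine loses both oxygens and
gains two hydrogens (-30 Da) — so expected masses and protonated (M+1) /
deprotonated (M-1) ion m/z follow from arithmetic on the molecular formula.

Detection bookkeeping mirrors the sensitivity of the LC-MS screen: an amine
yield above 1% is reliably detected, and failure to detect implies a yield
below 0.5%; yields between the two bounds are indeterminate.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "NOMINAL_MASS",
    "MONOISOTOPIC_MASS",
    "ReductionStage",
    "MolecularFormula",
    "ReductionProduct",
    "DetectionPolicy",
    "DetectionCall",
    "parse_formula",
    "format_formula",
    "reduce_nitro",
    "detection_call",
]

#: Integer nominal masses (most abundant isotope, unit resolution).
NOMINAL_MASS: dict[str, int] = {
    "C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "F": 19,
    "P": 31, "Cl": 35, "Br": 79, "I": 127, "B": 11, "Si": 28,
}

#: Monoisotopic masses (most abundant isotope), Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221,
    "S": 31.97207069, "F": 18.99840320, "P": 30.97376151,
    "Cl": 34.96885271, "Br": 78.9183376, "I": 126.904468,
    "B": 11.0093055, "Si": 27.9769265327,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ReductionStage(str, enum.Enum):
    NITROSO = "nitroso"
    HYDROXYLAMINE = "hydroxylamine"
    AMINE = "amine"


#: Compositional change from the parent nitro compound at each stage.
_STAGE_DELTA: dict[ReductionStage, dict[str, int]] = {
    ReductionStage.NITROSO: {"O": -1},
    ReductionStage.HYDROXYLAMINE: {"O": -1, "H": 2},
    ReductionStage.AMINE: {"O": -2, "H": 2},
}


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count mapping with mass arithmetic."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in NOMINAL_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}")
            if n:
                clean[el] = int(n)
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    @property
    def nominal_mass(self) -> int:
        return sum(NOMINAL_MASS[el] * n for el, n in self.counts.items())

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts.items())

    def shifted(self, delta: Mapping[str, int]) -> "MolecularFormula":
        """New formula with element counts shifted by ``delta``."""
        out = dict(self.counts)
        for el, d in delta.items():
            out[el] = out.get(el, 0) + d
            if out[el] < 0:
                raise ValueError(f"shift removes more {el} atoms than present")
        return MolecularFormula(out)

    def __str__(self) -> str:
        return format_formula(self)


@dataclass(frozen=True)
class ReductionProduct:
    """A predicted reduction product with nominal/monoisotopic masses and
    singly charged ion m/z (nominal M+1 protonated, M-1 deprotonated)."""

    stage: ReductionStage
    formula: MolecularFormula
    nominal_mass: int
    monoisotopic_mass: float
    mz_plus1: int
    mz_minus1: int


@dataclass(frozen=True)
class DetectionPolicy:
    """Detection sensitivity of the amine screen: yields above
    ``detect_threshold`` are detected; non-detection bounds the yield below
    ``absence_bound``."""

    detect_threshold: float = 0.01
    absence_bound: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.absence_bound < self.detect_threshold:
            raise ValueError("require 0 < absence_bound < detect_threshold")


class DetectionCall(str, enum.Enum):
    DETECTED = "detected"
    BELOW_BOUND = "below_bound"
    INDETERMINATE = "indeterminate"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation molecular formula string, e.g. 'C6H6N4O4'."""
    text = text.strip()
    if not text:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in NOMINAL_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def format_formula(formula: MolecularFormula) -> str:
    """Hill-order string: C, then H, then remaining elements alphabetically."""
    counts = dict(formula.counts)
    parts = []
    order = [el for el in ("C", "H") if el in counts]
    order += sorted(el for el in counts if el not in ("C", "H"))
    for el in order:
        n = counts[el]
        parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def reduce_nitro(parent: MolecularFormula, stage: ReductionStage | str) -> ReductionProduct:
    """Predict the product of reducing one nitro group of ``parent``.

    Exactly one -NO2 group is transformed per call; polynitro compounds
    therefore need repeated application (regiochemistry is outside mass
    arithmetic).  Requires the parent composition to contain a nitro group
    (N >= 1 and O >= 2).
    """
    stage = ReductionStage(stage)
    if parent["N"] < 1 or parent["O"] < 2:
        raise ValueError(
            f"formula {parent} lacks a nitro group (need N >= 1 and O >= 2)"
        )
    product = parent.shifted(_STAGE_DELTA[stage])
    nominal = product.nominal_mass
    return ReductionProduct(
        stage=stage,
        formula=product,
        nominal_mass=nominal,
        monoisotopic_mass=product.monoisotopic_mass,
        mz_plus1=nominal + 1,
        mz_minus1=nominal - 1,
    )


def detection_call(amine_yield: float, policy: DetectionPolicy = DetectionPolicy()) -> DetectionCall:
    """Classify an amine yield fraction against the screen's sensitivity."""
    if not 0 <= amine_yield <= 1:
        raise ValueError("amine_yield must be a fraction in [0, 1]")
    if amine_yield > policy.detect_threshold:
        return DetectionCall.DETECTED
    if amine_yield < policy.absence_bound:
        return DetectionCall.BELOW_BOUND
    return DetectionCall.INDETERMINATE
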