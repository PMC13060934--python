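"""Molecular-formula arithmetic for acyl-amine mass spectrometry.

All mass computation in the pipeline goes through this module: Hill-notation
formula parsing, monoisotopic masses, [M+H]+ m/z (positive-mode electrospray),
amide condensation (amine + fatty acid - H2O), the fatty-acid primary-amide
diagnostic fragment, and ppm mass error.

Masses are monoisotopic (most-abundant isotope per element) on the scale where
carbon-12 is exactly 12. The protonated ion uses the proton mass (1.007276 Da),
not the hydrogen atom mass, matching high-resolution positive-mode practice.
"""

from __future__ import annotations

import re
from collections.abc import Mapping

__all__ = [
    "MolecularFormula",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "condense_amide",
    "fatty_amide_formula",
    "ppm_error",
]

#: Monoisotopic atomic masses in Da (CODATA/IUPAC, most abundant isotope).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of the proton in Da; the [M+H]+ adduct mass.
PROTON_MASS: float = 1.00727646688

_WATER = {"H": 2, "O": 1}
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class MolecularFormula(Mapping):
    """An element -> count map with canonical Hill-order rendering.

    Immutable and hashable; two formulas compare equal iff their count maps
    are equal. Absent elements are omitted (all stored counts are >= 1).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for element, count in counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element symbol: {element!r}")
            count = int(count)
            if count < 0:
                raise ValueError(f"negative count for {element}: {count}")
            if count > 0:
                clean[element] = count
        if not clean:
            raise ValueError("empty formula")
        self._counts = clean

    # Mapping interface -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, element: str, default: int = 0) -> int:
        return self._counts.get(element, default)

    # Identity ----------------------------------------------------------
    def __eq__(self, other) -> bool:
        if isinstance(other, MolecularFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def hill(self) -> str:
        """Canonical Hill-order string: C first, H second, rest alphabetical.

        When no carbon is present all elements are alphabetical (standard
        Hill convention). Count 1 is rendered implicitly.
        """
        counts = self._counts
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(e for e in counts if e not in ("C", "H"))
        else:
            order = sorted(counts)
        return "".join(
            e if counts[e] == 1 else f"{e}{counts[e]}" for e in order
        )

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"MolecularFormula({self.hill()!r})"

    # Arithmetic ---------------------------------------------------------
    def __add__(self, other: Mapping[str, int]) -> "MolecularFormula":
        merged = dict(self._counts)
        for element, count in other.items():
            merged[element] = merged.get(element, 0) + count
        return MolecularFormula(merged)

    def __sub__(self, other: Mapping[str, int]) -> "MolecularFormula":
        merged = dict(self._counts)
        for element, count in other.items():
            new = merged.get(element, 0) - count
            if new < 0:
                raise ValueError(
                    f"subtraction makes {element} negative "
                    f"({merged.get(element, 0)} - {count})"
                )
            merged[element] = new
        return MolecularFormula(merged)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C22H44N4O3"``.

    Implicit count 1 is allowed (``"CO2"`` -> C1 O2). Raises ``ValueError``
    on empty input, unknown element symbols, or explicit zero counts.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = match.groups()
        if not element:
            break
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise ValueError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
        if pos == len(text):
            break
    if pos != len(text) or not counts:
        raise ValueError(f"cannot parse formula {text!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula | Mapping[str, int]) -> float:
    """Monoisotopic (exact) mass of a formula in Da."""
    try:
        return sum(
            count * MONOISOTOPIC_MASS[element]
            for element, count in formula.items()
        )
    except KeyError as exc:  # pragma: no cover - guarded by MolecularFormula
        raise ValueError(f"no monoisotopic mass for element {exc}") from exc


def protonated_mz(formula: MolecularFormula | Mapping[str, int]) -> float:
    """m/z of the [M+H]+ ion: neutral monoisotopic mass plus the proton mass."""
    return monoisotopic_mass(formula) + PROTON_MASS


def condense_amide(
    amine: MolecularFormula, fatty_acid: MolecularFormula
) -> MolecularFormula:
    """Formula of the N-acyl amide from an amine and a fatty acid.

    Amide bond formation condenses the carboxyl with the amine nitrogen,
    releasing one water: the product is the element-wise sum minus H2O.
    One conjugate per (amine, fatty acid) pair; polyfunctional amines are
    assumed to form only the N-acyl product.
    """
    if amine.get("N") < 1 or amine.get("H") < 2:
        raise ValueError(
            f"amine {amine} lacks an aminable N-H (needs >=1 N, >=2 H)"
        )
    if fatty_acid.get("O") < 2 or fatty_acid.get("H") < 1:
        raise ValueError(
            f"fatty acid {fatty_acid} lacks a carboxyl (needs >=2 O, >=1 H)"
        )
    return (amine + fatty_acid) - _WATER


def fatty_amide_formula(fatty_acid: MolecularFormula) -> MolecularFormula:
    """Primary-amide fragment formula of a fatty acid (FA + NH3 - H2O).

    This is the fatty-acid-side diagnostic fragment of an N-acyl amide
    (e.g. palmitic acid C16H32O2 -> palmitamide C16H33NO).
    """
    if fatty_acid.get("O") < 2 or fatty_acid.get("H") < 1:
        raise ValueError(
            f"fatty acid {fatty_acid} lacks a carboxyl (needs >=2 O, >=1 H)"
        )
    return (fatty_acid + {"N": 1, "H": 1}) - {"O": 1}


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6
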