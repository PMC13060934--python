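"""Combinatorial acyl-amine (N-acyl amide) library construction.

Every amine x fatty-acid pair contributes one conjugate carrying its neutral
monoisotopic mass, its [M+H]+ precursor m/z, and the two diagnostic MS/MS
fragments used downstream: the protonated free amine (amine moiety) and the
protonated fatty-acid primary amide. Name-distinct compounds with identical
formulas are retained as separate conjugates; only formulas are deduplicated
(by canonical Hill string) when counting unique masses.

The TSV written by :func:`write_library` is the single interchange format
between the library stage and MS annotation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chem import (
    MolecularFormula,
    condense_amide,
    fatty_amide_formula,
    monoisotopic_mass,
    parse_formula,
    protonated_mz,
)

__all__ = [
    "CompoundRecord",
    "Fragment",
    "Conjugate",
    "read_compounds",
    "write_compounds",
    "build_library",
    "unique_formula_count",
    "write_library",
    "read_library",
]

COMPOUND_CLASSES = ("amine", "fatty_acid")


@dataclass(frozen=True)
class CompoundRecord:
    """A named input compound: an amine or a fatty acid."""

    name: str
    formula: MolecularFormula
    compound_class: str

    def __post_init__(self):
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"compound_class must be one of {COMPOUND_CLASSES}, "
                f"got {self.compound_class!r}"
            )


@dataclass(frozen=True)
class Fragment:
    """A diagnostic MS/MS fragment: kind, formula, protonated m/z."""

    kind: str  # "amine_moiety" | "fatty_amide"
    formula: MolecularFormula
    mz: float


@dataclass(frozen=True)
class Conjugate:
    """One amine x fatty-acid amide with masses and diagnostic fragments."""

    amine_name: str
    fa_name: str
    formula: MolecularFormula
    neutral_mass: float
    precursor_mz: float
    fragments: tuple[Fragment, Fragment]

    @property
    def amine_fragment(self) -> Fragment:
        return self.fragments[0]

    @property
    def fatty_amide_fragment(self) -> Fragment:
        return self.fragments[1]


def read_compounds(path: str | Path) -> list[CompoundRecord]:
    """Read a compound list TSV with columns name, formula, class."""
    path = Path(path)
    records: list[CompoundRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {
            "name",
            "formula",
            "class",
        } <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected header with columns name, formula, class"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    CompoundRecord(
                        name=row["name"],
                        formula=parse_formula(row["formula"]),
                        compound_class=row["class"],
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: bad compound row: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no compound rows")
    return records


def write_compounds(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "formula", "class"])
        for rec in records:
            writer.writerow([rec.name, rec.formula.hill(), rec.compound_class])


def _check_classes(records: Sequence[CompoundRecord], expected: str) -> None:
    for rec in records:
        if rec.compound_class != expected:
            raise ValueError(
                f"{rec.name}: expected class {expected!r}, got {rec.compound_class!r}"
            )


def build_library(
    amines: Sequence[CompoundRecord], fatty_acids: Sequence[CompoundRecord]
) -> list[Conjugate]:
    """Enumerate all |amines| x |fatty_acids| conjugates, amine-major order.

    Each conjugate gets the condensation formula, neutral mass, [M+H]+
    precursor m/z, and both diagnostic fragments. A condensation failure
    aborts naming the offending pair.
    """
    if not amines or not fatty_acids:
        raise ValueError("amine and fatty-acid lists must be nonempty")
    _check_classes(amines, "amine")
    _check_classes(fatty_acids, "fatty_acid")

    # Per-fatty-acid amide fragments are shared across all amines.
    fa_fragments: list[Fragment] = []
    for fa in fatty_acids:
        try:
            amide = fatty_amide_formula(fa.formula)
        except ValueError as exc:
            raise ValueError(f"fatty acid {fa.name!r}: {exc}") from exc
        fa_fragments.append(Fragment("fatty_amide", amide, protonated_mz(amide)))

    library: list[Conjugate] = []
    for amine in amines:
        amine_frag = Fragment(
            "amine_moiety", amine.formula, protonated_mz(amine.formula)
        )
        for fa, fa_frag in zip(fatty_acids, fa_fragments):
            try:
                product = condense_amide(amine.formula, fa.formula)
            except ValueError as exc:
                raise ValueError(
                    f"condensation failed for ({amine.name!r}, {fa.name!r}): {exc}"
                ) from exc
            mass = monoisotopic_mass(product)
            library.append(
                Conjugate(
                    amine_name=amine.name,
                    fa_name=fa.name,
                    formula=product,
                    neutral_mass=mass,
                    precursor_mz=protonated_mz(product),
                    fragments=(amine_frag, fa_frag),
                )
            )
    return library


def unique_formula_count(library: Iterable[Conjugate]) -> int:
    """Number of distinct conjugate formulas (canonical Hill strings)."""
    return len({conj.formula.hill() for conj in library})


_LIBRARY_COLUMNS = [
    "amine_name",
    "fa_name",
    "formula",
    "neutral_mass",
    "precursor_mz",
    "amine_fragment_formula",
    "amine_fragment_mz",
    "fatty_amide_formula",
    "fatty_amide_mz",
]


def write_library(library: Iterable[Conjugate], path: str | Path) -> None:
    """Write the library TSV (masses at 6 decimals)."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_LIBRARY_COLUMNS)
        for c in library:
            af, ff = c.fragments
            writer.writerow(
                [
                    c.amine_name,
                    c.fa_name,
                    c.formula.hill(),
                    f"{c.neutral_mass:.6f}",
                    f"{c.precursor_mz:.6f}",
                    af.formula.hill(),
                    f"{af.mz:.6f}",
                    ff.formula.hill(),
                    f"{ff.mz:.6f}",
                ]
            )


def read_library(path: str | Path) -> list[Conjugate]:
    """Read a library TSV written by :func:`write_library`."""
    path = Path(path)
    library: list[Conjugate] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or set(_LIBRARY_COLUMNS) - set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: not a library TSV (bad header)")
        for lineno, row in enumerate(reader, start=2):
            try:
                fragments = (
                    Fragment(
                        "amine_moiety",
                        parse_formula(row["amine_fragment_formula"]),
                        float(row["amine_fragment_mz"]),
                    ),
                    Fragment(
                        "fatty_amide",
                        parse_formula(row["fatty_amide_formula"]),
                        float(row["fatty_amide_mz"]),
                    ),
                )
                library.append(
                    Conjugate(
                        amine_name=row["amine_name"],
                        fa_name=row["fa_name"],
                        formula=parse_formula(row["formula"]),
                        neutral_mass=float(row["neutral_mass"]),
                        precursor_mz=float(row["precursor_mz"]),
                        fragments=fragments,
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: bad library row: {exc}") from exc
    if not library:
        raise ValueError(f"{path}: empty library file")
    return library
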