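"""MS1/MS2 annotation of untargeted LC-MS features against the conjugate library.

MS1 features are matched to conjugate [M+H]+ m/z within a ppm tolerance
(default 5 ppm); hits are then confirmed by screening linked MS/MS spectra
for the two diagnostic fragments within a wider tolerance (default 10 ppm).
A feature may match several conjugates (near-isobars are resolved by MS2
evidence, not discarded); tolerances are applied against the theoretical m/z
with an inclusive boundary.

Confidence tiers: ``ms1_only`` (no fragment seen), ``partial`` (exactly one
of the two diagnostic fragments), ``confirmed`` (both).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import ppm_error
from .library import Conjugate

__all__ = [
    "MS1Feature",
    "MS2Spectrum",
    "AnnotationHit",
    "read_features",
    "write_features",
    "read_ms2_mgf",
    "write_ms2_mgf",
    "match_ms1",
    "screen_ms2",
    "annotate",
    "hits_to_frame",
]


@dataclass(frozen=True)
class MS1Feature:
    """One aligned untargeted LC-MS feature."""

    feature_id: str
    mz: float
    rt: float  # minutes
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: mz must be positive")
        if self.intensity < 0:
            raise ValueError(f"{self.feature_id}: negative intensity")


@dataclass(frozen=True)
class MS2Spectrum:
    """An MS/MS spectrum linked to its precursor feature by feature_id."""

    feature_id: str
    collision_energy: float | None
    peaks: tuple[tuple[float, float], ...]  # (mz, intensity), sorted by mz

    def __post_init__(self):
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p[0]))
            )
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError(f"{self.feature_id}: negative peak intensity")


@dataclass(frozen=True)
class AnnotationHit:
    """An MS1 feature matched to a conjugate, with MS2 evidence flags."""

    feature_id: str
    conjugate: Conjugate
    ppm_error: float
    amine_fragment_found: bool = False
    fatty_amide_fragment_found: bool = False

    @property
    def confidence(self) -> str:
        both = self.amine_fragment_found and self.fatty_amide_fragment_found
        if both:
            return "confirmed"
        if self.amine_fragment_found or self.fatty_amide_fragment_found:
            return "partial"
        return "ms1_only"


# ---------------------------------------------------------------------------
# Readers / writers


def read_features(path: str | Path) -> list[MS1Feature]:
    """Read a feature table TSV: feature_id, mz, rt, intensity."""
    path = Path(path)
    features: list[MS1Feature] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"feature_id", "mz", "rt", "intensity"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                feat = MS1Feature(
                    feature_id=row["feature_id"],
                    mz=float(row["mz"]),
                    rt=float(row["rt"]),
                    intensity=float(row["intensity"]),
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: bad feature row: {exc}") from exc
            if feat.feature_id in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate feature_id {feat.feature_id!r}"
                )
            seen.add(feat.feature_id)
            features.append(feat)
    return features


def write_features(features: Iterable[MS1Feature], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["feature_id", "mz", "rt", "intensity"])
        for f in features:
            writer.writerow(
                [f.feature_id, f"{f.mz:.6f}", f"{f.rt:.4f}", f"{f.intensity:.3f}"]
            )


def read_ms2_mgf(path: str | Path) -> dict[str, MS2Spectrum]:
    """Read MS/MS spectra from MGF; TITLE carries the feature_id.

    Returns a mapping feature_id -> spectrum. When several spectra share a
    feature_id (e.g. multiple collision energies) their peak lists are merged,
    mirroring the practice of pooling HCD energies before fragment screening.
    """
    spectra: dict[str, MS2Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            title = str(entry["params"].get("title", "")).strip()
            if not title:
                raise ValueError(f"{path}: MGF spectrum without TITLE")
            energy = entry["params"].get("collision_energy")
            peaks = tuple(
                zip(
                    (float(x) for x in entry["m/z array"]),
                    (float(y) for y in entry["intensity array"]),
                )
            )
            if title in spectra:
                merged = tuple(
                    sorted(spectra[title].peaks + peaks, key=lambda p: p[0])
                )
                spectra[title] = MS2Spectrum(title, None, merged)
            else:
                spectra[title] = MS2Spectrum(
                    title, float(energy) if energy is not None else None, peaks
                )
    return spectra


def write_ms2_mgf(spectra: Iterable[MS2Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.feature_id}
        if s.collision_energy is not None:
            params["collision_energy"] = s.collision_energy
        entries.append(
            {
                "params": params,
                "m/z array": np.array([p[0] for p in s.peaks]),
                "intensity array": np.array([p[1] for p in s.peaks]),
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Matching


def match_ms1(
    features: Sequence[MS1Feature],
    library: Sequence[Conjugate],
    tol_ppm: float = 5.0,
) -> list[AnnotationHit]:
    """Match features to conjugate precursor m/z within ``tol_ppm`` (inclusive).

    Every (feature, conjugate) pair within tolerance produces a hit; hits are
    sorted per feature by absolute ppm error. Tolerance is relative to the
    theoretical (conjugate) m/z.
    """
    if not library:
        raise ValueError("conjugate library is empty")
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    lib_mz = np.array([c.precursor_mz for c in library])
    order = np.argsort(lib_mz)
    sorted_mz = lib_mz[order]

    hits: list[AnnotationHit] = []
    for feat in features:
        # inclusive ppm window around the observed m/z, conservative bounds
        half = tol_ppm * 1e-6
        lo = np.searchsorted(sorted_mz, feat.mz / (1 + half) - 1e-9, side="left")
        hi = np.searchsorted(sorted_mz, feat.mz / (1 - half) + 1e-9, side="right")
        feat_hits = []
        for idx in order[lo:hi]:
            conj = library[idx]
            err = ppm_error(feat.mz, conj.precursor_mz)
            if abs(err) <= tol_ppm + 1e-9:
                feat_hits.append(AnnotationHit(feat.feature_id, conj, err))
        feat_hits.sort(key=lambda h: abs(h.ppm_error))
        hits.extend(feat_hits)
    return hits


def _peak_within(peaks, target_mz: float, tol_ppm: float) -> bool:
    tol = target_mz * tol_ppm * 1e-6
    return any(abs(mz - target_mz) <= tol + 1e-12 for mz, _ in peaks)


def screen_ms2(
    hit: AnnotationHit, spectrum: MS2Spectrum, tol_ppm: float = 10.0
) -> AnnotationHit:
    """Screen a spectrum for the hit's two diagnostic fragments.

    Each flag becomes true iff some peak lies within ``tol_ppm`` of that
    fragment's theoretical m/z.
    """
    if spectrum.feature_id != hit.feature_id:
        raise ValueError(
            f"spectrum feature_id {spectrum.feature_id!r} does not match "
            f"hit feature_id {hit.feature_id!r}"
        )
    amine_frag, amide_frag = hit.conjugate.fragments
    return replace(
        hit,
        amine_fragment_found=_peak_within(spectrum.peaks, amine_frag.mz, tol_ppm),
        fatty_amide_fragment_found=_peak_within(
            spectrum.peaks, amide_frag.mz, tol_ppm
        ),
    )


def annotate(
    features: Sequence[MS1Feature],
    spectra: Mapping[str, MS2Spectrum] | None,
    library: Sequence[Conjugate],
    ms1_tol_ppm: float = 5.0,
    ms2_tol_ppm: float = 10.0,
) -> list[AnnotationHit]:
    """End-to-end annotation: MS1 matching then MS2 fragment screening.

    Hits without a linked spectrum stay ``ms1_only``. The returned list has
    one row per MS1 hit.
    """
    hits = match_ms1(features, library, tol_ppm=ms1_tol_ppm)
    if not spectra:
        return hits
    return [
        screen_ms2(h, spectra[h.feature_id], tol_ppm=ms2_tol_ppm)
        if h.feature_id in spectra
        else h
        for h in hits
    ]


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    """Annotation hits as a tidy table (one row per hit)."""
    return pd.DataFrame(
        {
            "feature_id": [h.feature_id for h in hits],
            "amine_name": [h.conjugate.amine_name for h in hits],
            "fa_name": [h.conjugate.fa_name for h in hits],
            "formula": [h.conjugate.formula.hill() for h in hits],
            "precursor_mz": [h.conjugate.precursor_mz for h in hits],
            "ppm_error": [h.ppm_error for h in hits],
            "amine_fragment_found": [h.amine_fragment_found for h in hits],
            "fatty_amide_fragment_found": [
                h.fatty_amide_fragment_found for h in hits
            ],
            "confidence": [h.confidence for h in hits],
        }
    )
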