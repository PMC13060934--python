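"""Translated-read quantification of cassette genes in shotgun metagenomes.

Each read is translated in all six frames and locally aligned against a small
protein database of cassette (C/T/A) genes. A read counts as aligned iff its
best local alignment contains a window of at least ``len_min`` aligned
amino-acid columns (default 30) at percent identity >= ``id_min`` (default
90) over those columns. A read counts at most once regardless of how many
database proteins it matches. Per-sample abundance is reported as reads per
million total reads (RPM).

A lossless exact-seed prefilter accelerates the scan: any alignment window of
>= 30 columns at >= 90% identity must contain an exact 7-mer shared between the
translated frame and some database protein (pigeonhole over <= floor(w/10)
mismatch/gap columns), so frames sharing no 7-mer with the database are
skipped without alignment.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .cassette import _DEFAULT_ALIGNER
from . import stats as _stats

__all__ = [
    "ReadHit",
    "QuantResult",
    "GroupComparison",
    "six_frame_translate",
    "CassetteDB",
    "match_read",
    "quantify_sample",
    "quantify_reads",
    "compare_groups",
    "compare_many",
    "read_sample_sheet",
]

_SEED_K = 7

_CODON = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON[_stop] = "*"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ReadHit:
    """Best qualifying translated match of one read to a database protein."""

    read_id: str
    frame: int  # 1..3 forward, 4..6 reverse-complement
    subject_id: str
    window_identity: float  # % identity over the qualifying window
    window_length: int  # aligned aa columns in the qualifying window


@dataclass(frozen=True)
class QuantResult:
    """Per-sample aligned-read count normalized to reads per million."""

    sample_id: str
    aligned_reads: int
    total_reads: int

    @property
    def rpm(self) -> float:
        return self.aligned_reads / self.total_reads * 1e6

    def __post_init__(self):
        if self.total_reads < 1:
            raise ValueError(f"{self.sample_id}: total_reads must be >= 1")
        if not 0 <= self.aligned_reads <= self.total_reads:
            raise ValueError(f"{self.sample_id}: aligned_reads out of range")


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of RPM between two groups."""

    group_labels: tuple[str, str]
    rpm_a: tuple[float, ...]
    rpm_b: tuple[float, ...]
    u_statistic: float
    p_value: float
    q_value: float | None = None


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_frame(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON.get(codon, "X"))
    return "".join(out)


def six_frame_translate(read: str) -> list[str]:
    """Standard-code translation of the 3 forward and 3 reverse frames.

    Frames 1-3 are offsets 0-2 of the read; frames 4-6 are offsets 0-2 of
    its reverse complement. Codons containing N (or any ambiguity) become X;
    stop codons are rendered as ``*``.
    """
    read = read.upper()
    if len(read) < 3:
        raise ValueError("read shorter than one codon")
    rc = revcomp(read)
    return [
        _translate_frame(read),
        _translate_frame(read[1:]),
        _translate_frame(read[2:]),
        _translate_frame(rc),
        _translate_frame(rc[1:]),
        _translate_frame(rc[2:]),
    ]


class CassetteDB:
    """A small protein database with an exact 7-mer seed index."""

    def __init__(self, proteins: Mapping[str, str] | Iterable[tuple[str, str]]):
        if isinstance(proteins, Mapping):
            proteins = proteins.items()
        self.proteins: list[tuple[str, str]] = [
            (pid, seq.upper()) for pid, seq in proteins
        ]
        if not self.proteins:
            raise ValueError("empty protein database")
        self._kmers: set[str] = set()
        for _, seq in self.proteins:
            for i in range(len(seq) - _SEED_K + 1):
                self._kmers.add(seq[i : i + _SEED_K])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CassetteDB":
        records = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(records)

    def has_seed(self, peptide: str) -> bool:
        return any(
            peptide[i : i + _SEED_K] in self._kmers
            for i in range(len(peptide) - _SEED_K + 1)
        )


def _best_window(match_cols: np.ndarray, id_min: float, len_min: int):
    """Best (identity, length) window of >= len_min columns at >= id_min%.

    ``match_cols`` marks match columns of the alignment (gaps/mismatches are
    False). Returns None when no window qualifies.
    """
    n = match_cols.size
    if n < len_min:
        return None
    prefix = np.concatenate([[0], np.cumsum(match_cols)])
    best = None
    for length in range(len_min, n + 1):
        window_sums = prefix[length:] - prefix[:-length]
        top = int(window_sums.max())
        identity = 100.0 * top / length
        if identity >= id_min - 1e-9:
            if best is None or (identity, length) > best:
                best = (identity, length)
    return best


def _match_columns(alignment, query: str, subject: str) -> np.ndarray:
    """Per-column match flags (including gap columns) of a local alignment."""
    q_blocks, s_blocks = alignment.aligned
    cols: list[bool] = []
    for i, ((qs, qe), (ss, se)) in enumerate(zip(q_blocks, s_blocks)):
        if i > 0:
            gap = (qs - q_blocks[i - 1][1]) + (ss - s_blocks[i - 1][1])
            cols.extend([False] * gap)
        cols.extend(
            qc == sc and qc != "X"
            for qc, sc in zip(query[qs:qe], subject[ss:se])
        )
    return np.array(cols, dtype=bool)


def match_read(
    read: str,
    db: CassetteDB,
    id_min: float = 90.0,
    len_min: int = 30,
    read_id: str = "read",
) -> ReadHit | None:
    """Best qualifying hit of one read against the database, or None.

    All six frames are aligned against every database protein; the
    best-scoring qualifying alignment yields the hit. Frames sharing no
    exact 7-mer with the database are skipped (lossless for the default
    90%/30-aa rule).
    """
    frames = six_frame_translate(read)
    best_hit: ReadHit | None = None
    best_score = -np.inf
    for frame_no, peptide in enumerate(frames, start=1):
        if len(peptide) < len_min or not db.has_seed(peptide):
            continue
        for subject_id, subject in db.proteins:
            alignments = _DEFAULT_ALIGNER.align(peptide, subject)
            if len(alignments) == 0 or alignments.score <= 0:
                continue
            aln = alignments[0]
            if aln.score <= best_score:
                continue
            window = _best_window(
                _match_columns(aln, peptide, subject), id_min, len_min
            )
            if window is None:
                continue
            identity, length = window
            best_score = aln.score
            best_hit = ReadHit(read_id, frame_no, subject_id, identity, length)
    return best_hit


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield record.id, str(record.seq)


def quantify_reads(
    reads: Iterable[tuple[str, str]],
    db: CassetteDB,
    sample_id: str = "sample",
    id_min: float = 90.0,
    len_min: int = 30,
) -> QuantResult:
    """Count qualifying reads in a stream of (read_id, sequence) pairs."""
    total = 0
    aligned = 0
    for read_id, seq in reads:
        total += 1
        if len(seq) < 3:
            raise ValueError(
                f"{sample_id}: record {total} ({read_id!r}) shorter than a codon"
            )
        if match_read(seq, db, id_min=id_min, len_min=len_min, read_id=read_id):
            aligned += 1
    if total == 0:
        raise ValueError(f"{sample_id}: no reads")
    return QuantResult(sample_id=sample_id, aligned_reads=aligned, total_reads=total)


def quantify_sample(
    fastq_path: str | Path,
    db: CassetteDB,
    sample_id: str | None = None,
    id_min: float = 90.0,
    len_min: int = 30,
) -> QuantResult:
    """Streaming RPM quantification of one FASTQ file (plain or gzip)."""
    sample_id = sample_id or Path(fastq_path).stem
    return quantify_reads(
        _iter_fastq(fastq_path), db, sample_id=sample_id, id_min=id_min, len_min=len_min
    )


def compare_groups(
    rpm_a: Sequence[float],
    rpm_b: Sequence[float],
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of per-sample RPM vectors."""
    if len(rpm_a) < 2 or len(rpm_b) < 2:
        raise ValueError("need >= 2 observations per group")
    result = _stats.mann_whitney_u(rpm_a, rpm_b)
    return GroupComparison(
        group_labels=tuple(labels),
        rpm_a=tuple(float(v) for v in rpm_a),
        rpm_b=tuple(float(v) for v in rpm_b),
        u_statistic=result.statistic,
        p_value=result.p_value,
    )


def compare_many(
    comparisons: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> dict[str, GroupComparison]:
    """Several group comparisons (e.g. one per database) with BH correction."""
    raw = {name: compare_groups(a, b) for name, (a, b) in comparisons.items()}
    names = list(raw)
    q = _stats.bh_fdr([raw[n].p_value for n in names])
    return {
        name: GroupComparison(
            group_labels=raw[name].group_labels,
            rpm_a=raw[name].rpm_a,
            rpm_b=raw[name].rpm_b,
            u_statistic=raw[name].u_statistic,
            p_value=raw[name].p_value,
            q_value=float(qv),
        )
        for name, qv in zip(names, q)
    }


def read_sample_sheet(path: str | Path) -> list[dict]:
    """Read a sample sheet TSV: sample_id, fastq, group."""
    import csv

    rows = []
    with Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"sample_id", "fastq", "group"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            rows.append(
                {
                    "sample_id": row["sample_id"],
                    "fastq": row["fastq"],
                    "group": row["group"],
                }
            )
    if not rows:
        raise ValueError(f"{path}: empty sample sheet")
    return rows
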