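"""CTA acyl-amine-synthesis operon detection in bacterial genomes.

The cassette is a three-gene unit: an acyl transferase (C), a small acyl
carrier protein (T) and a fatty acyl-CoA ligase (A). Candidate C and A genes
are found by optimal local protein alignment (Smith-Waterman, BLOSUM62,
affine gaps open 11 / extend 1) against role-labelled reference proteins,
thresholded on percent identity (default >= 70%) and reference coverage
(default >= 80%). The carrier protein is too short for reliable homology
search and is instead identified positionally: a hit requires a C and an A
gene on the same contig and strand, within a bounded intergenic distance,
with exactly one small ORF strictly between them (the T).

Identity is matches / aligned columns (gap columns count, X never matches);
coverage is the fraction of the reference (subject) protein spanned by the
local alignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "GeneRecord",
    "AlignmentResult",
    "CassetteHit",
    "align_proteins",
    "find_homologs",
    "detect_cassettes",
    "summarize_species",
    "read_gene_table",
    "read_proteome_fasta",
    "read_reference_fasta",
    "hits_to_frame",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GeneRecord:
    """A called gene: nucleotide coordinates plus its protein product."""

    genome_id: str
    contig_id: str
    gene_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    protein: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.protein:
            raise ValueError(f"{self.gene_id}: empty protein")

    @property
    def aa_length(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class AlignmentResult:
    """Identity/coverage evidence from one local protein alignment."""

    query_id: str
    subject_id: str
    percent_identity: float  # % over aligned columns (gaps count)
    subject_coverage: float  # fraction of subject spanned by the alignment
    alignment_length: int  # aligned columns including gap columns
    score: float


@dataclass(frozen=True)
class CassetteHit:
    """A detected C-T-A operon on one contig."""

    genome_id: str
    contig_id: str
    c_gene: str
    t_gene: str
    a_gene: str
    span: tuple[int, int]
    evidence: Mapping[str, AlignmentResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def _validate_protein(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AA_ALPHABET - {"X"}
    if bad:
        raise ValueError(f"{label}: invalid protein characters {sorted(bad)}")
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    return seq


def _alignment_stats(alignment, query: str, subject: str):
    """(matches, columns, subject_span) for one local alignment.

    Columns include gap columns inside the local alignment; X never counts
    as a match even against itself.
    """
    q_blocks, s_blocks = alignment.aligned
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        columns += qe - qs
        for qc, sc in zip(query[qs:qe], subject[ss:se]):
            if qc == sc and qc != "X":
                matches += 1
    for i in range(1, len(q_blocks)):
        columns += (q_blocks[i][0] - q_blocks[i - 1][1]) + (
            s_blocks[i][0] - s_blocks[i - 1][1]
        )
    if len(s_blocks):
        subject_span = s_blocks[-1][1] - s_blocks[0][0]
    else:
        subject_span = 0
    return matches, columns, subject_span


def align_proteins(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    aligner: PairwiseAligner | None = None,
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    Smith-Waterman under BLOSUM62 with affine gaps (open 11, extend 1) by
    default. Returns identity over aligned columns, coverage of the subject,
    alignment length in columns, and the raw score.
    """
    query = _validate_protein(query, query_id)
    subject = _validate_protein(subject, subject_id)
    aligner = aligner or _DEFAULT_ALIGNER
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(query_id, subject_id, 0.0, 0.0, 0, 0.0)
    best = alignments[0]
    matches, columns, subject_span = _alignment_stats(best, query, subject)
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = subject_span / len(subject)
    return AlignmentResult(
        query_id, subject_id, identity, coverage, columns, float(best.score)
    )


# ---------------------------------------------------------------------------
# Homology search and operon rules


def find_homologs(
    proteome: Sequence[GeneRecord],
    references: Mapping[str, Sequence[tuple[str, str]]],
    id_min: float = 70.0,
    cov_min: float = 0.80,
) -> dict[str, tuple[str, AlignmentResult]]:
    """Assign C/A roles to genes by best reference alignment above cutoffs.

    ``references`` maps role ("C" or "A") to (ref_id, sequence) pairs. A gene
    is a candidate for a role iff its best alignment to any reference of that
    role reaches both ``id_min`` percent identity and ``cov_min`` subject
    coverage. The carrier protein (T) is deliberately absent here: it is
    identified positionally by :func:`detect_cassettes`.

    Returns gene_id -> (role, best AlignmentResult).
    """
    roles = {r: refs for r, refs in references.items() if r in ("C", "A")}
    if not roles or not any(roles.values()):
        raise ValueError("need nonempty C and/or A reference sets")
    assignments: dict[str, tuple[str, AlignmentResult]] = {}
    for gene in proteome:
        best: tuple[str, AlignmentResult] | None = None
        for role, refs in roles.items():
            for ref_id, ref_seq in refs:
                res = align_proteins(
                    gene.protein, ref_seq, query_id=gene.gene_id, subject_id=ref_id
                )
                if res.percent_identity >= id_min and res.subject_coverage >= cov_min:
                    if best is None or res.score > best[1].score:
                        best = (role, res)
        if best is not None:
            assignments[gene.gene_id] = best
    return assignments


def detect_cassettes(
    genes: Sequence[GeneRecord],
    role_assignments: Mapping[str, tuple[str, AlignmentResult]],
    max_gap_bp: int = 500,
    t_max_len: int = 120,
) -> list[CassetteHit]:
    """Find C-T-A operons from role assignments plus structural rules.

    A hit is a (C, A) pair on one contig and strand with exactly one ORF
    strictly between them in coordinate order, that ORF no longer than
    ``t_max_len`` aa (recorded as T), and both intergenic gaps at most
    ``max_gap_bp``. Gene order C..A and A..C are both accepted.
    """
    hits: list[CassetteHit] = []
    by_contig: dict[tuple[str, str], list[GeneRecord]] = {}
    for gene in genes:
        by_contig.setdefault((gene.genome_id, gene.contig_id), []).append(gene)

    for (genome_id, contig_id), contig_genes in sorted(by_contig.items()):
        ordered = sorted(contig_genes, key=lambda g: (g.start, g.end))
        for i, first in enumerate(ordered):
            role_i = role_assignments.get(first.gene_id, (None,))[0]
            if role_i not in ("C", "A"):
                continue
            # candidate triple: genes i, i+1 (T), i+2 (the partner)
            if i + 2 >= len(ordered):
                continue
            middle, last = ordered[i + 1], ordered[i + 2]
            role_k = role_assignments.get(last.gene_id, (None,))[0]
            if {role_i, role_k} != {"C", "A"}:
                continue
            if not (first.strand == middle.strand == last.strand):
                continue
            if middle.gene_id in role_assignments:
                continue  # the middle ORF must not itself be a C/A homolog
            if middle.aa_length > t_max_len:
                continue
            gap1 = middle.start - first.end - 1
            gap2 = last.start - middle.end - 1
            if gap1 > max_gap_bp or gap2 > max_gap_bp or gap1 < 0 or gap2 < 0:
                continue
            c_gene, a_gene = (
                (first, last) if role_i == "C" else (last, first)
            )
            evidence = {
                role_assignments[c_gene.gene_id][0]: role_assignments[c_gene.gene_id][1],
                role_assignments[a_gene.gene_id][0]: role_assignments[a_gene.gene_id][1],
            }
            hits.append(
                CassetteHit(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    c_gene=c_gene.gene_id,
                    t_gene=middle.gene_id,
                    a_gene=a_gene.gene_id,
                    span=(first.start, last.end),
                    evidence=evidence,
                )
            )
    return hits


def summarize_species(
    genome_species: Mapping[str, str], hits: Iterable[CassetteHit]
) -> pd.DataFrame:
    """Per-species counts of isolates with and without a cassette hit.

    ``genome_species`` maps every screened genome to its species label; an
    isolate "has the cassette" iff it carries at least one hit.
    """
    if not genome_species:
        raise ValueError("no genomes supplied")
    with_hit = {h.genome_id for h in hits}
    rows: dict[str, dict[str, int]] = {}
    for genome_id, species in genome_species.items():
        entry = rows.setdefault(species, {"n_with": 0, "n_without": 0})
        entry["n_with" if genome_id in with_hit else "n_without"] += 1
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "species"
    frame["n_isolates"] = frame["n_with"] + frame["n_without"]
    return frame.reset_index()


# ---------------------------------------------------------------------------
# I/O


def read_gene_table(path: str | Path) -> list[dict]:
    """Read a GFF-lite TSV: genome_id, contig_id, gene_id, start, end, strand."""
    path = Path(path)
    rows = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"genome_id", "contig_id", "gene_id", "start", "end", "strand"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    {
                        "genome_id": row["genome_id"],
                        "contig_id": row["contig_id"],
                        "gene_id": row["gene_id"],
                        "start": int(row["start"]),
                        "end": int(row["end"]),
                        "strand": row["strand"],
                    }
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: bad gene row: {exc}") from exc
    return rows


def read_proteome_fasta(
    fasta_path: str | Path, gene_table_path: str | Path
) -> list[GeneRecord]:
    """Join a protein FASTA (headers ``genome|contig|gene``) with coordinates."""
    coords = {
        (r["genome_id"], r["contig_id"], r["gene_id"]): r
        for r in read_gene_table(gene_table_path)
    }
    genes: list[GeneRecord] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"{fasta_path}: header {record.id!r} is not genome|contig|gene"
            )
        key = tuple(parts)
        if key not in coords:
            raise ValueError(f"{fasta_path}: no coordinates for {record.id!r}")
        row = coords[key]
        genes.append(
            GeneRecord(
                genome_id=row["genome_id"],
                contig_id=row["contig_id"],
                gene_id=row["gene_id"],
                start=row["start"],
                end=row["end"],
                strand=row["strand"],
                protein=str(record.seq),
            )
        )
    return genes


def read_reference_fasta(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read role-tagged references: headers ``id role=C|T|A``."""
    references: dict[str, list[tuple[str, str]]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        role = None
        for token in record.description.split():
            if token.startswith("role="):
                role = token.split("=", 1)[1]
        if role not in ("C", "T", "A"):
            raise ValueError(
                f"{path}: reference {record.id!r} lacks a role=C|T|A tag"
            )
        references.setdefault(role, []).append((record.id, str(record.seq)))
    if not references:
        raise ValueError(f"{path}: no reference sequences")
    return references


def hits_to_frame(hits: Sequence[CassetteHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        c_ev = h.evidence.get("C")
        a_ev = h.evidence.get("A")
        rows.append(
            {
                "genome_id": h.genome_id,
                "contig_id": h.contig_id,
                "c_gene": h.c_gene,
                "t_gene": h.t_gene,
                "a_gene": h.a_gene,
                "span_start": h.span[0],
                "span_end": h.span[1],
                "c_identity": c_ev.percent_identity if c_ev else float("nan"),
                "c_coverage": c_ev.subject_coverage if c_ev else float("nan"),
                "a_identity": a_ev.percent_identity if a_ev else float("nan"),
                "a_coverage": a_ev.subject_coverage if a_ev else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "contig_id",
            "c_gene",
            "t_gene",
            "a_gene",
            "span_start",
            "span_end",
            "c_identity",
            "c_coverage",
            "a_identity",
            "a_coverage",
        ],
    )
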