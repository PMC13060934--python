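"""Synthetic inputs for every pipeline stage, with ground truth.

The generators emulate the statistical structure the analysis assumes: LC-MS
feature tables with conjugates spiked at known m/z plus ppm-scale Gaussian
mass error and decoy features kept well away from every library mass; MS/MS
spectra containing or omitting the diagnostic fragments; bacterial genomes
with planted C-T-A cassettes whose proteins are mutated to a controlled
identity; and shotgun read sets drawn from cassette-positive and -negative
genomes at stated abundances.

Every generator is a pure function of (config, seed): each draws from its own
``numpy`` Generator seeded from ``SimConfig.seed`` plus a fixed per-generator
offset, so adding one generator call never perturbs the others, and identical
config + seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import MS1Feature, MS2Spectrum
from .cassette import GeneRecord
from .chem import parse_formula
from .library import CompoundRecord, Conjugate
from .quant import revcomp

__all__ = [
    "SimConfig",
    "AMINE_ANCHORS",
    "FA_ANCHORS",
    "gen_compound_lists",
    "gen_feature_table",
    "gen_ms2_spectra",
    "make_reference_proteins",
    "mutate_protein",
    "gen_genomes",
    "gen_reads",
    "gen_cassette_reads",
    "gen_group_samples",
    "write_fastq",
]

# fixed per-generator RNG stream offsets
_STREAM_COMPOUNDS = 1
_STREAM_FEATURES = 2
_STREAM_MS2 = 3
_STREAM_REFS = 4
_STREAM_GENOMES = 5
_STREAM_READS = 6
_STREAM_GROUPS = 7

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Real compounds always included so mass anchors are exercised end to end.
AMINE_ANCHORS = [
    ("dopamine", "C8H11NO2"),
    ("ethanolamine", "C2H7NO"),
    ("arginine", "C6H14N4O2"),
]
FA_ANCHORS = [
    ("palmitic_acid", "C16H32O2"),
    ("oleic_acid", "C18H34O2"),
    ("linoleic_acid", "C18H32O2"),
    ("alpha_linolenic_acid", "C18H30O2"),
]


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs, defaulting to the screen's standard conditions."""

    seed: int = 0
    # compound lists (combinatorial library scale of the screen)
    n_amines: int = 460
    n_fas: int = 53
    # MS1 feature table
    spike_n: int = 20
    decoy_n: int = 200
    mass_error_ppm: float = 2.0  # SD of spiked-feature mass error
    ms1_tol_ppm: float = 5.0
    decoy_exclusion_factor: float = 3.0  # decoys >= factor x tol from library
    # MS2 spectra
    fragment_error_ppm: float = 2.0
    ms2_tol_ppm: float = 10.0
    omit_fraction: float = 0.0  # fraction of spectra missing the amine fragment
    n_noise_peaks: int = 6
    # genomes
    n_background_genes: int = 8
    background_gene_len: tuple[int, int] = (120, 360)
    intergenic_bp: tuple[int, int] = (60, 200)
    cassette_gap_bp: tuple[int, int] = (40, 120)
    t_length: int = 80
    # reads
    n_reads: int = 20_000
    read_length: int = 120
    error_rate: float = 0.0  # per-base substitution probability
    # group comparison
    group_size: int = 15
    reads_per_sample: int = 2000
    cassette_frac_base: float = 0.005
    effect_size: float = 3.0  # multiplicative shift of group A's fraction
    abundance_noise_sd: float = 0.3  # lognormal sigma on per-sample fraction


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# Compound lists


def gen_compound_lists(
    cfg: SimConfig,
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Chemically valid amine and fatty-acid lists of the configured sizes.

    Amines are CcH(2c+2+n-2u)N(n)O(o) with >= 1 N and >= 2 H; fatty acids are
    CnH(2n-2k)O2 saturated or unsaturated chains. The real anchor compounds
    (dopamine, ethanolamine, arginine; palmitic/oleic/linoleic/linolenic
    acid) are always included first.
    """
    if cfg.n_amines < 1 or cfg.n_fas < 1:
        raise ValueError("n_amines and n_fas must be >= 1")
    rng = _rng(cfg, _STREAM_COMPOUNDS)

    amines = [
        CompoundRecord(name, parse_formula(f), "amine")
        for name, f in AMINE_ANCHORS[: cfg.n_amines]
    ]
    idx = 0
    while len(amines) < cfg.n_amines:
        idx += 1
        c = int(rng.integers(2, 21))
        n = int(rng.integers(1, 4))
        o = int(rng.integers(0, 5))
        unsat = int(rng.integers(0, min(4, c) + 1))
        h = 2 * c + 2 + n - 2 * unsat
        if h < 2:
            continue
        counts = {"C": c, "H": h, "N": n}
        if o:
            counts["O"] = o
        amines.append(
            CompoundRecord(f"amine_{idx:04d}", parse_formula_counts(counts), "amine")
        )

    anchor_fa_params = {(16, 0), (18, 1), (18, 2), (18, 3)}
    fas = [
        CompoundRecord(name, parse_formula(f), "fatty_acid")
        for name, f in FA_ANCHORS[: cfg.n_fas]
    ]
    pool = [
        (n, k)
        for n in range(4, 25)
        for k in range(0, 7)
        if 2 * n - 2 * k >= 2 and (n, k) not in anchor_fa_params
    ]
    rng.shuffle(pool)
    idx = 0
    while len(fas) < cfg.n_fas:
        if pool:
            n, k = pool.pop()
        else:  # more FAs requested than distinct chain/unsaturation combos
            n = int(rng.integers(4, 25))
            k = int(rng.integers(0, min(6, n - 1) + 1))
        idx += 1
        counts = {"C": n, "H": 2 * n - 2 * k, "O": 2}
        fas.append(
            CompoundRecord(
                f"fatty_acid_{idx:04d}", parse_formula_counts(counts), "fatty_acid"
            )
        )
    return amines, fas


def parse_formula_counts(counts: Mapping[str, int]):
    from .chem import MolecularFormula

    return MolecularFormula(counts)


# ---------------------------------------------------------------------------
# Feature tables and MS2 spectra


def gen_feature_table(
    library: Sequence[Conjugate], cfg: SimConfig
) -> tuple[list[MS1Feature], pd.DataFrame]:
    """Feature table with spiked conjugates plus decoys, and its ground truth.

    Spikes sit at conjugate precursor m/z times (1 + eps), eps ~
    Normal(0, mass_error_ppm) in ppm. Decoys are uniform over the library
    m/z range but at least ``decoy_exclusion_factor x ms1_tol_ppm`` away from
    every library precursor, so false annotations are deterministically zero.
    """
    if cfg.spike_n > len(library):
        raise ValueError("spike_n exceeds library size")
    rng = _rng(cfg, _STREAM_FEATURES)
    lib_mz = np.sort(np.array([c.precursor_mz for c in library]))
    exclusion_ppm = cfg.decoy_exclusion_factor * cfg.ms1_tol_ppm

    spike_idx = rng.choice(len(library), size=cfg.spike_n, replace=False)
    rows: list[tuple[float, str, str, bool]] = []
    for i in spike_idx:
        conj = library[int(i)]
        eps = rng.normal(0.0, cfg.mass_error_ppm)
        rows.append(
            (conj.precursor_mz * (1 + eps * 1e-6), conj.amine_name, conj.fa_name, True)
        )

    lo, hi = lib_mz[0] - 10.0, lib_mz[-1] + 10.0
    placed = 0
    attempts = 0
    while placed < cfg.decoy_n:
        attempts += 1
        if attempts > 1000 * max(cfg.decoy_n, 1):
            raise RuntimeError(
                "decoy placement infeasible: library too dense for the "
                f"{exclusion_ppm:.0f} ppm exclusion zone"
            )
        mz = float(rng.uniform(lo, hi))
        j = np.searchsorted(lib_mz, mz)
        near = lib_mz[max(0, j - 1) : j + 1]
        if np.all(np.abs(mz - near) / near * 1e6 >= exclusion_ppm):
            rows.append((mz, "", "", False))
            placed += 1

    order = rng.permutation(len(rows))
    features: list[MS1Feature] = []
    truth_rows = []
    for new_id, old in enumerate(order, start=1):
        mz, amine, fa, is_spike = rows[int(old)]
        fid = f"F{new_id:05d}"
        features.append(
            MS1Feature(
                feature_id=fid,
                mz=mz,
                rt=float(rng.uniform(0.5, 20.0)),
                intensity=float(rng.lognormal(12.0, 1.0)),
            )
        )
        truth_rows.append(
            {"feature_id": fid, "amine_name": amine, "fa_name": fa, "is_spike": is_spike}
        )
    return features, pd.DataFrame(truth_rows)


def gen_ms2_spectra(
    truth: pd.DataFrame, library: Sequence[Conjugate], cfg: SimConfig
) -> dict[str, MS2Spectrum]:
    """MS/MS spectra for the spiked features, with controllable evidence.

    Each spectrum holds both diagnostic fragment peaks with ppm-scale mass
    error, except that a configured fraction omit the amine-moiety fragment
    (exercising the ``partial`` tier), plus uniform noise peaks kept at
    least three MS2 tolerances from both fragments.
    """
    rng = _rng(cfg, _STREAM_MS2)
    by_pair = {(c.amine_name, c.fa_name): c for c in library}
    spectra: dict[str, MS2Spectrum] = {}
    for row in truth.itertuples(index=False):
        if not row.is_spike:
            continue
        conj = by_pair[(row.amine_name, row.fa_name)]
        amine_frag, amide_frag = conj.fragments
        peaks: list[tuple[float, float]] = []
        omit_amine = bool(rng.random() < cfg.omit_fraction)
        targets = ([] if omit_amine else [amine_frag.mz]) + [amide_frag.mz]
        for frag_mz in targets:
            eps = rng.normal(0.0, cfg.fragment_error_ppm)
            peaks.append((frag_mz * (1 + eps * 1e-6), float(rng.uniform(1e4, 1e6))))
        guard = 3 * cfg.ms2_tol_ppm
        n_noise = 0
        while n_noise < cfg.n_noise_peaks:
            mz = float(rng.uniform(50.0, conj.precursor_mz))
            if all(
                abs(mz - f) / f * 1e6 >= guard
                for f in (amine_frag.mz, amide_frag.mz)
            ):
                peaks.append((mz, float(rng.uniform(1e3, 1e5))))
                n_noise += 1
        energy = float(rng.choice([20.0, 30.0, 40.0, 50.0]))
        spectra[row.feature_id] = MS2Spectrum(
            feature_id=row.feature_id,
            collision_energy=energy,
            peaks=tuple(sorted(peaks)),
        )
    return spectra


# ---------------------------------------------------------------------------
# Genomes with planted cassettes


def make_reference_proteins(cfg: SimConfig) -> dict[str, str]:
    """Synthetic C/T/A reference proteins (random sequences, realistic sizes).

    Stand-ins for the real acyl transferase (~240 aa), acyl carrier (~80 aa)
    and fatty acyl-CoA ligase (~330 aa) references, which are not bundled.
    """
    rng = _rng(cfg, _STREAM_REFS)
    lengths = {"C": 240, "T": cfg.t_length, "A": 330}
    return {
        role: "".join(rng.choice(list(AA20), size=n))
        for role, n in lengths.items()
    }


def mutate_protein(
    seq: str, target_identity: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Substitution-only mutation to a target global identity.

    Returns (mutated sequence, realized identity); realized identity is
    exact (1 - substitutions/length) and verified to lie within 2 percentage
    points of the target, which fails only for very short sequences.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    length = len(seq)
    n_sub = round((1 - target_identity) * length)
    realized = 1 - n_sub / length
    if abs(realized - target_identity) > 0.02:
        raise ValueError(
            f"cannot realize identity {target_identity:.2f} within 2 points "
            f"on a {length}-aa sequence"
        )
    positions = rng.choice(length, size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [a for a in AA20 if a != seq[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out), realized


_CODONS_FOR: dict[str, list[str]] = {}


def _codons_for(aa: str) -> list[str]:
    if not _CODONS_FOR:
        from .quant import _CODON

        for codon, res in _CODON.items():
            if "N" not in codon:
                _CODONS_FOR.setdefault(res, []).append(codon)
        for res in _CODONS_FOR:
            _CODONS_FOR[res].sort()
    return _CODONS_FOR[aa]


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _codons_for(aa)[int(rng.integers(len(_codons_for(aa))))] for aa in protein
    ]
    stops = _codons_for("*")
    codons.append(stops[int(rng.integers(len(stops)))])
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def gen_genomes(
    cfg: SimConfig,
    references: Mapping[str, str],
    identity_targets: Sequence[float | None],
) -> tuple[dict[str, dict[str, str]], list[GeneRecord], pd.DataFrame]:
    """Genomes with background genes and (optionally) a planted cassette.

    ``identity_targets[i]`` is the target identity of genome i's planted C
    and A proteins to the references, or None for a cassette-negative
    genome. Returns (contigs, gene records, truth table); the truth table
    records target and realized identities and the planted coordinates.
    """
    rng = _rng(cfg, _STREAM_GENOMES)
    contigs: dict[str, dict[str, str]] = {}
    genes: list[GeneRecord] = []
    truth_rows = []

    for g_idx, target in enumerate(identity_targets):
        genome_id = f"genome_{g_idx:03d}"
        contig_id = "contig_1"
        # plan the gene roster: background proteins plus an optional cassette
        roster: list[tuple[str, str, str | None]] = []  # (gene_id, protein, role)
        for b in range(cfg.n_background_genes):
            length = int(rng.integers(*cfg.background_gene_len))
            roster.append(
                (f"{genome_id}_bg{b:02d}", "".join(rng.choice(list(AA20), size=length)), None)
            )
        realized_c = realized_a = float("nan")
        if target is not None:
            c_prot, realized_c = mutate_protein(references["C"], target, rng)
            a_prot, realized_a = mutate_protein(references["A"], target, rng)
            cassette = [
                (f"{genome_id}_C", c_prot, "C"),
                (f"{genome_id}_T", references["T"], "T"),
                (f"{genome_id}_A", a_prot, "A"),
            ]
            insert_at = int(rng.integers(len(roster) + 1))
            roster = roster[:insert_at] + cassette + roster[insert_at:]

        cassette_strand = rng.choice(["+", "-"])
        parts: list[str] = [_random_dna(int(rng.integers(*cfg.intergenic_bp)), rng)]
        pos = len(parts[0])
        cassette_span: list[int] = []
        for idx, (gene_id, protein, role) in enumerate(roster):
            cds = _reverse_translate(protein, rng)
            strand = cassette_strand if role else rng.choice(["+", "-"])
            start = pos + 1
            end = pos + len(cds)
            parts.append(cds if strand == "+" else revcomp(cds))
            pos = end
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=str(strand),
                    protein=protein,
                )
            )
            if role:
                cassette_span += [start, end]
            next_role = roster[idx + 1][2] if idx + 1 < len(roster) else None
            gap_range = (
                cfg.cassette_gap_bp
                if role and next_role  # between two cassette members
                else cfg.intergenic_bp
            )
            gap = _random_dna(int(rng.integers(*gap_range)), rng)
            parts.append(gap)
            pos += len(gap)
        # trailing flank already appended by the loop
        contigs[genome_id] = {contig_id: "".join(parts)}
        truth_rows.append(
            {
                "genome_id": genome_id,
                "has_cassette": target is not None,
                "target_identity": float("nan") if target is None else target,
                "realized_identity_c": realized_c,
                "realized_identity_a": realized_a,
                "contig_id": contig_id,
                "cassette_start": min(cassette_span) if cassette_span else -1,
                "cassette_end": max(cassette_span) if cassette_span else -1,
                "cassette_strand": str(cassette_strand) if cassette_span else "",
            }
        )
    return contigs, genes, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Reads


def gen_reads(
    contigs: Mapping[str, Mapping[str, str]],
    abundances: Mapping[str, float],
    cfg: SimConfig,
    cassette_regions: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Shotgun reads sampled from genomes at the given relative abundances.

    Uniform fragment start positions, random orientation, per-base
    substitution errors at ``cfg.error_rate``. The truth table records the
    source genome and whether the fragment overlaps a planted cassette gene
    span (from ``cassette_regions``, genome -> (start, end)) by >= 90 nt.
    """
    rng = _rng(cfg, _STREAM_READS)
    genome_ids = sorted(abundances)
    weights = np.array([abundances[g] for g in genome_ids], dtype=float)
    if weights.sum() <= 0 or np.any(weights < 0):
        raise ValueError("abundances must be nonnegative and sum > 0")
    weights = weights / weights.sum()

    reads: list[tuple[str, str]] = []
    truth_rows = []
    picks = rng.choice(len(genome_ids), size=cfg.n_reads, p=weights)
    for r_idx, g_pick in enumerate(picks):
        genome_id = genome_ids[int(g_pick)]
        genome_contigs = contigs[genome_id]
        names = sorted(genome_contigs)
        lens = np.array([len(genome_contigs[c]) for c in names], dtype=float)
        contig_name = names[int(rng.choice(len(names), p=lens / lens.sum()))]
        seq = genome_contigs[contig_name]
        if cfg.read_length > len(seq):
            raise ValueError(
                f"read_length {cfg.read_length} exceeds contig length {len(seq)}"
            )
        start0 = int(rng.integers(0, len(seq) - cfg.read_length + 1))
        frag = seq[start0 : start0 + cfg.read_length]
        frag = _apply_errors(frag, cfg.error_rate, rng)
        if rng.random() < 0.5:
            frag = revcomp(frag)
        read_id = f"read_{r_idx:07d}"
        reads.append((read_id, frag))
        overlap = False
        if cassette_regions and genome_id in cassette_regions:
            c_start, c_end = cassette_regions[genome_id]
            ov = min(start0 + cfg.read_length, c_end) - max(start0 + 1, c_start) + 1
            overlap = ov >= 90
        truth_rows.append(
            {"read_id": read_id, "genome_id": genome_id, "cassette_overlap": overlap}
        )
    return reads, pd.DataFrame(truth_rows)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = int(rng.binomial(len(seq), rate))
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


def gen_cassette_reads(
    contig: str,
    gene: GeneRecord,
    n: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    id_prefix: str = "cta_read",
) -> list[tuple[str, str]]:
    """Error-free reads fully inside a cassette gene's coding region.

    Reads avoid the stop codon, so with the default 120-nt read length every
    read carries >= 39 complete codons of the protein in some frame and is
    guaranteed to pass the 90%/30-aa matching rule.
    """
    lo = gene.start - 1  # 0-based first coding base
    hi = gene.end - 3 - cfg.read_length  # keep clear of the stop codon
    if hi < lo:
        raise ValueError("gene too short for the configured read length")
    reads = []
    for i in range(n):
        start0 = int(rng.integers(lo, hi + 1))
        frag = contig[start0 : start0 + cfg.read_length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append((f"{id_prefix}_{i:06d}", frag))
    return reads


def gen_group_samples(
    cfg: SimConfig, references: Mapping[str, str] | None = None
) -> tuple[list[dict], dict[str, list[tuple[str, str]]], dict[str, str]]:
    """Two-group cohort of read sets with a cassette-abundance shift.

    Group A samples draw their cassette-read fraction ``effect_size`` times
    higher than group B (both with lognormal sample-to-sample noise); reads
    are otherwise background from a cassette-negative genome. Returns
    (sample sheet rows, reads per sample, reference proteins used).
    """
    references = references or make_reference_proteins(cfg)
    contigs, genes, truth = gen_genomes(cfg, references, [1.0, None])
    pos = truth[truth.has_cassette].iloc[0]
    pos_contig = contigs[pos.genome_id][pos.contig_id]
    c_gene = next(g for g in genes if g.gene_id == f"{pos.genome_id}_C")
    neg = truth[~truth.has_cassette].iloc[0]
    neg_contig = contigs[neg.genome_id][neg.contig_id]

    rng = _rng(cfg, _STREAM_GROUPS)
    sheet: list[dict] = []
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    for group, multiplier in (("group_a", cfg.effect_size), ("group_b", 1.0)):
        for i in range(cfg.group_size):
            sample_id = f"{group}_s{i:02d}"
            frac = cfg.cassette_frac_base * multiplier * float(
                rng.lognormal(0.0, cfg.abundance_noise_sd)
            )
            n_cassette = int(rng.binomial(cfg.reads_per_sample, min(frac, 1.0)))
            cassette_reads = gen_cassette_reads(
                pos_contig, c_gene, n_cassette, cfg, rng, id_prefix=f"{sample_id}_cta"
            )
            background = []
            for j in range(cfg.reads_per_sample - n_cassette):
                start0 = int(rng.integers(0, len(neg_contig) - cfg.read_length + 1))
                frag = neg_contig[start0 : start0 + cfg.read_length]
                frag = _apply_errors(frag, cfg.error_rate, rng)
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                background.append((f"{sample_id}_bg_{j:06d}", frag))
            sample_reads = cassette_reads + background
            order = rng.permutation(len(sample_reads))
            reads_by_sample[sample_id] = [sample_reads[int(k)] for k in order]
            sheet.append({"sample_id": sample_id, "group": group})
    return sheet, reads_by_sample, dict(references)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with flat quality."""
    with Path(path).open("w", encoding="utf-8") as handle:
        for read_id, seq in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
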