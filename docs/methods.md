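# Methods

This note documents the models, parameter choices and numerical conventions
behind `acylscreen`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Mass arithmetic and the conjugate library

All masses are monoisotopic, on the scale where ¹²C is exactly 12 Da, using
CODATA/IUPAC atomic masses to ≥ 6 decimals for C, H, N, O, S and P. Predicted
ions are [M+H]⁺ only (positive-mode electrospray); the adduct adds the proton
mass 1.007276 Da, not the hydrogen atom mass — the 0.55 mDa difference
matters at the 4-decimal precision used for fragment anchors (protonated
arginine computes to 175.1190).

Conjugation is amide condensation: the product formula is the element-wise
sum of amine and fatty acid minus H₂O. Each (amine, fatty acid) pair yields
exactly one conjugate; polyfunctional amines (dopamine's catechol hydroxyls,
arginine's guanidinium) are assumed to react only at the primary amine, so a
460 × 53 input enumerates exactly 24,380 conjugates. Name-distinct compounds
with identical formulas are kept as separate conjugates; only formulas are
deduplicated (by canonical Hill string) when counting unique masses. Two
diagnostic fragments are attached per conjugate: the protonated free amine
and the protonated fatty-acid primary amide (FA + NH₃ − H₂O). A fragment m/z
sometimes quoted for palmitamide (283.2631) is inconsistent with the
fragment's formula C16H33NO, whose [M+H]⁺ computes to 256.2635; fragment m/z
here is always derived from the formula.

Formulas are immutable element→count maps; rendering follows the Hill
convention (C, H, then alphabetical; fully alphabetical without carbon), and
parse→render→parse is the identity.

## MS1/MS2 annotation

Mass tolerances are always relative (ppm) with the theoretical m/z in the
denominator and an inclusive boundary: MS1 matching at 5 ppm, MS2 fragment
screening at 10 ppm. A feature may match several near-isobaric conjugates;
all are retained, because ambiguity is resolved by MS2 evidence rather than
by discarding candidates, and no retention-time model is applied (none is
available for unknowns). MS2 spectra are linked to precursors by feature id;
spectra recorded at several collision energies under the same id are pooled
before screening.

No single convention fixes whether one or both diagnostic fragments are
required to call an acyl amine, so the annotation preserves the evidence as
tiers: `confirmed` (both fragments), `partial` (exactly one),
`ms1_only` (neither). Downstream users can collapse tiers as they see fit.

## Cassette (CTA operon) detection

Candidate acyl transferase (C) and acyl-CoA ligase (A) genes are called by
optimal local alignment — Smith–Waterman under BLOSUM62 with affine gap
penalties (open 11, extend 1), the standard protein-search parameterization —
implemented via Biopython's `PairwiseAligner` and cross-checked in the test
suite against an independent Gotoh dynamic-programming oracle. Percent
identity is matches over aligned columns (gap columns count as columns, X
never counts as a match); coverage is the fraction of the *reference*
protein spanned by the local alignment. Default cutoffs: identity ≥ 70 %,
reference coverage ≥ 80 %.

The acyl carrier protein (T) is too short for reliable homology calls and is
identified positionally instead: a cassette hit requires a C and an A on the
same contig and strand with exactly one ORF strictly between them, that ORF
at most 120 aa and itself not a C/A homolog, and both intergenic gaps at
most 500 bp. Both gene orders (C–T–A and A–T–C) are accepted, since
strand-relative order is not constrained. The 500 bp / 120 aa thresholds are
design choices quantifying "putative operon structure" and are exposed as
parameters. An isolate "has the cassette" iff it has at least one hit;
per-species tallies report isolates with and without.

Raising the identity or coverage cutoff can only shrink the hit set
(monotonicity), which the tests assert.

## Translated-read quantification

Reads are translated in all six frames with the standard code (ambiguous
codons → X, stops → `*`). A read counts as cassette-derived iff the
best-scoring local alignment of some frame against some database protein
contains a window of ≥ 30 aligned amino-acid columns at ≥ 90 % identity over
those columns — homology is operationalized as percent identity. Each read
counts at most once, regardless of how many database proteins it matches;
per-sample abundance is aligned reads per million total reads (RPM).

A lossless exact-seed prefilter makes the scan practical at 10⁵–10⁶ read
scale: any qualifying window of length w ≥ 30 has at most ⌊w/10⌋
mismatch/gap columns, so by pigeonhole it contains an exact run of at least
⌈(w−⌊w/10⌋)/(⌊w/10⌋+1)⌉ ≥ 7 consecutive matches; frames sharing no 7-mer
with the database therefore cannot qualify and are skipped without
alignment. The prefilter can only skip reads that would not pass, never
drop a qualifying read.

Group comparisons of RPM use the Mann–Whitney U test; when several databases
are tested (e.g. a *Blautia*-specific versus an all-Clostridia reference
set), Benjamini–Hochberg correction is applied across comparisons.

## Statistics

Implemented from first principles, with scipy/statsmodels as independent
cross-checks in the tests only:

- **Mann–Whitney U**: U = Σ [xᵢ > yⱼ] + ½[xᵢ = yⱼ]. Exact mode enumerates
  all C(n, n₁) group labelings of the pooled midranks (default when
  n₁ + n₂ ≤ 12); otherwise a tie-corrected normal approximation with
  continuity correction 0.5. The two-sided p doubles the smaller tail,
  capped at 1.
- **Benjamini–Hochberg**: step-up q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, clipped at 1,
  original order restored; Bonferroni is available as a stricter
  alternative.
- **Hypergeometric enrichment**: P(X ≥ k) for X ~ Hypergeom(N, K, n),
  computed as a ratio of exact integer binomial sums (no log-gamma error at
  the small counts typical of pathway tables). The N/K/n/k mapping is: N
  metabolites annotated, K in the sub-pathway, n taxon-associated, k
  associated and in the sub-pathway.
- **Spearman**: Pearson correlation of midranks; p by t-approximation for
  n ≥ 10 and exact permutation below; constant vectors are rejected.
- **Trapezoidal AUC** for OGTT glucose curves (minutes × mg/dL), **relative
  growth** as the ratio of mean OD600 with versus without supplementation,
  and an inclusive ≥ 20 % **prevalence pre-filter** for differential
  abundance tables.

## Synthetic data: what it emulates, and what it does not

Each generator is a pure function of (config, seed); each draws from its own
`numpy` Generator seeded as (seed, generator-offset), so adding a call to
one generator never shifts another's stream, and reruns are byte-identical.

- **Compound lists** emulate the screen's 460 amines × 53 fatty acids with
  chemically consistent formulas (amines CcH₂c₊₂₊ₙ₋₂ᵤNₙOₒ; fatty acids
  CnH₂n₋₂kO₂, chain lengths 4–24, up to 6 unsaturations) and always include
  the real anchor compounds so printed-value tests run end to end.
- **Feature tables** spike 20 conjugates (default) with Gaussian ppm mass
  error (σ = 2 ppm) and add 200 decoys kept ≥ 3 × the MS1 tolerance from
  every library mass, making the expected false-annotation count exactly
  zero rather than merely small. Expected recall at 5 ppm is the two-sided
  N(0, 2 ppm) mass within ±5 ppm, 98.76 %; the acceptance test averages
  over 500 seeds so its Monte-Carlo standard error (~0.05 points) is far
  below the margin to the asserted 98 % bound.
- **Genomes** plant C–T–A cassettes whose C and A proteins are mutated to a
  target identity by substitutions only (no indels), so realized identity
  is exactly 1 − substitutions/length and verified within ±2 points. At
  BLOSUM62 the expected per-column score stays positive down to ~60 %
  identity, so local alignments of planted genes extend essentially full
  length and detection flips cleanly at the 70 % cutoff (100/85/75 %
  detected; 65/60 % rejected).
- **Reads** are uniform fragments with a flat per-base substitution error
  rate and random orientation; planted "passing" reads are drawn wholly
  inside a cassette CDS (clear of the stop codon), so a 120-nt read always
  carries ≥ 39 complete codons and must pass the 90 %/30-aa rule when
  error-free. Cohort samples draw the cassette-read fraction lognormally,
  with a configurable multiplicative group effect.

These generators reproduce the *statistical structure* the pipeline assumes,
not the full complexity of real data: no chromatographic RT structure, no
isotope envelopes or co-eluting adducts, no indel sequencing errors or
quality-score variation, no phylogenetic correlation among genomes, and
random (not homologous) background proteins. Passing tests therefore
demonstrate correctness of the matching rules, thresholds and statistics
under controlled conditions — not robustness to every artifact of real
LC-MS or sequencing runs.

## Problem sizes and numerical choices

Default test and acceptance scales: the full 24,380-conjugate library;
100-seed-class replication for stochastic properties where noise allows,
10 seeds for genome screens; quantification exercised at 10⁵ reads (25
planted passing reads → RPM 250 exactly) with the error-rate band checked at
2 × 10⁴ reads against an empirically calibrated per-read pass probability.
Boundary conventions throughout are inclusive (≤ tolerance, ≥ cutoff);
floating-point guards of 10⁻⁹–10⁻¹² absorb representation error at exact
boundaries. Known limitations: T-protein identification is purely
positional; paired-end reads are treated as independent; no attempt is made
to reproduce heuristic aligner (BLAST/Diamond) bit-scores — the contracts
are identity/coverage thresholds, which exact local alignment evaluates
deterministically.
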