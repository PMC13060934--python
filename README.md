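# acylscreen

Tools for linking gut-bacterial *N*-acyl amide (acyl amine) production to host
phenotypes. Commensal Clostridia such as *Blautia wexlerae* carry a three-gene
biosynthetic cassette — an acyl transferase (**C**), a small acyl carrier
protein (**T**) and a fatty acyl-CoA ligase (**A**) — that condenses fatty
acids with amines into bioactive conjugates (e.g. oleoyl ethanolamide, oleoyl
dopamine). `acylscreen` implements the computational arms of that discovery
workflow for metabolomics and microbiome researchers:

1. **Combinatorial conjugate library** (`acylscreen.chem`,
   `acylscreen.library`): every amine × fatty-acid amide, with monoisotopic
   mass, [M+H]⁺ precursor *m/z* (*m/z* = M + 1.007276), and the two diagnostic
   MS/MS fragments — the protonated free amine and the fatty-acid primary
   amide (FA + NH₃ − H₂O).
2. **Untargeted LC-MS annotation** (`acylscreen.annotate`): MS1 feature
   matching at 5 ppm (|Δm/z|/m/z·10⁶), MS/MS diagnostic-fragment screening at
   10 ppm, with evidence tiers `ms1_only` / `partial` / `confirmed`.
3. **CTA operon detection** (`acylscreen.cassette`): Smith–Waterman local
   alignment (BLOSUM62, affine gaps 11/1) of proteomes against C/A
   references at ≥ 70 % identity over ≥ 80 % of the reference, plus operon
   structure rules (same contig and strand, bounded intergenic gaps, one
   small ORF — the T — strictly between C and A).
4. **Metagenomic quantification** (`acylscreen.quant`): six-frame translated
   read matching against cassette proteins (≥ 90 % identity over a ≥ 30-aa
   window), reported as reads per million (RPM), with Mann–Whitney group
   comparison.
5. **Supporting statistics** (`acylscreen.stats`): exact Mann–Whitney U,
   Benjamini–Hochberg FDR, hypergeometric pathway enrichment
   P(X ≥ k), X ~ Hypergeom(N, K, n), Spearman rank correlation, trapezoidal
   OGTT AUC, relative growth, and the 20 % prevalence pre-filter.
6. **Synthetic data with ground truth** (`acylscreen.synthetic`): spiked
   feature tables, MS/MS spectra, genomes with identity-controlled planted
   cassettes, and cohort read sets, so every stage is testable end to end
   without any download.

## Worked example

Build a library from generated compound lists (the generator always includes
real anchors — dopamine, arginine, ethanolamine, palmitic/oleic/linoleic/
α-linolenic acid), simulate a feature table with 20 spiked conjugates and 200
decoys, and annotate it:

```bash
acylscreen simulate compounds --seed 3 --out sim
acylscreen library --amines sim/amines.tsv --fatty-acids sim/fatty_acids.tsv --out library.tsv
# -> 24380 conjugates, 5373 unique formulas
acylscreen simulate features --seed 3 --out feat
acylscreen annotate --features feat/features.tsv --ms2 feat/spectra.mgf \
    --library feat/library.tsv --out hits.tsv
# -> 136 annotation hits
```

24,380 conjugates is 460 amines × 53 fatty acids; distinct pairs can share a
formula (isomeric fatty acids), hence fewer unique formulas. The hits table
has one row per (feature, conjugate) match within 5 ppm; spiked features
whose spectra contain both diagnostic fragments are `confirmed`, near-isobar
secondary matches stay `ms1_only`:

```
feature_id  amine_name  fa_name          formula     precursor_mz  ppm_error  ...  confidence
F00006      amine_0433  fatty_acid_0029  C19H30N2O2  319.238005    1.378      ...  ms1_only
```

In Python, the same masses directly:

```python
>>> from acylscreen.chem import parse_formula, condense_amide, protonated_mz
>>> round(protonated_mz(parse_formula("C6H14N4O2")), 4)   # protonated arginine
175.119
>>> product = condense_amide(parse_formula("C8H11NO2"),   # dopamine
...                          parse_formula("C18H34O2"))   # oleic acid
>>> product.hill(), round(protonated_mz(product), 1)      # N-oleoyl dopamine
('C26H43NO3', 418.3)
```

Genome screening and metagenome quantification follow the same pattern
(`acylscreen simulate genomes` / `scan`, `acylscreen simulate cohort` /
`quant`); see `acylscreen --help` and the module docstrings.

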