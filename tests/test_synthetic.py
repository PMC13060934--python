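"""Generator determinism, ground-truth fidelity and reader compatibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from acylscreen import library, synthetic
from acylscreen.annotate import read_features, read_ms2_mgf, write_features, write_ms2_mgf
from acylscreen.chem import condense_amide
from acylscreen.library import build_library, read_compounds, write_compounds
from acylscreen.synthetic import SimConfig


class TestCompoundLists:
    def test_requested_sizes(self):
        cfg = SimConfig(seed=1, n_amines=25, n_fas=9)
        amines, fas = synthetic.gen_compound_lists(cfg)
        assert len(amines) == 25 and len(fas) == 9

    def test_anchor_compounds_present(self):
        cfg = SimConfig(seed=1, n_amines=10, n_fas=8)
        amines, fas = synthetic.gen_compound_lists(cfg)
        names = {r.name for r in amines} | {r.name for r in fas}
        assert {"dopamine", "arginine", "ethanolamine", "oleic_acid", "palmitic_acid"} <= names

    def test_every_pair_condenses(self):
        cfg = SimConfig(seed=2, n_amines=30, n_fas=12)
        amines, fas = synthetic.gen_compound_lists(cfg)
        for am in amines:
            for fa in fas:
                condense_amide(am.formula, fa.formula)  # must not raise

    def test_deterministic_across_runs(self, tmp_path):
        cfg = SimConfig(seed=3, n_amines=20, n_fas=10)
        paths = []
        for run in range(2):
            amines, fas = synthetic.gen_compound_lists(cfg)
            p = tmp_path / f"amines_{run}.tsv"
            write_compounds(amines, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_parses_through_reader(self, tmp_path):
        cfg = SimConfig(seed=4, n_amines=15, n_fas=6)
        amines, _ = synthetic.gen_compound_lists(cfg)
        path = tmp_path / "amines.tsv"
        write_compounds(amines, path)
        assert len(read_compounds(path)) == 15


class TestFeatureTable:
    def test_zero_mass_error_spikes_exact(self, small_library):
        cfg = SimConfig(seed=5, spike_n=6, decoy_n=10, mass_error_ppm=0.0)
        features, truth = synthetic.gen_feature_table(small_library, cfg)
        by_pair = {(c.amine_name, c.fa_name): c for c in small_library}
        by_id = {f.feature_id: f for f in features}
        for row in truth[truth.is_spike].itertuples():
            conj = by_pair[(row.amine_name, row.fa_name)]
            assert by_id[row.feature_id].mz == conj.precursor_mz

    def test_decoys_respect_exclusion_zone(self, small_library, small_cfg):
        features, truth = synthetic.gen_feature_table(small_library, small_cfg)
        lib_mz = np.array([c.precursor_mz for c in small_library])
        decoys = set(truth[~truth.is_spike].feature_id)
        guard = small_cfg.decoy_exclusion_factor * small_cfg.ms1_tol_ppm
        for f in features:
            if f.feature_id in decoys:
                assert np.min(np.abs(f.mz - lib_mz) / lib_mz * 1e6) >= guard

    def test_spike_n_larger_than_library_rejected(self, small_library):
        cfg = SimConfig(seed=6, spike_n=len(small_library) + 1)
        with pytest.raises(ValueError):
            synthetic.gen_feature_table(small_library, cfg)

    def test_roundtrip_through_readers(self, tmp_path, small_library, small_cfg):
        features, truth = synthetic.gen_feature_table(small_library, small_cfg)
        spectra = synthetic.gen_ms2_spectra(truth, small_library, small_cfg)
        write_features(features, tmp_path / "f.tsv")
        write_ms2_mgf(spectra.values(), tmp_path / "s.mgf")
        assert len(read_features(tmp_path / "f.tsv")) == len(features)
        assert set(read_ms2_mgf(tmp_path / "s.mgf")) == set(spectra)


class TestMutateProtein:
    def test_target_one_is_identity(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        mutated, realized = synthetic.mutate_protein(seq, 1.0, rng)
        assert mutated == seq and realized == 1.0

    def test_realized_within_band(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        mutated, realized = synthetic.mutate_protein(seq, 0.9, rng)
        assert 0.88 <= realized <= 0.92
        observed = sum(a == b for a, b in zip(seq, mutated)) / len(seq)
        assert observed == pytest.approx(realized)

    def test_same_length_substitution_only(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150))
        mutated, _ = synthetic.mutate_protein(seq, 0.7, rng)
        assert len(mutated) == len(seq)

    def test_infeasible_on_tiny_sequence(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            synthetic.mutate_protein("MK", 0.9, rng)


class TestGenomes:
    def test_planted_coordinates_match_contig(self):
        cfg = SimConfig(seed=8)
        refs = synthetic.make_reference_proteins(cfg)
        contigs, genes, truth = synthetic.gen_genomes(cfg, refs, [1.0])
        row = truth.iloc[0]
        contig = contigs[row.genome_id][row.contig_id]
        for g in genes:
            cds = contig[g.start - 1 : g.end]
            assert len(cds) == 3 * (g.aa_length + 1)  # CDS plus stop codon

    def test_negative_genomes_have_no_cassette_genes(self):
        cfg = SimConfig(seed=9)
        refs = synthetic.make_reference_proteins(cfg)
        _, genes, truth = synthetic.gen_genomes(cfg, refs, [None, None])
        assert not truth.has_cassette.any()
        assert all("_bg" in g.gene_id for g in genes)

    def test_deterministic(self):
        cfg = SimConfig(seed=10)
        refs = synthetic.make_reference_proteins(cfg)
        a = synthetic.gen_genomes(cfg, refs, [1.0, 0.8, None])
        b = synthetic.gen_genomes(cfg, refs, [1.0, 0.8, None])
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])


class TestReads:
    def test_read_truth_records_cassette_overlap(self):
        cfg = SimConfig(seed=11, n_reads=400)
        refs = synthetic.make_reference_proteins(cfg)
        contigs, _, truth = synthetic.gen_genomes(cfg, refs, [1.0])
        row = truth.iloc[0]
        reads, read_truth = synthetic.gen_reads(
            contigs,
            {row.genome_id: 1.0},
            cfg,
            cassette_regions={row.genome_id: (row.cassette_start, row.cassette_end)},
        )
        assert len(reads) == 400
        assert 0 < read_truth.cassette_overlap.sum() < 400

    def test_zero_abundance_genome_absent(self):
        cfg = SimConfig(seed=12, n_reads=300)
        refs = synthetic.make_reference_proteins(cfg)
        contigs, _, truth = synthetic.gen_genomes(cfg, refs, [1.0, None])
        pos, neg = truth.iloc[0], truth.iloc[1]
        _, read_truth = synthetic.gen_reads(
            contigs, {pos.genome_id: 0.0, neg.genome_id: 1.0}, cfg
        )
        assert (read_truth.genome_id == neg.genome_id).all()

    def test_fixed_seed_determinism(self):
        cfg = SimConfig(seed=13, n_reads=100)
        refs = synthetic.make_reference_proteins(cfg)
        contigs, _, truth = synthetic.gen_genomes(cfg, refs, [1.0])
        g = truth.iloc[0].genome_id
        r1, _ = synthetic.gen_reads(contigs, {g: 1.0}, cfg)
        r2, _ = synthetic.gen_reads(contigs, {g: 1.0}, cfg)
        assert r1 == r2


class TestGroupSamples:
    def test_sheet_shape_and_determinism(self):
        cfg = SimConfig(seed=14, group_size=3, reads_per_sample=50)
        sheet1, reads1, _ = synthetic.gen_group_samples(cfg)
        sheet2, reads2, _ = synthetic.gen_group_samples(cfg)
        assert sheet1 == sheet2
        assert reads1 == reads2
        assert len(sheet1) == 6
        groups = {s["group"] for s in sheet1}
        assert groups == {"group_a", "group_b"}

    def test_effect_detected_and_vanishes_when_shuffled(self):
        from acylscreen.quant import CassetteDB, compare_groups, quantify_reads

        rejections = 0
        shuffled_p = []
        for seed in range(3):
            cfg = SimConfig(
                seed=seed,
                group_size=8,
                reads_per_sample=400,
                cassette_frac_base=0.02,
                effect_size=4.0,
            )
            sheet, reads, refs = synthetic.gen_group_samples(cfg)
            db = CassetteDB({f"{r}_ref": s for r, s in refs.items()})
            rpm = {
                s["sample_id"]: quantify_reads(
                    reads[s["sample_id"]], db, s["sample_id"]
                ).rpm
                for s in sheet
            }
            a = [rpm[s["sample_id"]] for s in sheet if s["group"] == "group_a"]
            b = [rpm[s["sample_id"]] for s in sheet if s["group"] == "group_b"]
            if compare_groups(a, b).p_value < 0.05:
                rejections += 1
            pooled = a + b
            perm = np.random.default_rng(seed).permutation(len(pooled))
            half = len(pooled) // 2
            shuffled_p.append(
                compare_groups(
                    [pooled[i] for i in perm[:half]],
                    [pooled[i] for i in perm[half:]],
                ).p_value
            )
        assert rejections >= 2
        assert max(shuffled_p) > 0.05  # permuted labels lose significance

    def test_labels_balanced(self):
        cfg = SimConfig(seed=15, group_size=4, reads_per_sample=30)
        sheet, reads, _ = synthetic.gen_group_samples(cfg)
        counts = pd.Series([s["group"] for s in sheet]).value_counts()
        assert (counts == 4).all()
        assert all(len(reads[s["sample_id"]]) == 30 for s in sheet)
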