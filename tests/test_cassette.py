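"""Protein local alignment, homology cutoffs and operon-structure rules."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from acylscreen.cassette import (
    GeneRecord,
    align_proteins,
    detect_cassettes,
    find_homologs,
    read_proteome_fasta,
    read_reference_fasta,
    summarize_species,
)
from acylscreen import synthetic

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_local(query, subject, gap_open=-11.0, gap_extend=-1.0):
    """Independent affine-gap Smith-Waterman oracle with traceback.

    Returns (score, matches, columns, subject_span) of one optimal local
    alignment, via straightforward O(nm) dynamic programming.
    """
    n, m = len(query), len(subject)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in query (consumes subject)
    F = np.full((n + 1, m + 1), NEG)  # gap in subject (consumes query)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = _B62[query[i - 1]][subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
    score = H.max()
    if score <= 0:
        return 0.0, 0, 0, 0
    i, j = np.unravel_index(np.argmax(H), H.shape)
    matches = columns = 0
    s_end = j
    state = "H"
    while H[i][j] > 0 or state != "H":
        if state == "H":
            s = _B62[query[i - 1]][subject[j - 1]]
            if H[i][j] == E[i][j]:
                state = "E"
                continue
            if H[i][j] == F[i][j]:
                state = "F"
                continue
            assert H[i][j] == H[i - 1][j - 1] + s
            columns += 1
            if query[i - 1] == subject[j - 1] and query[i - 1] != "X":
                matches += 1
            i, j = i - 1, j - 1
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
    return float(score), matches, columns, int(s_end - j)


def _random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


class TestAlign:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        seq = _random_protein(rng, 100)
        res = align_proteins(seq, seq)
        assert res.percent_identity == 100.0
        assert res.subject_coverage == 1.0
        assert res.alignment_length == 100

    def test_subject_contained_in_query(self):
        rng = np.random.default_rng(1)
        query = _random_protein(rng, 100)
        subject = query[:50]
        res = align_proteins(query, subject)
        assert res.subject_coverage == 1.0
        assert res.alignment_length == 50

    def test_ten_planted_substitutions_give_90_percent(self):
        rng = np.random.default_rng(2)
        subject = _random_protein(rng, 100)
        query = list(subject)
        positions = rng.choice(100, size=10, replace=False)
        for pos in positions:
            query[pos] = next(a for a in AA20 if a != subject[pos])
        res = align_proteins("".join(query), subject)
        assert res.percent_identity == pytest.approx(90.0)
        assert res.alignment_length == 100

    def test_x_never_counts_as_match(self):
        res = align_proteins("MKVXLATRE", "MKVXLATRE")
        assert res.percent_identity == pytest.approx(100 * 8 / 9)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("MKV*", "MKV")

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_dp_oracle(self, seed):
        # mutated copies <= 30 aa: near-unique optima, identity/coverage
        # must match the independent Gotoh traceback
        rng = np.random.default_rng(seed)
        length = int(rng.integers(15, 31))
        subject = _random_protein(rng, length)
        query = list(subject)
        for _ in range(int(rng.integers(0, 4))):
            pos = int(rng.integers(length))
            query[pos] = str(rng.choice(list(AA20)))
        if rng.random() < 0.5:  # occasional deletion
            del query[int(rng.integers(len(query)))]
        query = "".join(query)
        res = align_proteins(query, subject)
        score, matches, columns, span = gotoh_local(query, subject)
        assert res.score == pytest.approx(score)
        assert res.percent_identity == pytest.approx(
            100 * matches / columns if columns else 0.0
        )
        assert res.subject_coverage == pytest.approx(span / length)


def _gene(gene_id, start, end, protein, strand="+", genome="g1", contig="c1"):
    return GeneRecord(genome, contig, gene_id, start, end, strand, protein)


@pytest.fixture(scope="module")
def refs():
    cfg = synthetic.SimConfig(seed=42)
    return synthetic.make_reference_proteins(cfg)


class TestFindHomologs:
    def test_exact_copy_assigned(self, refs):
        gene = _gene("c1g1", 1, 3 * len(refs["C"]) + 3, refs["C"])
        roles = find_homologs([gene], {"C": [("C_ref", refs["C"])], "A": []})
        assert roles["c1g1"][0] == "C"

    def test_low_identity_not_assigned(self, refs):
        rng = np.random.default_rng(3)
        mutated, realized = synthetic.mutate_protein(refs["C"], 0.60, rng)
        assert realized < 0.70 - 0.02
        gene = _gene("c1g1", 1, 100, mutated)
        roles = find_homologs([gene], {"C": [("C_ref", refs["C"])], "A": []})
        assert "c1g1" not in roles

    def test_truncation_fails_coverage(self, refs):
        truncated = refs["C"][: int(0.6 * len(refs["C"]))]
        gene = _gene("c1g1", 1, 100, truncated)
        roles = find_homologs([gene], {"C": [("C_ref", refs["C"])], "A": []})
        assert "c1g1" not in roles

    def test_empty_references_rejected(self, refs):
        gene = _gene("c1g1", 1, 100, refs["C"])
        with pytest.raises(ValueError):
            find_homologs([gene], {})

    def test_monotone_in_cutoffs(self, refs):
        rng = np.random.default_rng(4)
        genes = []
        for i, target in enumerate([1.0, 0.9, 0.8, 0.75, 0.72]):
            mutated, _ = synthetic.mutate_protein(refs["C"], target, rng)
            genes.append(_gene(f"g{i}", 1 + 1000 * i, 900 + 1000 * i, mutated))
        ref_map = {"C": [("C_ref", refs["C"])], "A": []}
        loose = set(find_homologs(genes, ref_map, id_min=70))
        tight = set(find_homologs(genes, ref_map, id_min=85))
        tighter_cov = set(find_homologs(genes, ref_map, id_min=70, cov_min=0.95))
        assert tight <= loose and tighter_cov <= loose


class TestDetectCassettes:
    def _triple(self, refs, strand=("+", "+", "+"), gaps=(100, 100)):
        c_len, t_len, a_len = (3 * len(refs[r]) + 3 for r in "CTA")
        c_start = 200
        t_start = c_start + c_len + gaps[0]
        a_start = t_start + t_len + gaps[1]
        genes = [
            _gene("gC", c_start, c_start + c_len - 1, refs["C"], strand[0]),
            _gene("gT", t_start, t_start + t_len - 1, refs["T"], strand[1]),
            _gene("gA", a_start, a_start + a_len - 1, refs["A"], strand[2]),
        ]
        roles = find_homologs(
            genes, {"C": [("C_ref", refs["C"])], "A": [("A_ref", refs["A"])]}
        )
        return genes, roles

    def test_adjacent_cta_found(self, refs):
        genes, roles = self._triple(refs)
        hits = detect_cassettes(genes, roles)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.c_gene, hit.t_gene, hit.a_gene) == ("gC", "gT", "gA")
        assert hit.evidence["C"].percent_identity == 100.0

    def test_reversed_gene_order_accepted(self, refs):
        a_len, t_len, c_len = (3 * len(refs[r]) + 3 for r in "ATC")
        a_start = 200
        t_start = a_start + a_len + 100
        c_start = t_start + t_len + 100
        genes = [
            _gene("gA", a_start, a_start + a_len - 1, refs["A"]),
            _gene("gT", t_start, t_start + t_len - 1, refs["T"]),
            _gene("gC", c_start, c_start + c_len - 1, refs["C"]),
        ]
        roles = find_homologs(
            genes, {"C": [("C_ref", refs["C"])], "A": [("A_ref", refs["A"])]}
        )
        hits = detect_cassettes(genes, roles)
        assert len(hits) == 1
        assert hits[0].c_gene == "gC" and hits[0].a_gene == "gA"
        assert hits[0].t_gene == "gT"

    def test_opposite_strands_rejected(self, refs):
        genes, roles = self._triple(refs, strand=("+", "+", "-"))
        assert detect_cassettes(genes, roles) == []

    def test_distant_pair_rejected(self, refs):
        genes, roles = self._triple(refs, gaps=(100, 10_000))
        assert detect_cassettes(genes, roles) == []

    def test_oversized_middle_orf_rejected(self, refs):
        genes, roles = self._triple(refs)
        big_t = _gene("gT", genes[1].start, genes[1].end, "M" * 200)
        assert detect_cassettes([genes[0], big_t, genes[2]], roles) == []


class TestSummarize:
    def test_counts(self, refs):
        cfg = synthetic.SimConfig(seed=11)
        contigs, genes, truth = synthetic.gen_genomes(
            cfg, refs, [1.0, 1.0, None, 0.85, None]
        )
        ref_map = {"C": [("C_ref", refs["C"])], "A": [("A_ref", refs["A"])]}
        roles = find_homologs(genes, ref_map)
        hits = detect_cassettes(genes, roles)
        species = {
            r.genome_id: ("bwex" if i < 3 else "other")
            for i, r in enumerate(truth.itertuples())
        }
        summary = summarize_species(species, hits).set_index("species")
        assert summary.loc["bwex", "n_with"] == 2
        assert summary.loc["bwex", "n_without"] == 1
        assert summary.loc["other", "n_with"] == 1
        assert (summary["n_with"] + summary["n_without"] == summary["n_isolates"]).all()

    def test_all_without(self):
        summary = summarize_species({"g1": "sp", "g2": "sp"}, [])
        assert summary.iloc[0]["n_with"] == 0
        assert summary.iloc[0]["n_without"] == 2


class TestIO:
    def test_fasta_gene_table_roundtrip(self, tmp_path, refs):
        cfg = synthetic.SimConfig(seed=12)
        _, genes, _ = synthetic.gen_genomes(cfg, refs, [1.0, None])
        faa = tmp_path / "proteome.faa"
        tsv = tmp_path / "genes.tsv"
        with faa.open("w") as fh:
            for g in genes:
                fh.write(f">{g.genome_id}|{g.contig_id}|{g.gene_id}\n{g.protein}\n")
        with tsv.open("w") as fh:
            fh.write("genome_id\tcontig_id\tgene_id\tstart\tend\tstrand\n")
            for g in genes:
                fh.write(
                    f"{g.genome_id}\t{g.contig_id}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\n"
                )
        back = read_proteome_fasta(faa, tsv)
        assert back == genes

    def test_reference_fasta_roles(self, tmp_path, refs):
        path = tmp_path / "refs.faa"
        with path.open("w") as fh:
            for role, seq in refs.items():
                fh.write(f">{role}_ref role={role}\n{seq}\n")
        parsed = read_reference_fasta(path)
        assert set(parsed) == {"C", "T", "A"}
        assert parsed["C"][0][1] == refs["C"]

    def test_untagged_reference_rejected(self, tmp_path):
        path = tmp_path / "refs.faa"
        path.write_text(">ref1\nMKVLAT\n")
        with pytest.raises(ValueError, match="role"):
            read_reference_fasta(path)
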