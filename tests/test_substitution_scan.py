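"""Alignment, pairwise differences and the segregation scan."""

import itertools

import numpy as np
import pytest
from Bio import Align

from saltscan.sequence_io import SeqRecord
from saltscan.substitution_scan import (
    AlignmentMatrix,
    LabeledSequencePanel,
    align_pair,
    alignment_score,
    map_column_to_ref,
    nucleotide_site_table,
    pairwise_differences,
    read_alignment,
    read_labels,
    scan_segregating_sites,
)
from saltscan.synthetic_data import PanelSpec, gen_panel, reverse_translate

AA = "ACDEFGHIKLMNPQRSTVWY"


def exhaustive_affine_score(a, b, match=1.0, mismatch=-1.0, gap_open=10.0, gap_extend=0.5):
    """Enumerate every global alignment as a move string (no dynamic
    programming) and return the best affine-gap score."""
    best = -float("inf")

    def walk(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, "M", score + s)
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            walk(i + 1, j, "X", score - cost)
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            walk(i, j + 1, "Y", score - cost)

    walk(0, 0, "", 0.0)
    return best


def biopython_score(a, b, match=1.0, mismatch=-1.0, gap_open=10.0, gap_extend=0.5):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner.score(a, b)


class TestAlignPair:
    def test_identity(self):
        aln = align_pair("MKV", "MKV")
        assert aln.rows == {"a": "MKV", "b": "MKV"}
        assert aln.score == 3.0

    def test_single_substitution(self):
        aln = align_pair("MKV", "MRV")
        assert aln.rows == {"a": "MKV", "b": "MRV"}
        assert aln.score == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MKV")

    @pytest.mark.parametrize("seed", range(5))
    def test_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(6):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(1, 6))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(1, 6))))
            assert alignment_score(a, b) == pytest.approx(exhaustive_affine_score(a, b))

    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_independent_aligner(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = "".join(rng.choice(list(AA), size=int(rng.integers(5, 12))))
        b = "".join(rng.choice(list(AA), size=int(rng.integers(5, 12))))
        assert alignment_score(a, b) == pytest.approx(biopython_score(a, b))

    def test_toy_gap_alignment_score(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        assert alignment_score(a, b) == pytest.approx(biopython_score(a, b))
        # with cheap gaps the optimum changes; both routes must track it
        assert alignment_score(a, b, gap_open=2.0, gap_extend=0.5) == pytest.approx(
            biopython_score(a, b, gap_open=2.0, gap_extend=0.5)
        )

    def test_alignment_rows_ungap_to_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(3, 30))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(3, 30))))
            aln = align_pair(a, b)
            assert aln.ungapped("a") == a
            assert aln.ungapped("b") == b


class TestPairwiseDifferences:
    def test_self_difference_is_zero(self):
        aln = AlignmentMatrix(["x", "y"], ["MKVD", "MKVD"])
        assert pairwise_differences(aln, "x", "y").count == 0

    def test_gap_columns_are_indels_not_substitutions(self):
        aln = AlignmentMatrix(["x", "y"], ["MK-VD", "MKAVH"])
        d = pairwise_differences(aln, "x", "y")
        assert d.positions == (4,)  # D vs H, in x's ungapped frame
        assert d.indel_columns == (3,)

    def test_unknown_id_raises(self):
        aln = AlignmentMatrix(["x", "y"], ["MK", "MK"])
        with pytest.raises(KeyError):
            pairwise_differences(aln, "x", "z")

    def test_planted_differences_recovered(self):
        spec = PanelSpec(
            n_tolerant=1,
            n_sensitive=1,
            length=60,
            planted_sites=((10, "D", "H"), (40, "V", "L")),
            seed=5,
        )
        panel, aln, _, _ = gen_panel(spec)
        d = pairwise_differences(aln, "tol1", "sen1")
        assert d.positions == (10, 40)


class TestColumnMapping:
    def test_gap_accounting(self):
        aln = AlignmentMatrix(["r"], ["M-KV"])
        assert map_column_to_ref(aln, "r", 1) == 1
        assert map_column_to_ref(aln, "r", 2) is None
        assert map_column_to_ref(aln, "r", 3) == 2
        assert map_column_to_ref(aln, "r", 4) == 3

    def test_gapless_row_is_identity(self):
        aln = AlignmentMatrix(["r"], ["MKVDE"])
        for c in range(1, 6):
            assert map_column_to_ref(aln, "r", c) == c

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ungap_then_index_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chars = list(AA) + ["-"] * 5
        row = "".join(rng.choice(chars, size=40))
        if row.replace("-", "") == "":
            row = "M" + row[1:]
        aln = AlignmentMatrix(["r"], [row])
        # oracle: the ungapped position is the count of non-gap chars up to c
        for c in range(1, 41):
            expected = None if row[c - 1] == "-" else len(row[:c].replace("-", ""))
            assert map_column_to_ref(aln, "r", c) == expected

    def test_unknown_ref_raises(self):
        aln = AlignmentMatrix(["r"], ["MKV"])
        with pytest.raises(KeyError):
            map_column_to_ref(aln, "nope", 1)


class TestSegregationScan:
    def test_strict_site_and_confounder(self, toy_panel):
        panel, aln = toy_panel
        sites = {s.column: s for s in scan_segregating_sites(aln, panel, ref_id="tol1")}
        assert sites[6].verdict == "strict_segregating"
        assert sites[6].residues_by_class["tolerant"] == frozenset("D")
        assert sites[6].residues_by_class["sensitive"] == frozenset("H")
        assert sites[4].verdict == "non_segregating"
        # monomorphic columns are not reported at all
        assert 1 not in sites and 2 not in sites

    def test_codon_span_attached_to_ref_position(self, toy_panel):
        panel, aln = toy_panel
        sites = {s.column: s for s in scan_segregating_sites(aln, panel, ref_id="tol1")}
        assert (sites[6].codon.nt_start, sites[6].codon.nt_end) == (16, 18)

    def test_one_exception_demotes_strict_site(self, toy_panel):
        """Adding a sensitive sequence carrying the tolerant residue must
        demote the strict verdict (and reappear as candidate when allowed)."""
        panel, aln = toy_panel
        extra = SeqRecord(id="sen4", residues="MKVAEDGW", alphabet="protein")  # D at col 6
        panel2 = LabeledSequencePanel(
            records=panel.records + (extra,), labels={**panel.labels, "sen4": "sensitive"}
        )
        aln2 = AlignmentMatrix(list(aln.ids) + ["sen4"], [aln.rows[i] for i in aln.ids] + [extra.residues])
        strict0 = {s.column: s.verdict for s in scan_segregating_sites(aln2, panel2, ref_id="tol1")}
        assert strict0[6] == "non_segregating"
        relaxed = {s.column: s.verdict for s in scan_segregating_sites(aln2, panel2, ref_id="tol1", max_exceptions=1)}
        assert relaxed[6] == "candidate_with_exceptions"

    def test_gap_column_cannot_be_strict(self):
        aln = AlignmentMatrix(["t1", "t2", "s1"], ["MD-V", "MDAV", "MH-V"])
        panel = LabeledSequencePanel(
            records=(
                SeqRecord(id="t1", residues="MDV"),
                SeqRecord(id="t2", residues="MDAV"),
                SeqRecord(id="s1", residues="MHV"),
            ),
            labels={"t1": "tolerant", "t2": "tolerant", "s1": "sensitive"},
        )
        sites = {s.column: s for s in scan_segregating_sites(aln, panel, ref_id="t1")}
        assert sites[2].verdict == "strict_segregating"  # D/D vs H, gap-free
        assert sites[3].verdict == "non_segregating"  # tolerant side has a gap

    def test_policy_moderate_exclusion_vs_inclusion(self):
        spec = PanelSpec(
            n_tolerant=3, n_sensitive=3, n_moderate=2, length=50,
            planted_sites=((25, "D", "H"),), seed=11,
        )
        panel, aln, _, _ = gen_panel(spec)
        strict_excl = [
            s.column
            for s in scan_segregating_sites(aln, panel, ref_id="tol1", policy="exclude")
            if s.verdict == "strict_segregating"
        ]
        assert strict_excl == [25]
        # moderates carry the sensitive residue: folding them into the
        # tolerant class must break strictness
        strict_incl = [
            s.column
            for s in scan_segregating_sites(aln, panel, ref_id="tol1", policy="include_as_tolerant")
            if s.verdict == "strict_segregating"
        ]
        assert 25 not in strict_incl

    def test_requires_both_classes(self):
        panel = LabeledSequencePanel(
            records=(SeqRecord(id="a", residues="MD"), SeqRecord(id="b", residues="MH")),
            labels={"a": "tolerant", "b": "unknown"},
        )
        aln = AlignmentMatrix(["a", "b"], ["MD", "MH"])
        with pytest.raises(ValueError, match="tolerant and one sensitive"):
            scan_segregating_sites(aln, panel)

    def test_label_permutation_destroys_planted_signal(self):
        """Scrambling class labels must erase the strict verdicts of a
        class-linked planted site in the overwhelming majority of draws."""
        spec = PanelSpec(
            n_tolerant=4, n_sensitive=4, length=80,
            planted_sites=((40, "D", "H"),), background_rate=0.02, seed=21,
        )
        panel, aln, _, _ = gen_panel(spec)
        rng = np.random.default_rng(77)
        ids = [r.id for r in panel.records]
        base_labels = [panel.labels[i] for i in ids]
        n_with_strict = 0
        for _ in range(200):
            perm = rng.permutation(base_labels)
            permuted = LabeledSequencePanel(
                records=panel.records, labels=dict(zip(ids, perm))
            )
            sites = scan_segregating_sites(aln, permuted, ref_id=ids[0])
            if any(s.verdict == "strict_segregating" for s in sites):
                n_with_strict += 1
        assert n_with_strict <= 10  # >= 95% of permutations show no strict site


class TestNucleotideSiteTable:
    def test_snp_offsets_for_planted_dh_vl_sites(self):
        spec = PanelSpec(
            n_tolerant=2, n_sensitive=2, length=400,
            planted_sites=((332, "D", "H"), (395, "V", "L")), seed=3,
        )
        panel, aln, cds, _ = gen_panel(spec)
        sites = [
            s for s in scan_segregating_sites(aln, panel, ref_id="tol1")
            if s.verdict == "strict_segregating"
        ]
        tab = nucleotide_site_table(aln, panel, sites, cds).set_index("ref_pos")
        # GAC vs CAC and GTC vs CTC both differ at codon offset 1 only
        assert tab.loc[332, "differing_offsets"] == "1"
        assert tab.loc[332, "differing_nt_positions"] == "994"
        assert tab.loc[395, "differing_nt_positions"] == "1183"
        assert tab.loc[332, "tolerant_codons"] == "GAC"
        assert tab.loc[332, "sensitive_codons"] == "CAC"

    def test_confounded_site_has_no_flagged_offsets(self):
        """At an A/P column shared by both classes the per-class codon sets
        overlap at every offset, so nothing is flagged."""
        spec = PanelSpec(
            n_tolerant=2, n_sensitive=2, length=30, confounded_sites=(15,), seed=9,
        )
        panel, aln, cds, _ = gen_panel(spec)
        sites = [s for s in scan_segregating_sites(aln, panel, ref_id="tol1") if s.column == 15]
        tab = nucleotide_site_table(aln, panel, sites, cds)
        assert tab.iloc[0]["verdict"] == "non_segregating"
        assert tab.iloc[0]["differing_offsets"] == ""

    def test_his_codon_pair_differing_offsets(self):
        # Asp GAC vs His CAT: first and third codon positions both differ
        panel = LabeledSequencePanel(
            records=(SeqRecord(id="t", residues="MD"), SeqRecord(id="s", residues="MH")),
            labels={"t": "tolerant", "s": "sensitive"},
        )
        aln = AlignmentMatrix(["t", "s"], ["MD", "MH"])
        sites = scan_segregating_sites(aln, panel, ref_id="t")
        tab = nucleotide_site_table(aln, panel, sites, {"t": "ATGGAC", "s": "ATGCAT"})
        assert tab.iloc[0]["differing_offsets"] == "1,3"

    def test_cds_length_mismatch_raises(self):
        panel = LabeledSequencePanel(
            records=(SeqRecord(id="t", residues="MD"), SeqRecord(id="s", residues="MH")),
            labels={"t": "tolerant", "s": "sensitive"},
        )
        aln = AlignmentMatrix(["t", "s"], ["MD", "MH"])
        sites = scan_segregating_sites(aln, panel, ref_id="t")
        with pytest.raises(ValueError, match="mismatch"):
            nucleotide_site_table(aln, panel, sites, {"t": "ATGGACAA", "s": "ATGCAC"})


class TestReaders:
    def test_aligned_fasta_and_labels(self, tmp_path):
        (tmp_path / "aln.fasta").write_text(">t1\nMD-V\n>s1\nMHAV\n")
        aln = read_alignment(tmp_path / "aln.fasta")
        assert aln.width == 4 and aln.ungapped("t1") == "MDV"
        (tmp_path / "labels.csv").write_text("id,label\nt1,tolerant\ns1,sensitive\n")
        assert read_labels(tmp_path / "labels.csv") == {"t1": "tolerant", "s1": "sensitive"}

    def test_clustal_format(self, tmp_path):
        text = (
            "CLUSTAL W (1.83) multiple sequence alignment\n\n"
            "t1   MD-V\n"
            "s1   MHAV\n"
        )
        (tmp_path / "panel.aln").write_text(text)
        aln = read_alignment(tmp_path / "panel.aln")
        assert aln.rows["s1"] == "MHAV"
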