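"""Read classification: precedence, windows, tRNA-fragment typing and
agreement with simulation ground truth."""

import numpy as np
import pandas as pd
import pytest

from smallrna_atlas import classify, simdata


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


@pytest.fixture
def toy_tracks():
    return {
        "mirna": _bed([("chr1", 100, 122, "mir1", 0, "+")]),
        "trna": _bed([("chr1", 500, 572, "trna1", 0, "+")]),
        "pirna_cluster": _bed([("chr1", 1000, 3000, "pc1", 0, "+")]),
        "repeat": _bed([("chr1", 2500, 2800, "rep1", 0, "+"),
                        ("chr1", 5000, 5300, "rep2", 0, "+")]),
        "exon": _bed([("chr1", 7000, 7200, "ex1", 0, "+")]),
    }


def _read(chrom, start, end, strand="+"):
    return {"chrom": chrom, "start": start, "end": end, "strand": strand}


class TestClassifyRead:
    def test_mirna_locus(self, toy_tracks):
        assert classify.classify_read(_read("chr1", 100, 122),
                                      toy_tracks) == "mirna"

    def test_unannotated(self, toy_tracks):
        assert classify.classify_read(_read("chr1", 40_000, 40_030),
                                      toy_tracks) == "unannotated"

    def test_dual_overlap_resolved_by_precedence(self, toy_tracks):
        # read inside both the piRNA cluster and the repeat element
        read = _read("chr1", 2600, 2630)
        assert classify.classify_read(read, toy_tracks) == "pirna_cluster"
        flipped = classify.ClassConfig(precedence=(
            "mirna", "trna", "repeat", "pirna_cluster", "exon"))
        assert classify.classify_read(read, toy_tracks, flipped) == "repeat"

    def test_precedence_only_matters_for_multi_overlap(self, toy_tracks):
        """Exhaustive scan of reads tiling the toy tracks: flipping the
        precedence changes labels only where both classes overlap."""
        default = classify.ClassConfig()
        flipped = classify.ClassConfig(precedence=(
            "mirna", "trna", "repeat", "pirna_cluster", "exon"))
        starts = np.arange(0, 8000, 37)
        reads = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 30, "strand": "+"})
        l1 = classify.classify_reads(reads, toy_tracks, default)
        l2 = classify.classify_reads(reads, toy_tracks, flipped)
        differs = l1 != l2
        both = ((reads["start"] < 2800) & (2500 < reads["end"]))  # dual zone
        assert differs[~both.to_numpy()].eq(False).all()
        assert set(l1[differs]) <= {"pirna_cluster", "repeat"}

    def test_strand_awareness(self, toy_tracks):
        # tRNA lookup is strand-specific, repeat lookup is not
        assert classify.classify_read(_read("chr1", 500, 530, "-"),
                                      toy_tracks) != "trna"
        assert classify.classify_read(_read("chr1", 5000, 5030, "-"),
                                      toy_tracks) == "repeat"


class TestWindows:
    def test_partition_covers_18_36(self):
        win = classify.length_window(np.arange(18, 37))
        assert "outside" not in set(win)
        assert list(win[:7]) == ["short"] * 7
        assert list(win[7:14]) == ["mid"] * 7
        assert list(win[14:]) == ["long"] * 5

    def test_every_read_gets_one_class_and_window(self, small_experiment):
        exp = small_experiment
        reads = exp["reads"]["normal_01"]
        labels = classify.classify_reads(reads, exp["tracks"])
        windows = classify.length_window(
            (reads["end"] - reads["start"]).to_numpy())
        assert len(labels) == len(reads) == len(windows)
        assert labels.notna().all()


class TestComposition:
    def test_pure_trna_long_window(self, toy_tracks):
        reads = pd.DataFrame({
            "chrom": "chr1", "start": [500] * 5, "end": [533] * 5,
            "name": [f"r{i}" for i in range(5)], "score": 0,
            "strand": "+", "seq": "A" * 33})
        design = pd.DataFrame({"sample_id": ["s1"], "group": ["g"],
                               "condition": ["control"]})
        comp = classify.class_composition({"s1": reads}, design, toy_tracks)
        row = comp[(comp["window"] == "long") & (comp["class"] == "trna")]
        assert row["fraction"].iloc[0] == 1.0

    def test_long_window_mostly_trna(self, small_experiment):
        exp = small_experiment
        comp = classify.class_composition(exp["reads"], exp["design"],
                                          exp["tracks"])
        normal = comp[(comp["group"] == "normal") & (comp["window"] == "long")]
        trna_frac = normal.set_index("class")["fraction"].get("trna", 0.0)
        assert 0.8 < trna_frac < 0.97

    def test_mid_window_pirna_repeat_loss_in_tumor(self, small_experiment):
        exp = small_experiment
        comp = classify.class_composition(exp["reads"], exp["design"],
                                          exp["tracks"])

        def pr_frac(group):
            sub = comp[(comp["group"] == group) & (comp["window"] == "mid")]
            s = sub.set_index("class")["fraction"]
            return s.get("pirna_cluster", 0.0) + s.get("repeat", 0.0)

        assert pr_frac("normal") > pr_frac("tumor") + 0.2

    def test_labels_agree_with_truth(self, small_experiment):
        """>= 99 % of primary alignments get the class their truth
        feature implies."""
        exp = small_experiment
        reads = exp["reads"]["normal_03"].drop_duplicates("name")
        labels = classify.classify_reads(reads, exp["tracks"])
        truth_class = reads["name"].str.split("@", n=1).str[0]
        expected = truth_class.map({
            "miRNA": "mirna", "piRNA": "pirna_cluster", "tRNA_half": "trna",
            "tRF": "trna", "repeat": "repeat", "exon": "exon",
            "other": "unannotated"})
        assert (labels.to_numpy() == expected.to_numpy()).mean() >= 0.99


class TestTrnaTyping:
    GENE = {"chrom": "chr1", "start": 500, "end": 572, "strand": "+",
            "name": "trna-Glu-GAG"}

    def test_trf_5prime(self):
        call = classify.type_trna_fragment(
            {"chrom": "chr1", "start": 500, "end": 520, "strand": "+"},
            self.GENE)
        assert (call.fragment_type, call.origin_end) == ("tRF", "5prime")

    def test_half_5prime(self):
        call = classify.type_trna_fragment(
            {"chrom": "chr1", "start": 500, "end": 533, "strand": "+"},
            self.GENE)
        assert (call.fragment_type, call.origin_end) == ("tRNA_half", "5prime")

    def test_ambiguous_length(self):
        call = classify.type_trna_fragment(
            {"chrom": "chr1", "start": 500, "end": 526, "strand": "+"},
            self.GENE)
        assert call.fragment_type == "ambiguous"

    def test_3prime_and_internal(self):
        call3 = classify.type_trna_fragment(
            {"chrom": "chr1", "start": 552, "end": 572, "strand": "+"},
            self.GENE)
        assert call3.origin_end == "3prime"
        mid = classify.type_trna_fragment(
            {"chrom": "chr1", "start": 520, "end": 540, "strand": "+"},
            self.GENE)
        assert mid.origin_end == "internal"

    def test_minus_strand_gene_5prime_is_right_edge(self):
        gene = dict(self.GENE, strand="-")
        call = classify.type_trna_fragment(
            {"chrom": "chr1", "start": 552, "end": 572, "strand": "-"}, gene)
        assert call.origin_end == "5prime"

    def test_non_overlapping_read_raises(self):
        with pytest.raises(ValueError):
            classify.type_trna_fragment(
                {"chrom": "chr1", "start": 0, "end": 20, "strand": "+"},
                self.GENE)

    def test_simulated_reads_mostly_5prime(self, small_experiment):
        exp = small_experiment
        reads = exp["reads"]["normal_01"]
        trna_reads = reads[reads["name"].str.contains("@trna_")].head(2000)
        calls = classify.type_trna_reads(trna_reads, exp["tracks"]["trna"])
        assert (calls["origin_end"] == "5prime").mean() > 0.75
        halves = calls[calls["length"] >= 32]
        assert (halves["fragment_type"] == "tRNA_half").all()
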