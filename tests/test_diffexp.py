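"""Negative-binomial differential expression: size factors, dispersion
estimation, exact test, fold changes, BH adjustment and VST."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from smallrna_atlas import diffexp

from oracles import brute_bh, brute_count, brute_nb_exact


def _design(conditions):
    return pd.DataFrame({
        "sample_id": list(conditions.index),
        "group": conditions.values,
        "condition": conditions.values})


class TestCountReads:
    def _feats(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                           "score", "strand"])

    def test_alignments_inside_one_feature(self):
        feats = self._feats([("chr1", 0, 100, "f1", 0, "+")])
        aln = pd.DataFrame({"chrom": "chr1", "start": range(5),
                            "end": [i + 30 for i in range(5)],
                            "strand": "+"})
        assert diffexp.count_reads(feats, aln).iloc[0] == 5

    def test_multi_feature_overlap_adds_to_each(self):
        feats = self._feats([("chr1", 0, 50, "a", 0, "+"),
                             ("chr1", 50, 100, "b", 0, "+"),
                             ("chr2", 0, 50, "c", 0, "+")])
        aln = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [40, 10],
                            "end": [70, 40], "strand": "+"})
        c_all = diffexp.count_reads(feats, aln, "all")
        assert c_all.tolist() == [1, 1, 1]
        c_unique = diffexp.count_reads(feats, aln, "unique")
        assert c_unique.tolist() == [0, 0, 1]

    def test_empty_feature_set_raises(self):
        with pytest.raises(ValueError):
            diffexp.count_reads(self._feats([]), pd.DataFrame())

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            nf, nr = 15, 60
            frows, rrows = [], []
            for i in range(nf):
                s = int(rng.integers(0, 400))
                frows.append((f"chr{rng.integers(1, 3)}", s,
                              s + int(rng.integers(20, 120)), f"f{i}", 0, "+"))
            for _ in range(nr):
                s = int(rng.integers(0, 450))
                rrows.append((f"chr{rng.integers(1, 3)}", s,
                              s + int(rng.integers(18, 37)), "+"))
            feats = self._feats(frows)
            aln = pd.DataFrame(rrows, columns=["chrom", "start", "end",
                                               "strand"])
            for policy in ("all", "unique"):
                got = diffexp.count_reads(feats, aln, policy).tolist()
                want = brute_count(
                    [(c, s, e, st) for c, s, e, _, _, st in frows],
                    rrows, policy)
                assert got == want, f"trial {trial} policy {policy}"


class TestSizeFactors:
    def test_identical_samples_unity(self):
        c = pd.DataFrame({"a": [5, 9, 14], "b": [5, 9, 14]})
        assert np.allclose(diffexp.size_factors(c), 1.0)

    def test_hand_computed_doubling(self):
        c = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        s = diffexp.size_factors(c)
        assert s["s1"] == pytest.approx(1 / np.sqrt(2))
        assert s["s2"] == pytest.approx(np.sqrt(2))

    def test_single_sample_unity(self):
        c = pd.DataFrame({"only": [3, 8, 11]})
        assert diffexp.size_factors(c).iloc[0] == pytest.approx(1.0)

    def test_no_all_positive_feature_raises(self):
        c = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="filter"):
            diffexp.size_factors(c)

    def test_normalization_conservation(self):
        rng = np.random.default_rng(2)
        c = pd.DataFrame(rng.poisson(50, (200, 6)) + 1)
        s = diffexp.size_factors(c)
        norm = c.to_numpy() / s.to_numpy()
        geo = np.exp(np.log(norm).mean(axis=1))
        med = np.median(norm / geo[:, None], axis=0)
        assert np.allclose(med, 1.0, atol=0.02)


class TestDispersions:
    def _sim(self, alpha, mu=500.0, n=400, m=20, seed=0):
        rng = np.random.default_rng(seed)
        means = np.exp(rng.uniform(np.log(mu / 5), np.log(mu * 5), n))
        if alpha > 0:
            size = 1 / alpha
            arr = rng.negative_binomial(size, size / (size + means[:, None]),
                                        (n, m))
        else:
            arr = rng.poisson(means[:, None], (n, m))
        counts = pd.DataFrame(arr, columns=[f"s{j}" for j in range(m)])
        cond = pd.Series(["case"] * (m // 2) + ["control"] * (m - m // 2),
                         index=counts.columns)
        return counts, cond

    def test_constant_within_condition_floored(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [10, 20],
                               "c": [30, 5], "d": [30, 5]})
        cond = pd.Series(["x", "x", "y", "y"], index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        model = diffexp.estimate_dispersions(counts, sf, cond)
        assert (model.raw == 0).all()
        assert np.allclose(model.final, np.maximum(
            model.fitted, diffexp.DISPERSION_FLOOR))

    def test_recovers_true_dispersion(self):
        counts, cond = self._sim(alpha=0.2, seed=5)
        sf = diffexp.size_factors(counts)
        model = diffexp.estimate_dispersions(counts, sf, cond)
        assert 0.1 < model.final.median() < 0.4

    def test_poisson_data_small_asymptotic_dispersion(self):
        counts, cond = self._sim(alpha=0.0, mu=500.0, seed=6)
        sf = diffexp.size_factors(counts)
        model = diffexp.estimate_dispersions(counts, sf, cond)
        assert model.coeffs[0] <= 0.05

    def test_maximum_sharing(self):
        counts, cond = self._sim(alpha=0.1, seed=7)
        sf = diffexp.size_factors(counts)
        for fit_type in ("parametric", "local"):
            model = diffexp.estimate_dispersions(counts, sf, cond, fit_type)
            assert (model.final >= model.raw - 1e-12).all()
            assert (model.final >= diffexp.DISPERSION_FLOOR).all()

    def test_no_replication_raises(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        cond = pd.Series(["x", "y"], index=counts.columns)
        with pytest.raises(ValueError, match="replicat"):
            diffexp.estimate_dispersions(counts, pd.Series(1.0, index=counts.columns),
                                         cond)


class TestExactTest:
    def test_all_zero_feature_p_one(self):
        counts = pd.DataFrame({"a": [0], "b": [0], "c": [0], "d": [0]})
        cond = pd.Series(["case", "case", "control", "control"],
                         index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        p = diffexp.nbinom_test(counts, sf, pd.Series(0.1, index=counts.index),
                                cond)
        assert p.iloc[0] == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(120):
            k_a, k_b = (int(x) for x in rng.integers(0, 26, 2))
            s_a, s_b = rng.uniform(1.5, 6.0, 2)
            s2_a, s2_b = s_a * rng.uniform(0.3, 1.0), s_b * rng.uniform(0.3, 1.0)
            alpha = float(rng.uniform(0.0, 0.6))
            got = diffexp.nbinom_exact_pvalue(k_a, k_b, s_a, s_b, s2_a, s2_b,
                                              alpha)
            want = brute_nb_exact(k_a, k_b, s_a, s_b, s2_a, s2_b, alpha)
            assert got == pytest.approx(want, abs=1e-10)

    def test_exchangeable_in_group_labels(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(30, (50, 8)),
                              columns=[f"s{j}" for j in range(8)])
        cond = pd.Series(["case"] * 4 + ["control"] * 4, index=counts.columns)
        sf = diffexp.size_factors(counts)
        disp = pd.Series(0.1, index=counts.index)
        p1 = diffexp.nbinom_test(counts, sf, disp, cond)
        swapped = cond.map({"case": "control", "control": "case"})
        p2 = diffexp.nbinom_test(counts, sf, disp, swapped)
        assert np.allclose(p1, p2)

    def test_missing_dispersion_raises(self):
        counts = pd.DataFrame({"a": [1], "b": [2]})
        cond = pd.Series(["case", "control"], index=counts.columns)
        disp = pd.Series([np.nan], index=counts.index)
        with pytest.raises(ValueError, match="dispersion"):
            diffexp.nbinom_test(counts, pd.Series(1.0, index=counts.columns),
                                disp, cond)


class TestFoldChange:
    def _cm(self, case_vals, control_vals):
        counts = pd.DataFrame({"c1": case_vals, "c2": case_vals,
                               "n1": control_vals, "n2": control_vals})
        cond = pd.Series(["case", "case", "control", "control"],
                         index=counts.columns)
        return counts, cond

    def test_equal_means_zero(self):
        counts, cond = self._cm([10], [10])
        fc = diffexp.fold_change(counts, pd.Series(1.0, index=counts.columns),
                                 cond)
        assert fc["log2FoldChange"].iloc[0] == 0.0

    def test_infinite_fold_changes(self):
        counts, cond = self._cm([10, 0, 0], [0, 10, 0])
        fc = diffexp.fold_change(counts, pd.Series(1.0, index=counts.columns),
                                 cond)
        assert fc["log2FoldChange"].iloc[0] == np.inf
        assert fc["log2FoldChange"].iloc[1] == -np.inf
        assert np.isnan(fc["log2FoldChange"].iloc[2])


class TestBH:
    def test_single_p(self):
        assert diffexp.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_textbook_example(self):
        assert np.allclose(diffexp.bh_adjust([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_against_oracle_and_statsmodels(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 200)
        adj = diffexp.bh_adjust(p)
        assert np.allclose(adj, brute_bh(p))
        assert np.allclose(adj, multipletests(p, method="fdr_bh")[1])
        assert (adj >= p - 1e-15).all()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            diffexp.bh_adjust([0.5, 1.2])


class TestFilterSignificant:
    def _res(self, padj, lfc):
        return pd.DataFrame({"baseMean": 1.0, "log2FoldChange": lfc,
                             "pvalue": padj, "padj": padj},
                            index=[f"f{i}" for i in range(len(padj))])

    def test_strict_threshold_boundary(self):
        res = self._res([2e-7, 1e-6], [1.0, 2.0])
        sig = diffexp.filter_significant(res, 1e-6)
        assert list(sig.index) == ["f0"]

    def test_sorted_by_padj_then_absfc(self):
        res = self._res([1e-8, 1e-8, 1e-9], [2.0, -5.0, 1.0])
        sig = diffexp.filter_significant(res, 1e-6)
        assert list(sig.index) == ["f2", "f1", "f0"]


class TestVST:
    def _model(self, a0=0.05, a1=2.0):
        idx = pd.Index(["f"])
        return diffexp.DispersionModel(
            raw=pd.Series(0.1, index=idx), fitted=pd.Series(a0, index=idx),
            final=pd.Series(0.1, index=idx),
            base_mean=pd.Series(10.0, index=idx),
            fit_type="parametric", coeffs=(a0, a1))

    def test_monotone(self):
        q = pd.DataFrame({"s": np.linspace(0, 1e4, 500)})
        out = diffexp.vst(q, pd.Series(1.0, index=["s"]), self._model())
        assert (np.diff(out["s"].to_numpy()) > 0).all()

    def test_converges_to_log2_plus_constant(self):
        q = pd.DataFrame({"s": [1e5, 1e6, 1e7]})
        out = diffexp.vst(q, pd.Series(1.0, index=["s"]), self._model())
        diffs = out["s"].to_numpy() - np.log2(q["s"].to_numpy())
        assert np.all(np.abs(np.diff(diffs)) < 0.01)

    def test_poisson_limit_sqrt_behavior(self):
        """a0, a1 -> 0: the transform grows like sqrt(q) (Anscombe-type
        Poisson stabilization), checked against numeric integration."""
        from scipy.integrate import quad
        model = self._model(a0=1e-10, a1=0.0)
        qs = np.array([10.0, 100.0, 400.0, 900.0])
        out = diffexp.vst(pd.DataFrame({"s": qs}),
                          pd.Series(1.0, index=["s"]), model)
        v = out["s"].to_numpy()
        # growth between consecutive points matches int 1/sqrt(q) dq / ln2
        for (q1, q2, v1, v2) in zip(qs, qs[1:], v, v[1:]):
            integral = quad(lambda q: 1 / np.sqrt(q + 1e-10 * q * q),
                            q1, q2)[0]
            scale = np.sqrt(1e-10) / np.log(2)
            assert v2 - v1 == pytest.approx(integral * scale, rel=1e-4)

    def test_variance_flattening_on_nb_simulation(self):
        """Across 3 decades of mean, VST variance per feature varies far
        less than the untransformed variance."""
        rng = np.random.default_rng(13)
        alpha = 0.05
        means = np.concatenate([np.full(60, m) for m in (10, 100, 1000)])
        size = 1 / alpha
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + means[:, None]),
                                  (180, 20)),
            columns=[f"s{j}" for j in range(20)])
        cond = pd.Series(["case"] * 10 + ["control"] * 10,
                         index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        model = diffexp.estimate_dispersions(counts, sf, cond)
        out = diffexp.vst(counts, sf, model)
        raw_var = counts.var(axis=1).groupby(means).mean()
        vst_var = out.var(axis=1).groupby(means).mean()
        assert raw_var.max() / raw_var.min() > 100
        assert vst_var.max() / vst_var.min() < 4

    def test_unfitted_model_raises(self):
        model = self._model()
        model.fitted = None
        with pytest.raises(ValueError):
            diffexp.vst(pd.DataFrame({"s": [1.0]}),
                        pd.Series(1.0, index=["s"]), model)


class TestEndToEnd:
    def test_nbinom_de_on_injected_difference(self):
        rng = np.random.default_rng(31)
        n, m = 300, 12
        means = np.exp(rng.uniform(np.log(50), np.log(500), n))
        fc = np.ones(n)
        fc[:10] = 8.0
        size = 1 / 0.05
        case = rng.negative_binomial(
            size, size / (size + (means * fc)[:, None]), (n, 6))
        ctrl = rng.negative_binomial(
            size, size / (size + means[:, None]), (n, 6))
        counts = pd.DataFrame(
            np.hstack([case, ctrl]),
            columns=[f"c{j}" for j in range(6)] + [f"n{j}" for j in range(6)])
        design = pd.DataFrame({
            "sample_id": counts.columns,
            "group": ["case"] * 6 + ["control"] * 6,
            "condition": ["case"] * 6 + ["control"] * 6})
        res = diffexp.nbinom_de(diffexp.CountMatrix(counts, design))
        sig = diffexp.filter_significant(res, 1e-6)
        hits = set(sig.index) & set(counts.index[:10])
        assert len(hits) >= 9
        assert (res["padj"] >= res["pvalue"] - 1e-15).all()
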