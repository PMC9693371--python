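import numpy as np
import pandas as pd
import pytest
from scipy import stats

from familyscan.expression import (anova_oneway, ddct, fpkm, heatmap_matrix,
                                   pearson_with_p, stars_for_p,
                                   tissue_max_calls)
from familyscan.synthetic_data import generate_qpcr


def _mat(values, genes=None, tissues=None):
    values = np.atleast_2d(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=tissues)


class TestFpkm:
    def test_direct_formula(self):
        counts = _mat([[10]])
        out = fpkm(counts, pd.Series({"g0": 500.0}), pd.Series({"t0": 1e6}))
        assert out.iloc[0, 0] == pytest.approx(20.0)

    def test_zero_counts_give_zero(self):
        out = fpkm(_mat([[0]]), pd.Series({"g0": 500.0}), pd.Series({"t0": 1e6}))
        assert out.iloc[0, 0] == 0.0

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            fpkm(_mat([[-1]]), pd.Series({"g0": 500.0}), pd.Series({"t0": 1e6}))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        counts = _mat(rng.integers(0, 1000, size=(20, 5)))
        lengths = pd.Series(rng.integers(200, 3000, size=20).astype(float),
                            index=counts.index)
        libs = pd.Series(rng.integers(1e6, 5e7, size=5).astype(float),
                         index=counts.columns)
        out = fpkm(counts, lengths, libs)
        for g in counts.index:
            for t in counts.columns:
                oracle = 1e9 * counts.loc[g, t] / (libs[t] * lengths[g])
                assert out.loc[g, t] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_proportional_library_split(self):
        counts = _mat([[100, 50]], tissues=["t0", "t1"])
        lengths = pd.Series({"g0": 1000.0})
        libs = pd.Series({"t0": 2e6, "t1": 1e6})
        out = fpkm(counts, lengths, libs)
        # halving counts and library size together leaves FPKM unchanged
        assert out.loc["g0", "t0"] == pytest.approx(out.loc["g0", "t1"])


class TestHeatmap:
    def test_log2_plus_one_values(self):
        mat, flags = heatmap_matrix(_mat([[0.0, 7.0]]))
        assert mat.iloc[0, 0] == 0.0 and mat.iloc[0, 1] == pytest.approx(3.0)

    def test_all_zero_genes_flagged_not_expressed(self):
        mat, flags = heatmap_matrix(_mat([[0, 0], [1, 0]]))
        assert flags.tolist() == [True, False]


class TestTissueCalls:
    def test_argmax_tissue(self):
        calls = tissue_max_calls(_mat([[1, 2, 9]], tissues=["a", "b", "c"]))
        assert calls.iloc[0] == "c"

    def test_tie_is_ambiguous(self):
        calls = tissue_max_calls(_mat([[3, 3, 3]]))
        assert calls.iloc[0] == "ambiguous"


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(7, dtype=float)
        r, p, s = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and s == "***"

    def test_perfect_anticorrelation(self):
        x = np.arange(5, dtype=float)
        r, _, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_p_matches_independent_oracle(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0, 8.0])
        r, p, _ = pearson_with_p(x, y)
        r_o, p_o = stats.pearsonr(x, y)
        assert r == pytest.approx(r_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_p_invariant_under_affine_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        _, p1, _ = pearson_with_p(x, y)
        _, p2, _ = pearson_with_p(3 * x - 7, -2 * y + 11)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.05, ""), (0.049999, "*"), (0.01, "*"), (0.009999, "**"),
        (0.001, "**"), (0.0009999, "***"), (0.5, ""),
    ])
    def test_threshold_boundaries(self, p, expected):
        assert stars_for_p(p) == expected


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = anova_oneway([np.array([1.0, 2, 3]), np.array([3.0, 2, 1])])
        assert f == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc=i, size=5) for i in range(3)]
        f, p = anova_oneway(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = len(groups), allv.size
        f_o = (ssb / (k - 1)) / (ssw / (n - k))
        p_o = stats.f.sf(f_o, k - 1, n - k)
        assert f == pytest.approx(f_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_degenerate_groups_error(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([5.0, 5.0]), np.array([5.0, 5.0])])


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])

    def test_calibrator_rq_exactly_one(self):
        rows = [("STT", "Actin", 1, 20.0), ("STT", "MYB1", 1, 24.0),
                ("R", "Actin", 1, 20.0), ("R", "MYB1", 1, 22.0)]
        out = ddct(self._table(rows), "Actin", "STT")
        rq = {(q.gene, q.sample): q.relative_expression for q in out}
        assert rq[("MYB1", "STT")] == 1.0

    def test_delta_ct_difference_of_two_gives_fourfold(self):
        rows = [("STT", "Actin", 1, 20.0), ("STT", "MYB1", 1, 24.0),
                ("R", "Actin", 1, 20.0), ("R", "MYB1", 1, 22.0)]
        out = ddct(self._table(rows), "Actin", "STT")
        rq = {(q.gene, q.sample): q.relative_expression for q in out}
        # dCt(R)=2 vs dCt(STT)=4 -> RQ = 2^2 = 4
        assert rq[("MYB1", "R")] == pytest.approx(4.0)

    def test_missing_reference_errors(self):
        rows = [("STT", "MYB1", 1, 24.0)]
        with pytest.raises(ValueError):
            ddct(self._table(rows), "Actin", "STT")

    def test_calibrator_is_one_even_with_noise(self):
        ct = generate_qpcr(["MYB1"], ["STT", "R", "LE"],
                           {"MYB1": {"R": 4.0, "LE": 0.5}}, noise_sd=0.3, seed=3)
        out = ddct(ct, "Actin", "STT")
        rq = {(q.gene, q.sample): q.relative_expression for q in out}
        assert rq[("MYB1", "STT")] == 1.0

    def test_planted_folds_recovered_at_low_noise(self):
        folds = {"MYB1": {"R": 4.0, "LE": 0.25}, "MYB2": {"R": 2.0, "LE": 8.0}}
        ct = generate_qpcr(["MYB1", "MYB2"], ["STT", "R", "LE"], folds,
                           noise_sd=0.05, seed=4)
        out = ddct(ct, "Actin", "STT")
        rq = {(q.gene, q.sample): q.relative_expression for q in out}
        for g, spec in folds.items():
            for s, fold in spec.items():
                assert rq[(g, s)] == pytest.approx(fold, rel=0.10)
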