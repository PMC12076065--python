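import numpy as np
import pandas as pd
import pytest
from scipy import stats

from droughtring.lmm import (
    AnimalModel,
    BivariateAnimalModel,
    NormalityTransformer,
    emmeans_tukey,
    genetic_correlation,
    heritability,
    normalize_transform,
    phenotypic_correlations,
)

from conftest import simulate_halfsib_trait


class FakeResult:
    """Minimal REML-result stub for the pure-arithmetic heritability checks."""

    def __init__(self, sa, sb, ss, se_res, cov=None):
        self.G_a = np.array([[sa]])
        self.R = np.array([[se_res]])
        self.factor_variances = {"block_id": np.array([sb]), "set_id": np.array([ss])}
        self.param_labels = [("Ga", 0, 0), ("F", "block_id", 0), ("F", "set_id", 0),
                             ("R", 0, 0)]
        self.cov_params = cov if cov is not None else np.eye(4) * 1e-4


class TestHeritability:
    def test_equal_components_quarter(self):
        h2, _ = heritability(FakeResult(1.0, 1.0, 1.0, 1.0))
        assert h2 == pytest.approx(0.25)

    def test_zero_additive(self):
        h2, _ = heritability(FakeResult(0.0, 1.0, 1.0, 1.0))
        assert h2 == 0.0

    def test_conventional_denominator(self):
        h2, _ = heritability(FakeResult(1.0, 1.0, 1.0, 1.0), denominator="conventional")
        assert h2 == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            heritability(FakeResult(0.0, 0.0, 0.0, 0.0))

    def test_delta_se_close_to_bootstrap(self):
        """Delta-method SE of h2 agrees with a parametric bootstrap."""
        rng = np.random.default_rng(21)
        df, A, _ = simulate_halfsib_trait(rng, 80, 10, sa2=0.6, se2=1.4)
        m = AnimalModel("y", relationship=A, random_effects=(),
                        method="ai", tol=1e-9).fit(df)
        boots = []
        sa, se_res = m.varcomp_["additive"], m.varcomp_["residual"]
        for b in range(30):
            rb = np.random.default_rng(100 + b)
            dfb, Ab, _ = simulate_halfsib_trait(rb, 80, 10, sa2=sa, se2=se_res)
            mb = AnimalModel("y", relationship=Ab, random_effects=(),
                            method="ai", tol=1e-8).fit(dfb)
            boots.append(mb.heritability_)
        assert m.heritability_se_ == pytest.approx(np.std(boots, ddof=1), rel=0.35)


class TestAnimalModel:
    def test_h2_recovery_single_fit(self):
        rng = np.random.default_rng(31)
        df, A, a_true = simulate_halfsib_trait(rng, 100, 15, sa2=0.4, se2=0.6,
                                               sb2=0.1, ss2=0.1)
        m = AnimalModel("y", relationship=A).fit(df)
        # Eq-6-style denominator includes the design variances
        truth = 0.4 / (0.4 + 0.1 + 0.1 + 0.6)
        assert m.heritability_ == pytest.approx(truth, abs=0.12)
        # BLUPs track the true breeding values
        r = np.corrcoef(m.breeding_values_.loc[df["tree_id"]], a_true)[0, 1]
        assert r > 0.5

    def test_blup_accuracy_increases_with_h2(self):
        rs = []
        for sa2, se2 in [(0.1, 1.9), (1.0, 1.0)]:
            rng = np.random.default_rng(41)
            df, A, a_true = simulate_halfsib_trait(rng, 60, 10, sa2=sa2, se2=se2)
            m = AnimalModel("y", relationship=A, random_effects=(), method="ai").fit(df)
            rs.append(np.corrcoef(m.breeding_values_.loc[df["tree_id"]], a_true)[0, 1])
        assert rs[1] > rs[0]

    def test_missing_ids_rejected(self):
        rng = np.random.default_rng(51)
        df, A, _ = simulate_halfsib_trait(rng, 10, 5, sa2=0.5, se2=1.0)
        with pytest.raises(ValueError, match="lacks ids"):
            AnimalModel("y", relationship=A.iloc[:10, :10]).fit(df)


class TestGeneticCorrelation:
    def test_bivariate_estimator(self):
        rng = np.random.default_rng(61)
        s, k = 80, 12
        n = s * k
        fam = np.repeat(np.arange(s), k)
        r_true = -0.6
        Ga = np.array([[0.5, r_true * 0.5], [r_true * 0.5, 0.5]])
        Ld = np.linalg.cholesky(Ga)
        dam = rng.standard_normal((s, 2)) @ Ld.T / 2
        a = dam[fam] + rng.standard_normal((n, 2)) @ Ld.T * np.sqrt(0.75)
        Y = 3.0 + a + rng.standard_normal((n, 2))
        ids = [f"T{i}" for i in range(n)]
        df = pd.DataFrame({"tree_id": ids, "u": Y[:, 0], "v": Y[:, 1]})
        A = np.where(fam[:, None] == fam[None, :], 0.25, 0.0)
        np.fill_diagonal(A, 1.0)
        A = pd.DataFrame(A, index=ids, columns=ids)
        m = BivariateAnimalModel(("u", "v"), relationship=A, random_effects=()).fit(df)
        assert abs(m.genetic_correlation_ - r_true) < 2.5 * m.genetic_correlation_se_ + 0.1

    def test_zero_covariance_not_significant(self):
        class Res:
            G_a = np.array([[0.5, 0.0], [0.0, 0.5]])
            R = np.array([[1.0, 0.0], [0.0, 1.0]])
            param_labels = [("Ga", 0, 0), ("Ga", 0, 1), ("Ga", 1, 1)]
            cov_params = np.eye(3) * 0.01
        r, se = genetic_correlation(Res())
        assert r == 0.0 and abs(r) <= 2 * se

    def test_boundary_variance_undefined(self):
        class Res:
            G_a = np.array([[0.0, 0.0], [0.0, 0.5]])
            R = np.array([[1.0, 0.0], [0.0, 1.0]])
            param_labels = [("Ga", 0, 0), ("Ga", 0, 1), ("Ga", 1, 1)]
            cov_params = np.eye(3)
        r, se = genetic_correlation(Res())
        assert r is None


class TestEMMs:
    def make_data(self, rng, offsets, n_per=150):
        rows = []
        for s, off in offsets.items():
            for i in range(n_per):
                b = f"{s}b{rng.integers(0, 5)}"
                rows.append((s, b, b + f"s{rng.integers(0, 4)}",
                             off + rng.standard_normal()))
        return pd.DataFrame(rows, columns=["site", "block_id", "set_id", "y"])

    def test_identical_sites_share_letter(self):
        rng = np.random.default_rng(71)
        d = self.make_data(rng, {"A": 0.0, "B": 0.0})
        means, _ = emmeans_tukey(d, "y")
        assert means["letters"].nunique() == 1

    def test_two_groups_tukey_equals_t(self):
        # with k = 2 the studentized-range p equals the two-sided t-test p
        rng = np.random.default_rng(72)
        d = self.make_data(rng, {"A": 0.0, "B": 0.35}, n_per=60)
        _, contrasts = emmeans_tukey(d, "y", random_effects=())
        diff, se = contrasts.loc[0, "diff"], contrasts.loc[0, "se"]
        df = len(d) - 2
        p_t = 2 * stats.t.sf(abs(diff) / se, df)
        assert contrasts.loc[0, "p_tukey"] == pytest.approx(p_t, rel=1e-4)

    def test_known_offsets_match_welch_tukey_grouping(self):
        rng = np.random.default_rng(73)
        d = self.make_data(rng, {"A": 0.0, "B": 0.05, "C": 1.2, "D": 2.6}, n_per=200)
        means, contrasts = emmeans_tukey(d, "y", random_effects=())
        by = means.set_index("site")["letters"]
        # brute-force all-pairs Welch t against the studentized range critical value
        k, df = 4, len(d) - 4
        crit = stats.studentized_range.ppf(0.95, k, df)
        groups = {s: d.loc[d["site"] == s, "y"] for s in "ABCD"}
        for a in "ABCD":
            for b in "ABCD":
                if a >= b:
                    continue
                ga, gb = groups[a], groups[b]
                t = abs(ga.mean() - gb.mean()) / np.sqrt(ga.var() / len(ga) + gb.var() / len(gb))
                sig = t * np.sqrt(2) > crit
                share = bool(set(by[a]) & set(by[b]))
                assert share == (not sig)


class TestTransforms:
    def test_normal_sample_untouched(self):
        x = np.random.default_rng(81).standard_normal(500)
        _, chosen = normalize_transform(x)
        assert chosen == "none"

    def test_lognormal_gets_log(self):
        x = np.exp(np.random.default_rng(82).standard_normal(500))
        _, chosen = normalize_transform(x)
        assert chosen == "log"

    def test_constant_vector_none(self):
        _, chosen = normalize_transform(np.full(50, 3.0))
        assert chosen == "none"

    def test_transformer_roundtrip(self):
        x = np.exp(np.random.default_rng(83).standard_normal(300))
        t = NormalityTransformer().fit(x)
        assert np.allclose(t.transform(x), np.log(x))


class TestPhenotypicCorrelations:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(91)
        df = pd.DataFrame({"a": rng.standard_normal(50)})
        df["b"] = df["a"]
        r, p, padj = phenotypic_correlations(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_exact_linear_relationship(self):
        x = np.linspace(0, 1, 40)
        r, _, _ = phenotypic_correlations(pd.DataFrame({"x": x, "y": 2 * x}))
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_bonferroni_controls_false_positives(self):
        rng = np.random.default_rng(92)
        df = pd.DataFrame(rng.standard_normal((120, 15)),
                          columns=[f"t{i}" for i in range(15)])
        r, p, padj = phenotypic_correlations(df)
        k = 15 * 14 // 2  # 105 tested pairs
        raw_hits = (p.to_numpy()[np.triu_indices(15, 1)] < 0.05).sum()
        adj_hits = (padj.to_numpy()[np.triu_indices(15, 1)] < 0.05).sum()
        assert raw_hits <= stats.binom.ppf(0.999, k, 0.05) + 1
        assert adj_hits <= 1

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"a": np.ones(30), "b": np.arange(30.0)})
        r, p, _ = phenotypic_correlations(df)
        assert np.isnan(r.loc["a", "b"])
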