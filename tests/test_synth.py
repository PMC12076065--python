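import numpy as np
import pandas as pd
import pytest
from scipy import stats

from droughtring import synth
from droughtring.rings import bai, decline, drought_indices_table


class TestDesign:
    def test_study_dimensions(self, small_layout):
        counts = small_layout.groupby("family").size()
        assert (counts == 20).all()  # 5 blocks x 4-tree plots

    def test_family_once_per_set_block(self, small_layout):
        per = small_layout.groupby(["family", "block"])["plot"].nunique()
        assert (per == 1).all()

    def test_spacing(self, small_layout):
        xs = np.sort(small_layout["x_m"].unique())
        assert np.allclose(np.diff(xs), 2.5)

    def test_no_mortality_all_alive(self, small_layout):
        assert small_layout["alive"].all()

    def test_mortality_within_binomial_bounds(self):
        lay = synth.simulate_design(n_sites=1, n_families=50, n_sets=5,
                                    mortality_rate=0.5, seed=4)
        n = len(lay)
        k = int(lay["alive"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= k <= hi

    def test_determinism(self):
        a = synth.simulate_design(n_sites=2, n_families=20, n_sets=4, seed=9)
        b = synth.simulate_design(n_sites=2, n_families=20, n_sets=4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_sets_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            synth.simulate_design(n_families=3, n_sets=5)


class TestClimate:
    def test_drought_years_negative_cmi(self):
        clim = synth.simulate_climate(seed=7)
        assert clim.cmi(2002) < 0 and clim.cmi(2010) < 0
        others = [clim.cmi(y) for y in range(1982, 2017) if y not in (2002, 2010)]
        assert np.median(others) > 0

    def test_monthly_annual_consistency(self):
        clim = synth.simulate_climate(seed=3)
        msum = clim.monthly.groupby("year")["precip"].sum()
        for r in clim.annual.itertuples():
            assert msum[r.year] == pytest.approx(r.precip)

    def test_zero_precip_cmi_is_minus_pet(self):
        pet = synth.hargreaves_pet(15.0, 9.0, 21.0, 54.5, 7)
        assert pet > 0  # so P=0 gives CMI = -PET < 0

    def test_precip_equal_pet_gives_zero_cmi(self):
        pet = synth.hargreaves_pet(15.0, 9.0, 21.0, 54.5, 7)
        assert pet - pet == pytest.approx(0.0)

    def test_empty_years_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_climate(years=[])


class TestGenetics:
    def make_ped(self, n_fam=200, k=2):
        rows = [(f"D{f}", None, None, f"F{f}", f"F{f}") for f in range(n_fam)]
        for f in range(n_fam):
            for j in range(k):
                rows.append((f"O{f}_{j}", f"D{f}", None, f"F{f}", f"F{f}"))
        return pd.DataFrame(rows, columns=["id", "dam", "sire", "family", "true_family"])

    def test_zero_variance_zero_bvs(self):
        ped = self.make_ped(5)
        t = synth.simulate_genetics(ped, {"x": dict(sigma_a2=0.0, sigma_block2=0, sigma_set2=0, sigma_e2=1.0)}, seed=1)
        assert (t.breeding_values["x"] == 0).all()

    def test_identity_rg_uncorrelated_founders(self):
        ped = pd.DataFrame({"id": [f"D{i}" for i in range(10000)],
                            "dam": None, "sire": None, "family": "F", "true_family": "F"})
        specs = {t: dict(sigma_a2=1.0, sigma_block2=0, sigma_set2=0, sigma_e2=0) for t in "ab"}
        truth = synth.simulate_genetics(ped, specs, r_g=np.eye(2), seed=2)
        r = np.corrcoef(truth.breeding_values["a"], truth.breeding_values["b"])[0, 1]
        assert abs(r) < 0.03

    def test_halfsib_covariance_quarter(self):
        ped = self.make_ped(4000, k=2)
        specs = {"x": dict(sigma_a2=1.0, sigma_block2=0, sigma_set2=0, sigma_e2=0)}
        truth = synth.simulate_genetics(ped, specs, seed=3)
        bv = truth.breeding_values["x"]
        prods = [bv[f"O{f}_0"] * bv[f"O{f}_1"] for f in range(4000)]
        se = np.std(prods) / np.sqrt(len(prods))
        assert abs(np.mean(prods) - 0.25) < 3 * se

    def test_parent_offspring_covariance_half(self):
        ped = self.make_ped(4000, k=1)
        specs = {"x": dict(sigma_a2=1.0, sigma_block2=0, sigma_set2=0, sigma_e2=0)}
        truth = synth.simulate_genetics(ped, specs, seed=4)
        bv = truth.breeding_values["x"]
        prods = [bv[f"D{f}"] * bv[f"O{f}_0"] for f in range(4000)]
        se = np.std(prods) / np.sqrt(len(prods))
        assert abs(np.mean(prods) - 0.5) < 3 * se

    def test_founder_variance_matches(self):
        ped = pd.DataFrame({"id": [f"D{i}" for i in range(8000)],
                            "dam": None, "sire": None, "family": "F", "true_family": "F"})
        specs = {"x": dict(sigma_a2=2.5, sigma_block2=0, sigma_set2=0, sigma_e2=0)}
        truth = synth.simulate_genetics(ped, specs, seed=5)
        assert truth.breeding_values["x"].var() == pytest.approx(2.5, rel=0.08)

    def test_non_psd_rejected(self):
        ped = self.make_ped(2)
        specs = {t: dict(sigma_a2=1.0, sigma_block2=0, sigma_set2=0, sigma_e2=0) for t in "ab"}
        with pytest.raises(ValueError, match="positive semi-definite"):
            synth.simulate_genetics(ped, specs, r_g=np.array([[1, 2], [2, 1]]), seed=1)


class TestSNPs:
    def test_forced_heterozygote(self):
        # wherever dam is homozygous alt and sire homozygous ref, the
        # offspring must be heterozygous (dosage exactly 1)
        ped = pd.DataFrame({
            "id": ["A", "B", "O"],
            "dam": [None, None, "A"],
            "sire": [None, None, "B"],
            "family": "F", "true_family": "F",
        })
        geno = synth.simulate_snps(ped, n_snps=400, maf_range=(0.5, 0.5), seed=1)
        forced = (geno.loc["A"] == 2.0) & (geno.loc["B"] == 0.0)
        assert forced.sum() > 5
        assert (geno.loc["O"][forced] == 1.0).all()

    def test_no_missing_by_default(self, small_study):
        geno = synth.simulate_snps(small_study["pedigree"].head(50), n_snps=20, seed=2)
        assert not geno.isna().any().any()

    def test_missing_rate(self, small_study):
        geno = synth.simulate_snps(small_study["pedigree"].head(80), n_snps=50,
                                   missing_rate=0.1, seed=3)
        assert geno.isna().to_numpy().mean() == pytest.approx(0.1, abs=0.02)

    def test_invalid_args(self, small_study):
        ped = small_study["pedigree"].head(5)
        with pytest.raises(ValueError):
            synth.simulate_snps(ped, n_snps=0)
        with pytest.raises(ValueError):
            synth.simulate_snps(ped, n_snps=5, maf_range=(0.0, 0.6))


class TestGrowth:
    def zero_noise_params(self, **kw):
        base = dict(noise_sd=0.0, event_env_sd=0.0, recovery_env_sd=0.0,
                    rust_gamma=0.0, comp_coef=0.0, dbh_noise_cm=0.0)
        base.update(kw)
        return synth.GrowthParams(**base)

    def test_no_drought_closed_form_decline(self, small_study):
        """With no drought, no noise and no competition the decline index
        follows in closed form from the age-trend curve."""
        p = self.zero_noise_params()
        series, _ = synth.simulate_growth(
            small_study["layout"].head(40), small_study["climate"],
            small_study["truth"], params=p, seed=1, drought_years=(),
        )
        years = np.arange(1982, 2017)
        ages = years - 1981
        hump = ((ages / p.age_peak) * np.exp(1 - ages / p.age_peak)) ** p.age_shape
        w = p.w_max * hump
        r = np.cumsum(w)
        bai_vals = np.pi * (r**2 - np.concatenate([[0], r[:-1]]) ** 2)
        expect = bai_vals[(years >= 1997) & (years <= 2001)].mean() / \
            bai_vals[(years >= 2012) & (years <= 2016)].mean()
        for s in series.values():
            d = decline(bai(s))
            # per-tree genetic growth multiplier cancels in the ratio
            assert d == pytest.approx(expect, rel=1e-9)

    def test_identity_multiplier_indices_equal_baseline(self, small_study):
        """With every drought multiplier forced to 1 the indices reduce to
        the closed-form age-trend baseline, identical for all trees (the
        drought channels contribute nothing)."""
        import copy

        p = self.zero_noise_params(event_depth=0.0, recovery_depth=0.0,
                                   recovery_base=0.0, persist_coef=0.0)
        truth = copy.deepcopy(small_study["truth"])
        truth.breeding_values["resist"] = 0.0
        truth.breeding_values["recov"] = 0.0
        series, _ = synth.simulate_growth(
            small_study["layout"].head(40), small_study["climate"], truth, params=p, seed=1
        )
        idx = drought_indices_table(series)
        years = np.arange(1982, 2017)
        ages = years - 1981
        w = p.w_max * ((ages / p.age_peak) * np.exp(1 - ages / p.age_peak)) ** p.age_shape
        r = np.cumsum(w)
        bai_vals = np.pi * (r**2 - np.concatenate([[0], r[:-1]]) ** 2)

        def wmean(a, b):
            return bai_vals[(years >= a) & (years <= b)].mean()

        expect_resist = bai_vals[years == 2002][0] / wmean(1998, 2001)
        expect_resil = wmean(2011, 2014) / wmean(2006, 2009)
        assert np.allclose(idx["resistance_2002"], expect_resist)
        assert np.allclose(idx["resilience_2010"], expect_resil)
        assert idx["resistance_2002"].nunique() == 1  # identical across trees

    def test_lower_recovery_means_larger_decline(self, small_study):
        import copy

        p = self.zero_noise_params()
        lay = small_study["layout"].head(8).copy()
        truth = copy.deepcopy(small_study["truth"])
        ids = lay["tree_id"].tolist()
        truth.breeding_values.loc[ids, ["resist", "recov", "height", "d13c", "density"]] = 0.0
        truth.breeding_values.loc[ids[0], "recov"] = -0.2   # slow recoverer
        truth.breeding_values.loc[ids[1], "recov"] = +0.2   # fast recoverer
        series, _ = synth.simulate_growth(lay, small_study["climate"], truth, params=p, seed=1)
        d_slow = decline(bai(series[ids[0]]))
        d_fast = decline(bai(series[ids[1]]))
        assert d_slow > d_fast

    def test_missing_climate_years_rejected(self, small_study):
        clim = synth.simulate_climate(years=range(1982, 2000), drought_years=(1990,), seed=1)
        with pytest.raises(ValueError, match="drought"):
            synth.simulate_growth(small_study["layout"].head(8), clim,
                                  small_study["truth"], seed=1, drought_years=(2002,))

    def test_fixed_seed_byte_identical(self, small_study):
        kw = dict(layout=small_study["layout"].head(20), climate=small_study["climate"],
                  truth=small_study["truth"], seed=42)
        s1, t1 = synth.simulate_growth(**kw)
        s2, t2 = synth.simulate_growth(**kw)
        pd.testing.assert_frame_equal(t1, t2)
        for tid in s1:
            assert np.array_equal(s1[tid].widths, s2[tid].widths)


class TestDensityProfileGenerator:
    def test_sample_count_arithmetic(self):
        prof = synth.simulate_density_profile([2.54, 2.54], step=0.0254)
        assert prof.n_samples == 200

    def test_zero_noise_piecewise_constant(self):
        prof = synth.simulate_density_profile([1.0, 1.5, 2.0], noise_sd=0.0)
        vals = set(np.round(prof.density, 6))
        assert vals == {350.0, 650.0}

    def test_weighted_mean_density(self):
        prof = synth.simulate_density_profile([2.54], ew_density=350, lw_density=650,
                                              ew_fraction=0.5, noise_sd=0.0)
        assert prof.density.mean() == pytest.approx(500.0)

    def test_narrow_ring_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_density_profile([0.03], step=0.0254)
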