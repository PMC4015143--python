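"""Accuracy measures, LOOCV, heritability, robust correlation, meta-analysis,
tissue F statistics, enrichment, coefficient of variation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epiclock import (
    BetaMatrix,
    SampleTable,
    accuracy_report,
    biweight_midcorrelation,
    category_enrichment,
    coefficient_of_variation,
    falconer_heritability,
    fit_clock,
    loocv_by_dataset,
    meta_analysis_age_correlation,
    tissue_f_statistics,
)
from oracles import fisher_two_sided_by_enumeration
from epiclock.synthetic_data import (
    SimConfig,
    simulate_methylome,
    simulate_twin_cohort,
    twin_pairs_with_exact_correlations,
)


class TestAccuracyReport:
    def test_perfect_prediction(self):
        rep = accuracy_report([5, 10, 20], [5, 10, 20])
        assert rep.age_correlation == pytest.approx(1.0)
        assert rep.median_error == 0.0
        assert rep.average_age_acceleration == 0.0

    def test_hand_example(self):
        rep = accuracy_report([5, 10, 20], [6, 12, 18])
        assert rep.median_error == pytest.approx(2.0)  # median of {1, 2, 2}
        assert rep.average_age_acceleration == pytest.approx(-1 / 3)

    def test_even_n_median_is_mean_of_middle_two(self):
        rep = accuracy_report([1, 2, 3, 10], [0, 0, 0, 0])
        assert rep.median_error == pytest.approx(2.5)

    def test_median_error_bounds_majority_of_subjects(self):
        # an error of e means |dnam - age| <= e in at least 50% of subjects
        rng = np.random.default_rng(0)
        ages = rng.uniform(0, 90, 201)
        dnam = ages + rng.normal(0, 6, 201)
        rep = accuracy_report(dnam, ages)
        frac_within = np.mean(np.abs(dnam - ages) <= rep.median_error)
        assert frac_within >= 0.5

    def test_constant_age_correlation_undefined_not_zero(self):
        rep = accuracy_report([4.0, 5.0, 6.0], [5.0, 5.0, 5.0])
        assert np.isnan(rep.age_correlation)
        assert rep.median_error == 1.0

    def test_median_error_shift_invariance(self):
        d = np.array([3.0, 9.0, 27.0])
        a = np.array([1.0, 8.0, 30.0])
        r1 = accuracy_report(d, a)
        r2 = accuracy_report(d + 7.5, a + 7.5)
        assert r1.median_error == pytest.approx(r2.median_error)

    def test_missing_pairs_dropped(self):
        rep = accuracy_report([10.0, np.nan, 30.0], [12.0, 20.0, np.nan])
        assert rep.n == 1
        assert rep.median_error == pytest.approx(2.0)


class TestFalconer:
    def test_published_newborn_correlations_clamp_to_one(self):
        # cor(MZ) = 0.77, cor(DZ) = -0.21 -> 2 * 0.98 = 1.96, clamped to 1
        pairs = twin_pairs_with_exact_correlations(0.77, -0.21, n_pairs=12, seed=0)
        est = falconer_heritability(pairs)
        assert est.cor_mz == pytest.approx(0.77, abs=1e-9)
        assert est.cor_dz == pytest.approx(-0.21, abs=1e-9)
        assert est.h2 == 1.0

    def test_equal_correlations_give_zero(self):
        pairs = twin_pairs_with_exact_correlations(0.5, 0.5, n_pairs=10, seed=1)
        est = falconer_heritability(pairs)
        assert est.h2 == pytest.approx(0.0, abs=1e-12)

    def test_clamped_to_unit_interval(self):
        for r_mz, r_dz in [(0.1, 0.9), (-0.5, 0.5), (0.99, -0.99)]:
            pairs = twin_pairs_with_exact_correlations(r_mz, r_dz, seed=2)
            est = falconer_heritability(pairs)
            assert 0.0 <= est.h2 <= 1.0

    def test_monte_carlo_recovery_of_additive_share(self):
        # acceleration = g + e with genetic share 0.5
        ests = []
        for seed in range(20):
            pairs = simulate_twin_cohort(500, 500, h2=0.5, seed=seed)
            ests.append(falconer_heritability(pairs, seed=seed).h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.15)

    def test_missing_zygosity_excluded_with_count(self):
        pairs = twin_pairs_with_exact_correlations(0.6, 0.3, n_pairs=8, seed=3)
        pairs.loc[0, "zygosity"] = np.nan
        pairs.loc[1, "zygosity"] = np.nan
        est = falconer_heritability(pairs)
        assert est.n_excluded == 2

    def test_too_few_pairs_rejected(self):
        pairs = simulate_twin_cohort(2, 5, h2=0.5, seed=0)
        with pytest.raises(ValueError, match="MZ"):
            falconer_heritability(pairs)


class TestBiweightMidcorrelation:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 3.0, 2.0, 8.0, 5.0])
        assert biweight_midcorrelation(x, x) == pytest.approx(1.0)
        assert biweight_midcorrelation(x, -x) == pytest.approx(-1.0)

    def test_equals_pearson_when_no_outliers(self):
        # all |u| < 1 yet weights are not all equal; agreement is approximate
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 1000)
        y = 0.5 * x + np.sqrt(0.75) * rng.normal(0, 1, 1000)
        bicor = biweight_midcorrelation(x, y)
        pearson = np.corrcoef(x, y)[0, 1]
        assert bicor == pytest.approx(pearson, abs=0.05)

    def test_robust_to_gross_outliers(self):
        rng = np.random.default_rng(2)
        n = 1000
        x = rng.normal(0, 1, n)
        y = 0.5 * x + np.sqrt(0.75) * rng.normal(0, 1, n)
        true_r = 0.5
        idx = rng.choice(n, size=20, replace=False)
        xc, yc = x.copy(), y.copy()
        xc[idx] = rng.uniform(50, 100, 20)
        yc[idx] = rng.uniform(-100, -50, 20)
        bicor = biweight_midcorrelation(xc, yc)
        pearson = np.corrcoef(xc, yc)[0, 1]
        assert abs(bicor - true_r) < abs(pearson - true_r)

    def test_zero_mad_falls_back_gracefully(self):
        # one vector mostly constant: MAD = 0 -> mean-centered fallback
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0])
        y = np.array([0.0, 0.1, 0.2, 0.3, 1.0])
        r = biweight_midcorrelation(x, y)
        assert -1.0 <= r <= 1.0 and np.isfinite(r)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            biweight_midcorrelation([1, 2], [3, 4])


def _cohort_for_meta(n_datasets=2, n=60, n_probes=100, age_effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:05d}" for i in range(n_probes)]
    ids, ages, ds = [], [], []
    for k in range(n_datasets):
        for j in range(n):
            ids.append(f"d{k}s{j}")
            ds.append(f"D{k}")
    ages = rng.uniform(0, 90, len(ids))
    base = rng.uniform(0.2, 0.8, n_probes)
    vals = np.tile(base[:, None], (1, len(ids))) + rng.normal(0, 0.05, (n_probes, len(ids)))
    if age_effect:
        vals[0] += age_effect * (ages - 45) / 90
    vals = np.clip(vals, 0, 1)
    bm = BetaMatrix(pd.DataFrame(vals, index=probes, columns=ids))
    st = SampleTable(pd.DataFrame({"age": ages, "dataset_id": ds},
                                  index=pd.Index(ids, name="sample_id")))
    return bm, st


class TestMetaAnalysis:
    def test_single_dataset_reduces_to_fisher_z_statistic(self):
        bm, st = _cohort_for_meta(n_datasets=1, n=40, n_probes=5, seed=1)
        res = meta_analysis_age_correlation(bm, st)
        r = res.table["r_D0"]
        z_expected = np.sqrt(40 - 3) * np.arctanh(r)
        np.testing.assert_allclose(res.table["combined_z"], z_expected, atol=1e-9)

    def test_sign_convention_positive_slope(self):
        bm, st = _cohort_for_meta(n_datasets=2, age_effect=0.4, seed=2)
        res = meta_analysis_age_correlation(bm, st)
        assert res.table.loc["cg00000", "signed_log10_p"] > 0
        assert res.table.loc["cg00000", "combined_z"] > 0

    def test_sign_matches_z(self):
        bm, st = _cohort_for_meta(n_datasets=2, seed=3)
        res = meta_analysis_age_correlation(bm, st)
        t = res.table.dropna(subset=["combined_z"])
        nonzero = t[t["combined_z"] != 0]
        assert (np.sign(nonzero["signed_log10_p"]) == np.sign(nonzero["combined_z"])).all()

    def test_null_type_i_error_calibrated(self):
        # no age effect anywhere: ~5% of probes at |p| < 0.05
        fracs = []
        for seed in range(10):
            bm, st = _cohort_for_meta(n_datasets=2, n=50, n_probes=200, seed=100 + seed)
            res = meta_analysis_age_correlation(bm, st)
            p = 10.0 ** (-res.table["signed_log10_p"].abs())
            fracs.append(float((p < 0.05).mean()))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)

    def test_probe_missing_in_one_dataset_still_combined(self):
        bm, st = _cohort_for_meta(n_datasets=2, n=30, n_probes=4, seed=4)
        v = bm.values.copy()
        d0_cols = [c for c in v.columns if c.startswith("d0")]
        v.loc["cg00002", d0_cols] = np.nan
        res = meta_analysis_age_correlation(BetaMatrix(v), st)
        row = res.table.loc["cg00002"]
        assert np.isnan(row["r_D0"]) and np.isfinite(row["r_D1"])
        assert np.isfinite(row["combined_z"])


class TestTissueF:
    def _cohort(self, tissue_shift=0.0, n=120, n_probes=40, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{j}" for j in range(n)]
        tissue = np.where(np.arange(n) % 2 == 0, "blood", "brain")
        # tissues get different age distributions (confounding structure)
        ages = np.where(tissue == "blood",
                        rng.uniform(0, 50, n), rng.uniform(30, 90, n))
        base = rng.uniform(0.3, 0.7, n_probes)
        vals = np.tile(base[:, None], (1, n)) + rng.normal(0, 0.04, (n_probes, n))
        vals[0] += np.where(tissue == "brain", tissue_shift, -tissue_shift)
        vals = np.clip(vals, 0, 1)
        bm = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i:04d}" for i in range(n_probes)],
                                     columns=ids))
        st = SampleTable(pd.DataFrame({"age": ages, "tissue": tissue},
                                      index=pd.Index(ids, name="sample_id")))
        return bm, st

    def test_null_f_values_small(self):
        bm, st = self._cohort(tissue_shift=0.0, seed=1)
        f = tissue_f_statistics(bm, st)
        crit = sps.f.ppf(0.95, 1, len(st) - 3)
        assert f.median() <= crit

    def test_tissue_offset_detected(self):
        bm, st = self._cohort(tissue_shift=0.2, seed=2)
        f = tissue_f_statistics(bm, st)
        null_f = f.drop("cg0000")
        assert f["cg0000"] > np.quantile(null_f, 0.99)
        assert f["cg0000"] > sps.f.ppf(0.999, 1, len(st) - 3)

    def test_one_tissue_rejected(self):
        bm, st = self._cohort()
        st.data["tissue"] = "blood"
        with pytest.raises(ValueError):
            tissue_f_statistics(bm, st)

    def test_f_nonnegative(self):
        bm, st = self._cohort(seed=3)
        f = tissue_f_statistics(bm, st).dropna()
        assert (f >= 0).all()


class TestEnrichment:
    def test_matches_hypergeometric_enumeration(self):
        # tables with totals <= 30, including the 8/2/1/9 example
        tables = [(8, 2, 1, 9), (3, 7, 6, 4), (0, 10, 10, 0), (5, 5, 5, 5),
                  (1, 0, 0, 1), (12, 3, 2, 13)]
        for a, b, c, d in tables:
            selected = {f"s{i}" for i in range(a + b)}
            others = {f"o{i}" for i in range(c + d)}
            universe = selected | others
            cats = {f"s{i}": "cat" for i in range(a)}
            cats.update({f"o{i}": "cat" for i in range(c)})
            cats.update({p: "other" for p in universe if p not in cats})
            res = {r.category: r for r in category_enrichment(selected, cats, universe)}
            got = res["cat"]
            assert (got.a, got.b, got.c, got.d) == (a, b, c, d)
            want = fisher_two_sided_by_enumeration(a, b, c, d)
            assert got.p_value == pytest.approx(want, rel=1e-9)

    def test_selected_equals_universe(self):
        universe = {"p1", "p2", "p3"}
        res = category_enrichment(universe, {"p1": "isl"}, universe)
        assert res[0].p_value == pytest.approx(1.0)

    def test_disjoint_category_odds_zero(self):
        universe = {f"p{i}" for i in range(10)}
        selected = {"p0", "p1"}
        cats = {"p5": "shore", "p6": "shore"}
        res = {r.category: r for r in category_enrichment(selected, cats, universe)}
        assert res["shore"].odds_ratio == 0.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            category_enrichment(set(), {}, set())

    def test_direction_split_runs_independently(self):
        universe = {f"p{i}" for i in range(20)}
        pos = {f"p{i}" for i in range(0, 6)}
        neg = {f"p{i}" for i in range(6, 10)}
        cats = {f"p{i}": "shore" for i in range(4, 12)}
        r_pos = category_enrichment(pos, cats, universe)
        r_neg = category_enrichment(neg, cats, universe)
        assert r_pos[0].a == 2 and r_neg[0].a == 4


class TestCoefficientOfVariation:
    def test_constant_vector(self):
        assert coefficient_of_variation([7.0, 7.0, 7.0]) == 0.0

    def test_hand_example(self):
        assert coefficient_of_variation([30.0, 40.0, 50.0]) == pytest.approx(0.25)

    def test_scale_invariance(self):
        v = [12.0, 20.0, 33.0]
        assert coefficient_of_variation(v) == pytest.approx(
            coefficient_of_variation([3.5 * x for x in v])
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


@pytest.fixture(scope="module")
def multi_dataset_cohort():
    cfg = SimConfig(n_samples=180, n_probes=250, n_causal=40,
                    n_datasets=3, seed=9)
    return simulate_methylome(cfg)


class TestLOOCV:
    def test_loocv_close_to_within_set_accuracy(self, multi_dataset_cohort):
        betas, samples, _ = multi_dataset_cohort
        reports, summary, models = loocv_by_dataset(
            betas, samples, seed=9, cv_folds=5)
        assert set(summary.index) == {"D00", "D01", "D02"}
        # datasets are statistically identical, so each fold generalizes
        for rep in reports.values():
            assert rep.age_correlation > 0.85

    def test_loocv_never_uses_held_out_data(self, multi_dataset_cohort):
        betas, samples, _ = multi_dataset_cohort
        _, _, models = loocv_by_dataset(betas, samples, seed=9, cv_folds=5)
        poisoned = samples.data.copy()
        held = poisoned["dataset_id"] == "D00"
        rng = np.random.default_rng(0)
        poisoned.loc[held, "age"] = rng.uniform(0, 101, int(held.sum()))
        _, _, models2 = loocv_by_dataset(
            betas, SampleTable(poisoned), seed=9, cv_folds=5)
        assert models["D00"].coefficients == models2["D00"].coefficients
        assert models["D00"].intercept == models2["D00"].intercept

    def test_constant_age_dataset_r_missing_error_reported(self, multi_dataset_cohort):
        betas, samples, _ = multi_dataset_cohort
        newborns = samples.data.copy()
        held = newborns["dataset_id"] == "D02"
        newborns.loc[held, "age"] = 0.0
        reports, summary, _ = loocv_by_dataset(
            betas, SampleTable(newborns), seed=9, cv_folds=5)
        assert np.isnan(reports["D02"].age_correlation)
        assert np.isfinite(reports["D02"].median_error)

    def test_requires_two_datasets(self):
        cfg = SimConfig(n_samples=60, n_probes=50, n_causal=10, seed=2)
        betas, samples, _ = simulate_methylome(cfg)
        with pytest.raises(ValueError):
            loocv_by_dataset(betas, samples)
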