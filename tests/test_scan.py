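"""Residualization, logistic scanning, BH adjustment and scan variants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from microscan.scan import (
    bh_adjust,
    benjamini_hochberg,
    logistic_scan,
    residualize,
    run_scan_variants,
)
from microscan.synthetic import SimConfig, simulate_cohort


def _covariates(n, rng, constant=False):
    if constant:
        return pd.DataFrame(
            {
                "age": np.full(n, 60.0),
                "bmi": np.full(n, 26.0),
                "sequencing_depth": np.full(n, 20000.0),
                "sex": ["F"] * n,
                "dna_extractor": ["e1"] * n,
                "collection_method": ["m1"] * n,
                "sequencing_run": ["r1"] * n,
                "family_id": [f"f{i}" for i in range(n)],
            },
            index=[f"s{i}" for i in range(n)],
        )
    return pd.DataFrame(
        {
            "age": rng.normal(60, 12, n),
            "bmi": rng.normal(26, 5, n),
            "sequencing_depth": rng.lognormal(10, 0.5, n),
            "sex": rng.choice(["F", "M"], n),
            "dna_extractor": rng.choice(["e1", "e2", "e3"], n),
            "collection_method": rng.choice(["m1", "m2"], n),
            "sequencing_run": rng.choice([f"r{k}" for k in range(6)], n),
            "family_id": [f"f{i // 2}" for i in range(n)],
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestResidualize:
    @pytest.mark.parametrize("engine", ["ols", "lmm"])
    def test_constant_covariates_give_demeaned_trait(self, rng, engine):
        cov = _covariates(50, rng, constant=True)
        traits = pd.DataFrame({"t": rng.normal(size=50)}, index=cov.index)
        with pytest.warns(UserWarning, match="single level"):
            resid = residualize(traits, cov, engine=engine)
        expected = traits["t"] - traits["t"].mean()
        assert np.allclose(resid["t"], expected, atol=1e-6)

    def test_age_signal_removed(self, rng):
        cov = _covariates(2000, rng)
        traits = pd.DataFrame(
            {"t": 2.0 * cov["age"] + rng.normal(size=2000)}, index=cov.index
        )
        resid = residualize(traits, cov, engine="ols")
        assert abs(np.corrcoef(resid["t"], cov["age"])[0, 1]) < 0.02
        assert abs(resid["t"].mean()) < 1e-8 * resid["t"].std()

    def test_batch_shift_removed(self, rng):
        cov = _covariates(1000, rng)
        shift = (cov["sequencing_run"] == "r3").astype(float)
        traits = pd.DataFrame({"t": rng.normal(size=1000) + shift}, index=cov.index)
        resid = residualize(traits, cov, engine="ols")
        means = resid["t"].groupby(cov["sequencing_run"]).mean()
        assert means.abs().max() < 0.1 * resid["t"].std()

    def test_lmm_close_to_ols_and_shrinks_family_effect(self, small_cohort):
        traits = small_cohort.traits.iloc[:, :3]
        lmm = residualize(traits, small_cohort.covariates, engine="lmm")
        ols = residualize(traits, small_cohort.covariates, engine="ols")
        for c in traits.columns:
            assert np.corrcoef(lmm[c], ols[c])[0, 1] > 0.9

    def test_missing_covariates_rejected(self, rng):
        cov = _covariates(20, rng)
        traits = pd.DataFrame({"t": np.arange(25.0)}, index=[f"s{i}" for i in range(25)])
        with pytest.raises(ValueError, match="missing"):
            residualize(traits, cov)

    def test_unknown_variant_rejected(self, rng):
        cov = _covariates(20, rng)
        traits = pd.DataFrame({"t": rng.normal(size=20)}, index=cov.index)
        with pytest.raises(ValueError, match="variant"):
            residualize(traits, cov, variant="bogus")


class TestLogisticScan:
    def test_planted_effect_detected_with_correct_sign(self, small_cohort):
        resid = residualize(small_cohort.traits, small_cohort.covariates, engine="ols")
        res = logistic_scan(small_cohort.phenotypes, resid)
        row = res[(res.phenotype == "disease_a") & (res.trait == "block01_t1")].iloc[0]
        assert row.status == "ok"
        assert row.p < 1e-4
        assert row.beta > 0
        neg = res[(res.phenotype == "disease_b") & (res.trait == "block02_t1")].iloc[0]
        assert neg.beta < 0 and neg.p < 1e-4

    def test_null_pvalues_uniform(self):
        cfg = SimConfig(
            n_individuals=800, n_twin_pairs=200,
            phenotype_specs=[(f"p{i}", 0.1 + 0.03 * i) for i in range(5)],
            n_trait_blocks=10, traits_per_block=1, within_block_rho=0.0,
            seed=314,
        )
        fx = simulate_cohort(cfg)
        resid = residualize(fx.traits, fx.covariates, engine="ols")
        res = logistic_scan(fx.phenotypes, resid)
        p = res.loc[res.status == "ok", "p"]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_null_pvalues_uniform_across_replicates(self):
        """KS uniformity holds in nearly all null replicates.

        Independent traits are used because the KS test's nominal size
        assumes independent p-values; block-correlated traits inflate the
        KS statistic without any miscalibration of the individual tests.
        """
        ks_pass = 0
        for rep in range(40):
            cfg = SimConfig(
                n_individuals=500, n_twin_pairs=125,
                phenotype_specs=[(f"p{i}", 0.1 + 0.02 * i) for i in range(10)],
                n_trait_blocks=20, traits_per_block=1, within_block_rho=0.0,
                seed=90_000 + rep,
            )
            fx = simulate_cohort(cfg)
            resid = residualize(fx.traits, fx.covariates, engine="ols")
            res = logistic_scan(fx.phenotypes, resid)
            p = res.loc[res.status == "ok", "p"]
            if stats.kstest(p, "uniform").pvalue > 0.01:
                ks_pass += 1
        assert ks_pass / 40 >= 0.95

    def test_perfect_separation_flagged(self, rng):
        x = np.concatenate([rng.normal(-3, 0.1, 30), rng.normal(3, 0.1, 30)])
        y = np.array([0.0] * 30 + [1.0] * 30)
        idx = [f"s{i}" for i in range(60)]
        res = logistic_scan(
            pd.DataFrame({"d": y}, index=idx), pd.DataFrame({"t": x}, index=idx)
        )
        assert res.iloc[0].status in {"separated", "unconverged"}

    def test_zero_cases_skipped_not_dropped(self, rng):
        idx = [f"s{i}" for i in range(40)]
        res = logistic_scan(
            pd.DataFrame({"d": np.zeros(40)}, index=idx),
            pd.DataFrame({"t": rng.normal(size=40)}, index=idx),
        )
        assert len(res) == 1
        assert res.iloc[0].status == "skipped"
        assert res.iloc[0].n_cases == 0

    def test_unknown_statuses_excluded_pairwise(self, rng):
        y = np.array([1.0, 0.0] * 20 + [np.nan] * 10)
        idx = [f"s{i}" for i in range(50)]
        res = logistic_scan(
            pd.DataFrame({"d": y}, index=idx),
            pd.DataFrame({"t": rng.normal(size=50)}, index=idx),
        )
        assert res.iloc[0].n_cases + res.iloc[0].n_controls == 40


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_pvalue_unchanged(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_monotone_nondecreasing_in_sorted_p(self, rng):
        p = np.sort(rng.random(50))
        q = benjamini_hochberg(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_agrees_with_statsmodels(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])

    def test_bh_adjust_scopes_and_exclusions(self, small_cohort):
        resid = residualize(small_cohort.traits, small_cohort.covariates, engine="ols")
        res = logistic_scan(small_cohort.phenotypes, resid)
        res_global = bh_adjust(res, scope="global")
        ok = res_global.status == "ok"
        assert (res_global.loc[ok, "q"] >= res_global.loc[ok, "p"] - 1e-15).all()
        assert res_global.loc[~ok, "q"].isna().all()
        res_pp = bh_adjust(res, scope="per_phenotype")
        one = res_pp[(res_pp.phenotype == "disease_a") & ok]
        assert np.allclose(
            one["q"], benjamini_hochberg(one["p"].to_numpy()), atol=1e-12
        )


class TestScanVariants:
    def test_variant_labels_and_cross_correlation(self, small_cohort):
        scan = run_scan_variants(
            small_cohort.phenotypes, small_cohort.traits, small_cohort.covariates,
            engine="ols",
        )
        assert set(scan.results) == {"full", "no_bmi", "no_age", "neither"}
        for variant, res in scan.results.items():
            assert (res["variant"] == variant).all()
        # no age/BMI confounding planted: betas nearly identical across variants
        off = scan.beta_correlations.to_numpy()[np.triu_indices(4, k=1)]
        assert (off > 0.95).all()

    def test_deterministic_given_inputs(self, small_cohort):
        kwargs = dict(engine="ols", variants=("full",))
        a = run_scan_variants(small_cohort.phenotypes, small_cohort.traits,
                              small_cohort.covariates, **kwargs)
        b = run_scan_variants(small_cohort.phenotypes, small_cohort.traits,
                              small_cohort.covariates, **kwargs)
        pd.testing.assert_frame_equal(a.results["full"], b.results["full"])
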