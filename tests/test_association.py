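import numpy as np
import pandas as pd
import pytest

from rohburden.association import (
    build_covariates,
    compute_grm,
    fit_logistic,
    grm_pcs,
    interaction_test,
    or_per_percent,
    per_dataset_fits,
    sweep_association,
    wald_p,
)
from rohburden.roh import ROHSegment, ROHSet, ThresholdGrid
from rohburden.synthetic_cohort import simulate_phenotype_cohort

from .conftest import make_matrix


class TestClosedForms:
    def test_or_per_percent_paper_slopes(self):
        assert or_per_percent(16.1) == pytest.approx(17.468, abs=1e-3)
        assert round(or_per_percent(16.1)) == 17
        assert or_per_percent(0.0) == 0.0
        assert or_per_percent(4.86) == pytest.approx(100 * (np.exp(0.0486) - 1), abs=1e-9)

    def test_or_per_percent_monotone(self):
        betas = np.linspace(-30, 30, 61)
        vals = [or_per_percent(b) for b in betas]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_wald_p_values(self):
        assert wald_p(0.0) == 1.0
        assert wald_p(3.44) == pytest.approx(5.8e-4, abs=3e-5)
        assert round(wald_p(2.40), 2) == 0.02
        assert wald_p(-1.42) == wald_p(1.42)


class TestGrm:
    def test_duplicate_samples_offdiag_matches_diag(self, rng):
        calls = rng.binomial(2, rng.uniform(0.2, 0.5, 2000), size=(10, 2000)).astype(np.int8)
        calls[1] = calls[0]
        m = make_matrix(calls, np.arange(1, 2001) * 1000)
        g = compute_grm(m)
        assert g[0, 1] == pytest.approx(g[0, 0], rel=1e-9)

    def test_independent_simulants_sampling_variance(self, rng):
        n, m_snps = 40, 5000
        calls = rng.binomial(2, rng.uniform(0.2, 0.5, m_snps), size=(n, m_snps)).astype(np.int8)
        g = compute_grm(make_matrix(calls, np.arange(1, m_snps + 1) * 1000))
        off = g[np.triu_indices(n, k=1)]
        # in-sample allele frequencies center the off-diagonals at -1/(n-1)
        assert off.mean() == pytest.approx(-1 / (n - 1), abs=0.01)
        assert off.std() == pytest.approx(1 / np.sqrt(m_snps), rel=0.35)

    def test_hand_computed_toy(self):
        calls = np.array([[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 0]], dtype=np.int8)
        m = make_matrix(calls, [100, 200, 300, 400])
        g = compute_grm(m)
        # independent double-loop oracle with observed allele frequencies
        X = calls.astype(float)
        p = X.mean(axis=0) / 2
        expected = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                vals = [
                    (X[i, k] - 2 * p[k]) * (X[j, k] - 2 * p[k]) / (2 * p[k] * (1 - p[k]))
                    for k in range(4)
                ]
                expected[i, j] = np.mean(vals)
        np.testing.assert_allclose(g, expected, rtol=1e-12)


class TestGrmPcs:
    def test_two_clusters_separated_by_pc1(self, rng):
        m_snps = 800
        p1 = rng.uniform(0.1, 0.4, m_snps)
        p2 = np.clip(p1 + rng.choice([-0.25, 0.25], m_snps), 0.05, 0.95)
        calls = np.vstack([
            rng.binomial(2, p1, size=(15, m_snps)),
            rng.binomial(2, p2, size=(15, m_snps)),
        ]).astype(np.int8)
        g = compute_grm(make_matrix(calls, np.arange(1, m_snps + 1) * 500))
        pcs = grm_pcs(g, k=2)
        pc1 = pcs[:, 0]
        assert (pc1[:15].mean() > 0) != (pc1[15:].mean() > 0)
        assert abs(pc1[:15].mean() - pc1[15:].mean()) > 3 * (pc1[:15].std() + pc1[15:].std())

    def test_k_zero_empty(self):
        assert grm_pcs(np.eye(4), k=0).shape == (4, 0)

    def test_k_equals_n_reconstructs(self, rng):
        calls = rng.binomial(2, rng.uniform(0.2, 0.5, 500), size=(8, 500)).astype(np.int8)
        g = compute_grm(make_matrix(calls, np.arange(1, 501) * 100))
        pcs = grm_pcs(g, k=8)
        np.testing.assert_allclose(pcs @ pcs.T, g, atol=1e-8)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            grm_pcs(np.eye(3), k=4)

    def test_deterministic_sign(self, rng):
        g = compute_grm(make_matrix(
            rng.binomial(2, rng.uniform(0.2, 0.5, 400), size=(10, 400)).astype(np.int8),
            np.arange(1, 401) * 100))
        a, b = grm_pcs(g, 3), grm_pcs(g, 3)
        np.testing.assert_array_equal(a, b)
        for j in range(3):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # exposed: 30 cases / 10 controls; unexposed: 70 cases / 90 controls
        y = np.array([1] * 30 + [0] * 10 + [1] * 70 + [0] * 90)
        x = np.array([1.0] * 40 + [0.0] * 160)
        res = fit_logistic(y, x)
        assert res.beta == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-8)
        assert res.converged

    def test_constant_froh_aliased(self):
        y = np.array([0, 1] * 20)
        with pytest.warns(UserWarning, match="aliased"):
            res = fit_logistic(y, np.full(40, 0.01))
        assert res.aliased and not res.converged
        assert np.isnan(res.beta) and res.p == 1.0

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 500
        froh = rng.exponential(0.005, n)
        cov = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        ds = np.repeat(["a", "b"], n // 2)
        eta = -0.2 + 12 * froh + 0.3 * cov["c1"].to_numpy()
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        res = fit_logistic(y, froh, cov, ds)

        X = np.column_stack([np.ones(n), froh, cov["c1"], cov["c2"], (ds == "b").astype(float)])
        fit = sm.Logit(y, X).fit(disp=0)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-6)
        assert res.se == pytest.approx(fit.bse[1], rel=1e-5)

    def test_separation_flagged(self):
        y = np.array([0] * 20 + [1] * 20)
        froh = np.array([0.0] * 20 + [0.02] * 20)
        res = fit_logistic(y, froh)
        assert res.separated
        assert res.se == np.inf and res.p == 1.0

    def test_coverage_small_scale(self, rng):
        covered = 0
        n_reps = 40
        for _ in range(n_reps):
            df = simulate_phenotype_cohort({"s": 4000}, beta_true=16.1,
                                           froh_mean=0.005, intercept=-0.08, rng=rng)
            res = fit_logistic(df["y"].to_numpy(), df["froh"].to_numpy())
            lo, hi = res.ci95
            covered += lo <= 16.1 <= hi
        assert covered >= int(0.85 * n_reps)  # loose band at this scale

    def test_nonbinary_y_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.array([0, 1, 2]), np.zeros(3))


class TestInteraction:
    def test_constant_flag_rejected(self, rng):
        df = simulate_phenotype_cohort({"s": 100}, rng=rng)
        with pytest.raises(ValueError, match="constant"):
            interaction_test(df["y"].to_numpy(), df["froh"].to_numpy(), None,
                             np.ones(100))

    def test_null_interaction_centered(self, rng):
        zs = []
        for _ in range(20):
            df = simulate_phenotype_cohort({"a": 1500, "b": 1500}, beta_true=10.0,
                                           froh_mean=0.005, rng=rng)
            flag = (df["dataset_id"] == "b").astype(float).to_numpy()
            res = interaction_test(df["y"].to_numpy(), df["froh"].to_numpy(),
                                   None, flag, df["dataset_id"].to_numpy())
            zs.append(res.z)
        assert abs(np.mean(zs)) < 1.0

    def test_differential_effect_negative_sign(self, rng):
        # stratum a: strong effect; stratum b: none -> negative product term
        a = simulate_phenotype_cohort({"a": 20000}, beta_true=30.0,
                                      froh_mean=0.005, rng=rng)
        b = simulate_phenotype_cohort({"b": 20000}, beta_true=0.0,
                                      froh_mean=0.005, rng=rng)
        df = pd.concat([a, b], ignore_index=True)
        flag = (df["dataset_id"] == "b").astype(float).to_numpy()
        res = interaction_test(df["y"].to_numpy(), df["froh"].to_numpy(),
                               None, flag, df["dataset_id"].to_numpy())
        assert res.beta < 0


class TestPerDatasetAndSweep:
    def test_two_identical_datasets(self, rng):
        df1 = simulate_phenotype_cohort({"a": 3000}, beta_true=12.0,
                                        froh_mean=0.005, seed=7)
        df2 = df1.copy()
        df2["dataset_id"] = "b"
        df = pd.concat([df1, df2], ignore_index=True)
        per, pooled = per_dataset_fits(df["y"].to_numpy(), df["froh"].to_numpy(),
                                       None, df["dataset_id"].to_numpy())
        assert per["a"].beta == pytest.approx(per["b"].beta, abs=1e-6)
        lo = min(per["a"].beta, per["b"].beta) - 1e-9
        hi = max(per["a"].beta, per["b"].beta) + 1e-9
        assert lo <= pooled.beta <= hi

    def test_single_class_dataset_skipped(self, rng):
        df = simulate_phenotype_cohort({"a": 400, "b": 400}, rng=rng)
        y = df["y"].to_numpy()
        y[df["dataset_id"] == "b"] = 0
        with pytest.warns(UserWarning, match="single phenotype class"):
            per, _ = per_dataset_fits(y, df["froh"].to_numpy(), None,
                                      df["dataset_id"].to_numpy())
        assert "b" not in per

    def test_confounded_dataset_biased_upward(self, rng):
        df = simulate_phenotype_cohort(
            {"a": 4000, "b": 4000}, beta_true=0.0, froh_mean=0.005,
            delta_by_site={"a": 0.004, "b": 0.0}, rng=rng)
        per, _ = per_dataset_fits(df["y"].to_numpy(), df["froh"].to_numpy(),
                                  None, df["dataset_id"].to_numpy())
        assert per["a"].beta > per["b"].beta
        assert per["a"].beta > 10  # strong positive bias from the shift

    def test_sweep_grid_of_one_matches_direct_fit(self, rng):
        segs = []
        ids = [f"s{i}" for i in range(60)]
        for i, sid in enumerate(ids):
            if i % 2 == 0:
                segs.append(ROHSegment(sid, "1", 1, int(3e6) + i * 10_000, 120))
        rs = ROHSet(segs)
        samples = pd.DataFrame({
            "sample_id": ids,
            "dataset_id": ["x"] * 60,
            "phenotype": list(np.resize([0, 1, 1, 0], 60)),
        })
        grid = ThresholdGrid(snp_thresholds=(110,), mb_thresholds=(2,))
        sweeps = sweep_association(rs, samples, grid)
        from rohburden.autozygosity import compute_froh
        from rohburden.roh import filter_roh

        direct = fit_logistic(
            samples["phenotype"].to_numpy(),
            compute_froh(filter_roh(rs, min_snps=110), samples)["froh"].to_numpy())
        snp_res = sweeps[0].results[0]
        assert snp_res.beta == pytest.approx(direct.beta, abs=1e-9)
        assert len(sweeps[0].results) == 1 and len(sweeps[1].results) == 1

    def test_sweep_never_aborts(self, rng):
        # empty ROH set: every fit is degenerate but the sweep completes
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(20)],
            "dataset_id": ["x"] * 20,
            "phenotype": [0, 1] * 10,
        })
        sweeps = sweep_association(ROHSet([]), samples)
        assert len(sweeps[0].results) == len(ThresholdGrid().snp_thresholds)
        assert all(not r.converged or r.aliased or np.isnan(r.beta) or r.p == 1.0
                   for r in sweeps[0].results)


class TestBuildCovariates:
    def test_shape_and_excess_het_centering(self, rng):
        calls = rng.binomial(2, rng.uniform(0.2, 0.5, 600), size=(30, 600)).astype(np.int8)
        m = make_matrix(calls, np.arange(1, 601) * 1000,
                        datasets=["a"] * 15 + ["b"] * 15)
        cov = build_covariates(m, n_pcs=5)
        assert list(cov.columns) == [f"PC{i}" for i in range(1, 6)] + [
            "missing_rate", "excess_het"]
        het = cov["excess_het"].to_numpy()
        assert abs(het[:15].mean()) < 1e-12 and abs(het[15:].mean()) < 1e-12
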