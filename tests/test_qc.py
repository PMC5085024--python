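import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from rohburden.datamodel import MISSING
from rohburden.qc import (
    HWEUndefinedError,
    QCThresholds,
    hwe_exact_p,
    pihat_matrix,
    sample_filters,
    snp_filters,
    vif_prune,
)

from .conftest import make_matrix, reference_hwe_enumeration, reference_vif_prune_window


def hwe_matrix(rng, n_samples, n_snps, maf_low=0.1, maf_high=0.5):
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    calls = rng.binomial(2, p, size=(n_samples, n_snps)).astype(np.int8)
    pos = np.sort(rng.choice(10**8, size=n_snps, replace=False)) + 1
    return calls, pos


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert hwe_exact_p(17, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 9) == 1.0

    def test_3_5_2_matches_enumeration(self):
        assert hwe_exact_p(3, 5, 2) == pytest.approx(reference_hwe_enumeration(3, 5, 2))

    def test_large_balanced_near_one_and_chi2_agreement(self):
        # (500, 1000, 500) sits exactly at the HWE expectation
        p = hwe_exact_p(500, 1000, 500)
        assert p > 0.9
        n = 2000
        exp_het = 0.5 * n
        stat = 0.0  # observed equals expected
        p_chi2 = chi2.sf(stat, df=1)
        assert abs(p - p_chi2) / p_chi2 < 0.10

    def test_all_missing_raises_distinctly(self):
        with pytest.raises(HWEUndefinedError):
            hwe_exact_p(0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)

    @settings(max_examples=150, deadline=None)
    @given(
        n_hom1=st.integers(0, 40),
        n_het=st.integers(0, 40),
        n_hom2=st.integers(0, 40),
    )
    def test_matches_enumeration_property(self, n_hom1, n_het, n_hom2):
        if n_hom1 + n_het + n_hom2 == 0:
            return
        got = hwe_exact_p(n_hom1, n_het, n_hom2)
        want = reference_hwe_enumeration(n_hom1, n_het, n_hom2)
        assert got == pytest.approx(want, rel=1e-9)
        assert 0 < got <= 1


class TestSampleFilters:
    def test_duplicate_sample_one_removed(self, rng):
        calls, pos = hwe_matrix(rng, 20, 1500)
        calls[1] = calls[0]  # exact duplicate pair
        m = make_matrix(calls, pos)
        pihat = pihat_matrix(m)
        assert pihat[0, 1] > 0.5  # well above the 0.2 limit; ~1 at large m
        out, report = sample_filters(m)
        assert out.n_samples == 19
        steps = {s["filter"]: s["n_removed"] for s in report.steps}
        assert steps["relatedness_pihat"] == 1

    def test_high_missingness_removed(self, rng):
        calls, pos = hwe_matrix(rng, 20, 1500)
        drop = rng.random(1500) < 0.05
        calls[3, drop] = MISSING
        out, report = sample_filters(make_matrix(calls, pos))
        assert "s3" not in out.sample_ids()
        steps = {s["filter"]: s["n_removed"] for s in report.steps}
        assert steps["sample_missingness"] == 1

    def test_unrelated_cohort_calibration(self):
        # pi-hat centered near 0 for independent simulants: few false removals
        removed = total = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            calls, pos = hwe_matrix(rng, 20, 2000)
            out, _ = sample_filters(make_matrix(calls, pos))
            removed += 20 - out.n_samples
            total += 20
        assert removed / total < 0.01

    def test_idempotent(self, rng):
        calls, pos = hwe_matrix(rng, 25, 1500)
        calls[2] = calls[0]
        once, _ = sample_filters(make_matrix(calls, pos))
        twice, report = sample_filters(once)
        assert twice.n_samples == once.n_samples
        assert all(s["n_removed"] == 0 for s in report.steps)


class TestSnpFilters:
    def test_clean_snp_retained(self, rng):
        calls, pos = hwe_matrix(rng, 100, 50)
        pheno = [0, 1] * 50
        out, _ = snp_filters(make_matrix(calls, pos, phenotypes=pheno))
        assert out.n_variants == 50

    def test_differential_missingness_removed(self, rng):
        calls, pos = hwe_matrix(rng, 200, 30)
        pheno = [1] * 100 + [0] * 100
        # SNP 5 missing in 3% of cases, 0% of controls
        calls[:3, 5] = MISSING
        out, report = snp_filters(make_matrix(calls, pos, phenotypes=pheno))
        assert "v5" not in [v.id for v in out.variants]
        steps = {s["filter"]: s["n_removed"] for s in report.steps}
        assert steps["differential_missingness"] >= 1

    def test_hwe_failure_removed(self, rng):
        calls, pos = hwe_matrix(rng, 300, 20)
        calls[:, 7] = np.where(np.arange(300) % 2 == 0, 0, 2)  # no hets at MAF 0.5
        pheno = [0, 1] * 150
        out, _ = snp_filters(make_matrix(calls, pos, phenotypes=pheno))
        assert "v7" not in [v.id for v in out.variants]

    def test_matches_brute_force_oracle(self, rng):
        calls, pos = hwe_matrix(rng, 150, 80)
        mask = rng.random(calls.shape) < 0.01
        calls[mask] = MISSING
        calls[:, 11] = np.where(np.arange(150) % 2 == 0, 0, 2)
        calls[:30, 23] = MISSING
        pheno = list(rng.integers(0, 2, 150))
        m = make_matrix(calls, pos, phenotypes=pheno)
        out, _ = snp_filters(m)

        # independent reapplication of the three rules
        th = QCThresholds()
        pheno = np.array(pheno)
        expected = []
        for j, v in enumerate(m.variants):
            col = m.calls[:, j]
            obs = col != MISSING
            p_hwe = reference_hwe_enumeration(
                int((col[obs] == 0).sum()), int((col == 1).sum()),
                int((col[obs] == 2).sum()))
            miss = (~obs).mean()
            diff = abs((col[pheno == 1] == MISSING).mean()
                       - (col[pheno == 0] == MISSING).mean())
            if p_hwe >= th.hwe_p_min and miss <= th.max_snp_missing and diff <= th.max_diff_missing:
                expected.append(v.id)
        assert [v.id for v in out.variants] == expected

    def test_single_class_skips_differential(self, rng):
        calls, pos = hwe_matrix(rng, 50, 10)
        m = make_matrix(calls, pos, phenotypes=[0] * 50)
        with pytest.warns(UserWarning, match="single class"):
            snp_filters(m)


class TestVifPrune:
    def test_independent_snps_untouched(self, rng):
        calls, pos = hwe_matrix(rng, 200, 60)
        m = make_matrix(calls, pos)
        out, kept = vif_prune(m)
        assert out.n_variants == 60 and kept == list(range(60))

    def test_duplicate_column_one_removed(self, rng):
        calls, pos = hwe_matrix(rng, 100, 30)
        calls[:, 12] = calls[:, 11]
        out, kept = vif_prune(make_matrix(calls, pos))
        assert out.n_variants == 29
        assert (11 in kept) != (12 in kept)

    def test_window_matches_exhaustive_oracle(self, rng):
        # heterogeneous LD: two tightly linked pairs among independents
        n = 300
        base = rng.binomial(2, rng.uniform(0.2, 0.5, 10), size=(n, 10)).astype(float)
        base[:, 1] = base[:, 0]                       # exact duplicate
        flip = rng.random(n) < 0.03
        base[:, 4] = np.where(flip, 2 - base[:, 3], base[:, 3])  # near duplicate
        calls = base.astype(np.int8)
        pos = np.arange(1, 11) * 1000
        m = make_matrix(calls, pos)
        _, kept = vif_prune(m, vif_limit=10.0, window=10, step=10)
        oracle = reference_vif_prune_window(base, limit=10.0)
        assert kept == oracle

    def test_no_window_exceeds_limit_after_pruning(self, rng):
        n = 150
        k = 40
        calls = rng.binomial(2, rng.uniform(0.2, 0.5, k), size=(n, k)).astype(np.int8)
        for j in range(5, 20, 3):  # make some correlated neighbors
            calls[:, j] = calls[:, j - 1]
        pos = np.arange(1, k + 1) * 1000
        m = make_matrix(calls, pos)
        out, kept = vif_prune(m, vif_limit=10.0, window=10, step=3)
        X = out.calls.astype(float)
        from rohburden.qc import _window_vifs

        for i in range(0, out.n_variants, 3):
            win = X[:, i : i + 10]
            if win.shape[1] >= 2:
                assert _window_vifs(win).max() <= 10.0 + 1e-6

    def test_window_larger_than_chromosome_ok(self, rng):
        calls, pos = hwe_matrix(rng, 50, 8)
        out, kept = vif_prune(make_matrix(calls, pos), window=50)
        assert out.n_variants == 8

    def test_idempotent(self, rng):
        calls, pos = hwe_matrix(rng, 120, 40)
        calls[:, 7] = calls[:, 6]
        calls[:, 25] = calls[:, 24]
        m = make_matrix(calls, pos)
        once, _ = vif_prune(m)
        twice, kept = vif_prune(once)
        assert twice.n_variants == once.n_variants


class TestThresholds:
    def test_defaults_exact(self):
        th = QCThresholds()
        assert (th.max_sample_missing, th.het_sd_limit, th.max_pihat) == (0.02, 6, 0.2)
        assert (th.hwe_p_min, th.max_snp_missing, th.max_diff_missing) == (1e-6, 0.02, 0.02)
        assert (th.vif_limit, th.vif_window) == (10, 50)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            QCThresholds(max_pihat=0)
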