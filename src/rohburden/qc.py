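"""Sample and SNP quality control, plus VIF-based LD pruning.

Filter order (configurable at the call sites): relatedness, sample
missingness, heterozygosity outliers; then HWE, SNP missingness and
case-control differential missingness; then the sliding-window VIF prune.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, InvariantError


@dataclass(frozen=True)
class QCThresholds:
    max_sample_missing: float = 0.02
    het_sd_limit: float = 6.0
    max_pihat: float = 0.2
    hwe_p_min: float = 1e-6
    max_snp_missing: float = 0.02
    max_diff_missing: float = 0.02
    vif_limit: float = 10.0
    vif_window: int = 50
    vif_step: int = 5

    def __post_init__(self) -> None:
        for name in (
            "max_sample_missing", "het_sd_limit", "max_pihat", "hwe_p_min",
            "max_snp_missing", "max_diff_missing", "vif_limit", "vif_window",
            "vif_step",
        ):
            if getattr(self, name) <= 0:
                raise InvariantError(f"threshold {name} must be positive")


@dataclass
class QCReport:
    """Ordered per-filter removal counts with input/output dimensions."""

    input_samples: int = 0
    input_variants: int = 0
    steps: list[dict] = field(default_factory=list)
    output_samples: int = 0
    output_variants: int = 0

    def add(self, name: str, kind: str, n_removed: int) -> None:
        self.steps.append({"filter": name, "kind": kind, "n_removed": int(n_removed)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def check_consistency(self) -> None:
        removed_s = sum(s["n_removed"] for s in self.steps if s["kind"] == "sample")
        removed_v = sum(s["n_removed"] for s in self.steps if s["kind"] == "variant")
        if self.input_samples - removed_s != self.output_samples:
            raise InvariantError("sample removal counts inconsistent with dimensions")
        if self.input_variants - removed_v != self.output_variants:
            raise InvariantError("variant removal counts inconsistent with dimensions")


class HWEUndefinedError(ValueError):
    """HWE test requested for a variant with no observed genotypes."""


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity) whose conditional probability does
    not exceed that of the observed count.  Probabilities are built by the
    standard recurrence from the mode, so the test is exact and O(n).
    """
    for v in (n_hom1, n_het, n_hom2):
        if v < 0 or int(v) != v:
            raise ValueError("genotype counts must be nonnegative integers")
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise HWEUndefinedError("no observed genotypes: HWE p undefined")
    rare = 2 * min(n_hom1, n_hom2) + n_het  # copies of the minor allele
    if rare == 0:
        return 1.0

    # het counts share the parity of the rare-allele count
    het_values = list(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))
    probs = np.zeros(len(het_values))
    # anchor the recurrence at the distribution mode for numerical stability
    mode = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if (mode - rare) % 2 != 0:
        mode += 1 if mode < het_values[-1] else -1
    mode = min(max(mode, het_values[0]), het_values[-1])
    mode_idx = het_values.index(mode)
    probs[mode_idx] = 1.0
    # downward: P(het-2)/P(het) = het*(het-1) / (4*(hom_r+1)*(hom_c+1))
    het = mode
    hom_r = (rare - het) // 2
    hom_c = n - het - hom_r
    for idx in range(mode_idx, 0, -1):
        probs[idx - 1] = probs[idx] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
        hom_r += 1
        hom_c += 1
    # upward: P(het+2)/P(het) = 4*hom_r*hom_c / ((het+2)*(het+1))
    het = mode
    hom_r = (rare - het) // 2
    hom_c = n - het - hom_r
    for idx in range(mode_idx, len(het_values) - 1):
        probs[idx + 1] = probs[idx] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
        hom_r -= 1
        hom_c -= 1
    probs /= probs.sum()

    obs_p = probs[het_values.index(n_het)]
    return float(min(1.0, probs[probs <= obs_p * (1.0 + 1e-12)].sum()))


def hwe_exact_p_vector(matrix: GenotypeMatrix) -> np.ndarray:
    """HWE exact p per variant (pooled samples); NaN for all-missing variants."""
    out = np.empty(matrix.n_variants)
    for j in range(matrix.n_variants):
        col = matrix.calls[:, j]
        obs = col != MISSING
        n_het = int((col == 1).sum())
        n_hom1 = int((col[obs] == 0).sum())
        n_hom2 = int((col[obs] == 2).sum())
        try:
            out[j] = hwe_exact_p(n_hom1, n_het, n_hom2)
        except HWEUndefinedError:
            out[j] = np.nan
    return out


# ---------------------------------------------------------------------------
# relatedness


def _standardized_calls(matrix: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, allele-frequency standardized call matrix (float64).

    Monomorphic variants get zero columns (they carry no information).
    """
    X = matrix.calls.astype(float)
    X[X == MISSING] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    X = np.where(np.isnan(X), 2.0 * p, X)
    denom = np.sqrt(2.0 * p * (1.0 - p))
    poly = denom > 0
    X = X - 2.0 * p
    X[:, poly] /= denom[poly]
    X[:, ~poly] = 0.0
    return X


def pihat_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments genome-wide relatedness (pi-hat) for all pairs.

    Approximated by the off-diagonals of the allele-frequency standardized
    genotype covariance (GRM): ~0 for unrelated pairs, ~0.5 for first-degree
    relatives, ~1 for duplicates.
    """
    X = _standardized_calls(matrix)
    m = max(1, (X != 0).any(axis=0).sum())
    return X @ X.T / m


def sample_filters(
    matrix: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the sample-level filters in order.

    1. relatedness: from each pair with pi-hat above the limit, drop the
       member with the higher missing rate;
    2. sample missingness above the limit;
    3. heterozygosity more than ``het_sd_limit`` SDs above the mean
       (one-sided high).
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport(input_samples=matrix.n_samples, input_variants=matrix.n_variants)

    keep = np.ones(matrix.n_samples, dtype=bool)
    miss = matrix.sample_missing_rate()

    if matrix.n_samples >= 2 and matrix.n_variants > 0:
        pihat = pihat_matrix(matrix)
        iu, ju = np.triu_indices(matrix.n_samples, k=1)
        related = pihat[iu, ju] > thresholds.max_pihat
        # greedy: resolve pairs in order, skipping pairs already broken
        for i, j in zip(iu[related], ju[related]):
            if keep[i] and keep[j]:
                drop = i if miss[i] >= miss[j] else j
                keep[drop] = False
    report.add("relatedness_pihat", "sample", (~keep).sum())

    n_before = keep.sum()
    keep &= ~(miss > thresholds.max_sample_missing)
    report.add("sample_missingness", "sample", n_before - keep.sum())

    het = matrix.sample_heterozygosity()
    surv = het[keep]
    n_before = keep.sum()
    if surv.size >= 2 and np.nanstd(surv, ddof=1) > 0:
        limit = np.nanmean(surv) + thresholds.het_sd_limit * np.nanstd(surv, ddof=1)
        keep &= ~(het > limit)
    report.add("heterozygosity_outlier", "sample", n_before - keep.sum())

    if not keep.any():
        warnings.warn("sample QC removed every sample", stacklevel=2)
    out = matrix.subset(sample_idx=np.flatnonzero(keep)).refresh_metadata()
    report.output_samples, report.output_variants = out.n_samples, out.n_variants
    report.check_consistency()
    return out, report


def snp_filters(
    matrix: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the three SNP-level filters, each evaluated on the input matrix.

    Removes variants that (a) fail the pooled HWE exact test below
    ``hwe_p_min``, (b) exceed ``max_snp_missing``, or (c) differ in
    case/control missingness by more than ``max_diff_missing``.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport(input_samples=matrix.n_samples, input_variants=matrix.n_variants)

    hwe_p = hwe_exact_p_vector(matrix)
    fail_hwe = hwe_p < thresholds.hwe_p_min  # NaN compares False: all-missing kept here
    report.add("hwe_exact", "variant", fail_hwe.sum())

    miss = (matrix.calls == MISSING).mean(axis=0)
    fail_miss = miss > thresholds.max_snp_missing
    report.add("snp_missingness", "variant", (fail_miss & ~fail_hwe).sum())

    pheno = matrix.phenotypes()
    cases, controls = pheno == 1, pheno == 0
    if cases.any() and controls.any():
        miss_ca = (matrix.calls[cases] == MISSING).mean(axis=0)
        miss_co = (matrix.calls[controls] == MISSING).mean(axis=0)
        fail_diff = np.abs(miss_ca - miss_co) > thresholds.max_diff_missing
    else:
        warnings.warn(
            "phenotype has a single class: differential-missingness filter skipped",
            stacklevel=2,
        )
        fail_diff = np.zeros(matrix.n_variants, dtype=bool)
    report.add("differential_missingness", "variant",
               (fail_diff & ~fail_hwe & ~fail_miss).sum())

    keep = ~(fail_hwe | fail_miss | fail_diff)
    out = matrix.subset(variant_idx=np.flatnonzero(keep)).refresh_metadata()
    report.output_samples, report.output_variants = out.n_samples, out.n_variants
    report.check_consistency()
    return out, report


# ---------------------------------------------------------------------------
# VIF pruning


def _window_vifs(X: np.ndarray) -> np.ndarray:
    """VIF of each column of a standardized window (ridge-stabilized inverse)."""
    n, k = X.shape
    sd = X.std(axis=0)
    ok = sd > 0
    vif = np.ones(k)
    if ok.sum() < 2:
        return vif
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    R = Z.T @ Z / n
    R[np.diag_indices_from(R)] += 1e-8
    vif[ok] = np.diag(np.linalg.inv(R))
    return np.maximum(vif, 1.0)


def vif_prune(
    matrix: GenotypeMatrix,
    vif_limit: float = 10.0,
    window: int = 50,
    step: int = 5,
) -> tuple[GenotypeMatrix, list[int]]:
    """Sliding-window VIF pruning per chromosome.

    Within each window, the SNP with the largest VIF (computed from the
    mean-imputed genotype correlation matrix) is removed iteratively until
    every VIF is at or below the limit; removal is global and permanent.
    Returns the pruned matrix and the kept variant indices (into the input).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    X = matrix.calls.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(X), col_mean, X)

    chroms = matrix.chroms()
    kept_global: list[int] = []
    for c in pd.unique(chroms):
        kept = list(np.flatnonzero(chroms == c))
        i = 0
        while i < len(kept):
            win = kept[i : i + window]
            while len(win) >= 2:
                vifs = _window_vifs(X[:, win])
                worst = int(np.argmax(vifs))
                if vifs[worst] <= vif_limit:
                    break
                removed = win.pop(worst)
                kept.remove(removed)
            i += step
        kept_global.extend(kept)
    kept_global.sort()
    out = matrix.subset(variant_idx=kept_global).refresh_metadata()
    return out, kept_global


def ancestry_outliers(
    matrix: GenotypeMatrix, k_sd: float = 6.0, n_pcs: int = 2
) -> np.ndarray:
    """Indices of samples > ``k_sd`` SDs from the centroid of the top GRM PCs.

    A panel-free stand-in for reference-based ancestry filtering.
    """
    from .association import compute_grm, grm_pcs

    pcs = grm_pcs(compute_grm(matrix), k=min(n_pcs, matrix.n_samples))
    z = (pcs - pcs.mean(axis=0)) / np.where(pcs.std(axis=0) > 0, pcs.std(axis=0), 1.0)
    dist = np.sqrt((z**2).sum(axis=1))
    return np.flatnonzero(dist > k_sd)
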