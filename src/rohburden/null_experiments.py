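"""Permutation and power experiments for the burden test.

The site-flip scheme builds a null in which each dataset's phenotype vector
is either left alone or inverted wholesale (probability 1/2 each, per
permutation).  A whole-site flip negates the site's froh-phenotype
association without shrinking its magnitude, so under site-level
confounding the pooled test stays inflated — the effective degrees of
freedom are closer to the number of sites than to the number of subjects.
A per-individual shuffle mode is provided as a contrast: it destroys the
within-site association and restores calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .association import fit_logistic
from .synthetic_cohort import simulate_phenotype_cohort


@dataclass
class PermutationResult:
    n_perm: int
    n_significant: int
    alpha: float
    seed: int | None
    n_nonconverged: int = 0
    p_values: np.ndarray | None = None

    @property
    def empirical_type1(self) -> float:
        return self.n_significant / self.n_perm if self.n_perm else float("nan")

    @property
    def binomial_se(self) -> float:
        t = self.empirical_type1
        return float(np.sqrt(t * (1.0 - t) / self.n_perm)) if self.n_perm else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "n_significant": self.n_significant,
            "alpha": self.alpha,
            "empirical_type1": self.empirical_type1,
            "binomial_se": self.binomial_se,
            "n_nonconverged": self.n_nonconverged,
            "seed": self.seed,
        }


def site_flip_permutation(
    y: np.ndarray,
    froh: np.ndarray,
    covariates: pd.DataFrame | None,
    dataset_ids: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: Literal["site_flip", "shuffle"] = "site_flip",
    keep_p_values: bool = True,
) -> PermutationResult:
    """Empirical type-I error of the pooled fixed-effects fit under flips.

    Covariates are held fixed across permutations (flips do not alter
    genotypes).  A permutation whose refit fails to converge contributes
    p = 1, i.e. counts as non-significant.
    """
    y = np.asarray(y, dtype=int)
    froh = np.asarray(froh, dtype=float)
    ds = np.asarray(dataset_ids)
    levels = pd.unique(ds)
    site_masks = [ds == lev for lev in levels]
    use_ds = ds if len(levels) > 1 else None

    rng = np.random.default_rng(seed)
    p_values = np.empty(n_perm)
    n_nonconverged = 0
    for b in range(n_perm):
        if mode == "site_flip":
            y_perm = y.copy()
            flips = rng.random(len(levels)) < 0.5
            for mask, flip in zip(site_masks, flips):
                if flip:
                    y_perm[mask] = 1 - y_perm[mask]
        elif mode == "shuffle":
            y_perm = y.copy()
            for mask in site_masks:
                idx = np.flatnonzero(mask)
                y_perm[idx] = y_perm[rng.permutation(idx)]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        res = fit_logistic(y_perm, froh, covariates, use_ds)
        if not res.converged:
            n_nonconverged += 1
            p_values[b] = 1.0
        else:
            p_values[b] = res.p
    n_sig = int((p_values < alpha).sum())
    return PermutationResult(
        n_perm=n_perm, n_significant=n_sig, alpha=alpha, seed=seed,
        n_nonconverged=n_nonconverged,
        p_values=p_values if keep_p_values else None,
    )


@dataclass
class PowerResult:
    beta_true: float
    n: int
    n_reps: int
    alpha: float
    fraction_significant: float
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "beta_true": self.beta_true,
            "n": self.n,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "fraction_significant": self.fraction_significant,
            "seed": self.seed,
        }


def power_simulation(
    beta_true: float,
    cohort_template: Mapping,
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PowerResult:
    """Fraction of simulated cohorts whose burden fit reaches p < alpha.

    ``cohort_template`` keys: ``site_sizes`` (mapping site -> n, or a plain
    ``n`` for a single site), plus any of ``froh_mean``,
    ``froh_zero_fraction``, ``intercept``, ``confound_tau``.
    """
    template = dict(cohort_template)
    site_sizes = template.pop("site_sizes", None)
    if site_sizes is None:
        site_sizes = {"s1": int(template.pop("n"))}
    rng = np.random.default_rng(seed)
    n_total = sum(site_sizes.values())
    n_sig = 0
    for _ in range(n_reps):
        df = simulate_phenotype_cohort(site_sizes, beta_true=beta_true, rng=rng, **template)
        ds = df["dataset_id"].to_numpy() if len(site_sizes) > 1 else None
        res = fit_logistic(df["y"].to_numpy(), df["froh"].to_numpy(), None, ds)
        if res.converged and res.p < alpha:
            n_sig += 1
    return PowerResult(
        beta_true=beta_true, n=n_total, n_reps=n_reps, alpha=alpha,
        fraction_significant=n_sig / n_reps, seed=seed,
    )
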