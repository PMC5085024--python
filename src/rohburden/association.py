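"""Covariate-adjusted logistic burden regression and threshold sweeps.

The burden predictor (froh) always enters on the proportion scale (0-1),
so a slope ``beta`` translates to a per-1%-of-genome odds change of
``100 * (exp(beta / 100) - 1)`` percent.  Fits are maximum likelihood by
iteratively reweighted least squares with Wald inference; the site factor
is modeled as fixed-effect indicator columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit
from scipy.stats import norm

from .autozygosity import MAPPABLE_BP, compute_froh
from .roh import ROHSet, ThresholdGrid, filter_roh

logger = logging.getLogger(__name__)

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 25


def or_per_percent(beta: float) -> float:
    """Percent change in odds per additional 1% of the genome in ROHs."""
    return 100.0 * (np.exp(beta / 100.0) - 1.0)


def wald_p(z: float) -> float:
    """Two-sided normal-tail p-value for a Wald statistic."""
    return float(2.0 * norm.sf(abs(z)))


@dataclass
class AssociationResult:
    """Slope inference for one fitted burden model (froh term unless noted)."""

    beta: float
    se: float
    n: int
    threshold: str = ""
    converged: bool = True
    separated: bool = False
    aliased: bool = False
    note: str = ""

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 and np.isfinite(self.se) else 0.0

    @property
    def p(self) -> float:
        if self.separated or self.aliased or not np.isfinite(self.se):
            return 1.0
        return wald_p(self.z)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def or_per_percent(self) -> float:
        return or_per_percent(self.beta)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "threshold": self.threshold,
            "beta": self.beta,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "ci_lo": lo,
            "ci_hi": hi,
            "or_per_percent": self.or_per_percent,
            "n": self.n,
            "converged": self.converged,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# design construction


def build_design(
    froh: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    dataset_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble [intercept, froh, covariates..., site dummies...].

    Site indicators drop the first (reference) level; the result is the
    fixed-effects design used by every pooled fit.
    """
    n = len(froh)
    cols = [np.ones(n), np.asarray(froh, dtype=float)]
    names = ["intercept", "froh"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for name in cov.columns:
            cols.append(cov[name].to_numpy(dtype=float))
            names.append(str(name))
    if dataset_ids is not None:
        levels = pd.unique(np.asarray(dataset_ids))
        for lev in levels[1:]:
            cols.append((np.asarray(dataset_ids) == lev).astype(float))
            names.append(f"dataset[{lev}]")
    return np.column_stack(cols), names


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop linearly dependent columns via pivoted QR; returns kept design."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.info("dropping aliased design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep], dropped


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS logistic fit; returns (beta, covariance, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    XtWX = np.eye(p)
    converged = False
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < IRLS_TOL:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        XtWX = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(XtWX, score, rcond=None)[0]
        beta = beta + delta
    eta = np.clip(X @ beta, -30.0, 30.0)
    w = np.maximum(expit(eta) * (1.0 - expit(eta)), 1e-10)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.inf)
    return beta, cov, converged


def _is_separated(X: np.ndarray, beta: np.ndarray, y: np.ndarray) -> bool:
    mu = expit(np.clip(X @ beta, -30.0, 30.0))
    cases, controls = y == 1, y == 0
    if not cases.any() or not controls.any():
        return True
    return bool(mu[cases].min() > 1 - 1e-6 and mu[controls].max() < 1e-6)


def fit_logistic(
    y: np.ndarray,
    froh: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    dataset_ids: np.ndarray | None = None,
    threshold: str = "",
    term: str = "froh",
) -> AssociationResult:
    """Fit the burden model and report Wald inference on one term.

    Aliased columns are dropped (a fit with froh itself aliased is flagged
    and carries no estimate); perfect separation is flagged with infinite SE
    and the conservative convention p = 1.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    X, names = build_design(froh, covariates, dataset_ids)
    X, names, dropped = _drop_aliased(X, names)
    n = len(y)
    if term not in names:
        warnings.warn(f"term {term!r} aliased with other design columns", stacklevel=2)
        return AssociationResult(beta=np.nan, se=np.nan, n=n, threshold=threshold,
                                 converged=False, aliased=True, note="term aliased")
    beta_vec, cov, converged = _irls(X, y)
    j = names.index(term)
    separated = _is_separated(X, beta_vec, y)
    se = np.sqrt(cov[j, j]) if cov[j, j] > 0 else np.inf
    if separated:
        se = np.inf
    note = f"dropped: {','.join(dropped)}" if dropped else ""
    return AssociationResult(
        beta=float(beta_vec[j]), se=float(se), n=n, threshold=threshold,
        converged=converged, separated=separated, note=note,
    )


# ---------------------------------------------------------------------------
# GRM and principal components


def compute_grm(matrix) -> np.ndarray:
    """Genomic relationship matrix from allele-frequency standardized calls.

    Entry (i, j) averages ``(x_i - 2p)(x_j - 2p) / (2p(1-p))`` over
    polymorphic SNPs; missing calls are mean-imputed for this computation
    only.  Monomorphic SNPs are excluded (count logged).
    """
    from .qc import _standardized_calls

    X = _standardized_calls(matrix)
    poly = (X != 0).any(axis=0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("compute_grm: excluded %d monomorphic SNPs", n_mono)
    m = max(1, int(poly.sum()))
    return X[:, poly] @ X[:, poly].T / m


def grm_pcs(grm: np.ndarray, k: int = 20) -> np.ndarray:
    """Top-k GRM eigenvectors scaled by sqrt(eigenvalue).

    Sign convention: the largest-magnitude loading of each component is
    positive, making the decomposition deterministic.
    """
    grm = np.asarray(grm, dtype=float)
    n = grm.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds matrix dimension {n}")
    if k == 0:
        return np.zeros((n, 0))
    vals, vecs = np.linalg.eigh((grm + grm.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    pcs = vecs * np.sqrt(np.clip(vals, 0.0, None))
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] *= -1.0
    return pcs


def build_covariates(
    matrix,
    n_pcs: int = 20,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Standard covariate block: PCs, missing rate and excess heterozygosity.

    Excess heterozygosity is observed het centered within dataset (site-
    specific chip effects).  PCs may be passed in to avoid recomputing the
    GRM on every call.
    """
    if pcs is None:
        pcs = grm_pcs(compute_grm(matrix), k=min(n_pcs, matrix.n_samples))
    df = pd.DataFrame(pcs, columns=[f"PC{i + 1}" for i in range(pcs.shape[1])])
    df["missing_rate"] = matrix.sample_missing_rate()
    het = pd.Series(matrix.sample_heterozygosity())
    ds = pd.Series(matrix.dataset_ids())
    df["excess_het"] = (het - het.groupby(ds).transform("mean")).to_numpy()
    return df


# ---------------------------------------------------------------------------
# sweeps, interaction, per-dataset fits


@dataclass
class SweepResult:
    grid_type: str  # "snp" or "mb"
    results: list[AssociationResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])


def sweep_association(
    rohset: ROHSet,
    samples,
    grid: ThresholdGrid | None = None,
    covariates: pd.DataFrame | None = None,
    use_dataset_effects: bool = True,
    mappable_bp: float = MAPPABLE_BP,
) -> list[SweepResult]:
    """Refilter-and-refit across the SNP-count and Mb threshold grids.

    Per-point errors are recorded on the result, never aborting the sweep.
    """
    grid = grid or ThresholdGrid()
    base = compute_froh(rohset, samples, mappable_bp)
    y = base["phenotype"].to_numpy()
    ds = base["dataset_id"].to_numpy() if use_dataset_effects else None
    if ds is not None and len(pd.unique(ds)) < 2:
        ds = None
    out = []
    for grid_type, values in (("snp", grid.snp_thresholds), ("mb", grid.mb_thresholds)):
        sweep = SweepResult(grid_type=grid_type)
        for t in values:
            label = f"{t}snp" if grid_type == "snp" else f"{t}mb"
            try:
                sub = (
                    filter_roh(rohset, min_snps=t)
                    if grid_type == "snp"
                    else filter_roh(rohset, min_mb=t)
                )
                froh = compute_froh(sub, samples, mappable_bp)["froh"].to_numpy()
                res = fit_logistic(y, froh, covariates, ds, threshold=label)
            except Exception as exc:  # keep sweeping
                res = AssociationResult(beta=np.nan, se=np.nan, n=len(y),
                                        threshold=label, converged=False,
                                        note=f"error: {exc}")
            sweep.results.append(res)
        out.append(sweep)
    return out


def interaction_test(
    y: np.ndarray,
    froh: np.ndarray,
    covariates: pd.DataFrame | None,
    replication_flag: np.ndarray,
    dataset_ids: np.ndarray | None = None,
) -> AssociationResult:
    """Wald test of the froh x stratum product term."""
    flag = np.asarray(replication_flag, dtype=float)
    if len(np.unique(flag)) < 2:
        raise ValueError("replication_flag is constant: both strata required")
    extra = pd.DataFrame({
        "replication": flag,
        "froh_x_replication": np.asarray(froh, dtype=float) * flag,
    })
    cov = extra if covariates is None else pd.concat(
        [pd.DataFrame(covariates).reset_index(drop=True), extra], axis=1
    )
    return fit_logistic(y, froh, cov, dataset_ids, term="froh_x_replication",
                        threshold="interaction")


def per_dataset_fits(
    y: np.ndarray,
    froh: np.ndarray,
    covariates: pd.DataFrame | None,
    dataset_ids: np.ndarray,
) -> tuple[dict[str, AssociationResult], AssociationResult]:
    """Independent per-site fits plus the pooled fixed-effects fit.

    Sites lacking both phenotype classes are skipped with a warning.
    """
    y = np.asarray(y)
    ds = np.asarray(dataset_ids)
    per: dict[str, AssociationResult] = {}
    for level in pd.unique(ds):
        mask = ds == level
        if len(np.unique(y[mask])) < 2:
            warnings.warn(f"dataset {level}: single phenotype class, skipped",
                          stacklevel=2)
            continue
        cov = None
        if covariates is not None:
            cov = pd.DataFrame(covariates).iloc[mask].reset_index(drop=True)
        per[str(level)] = fit_logistic(y[mask], np.asarray(froh)[mask], cov,
                                       threshold=str(level))
    pooled = fit_logistic(y, froh, covariates, ds if len(pd.unique(ds)) > 1 else None,
                          threshold="pooled")
    return per, pooled
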