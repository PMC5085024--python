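"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rohburden.datamodel import GenotypeMatrix, SampleRecord, VariantRecord
from rohburden.roh import CallingParams


def make_matrix(calls, positions, chrom="1", phenotypes=None, datasets=None,
                sample_ids=None):
    """Build a GenotypeMatrix from a 2-D call array and one position list."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_var = calls.shape
    if isinstance(chrom, str):
        chroms = [chrom] * n_var
    else:
        chroms = list(chrom)
    variants = [
        VariantRecord(chrom=chroms[j], id=f"v{j}", pos_bp=int(positions[j]))
        for j in range(n_var)
    ]
    samples = [
        SampleRecord(
            sample_id=(sample_ids[i] if sample_ids else f"s{i}"),
            dataset_id=(datasets[i] if datasets else "all"),
            phenotype=(phenotypes[i] if phenotypes is not None else 0),
        )
        for i in range(n_samples)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls).refresh_metadata()


# ---------------------------------------------------------------------------
# oracle: naive linear-scan ROH caller (kept deliberately simple and slow)


def reference_roh_scan(calls, positions, params: CallingParams | None = None):
    """Independent O(n) reference: returns [(start_bp, end_bp, n_snps), ...]."""
    params = params or CallingParams()
    out = []
    cur: list[int] = []

    def flush():
        nonlocal cur
        if cur:
            n = len(cur)
            s, e = positions[cur[0]], positions[cur[-1]]
            length = e - s + 1
            if n >= params.min_snps_initial and n * params.min_density_bp > length:
                out.append((int(s), int(e), n))
        cur = []

    for i, g in enumerate(calls):
        if g not in (0, 2):  # het or missing breaks the run
            flush()
            continue
        if cur and positions[i] - positions[cur[-1]] > params.gap_split_bp:
            flush()
        cur.append(i)
    flush()
    return out


# ---------------------------------------------------------------------------
# oracle: HWE exact test by full enumeration in exact integer arithmetic


def reference_hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided HWE p by enumerating all het counts with integer weights."""
    n = n_hom1 + n_het + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0
    weights = {}
    for het in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        # multinomial count of genotype configurations x 2^het orderings
        weights[het] = (
            math.factorial(n)
            // (math.factorial(hom_r) * math.factorial(het) * math.factorial(hom_c))
            * 2**het
        )
    total = sum(weights.values())
    obs = weights[n_het]
    return min(1.0, sum(w for w in weights.values() if w <= obs) / total)


# ---------------------------------------------------------------------------
# oracle: exhaustive single-window VIF pruner


def reference_vif_prune_window(X: np.ndarray, limit: float = 10.0) -> list[int]:
    """Iteratively drop the worst-VIF column (regression definition) of X."""
    X = np.asarray(X, dtype=float)
    cols = list(range(X.shape[1]))
    while len(cols) > 1:
        vifs = []
        for j in cols:
            others = [c for c in cols if c != j]
            A = np.column_stack([np.ones(len(X))] + [X[:, c] for c in others])
            b = X[:, j]
            coef = np.linalg.lstsq(A, b, rcond=None)[0]
            resid = b - A @ coef
            denom = b.var()
            r2 = 1.0 - resid.var() / denom if denom > 0 else 0.0
            vifs.append(1.0 / max(1.0 - r2, 1e-12))
        worst = int(np.argmax(vifs))
        if vifs[worst] <= limit:
            break
        cols.pop(worst)
    return cols


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
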