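"""Multi-site case-control cohort simulator with planted autozygosity.

Each individual receives a target autozygous genome fraction F; IBD-like
segments are planted until the target is met, forcing homozygosity inside
them (the homozygote class drawn by allele frequency), while everything
outside follows Hardy-Weinberg proportions at each SNP's allele frequency.
Case status follows a logistic liability model on the *planted* F, so
attenuation from calling error is measurable downstream.  Optional site-level
case/control F shifts model differential ascertainment.

SNPs are independent given allele frequency (no LD): the analysis pipeline
prunes LD before calling, so LD realism buys nothing on this surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import MISSING, GenotypeMatrix, SampleRecord, VariantRecord

#: Total simulated genome size, matching the mappable-distance constant
#: used for Froh (2.77e9 bp over 22 autosomes).
GENOME_BP = 2_770_000_000

# rough relative autosome sizes (Mb), rescaled so the total is GENOME_BP
_REL_MB = [249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135,
           134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51]


def default_chrom_lengths() -> dict[str, int]:
    """22 autosomes with realistic relative sizes summing exactly to GENOME_BP."""
    total = sum(_REL_MB)
    out = {str(i + 1): int(round(GENOME_BP * mb / total)) for i, mb in enumerate(_REL_MB)}
    out["22"] += GENOME_BP - sum(out.values())
    return out


@dataclass(frozen=True)
class SiteSpec:
    """One collection site: expected case/control composition.

    ``n_cases``/``n_controls`` set the site size and the target case
    fraction; realized counts vary because phenotypes are drawn from the
    liability model.  ``intercept`` defaults to the logit of the target
    case fraction (net of the mean froh effect).
    """

    name: str
    n_cases: int
    n_controls: int
    intercept: float | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError(f"site {self.name}: counts must be >= 0")
        if self.n_cases + self.n_controls == 0:
            raise ValueError(f"site {self.name}: empty site")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    The per-individual target F is a mixture: 0 with probability
    ``f_zero_fraction``, otherwise ``f_constant`` if set, else an
    exponential draw with mean ``f_mean``.  ``confound_tau`` is the SD of
    the per-site case-minus-control mean-F shift; ``delta_by_site`` gives
    explicit shifts instead.
    """

    sites: list[SiteSpec]
    n_snps: int = 20_000
    chrom_lengths_bp: dict[str, int] = field(default_factory=default_chrom_lengths)
    maf_min: float = 0.15
    maf_max: float = 0.5
    f_zero_fraction: float = 0.5
    f_mean: float = 0.005
    f_constant: float | None = None
    segment_mean_mb: float = 3.0
    segment_min_mb: float = 0.5
    beta_true: float = 0.0
    confound_tau: float = 0.0
    delta_by_site: dict[str, float] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.sites:
            raise ValueError("at least one site required")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        if not (0 <= self.f_zero_fraction <= 1):
            raise ValueError("f_zero_fraction must be in [0, 1]")
        if self.f_constant is not None and not (0 <= self.f_constant < 1):
            raise ValueError("f_constant must be in [0, 1)")
        if self.f_mean < 0 or self.segment_mean_mb <= 0 or self.segment_min_mb <= 0:
            raise ValueError("f_mean and segment lengths must be positive")
        if self.confound_tau < 0:
            raise ValueError("confound_tau must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 < self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("require 0 < maf_min <= maf_max <= 0.5")
        if any(l <= 0 for l in self.chrom_lengths_bp.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def genome_bp(self) -> int:
        return sum(self.chrom_lengths_bp.values())


@dataclass
class TruthRecord:
    """Ground truth for one simulated individual."""

    sample_id: str
    f_true: float
    planted_segments: list[tuple[str, int, int]]
    liability_linear_predictor: float


def _draw_f(spec: CohortSpec, rng: np.random.Generator) -> float:
    if rng.random() < spec.f_zero_fraction:
        return 0.0
    if spec.f_constant is not None:
        return spec.f_constant
    return float(rng.exponential(spec.f_mean))


def _lay_positions(spec: CohortSpec, rng: np.random.Generator):
    """Allocate SNPs to chromosomes by length and draw sorted unique positions."""
    chroms = list(spec.chrom_lengths_bp)
    lengths = np.array([spec.chrom_lengths_bp[c] for c in chroms], dtype=float)
    alloc = np.floor(spec.n_snps * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-lengths)[: spec.n_snps - alloc.sum()]:
        alloc[i] += 1
    variants: list[VariantRecord] = []
    for c, n_c, L in zip(chroms, alloc, lengths.astype(np.int64)):
        n_c = min(int(n_c), int(L))
        pos = np.unique(rng.integers(1, L + 1, size=n_c))
        while pos.size < n_c:  # top up after collisions (rare: n_c << L)
            extra = rng.integers(1, L + 1, size=n_c - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        for k, p in enumerate(pos):
            variants.append(VariantRecord(chrom=c, id=f"snp_{c}_{k}", pos_bp=int(p)))
    return variants


def _plant_segments(
    spec: CohortSpec, f_target: float, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Draw non-overlapping segments until planted length / genome >= target."""
    if f_target <= 0:
        return []
    chroms = list(spec.chrom_lengths_bp)
    lengths = np.array([spec.chrom_lengths_bp[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    genome = spec.genome_bp
    segments: list[tuple[str, int, int]] = []
    total = 0
    attempts = 0
    while total / genome < f_target and attempts < 1000:
        attempts += 1
        length = int(max(spec.segment_min_mb, rng.exponential(spec.segment_mean_mb)) * 1e6)
        ci = rng.choice(len(chroms), p=weights)
        L = int(lengths[ci])
        if length >= L:
            length = L
            start = 1
        else:
            start = int(rng.integers(1, L - length + 1))
        end = start + length - 1
        c = chroms[ci]
        if any(s[0] == c and not (end < s[1] or start > s[2]) for s in segments):
            continue  # overlap: redraw
        segments.append((c, start, end))
        total += length
    return segments


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, list[TruthRecord]]:
    """Simulate genotypes, phenotypes and ground truth for every site.

    Bit-reproducible for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    variants = _lay_positions(spec, rng)
    n_snps = len(variants)
    maf = rng.uniform(spec.maf_min, spec.maf_max, size=n_snps)
    chrom_arr = np.array([v.chrom for v in variants])
    pos_arr = np.array([v.pos_bp for v in variants], dtype=np.int64)
    chrom_index = {
        c: np.flatnonzero(chrom_arr == c) for c in spec.chrom_lengths_bp
    }

    # per-site confounding shifts
    if spec.delta_by_site is not None:
        delta = {s.name: spec.delta_by_site.get(s.name, 0.0) for s in spec.sites}
    elif spec.confound_tau > 0:
        delta = {s.name: float(rng.normal(0.0, spec.confound_tau)) for s in spec.sites}
    else:
        delta = {s.name: 0.0 for s in spec.sites}

    samples: list[SampleRecord] = []
    truth: list[TruthRecord] = []
    rows: list[np.ndarray] = []
    for site in spec.sites:
        f_nonzero_mean = (1 - spec.f_zero_fraction) * (
            spec.f_constant if spec.f_constant is not None else spec.f_mean
        )
        intercept = (
            site.intercept
            if site.intercept is not None
            else float(logit(site.case_fraction)) - spec.beta_true * f_nonzero_mean
        )
        for i in range(site.n):
            sid = f"{site.name}_{i:05d}"
            f_target = _draw_f(spec, rng)
            eta = intercept + spec.beta_true * f_target
            y = int(rng.random() < expit(eta))
            f_final = max(0.0, f_target + delta[site.name] * (y - site.case_fraction))
            segments = _plant_segments(spec, f_final, rng)

            row = rng.binomial(2, maf).astype(np.int8)
            for c, start, end in segments:
                idx = chrom_index[c]
                lo, hi = np.searchsorted(pos_arr[idx], [start, end + 1])
                sel = idx[lo:hi]
                row[sel] = 2 * (rng.random(sel.size) < maf[sel]).astype(np.int8)
            if spec.missing_rate > 0:
                row[rng.random(n_snps) < spec.missing_rate] = MISSING
            f_true = sum(e - s + 1 for _, s, e in segments) / spec.genome_bp
            samples.append(SampleRecord(sample_id=sid, dataset_id=site.name, phenotype=y))
            truth.append(TruthRecord(sid, f_true, segments, eta))
            rows.append(row)

    calls = np.vstack(rows) if rows else np.zeros((0, n_snps), dtype=np.int8)
    matrix = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    return matrix.refresh_metadata(), truth


def inject_site_confounding(
    matrix: GenotypeMatrix,
    truth: list[TruthRecord],
    delta_by_site: Mapping[str, float],
    spec: CohortSpec,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[TruthRecord]]:
    """Re-plant segments so each site's case-control mean-F gap ~= delta_s.

    Sites with a zero shift are left untouched (byte-identical rows).  New F
    targets are the existing planted F plus ``delta_s * (y - site case
    fraction)``, so the marginal F distribution is approximately preserved.
    Infeasible shifts are clipped with a warning.
    """
    rng = np.random.default_rng(seed)
    truth_by_id = {t.sample_id: t for t in truth}
    ds = matrix.dataset_ids()
    pheno = matrix.phenotypes()
    maf = matrix.variant_alt_freq()
    maf = np.where(np.isnan(maf), 0.0, maf)
    chrom_arr = matrix.chroms()
    pos_arr = matrix.positions()
    chrom_index = {c: np.flatnonzero(chrom_arr == c) for c in pd.unique(chrom_arr)}

    new_calls = matrix.calls.copy()
    new_truth = [TruthRecord(t.sample_id, t.f_true, list(t.planted_segments),
                             t.liability_linear_predictor) for t in truth]
    truth_pos = {t.sample_id: k for k, t in enumerate(new_truth)}

    for site, shift in delta_by_site.items():
        if shift == 0.0:
            continue
        members = np.flatnonzero(ds == site)
        if members.size == 0:
            continue
        pbar = pheno[members].mean()
        for i in members:
            t = truth_by_id[matrix.samples[i].sample_id]
            f_new = t.f_true + shift * (pheno[i] - pbar)
            if f_new < 0 or f_new > 0.9:
                warnings.warn(
                    f"site {site}: shift {shift} infeasible for sample "
                    f"{t.sample_id}; clipping (best effort)",
                    stacklevel=2,
                )
                f_new = min(max(f_new, 0.0), 0.9)
            segments = _plant_segments(spec, f_new, rng)
            row = rng.binomial(2, maf).astype(np.int8)
            for c, start, end in segments:
                idx = chrom_index[c]
                lo, hi = np.searchsorted(pos_arr[idx], [start, end + 1])
                sel = idx[lo:hi]
                row[sel] = 2 * (rng.random(sel.size) < maf[sel]).astype(np.int8)
            if spec.missing_rate > 0:
                row[rng.random(len(maf)) < spec.missing_rate] = MISSING
            new_calls[i] = row
            k = truth_pos[t.sample_id]
            new_truth[k].f_true = sum(e - s + 1 for _, s, e in segments) / spec.genome_bp
            new_truth[k].planted_segments = segments

    out = GenotypeMatrix(
        samples=[SampleRecord(s.sample_id, s.dataset_id, s.phenotype) for s in matrix.samples],
        variants=[VariantRecord(v.chrom, v.id, v.pos_bp, v.a1, v.a2) for v in matrix.variants],
        calls=new_calls,
    )
    return out.refresh_metadata(), new_truth


def simulate_phenotype_cohort(
    site_sizes: Mapping[str, int],
    beta_true: float = 0.0,
    froh_mean: float = 0.005,
    froh_zero_fraction: float = 0.0,
    confound_tau: float = 0.0,
    delta_by_site: Mapping[str, float] | None = None,
    intercept: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Froh-level cohort: (sample_id, dataset_id, froh, y) without genotypes.

    The fast path for calibration, coverage and power experiments: froh is
    drawn directly (zero-inflated exponential), phenotype from the logistic
    liability model, and site confounding applied as a mean shift
    ``delta_s * (y - site case fraction)`` truncated at zero.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    records = []
    for site, n in site_sizes.items():
        froh = np.where(
            rng.random(n) < froh_zero_fraction, 0.0, rng.exponential(froh_mean, size=n)
        )
        y = (rng.random(n) < expit(intercept + beta_true * froh)).astype(int)
        if delta_by_site is not None:
            d = delta_by_site.get(site, 0.0)
        elif confound_tau > 0:
            d = float(rng.normal(0.0, confound_tau))
        else:
            d = 0.0
        if d != 0.0 and n > 0:
            froh = np.maximum(0.0, froh + d * (y - y.mean()))
        for i in range(n):
            records.append((f"{site}_{i:05d}", site, float(froh[i]), int(y[i])))
    return pd.DataFrame(records, columns=["sample_id", "dataset_id", "froh", "y"])
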