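"""In-memory data model shared by every stage of the pipeline.

Genotypes are hard calls coded as counts of the second allele (``a2``):
0, 1, 2, with :data:`MISSING` (-1) for no-calls.  Coordinates are 1-based
inclusive throughout; the physical length of an interval is
``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in :attr:`GenotypeMatrix.calls`.
MISSING = -1

VALID_ALLELES = frozenset("ACGT120")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


class InvariantError(ValueError):
    """Raised when a data-model invariant is violated."""


@dataclass
class VariantRecord:
    """A single biallelic autosomal variant.

    ``maf`` and ``call_rate`` are summaries of the call matrix; use
    :meth:`GenotypeMatrix.refresh_metadata` to (re)compute them.
    """

    chrom: str
    id: str
    pos_bp: int
    a1: str = "1"
    a2: str = "2"
    maf: float = float("nan")
    call_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise InvariantError(f"variant {self.id}: pos_bp must be >= 1, got {self.pos_bp}")


@dataclass
class SampleRecord:
    """One individual: identity, site membership and phenotype.

    ``phenotype`` is 0 = control, 1 = case.  ``missing_rate`` and
    ``heterozygosity`` are recomputable summaries of the call matrix.
    """

    sample_id: str
    dataset_id: str = "all"
    phenotype: int = 0
    missing_rate: float = float("nan")
    heterozygosity: float = float("nan")

    def __post_init__(self) -> None:
        if self.phenotype not in (0, 1):
            raise InvariantError(
                f"sample {self.sample_id}: phenotype must be 0 or 1, got {self.phenotype}"
            )
        if not self.dataset_id:
            raise InvariantError(f"sample {self.sample_id}: dataset_id must be non-empty")


@dataclass
class GenotypeMatrix:
    """samples x variants matrix of hard calls with per-axis metadata.

    ``calls[i, j]`` counts copies of ``variants[j].a2`` carried by
    ``samples[i]`` (0/1/2), or :data:`MISSING`.
    """

    samples: list[SampleRecord]
    variants: list[VariantRecord]
    calls: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise InvariantError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise InvariantError("calls contain values outside {0, 1, 2, missing}")

    # ---- shape ----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # ---- derived arrays -------------------------------------------------

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def dataset_ids(self) -> np.ndarray:
        return np.array([s.dataset_id for s in self.samples])

    def phenotypes(self) -> np.ndarray:
        return np.array([s.phenotype for s in self.samples], dtype=int)

    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def positions(self) -> np.ndarray:
        return np.array([v.pos_bp for v in self.variants], dtype=np.int64)

    # ---- recomputable summaries ----------------------------------------

    def variant_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.full(self.n_variants, np.nan)
        return (self.calls != MISSING).mean(axis=0)

    def variant_maf(self) -> np.ndarray:
        """Minor-allele frequency per variant over non-missing calls."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
        return np.minimum(p, 1.0 - p)

    def variant_alt_freq(self) -> np.ndarray:
        """Frequency of the counted (a2) allele per variant."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def sample_missing_rate(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def sample_heterozygosity(self) -> np.ndarray:
        """Observed het fraction over non-missing calls, per sample."""
        obs = (self.calls != MISSING).sum(axis=1)
        het = (self.calls == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs > 0, het / obs, np.nan)

    def refresh_metadata(self) -> "GenotypeMatrix":
        """Overwrite cached per-variant and per-sample summaries from calls."""
        maf = self.variant_maf()
        cr = self.variant_call_rate()
        for j, v in enumerate(self.variants):
            v.maf = float(maf[j])
            v.call_rate = float(cr[j])
        miss = self.sample_missing_rate()
        het = self.sample_heterozygosity()
        for i, s in enumerate(self.samples):
            s.missing_rate = float(miss[i])
            s.heterozygosity = float(het[i])
        return self

    # ---- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check ordering invariants: per-chromosome strictly increasing positions."""
        chroms = self.chroms()
        pos = self.positions()
        for c in pd.unique(chroms):
            p = pos[chroms == c]
            if np.any(np.diff(p) <= 0):
                raise InvariantError(f"chromosome {c}: positions not strictly increasing")

    def is_position_sorted(self) -> bool:
        try:
            self.validate()
        except InvariantError:
            return False
        return True

    # ---- subsetting -----------------------------------------------------

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays (copies)."""
        si = (
            np.arange(self.n_samples)
            if sample_idx is None
            else np.asarray(sample_idx, dtype=np.intp)
        )
        vi = (
            np.arange(self.n_variants)
            if variant_idx is None
            else np.asarray(variant_idx, dtype=np.intp)
        )
        return GenotypeMatrix(
            samples=[replace(self.samples[int(i)]) for i in si],
            variants=[replace(self.variants[int(j)]) for j in vi],
            calls=self.calls[np.ix_(si, vi)].copy(),
        )

    # ---- table export ---------------------------------------------------

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "dataset_id": [s.dataset_id for s in self.samples],
                "phenotype": [s.phenotype for s in self.samples],
                "missing_rate": [s.missing_rate for s in self.samples],
                "heterozygosity": [s.heterozygosity for s in self.samples],
            }
        )

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "id": [v.id for v in self.variants],
                "pos_bp": [v.pos_bp for v in self.variants],
                "a1": [v.a1 for v in self.variants],
                "a2": [v.a2 for v in self.variants],
                "maf": [v.maf for v in self.variants],
                "call_rate": [v.call_rate for v in self.variants],
            }
        )


def sort_variants(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Sort variants by (chromosome, position), permuting calls consistently.

    Chromosomes are ordered numerically where the labels are integers,
    lexicographically otherwise.
    """

    def chrom_key(label: str):
        try:
            return (0, int(label), "")
        except ValueError:
            return (1, 0, label)

    order = sorted(
        range(matrix.n_variants),
        key=lambda j: (chrom_key(matrix.variants[j].chrom), matrix.variants[j].pos_bp),
    )
    return matrix.subset(variant_idx=order)
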