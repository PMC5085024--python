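"""Run-of-homozygosity calling and post-filtering.

An initial run is a maximal stretch of consecutive non-heterozygous calls
on one chromosome.  Runs are split at inter-SNP gaps above ``gap_split_bp``,
then kept only if they contain at least ``min_snps_initial`` SNPs and their
SNP density strictly exceeds one SNP per ``min_density_bp``.  Missing calls
terminate a run by default (configurable).  Post-filtering tightens the
SNP-count or physical-length threshold without re-calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, InvariantError


@dataclass(frozen=True)
class CallingParams:
    """Parameters of the initial run scan.

    ``max_het`` is fixed at 0: a single heterozygote call always breaks a run.
    ``min_density_bp`` is a floor: a segment must have strictly more than one
    SNP per this many bases.
    """

    min_snps_initial: int = 40
    max_het: int = 0
    min_density_bp: int = 200_000
    gap_split_bp: int = 500_000
    missing_breaks: bool = True

    def __post_init__(self) -> None:
        if self.min_snps_initial < 1:
            raise InvariantError("min_snps_initial must be >= 1")
        if self.max_het != 0:
            raise InvariantError("max_het is fixed at 0 (heterozygote-free runs)")
        if self.min_density_bp <= 0 or self.gap_split_bp <= 0:
            raise InvariantError("bp parameters must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One called run: 1-based inclusive bp coordinates of its first and last SNP."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise InvariantError(
                f"segment {self.sample_id}:{self.chrom}: end_bp {self.end_bp} < start_bp {self.start_bp}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class ROHSet:
    """A collection of called segments plus the thresholds they satisfy."""

    segments: list[ROHSegment]
    params: CallingParams = field(default_factory=CallingParams)
    min_snps_filter: int | None = None
    min_mb_filter: float | None = None

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def by_sample(self) -> dict[str, list[ROHSegment]]:
        out: dict[str, list[ROHSegment]] = {}
        for seg in self.segments:
            out.setdefault(seg.sample_id, []).append(seg)
        return out

    def total_bp_by_sample(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for seg in self.segments:
            out[seg.sample_id] = out.get(seg.sample_id, 0) + seg.length_bp
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.segments],
                "chrom": [s.chrom for s in self.segments],
                "start_bp": [s.start_bp for s in self.segments],
                "end_bp": [s.end_bp for s in self.segments],
                "n_snps": [s.n_snps for s in self.segments],
                "length_bp": [s.length_bp for s in self.segments],
            }
        )


def _scan_chromosome(
    hom: np.ndarray, pos: np.ndarray, params: CallingParams
) -> list[tuple[int, int, int]]:
    """Return (start_bp, end_bp, n_snps) for surviving runs on one chromosome.

    ``hom`` is a boolean array over position-sorted SNPs: True where the call
    participates in a run.  Gap-splitting and the SNP-count/density filters
    are applied here.
    """
    out: list[tuple[int, int, int]] = []
    n = hom.size
    if n == 0:
        return out
    # run boundaries of consecutive True
    padded = np.concatenate(([False], hom, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    for a, b in zip(starts, ends):
        # split at gaps > gap_split_bp between consecutive run SNPs
        gaps = np.diff(pos[a:b])
        cut = np.flatnonzero(gaps > params.gap_split_bp) + a + 1
        bounds = np.concatenate(([a], cut, [b]))
        for i in range(len(bounds) - 1):
            lo, hi = int(bounds[i]), int(bounds[i + 1])
            n_snps = hi - lo
            if n_snps < params.min_snps_initial:
                continue
            start_bp = int(pos[lo])
            end_bp = int(pos[hi - 1])
            length = end_bp - start_bp + 1
            # density strictly greater than 1 SNP per min_density_bp
            if n_snps * params.min_density_bp <= length:
                continue
            out.append((start_bp, end_bp, n_snps))
    return out


def call_roh(matrix: GenotypeMatrix, params: CallingParams | None = None) -> ROHSet:
    """Call runs of homozygosity for every sample.

    The matrix must be position-sorted within each chromosome; an unsorted
    matrix raises rather than being silently sorted.
    """
    params = params or CallingParams()
    matrix.validate()
    chroms = matrix.chroms()
    pos = matrix.positions()
    segments: list[ROHSegment] = []
    chrom_slices = []
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        chrom_slices.append((str(c), idx, pos[idx]))
    for i, sample in enumerate(matrix.samples):
        row = matrix.calls[i]
        for c, idx, cpos in chrom_slices:
            calls = row[idx]
            if params.missing_breaks:
                hom = (calls == 0) | (calls == 2)
                use_pos = cpos
            else:
                # missing is transparent: drop those sites from the scan
                keep = calls != -1
                hom = (calls[keep] == 0) | (calls[keep] == 2)
                use_pos = cpos[keep]
            for start_bp, end_bp, n_snps in _scan_chromosome(hom, use_pos, params):
                segments.append(
                    ROHSegment(sample.sample_id, c, start_bp, end_bp, n_snps)
                )
    return ROHSet(segments=segments, params=params, min_snps_filter=params.min_snps_initial)


def filter_roh(
    rohset: ROHSet, min_snps: int | None = None, min_mb: float | None = None
) -> ROHSet:
    """Tighten the post-filter threshold on an already-called set.

    Exactly one of ``min_snps`` / ``min_mb`` must be given.  Thresholds below
    the calling floor are refused: segments that would pass were never called.
    """
    if (min_snps is None) == (min_mb is None):
        raise ValueError("give exactly one of min_snps or min_mb")
    if min_snps is not None:
        if min_snps < rohset.params.min_snps_initial:
            raise ValueError(
                f"min_snps {min_snps} is below the calling floor "
                f"{rohset.params.min_snps_initial}; re-call instead of filtering"
            )
        kept = [s for s in rohset.segments if s.n_snps >= min_snps]
        return ROHSet(kept, rohset.params, min_snps_filter=min_snps,
                      min_mb_filter=rohset.min_mb_filter)
    if min_mb <= 0:
        raise ValueError("min_mb must be positive")
    min_bp = min_mb * 1e6
    kept = [s for s in rohset.segments if s.length_bp >= min_bp]
    return ROHSet(kept, rohset.params, min_snps_filter=rohset.min_snps_filter,
                  min_mb_filter=min_mb)


def longest_roh_per_sample(
    rohset: ROHSet, sample_ids: Iterable[str] | None = None
) -> pd.DataFrame:
    """Longest segment length (bp) per sample; 0 for samples without segments."""
    longest: dict[str, int] = {}
    for seg in rohset.segments:
        if seg.length_bp > longest.get(seg.sample_id, 0):
            longest[seg.sample_id] = seg.length_bp
    ids = list(sample_ids) if sample_ids is not None else sorted(longest)
    return pd.DataFrame(
        {"sample_id": ids, "longest_bp": [longest.get(s, 0) for s in ids]}
    )


def drop_extreme_roh(
    rohset: ROHSet,
    max_mb: float = 30.0,
    mode: Literal["drop_individuals", "drop_segments"] = "drop_individuals",
) -> tuple[ROHSet, list[str]]:
    """Remove very long segments, or every sample owning one.

    Returns the filtered set and the list of removed sample ids (empty in
    ``drop_segments`` mode).
    """
    max_bp = max_mb * 1e6
    if mode == "drop_segments":
        kept = [s for s in rohset.segments if s.length_bp <= max_bp]
        return (
            ROHSet(kept, rohset.params, rohset.min_snps_filter, rohset.min_mb_filter),
            [],
        )
    if mode != "drop_individuals":
        raise ValueError(f"unknown mode {mode!r}")
    flagged = sorted({s.sample_id for s in rohset.segments if s.length_bp > max_bp})
    kept = [s for s in rohset.segments if s.sample_id not in set(flagged)]
    return (
        ROHSet(kept, rohset.params, rohset.min_snps_filter, rohset.min_mb_filter),
        flagged,
    )


@dataclass(frozen=True)
class ThresholdGrid:
    """Default sweep grids: 40..200 SNPs by 10, and 1..20 Mb by 1."""

    snp_thresholds: tuple[int, ...] = tuple(range(40, 201, 10))
    mb_thresholds: tuple[int, ...] = tuple(range(1, 21))
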