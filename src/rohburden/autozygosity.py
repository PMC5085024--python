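"""Genomic inbreeding statistics from called ROH segments.

Froh is the summed autosomal segment length divided by a fixed mappable
genome size (default 2.77e9 bp).  The short/long decomposition partitions
segments at a physical-length cutoff: strictly below the cutoff is "short",
at or above is "long", so froh_short + froh_long == froh exactly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import SampleRecord
from .roh import ROHSet

#: Total SNP-mappable autosomal distance in base pairs.
MAPPABLE_BP = 2.77e9

#: Default grid for the variance-equalizing cutoff search (Mb).
DEFAULT_CUTOFF_GRID = tuple(range(1, 21))


def _sample_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
        if "dataset_id" not in df:
            df["dataset_id"] = "all"
        if "phenotype" not in df:
            df["phenotype"] = 0
        return df[["sample_id", "dataset_id", "phenotype"]]
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "dataset_id": [s.dataset_id for s in samples],
            "phenotype": [s.phenotype for s in samples],
        }
    )


def compute_froh(
    rohset: ROHSet,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    mappable_bp: float = MAPPABLE_BP,
) -> pd.DataFrame:
    """Per-sample Froh table.

    ``samples`` fixes the row set: individuals without any segment get
    froh = 0.  Columns: sample_id, dataset_id, phenotype, froh, n_segments,
    total_bp, mean_segment_mb.
    """
    if mappable_bp <= 0:
        raise ValueError("mappable_bp must be positive")
    df = _sample_frame(samples)
    total: dict[str, int] = {}
    count: dict[str, int] = {}
    for seg in rohset.segments:
        total[seg.sample_id] = total.get(seg.sample_id, 0) + seg.length_bp
        count[seg.sample_id] = count.get(seg.sample_id, 0) + 1
    df["total_bp"] = df["sample_id"].map(total).fillna(0).astype(np.int64)
    df["n_segments"] = df["sample_id"].map(count).fillna(0).astype(int)
    df["froh"] = df["total_bp"] / mappable_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        df["mean_segment_mb"] = np.where(
            df["n_segments"] > 0, df["total_bp"] / df["n_segments"] / 1e6, 0.0
        )
    return df


def split_froh(
    rohset: ROHSet,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    cutoff_mb: float = 8.0,
    mappable_bp: float = MAPPABLE_BP,
) -> pd.DataFrame:
    """Froh table with the short/long decomposition at ``cutoff_mb``.

    Segments with length < cutoff contribute to froh_short, >= cutoff to
    froh_long.
    """
    if cutoff_mb <= 0:
        raise ValueError("cutoff_mb must be positive")
    df = compute_froh(rohset, samples, mappable_bp)
    cutoff_bp = cutoff_mb * 1e6
    short: dict[str, int] = {}
    for seg in rohset.segments:
        if seg.length_bp < cutoff_bp:
            short[seg.sample_id] = short.get(seg.sample_id, 0) + seg.length_bp
    short_bp = df["sample_id"].map(short).fillna(0).astype(np.int64)
    df["froh_short"] = short_bp / mappable_bp
    df["froh_long"] = (df["total_bp"] - short_bp) / mappable_bp
    # enforce exact conservation: the sum of the two float quotients can be
    # 1 ulp from total_bp / mappable_bp
    df["froh"] = df["froh_short"] + df["froh_long"]
    return df


def variance_equalizing_cutoff(
    rohset: ROHSet,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    candidate_grid: Iterable[float] = DEFAULT_CUTOFF_GRID,
    mappable_bp: float = MAPPABLE_BP,
) -> float:
    """Grid cutoff minimizing |var(froh_short) - var(froh_long)| across samples.

    Ties break toward the smaller cutoff.  A degenerate set (all froh equal,
    hence zero variance everywhere) is refused.
    """
    grid = sorted(candidate_grid)
    if not grid:
        raise ValueError("candidate_grid is empty")
    base = compute_froh(rohset, samples, mappable_bp)
    if base["froh"].nunique() <= 1:
        raise ValueError(
            "degenerate froh distribution: all samples have identical froh, "
            "variances cannot be equalized"
        )
    best_cut, best_gap = None, np.inf
    for cut in grid:
        df = split_froh(rohset, samples, cutoff_mb=cut, mappable_bp=mappable_bp)
        gap = abs(df["froh_short"].var(ddof=1) - df["froh_long"].var(ddof=1))
        if gap < best_gap - 1e-18:
            best_cut, best_gap = cut, gap
    return float(best_cut)


def froh_descriptives(froh_df: pd.DataFrame, rohset: ROHSet) -> pd.DataFrame:
    """Per-dataset descriptive table.

    Rows: one per dataset.  Columns: n, n_cases, avg_froh_x100, sd_froh_x100,
    avg_mb, sd_mb.  Segment Mb statistics average over segments (not over
    per-sample means); SD with a single observation is reported as 0.
    """
    seg_df = rohset.to_frame()
    dataset_of = dict(zip(froh_df["sample_id"], froh_df["dataset_id"]))
    if len(seg_df):
        seg_df["dataset_id"] = seg_df["sample_id"].map(dataset_of)
        seg_df["length_mb"] = seg_df["length_bp"] / 1e6

    rows = []
    for ds, grp in froh_df.groupby("dataset_id", sort=True):
        froh100 = grp["froh"] * 100.0
        if len(seg_df):
            mb = seg_df.loc[seg_df["dataset_id"] == ds, "length_mb"]
        else:
            mb = pd.Series(dtype=float)
        rows.append(
            {
                "dataset_id": ds,
                "n": len(grp),
                "n_cases": int(grp["phenotype"].sum()),
                "avg_froh_x100": froh100.mean(),
                "sd_froh_x100": froh100.std(ddof=1) if len(grp) > 1 else 0.0,
                "avg_mb": mb.mean() if len(mb) else 0.0,
                "sd_mb": (mb.std(ddof=1) if len(mb) > 1 else 0.0),
            }
        )
    return pd.DataFrame(rows)
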