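"""Genomic interval primitives shared across the pipeline.

All coordinates are 1-based inclusive in memory (the convention of
PennCNV-style call records).  BED files on disk are 0-based half-open and
are converted at the I/O boundary (:mod:`cnvtrait.io`), never here.

An interval table is a :class:`pandas.DataFrame` with at least the columns
``chrom``, ``start_bp``, ``end_bp`` plus arbitrary payload columns (gene
name, event count, region label, ...).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start_bp", "end_bp"]


def span_bp(start_bp, end_bp):
    """Inclusive span in bp: ``end - start + 1``."""
    return np.asarray(end_bp) - np.asarray(start_bp) + 1


def overlap_bp(a_start, a_end, b_start, b_end):
    """bp overlap of two 1-based inclusive intervals (0 if disjoint)."""
    lo = np.maximum(np.asarray(a_start), np.asarray(b_start))
    hi = np.minimum(np.asarray(a_end), np.asarray(b_end))
    return np.maximum(hi - lo + 1, 0)


def reciprocal_overlap(a_start, a_end, b_start, b_end):
    """Smaller of the two overlap fractions (each anchored on its own span)."""
    ov = overlap_bp(a_start, a_end, b_start, b_end)
    fa = ov / span_bp(a_start, a_end)
    fb = ov / span_bp(b_start, b_end)
    return np.minimum(fa, fb)


def validate_intervals(df: pd.DataFrame) -> None:
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval table lacks columns {missing}")
    bad = df["start_bp"] > df["end_bp"]
    if bool(np.asarray(bad).any()):
        raise ValueError("interval with start_bp > end_bp")


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union-merge overlapping or book-ended intervals per chromosome.

    Payload columns are dropped; output is sorted by (chrom, start).
    Book-ended means touching at adjacent bp (end + 1 == next start).
    """
    if len(df) == 0:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    validate_intervals(df)
    out = []
    for chrom, grp in df.sort_values(["chrom", "start_bp", "end_bp"]).groupby(
        "chrom", sort=True
    ):
        cur_s = cur_e = None
        for s, e in zip(grp["start_bp"].to_numpy(), grp["end_bp"].to_numpy()):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


class _ChromIndex:
    """Sorted non-overlapping intervals of one chromosome for fast queries."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.starts = starts
        self.ends = ends

    def covered_bp(self, start: int, end: int) -> int:
        """bp of [start, end] covered by the (merged) intervals."""
        lo = np.searchsorted(self.ends, start, side="left")
        hi = np.searchsorted(self.starts, end, side="right")
        if hi <= lo:
            return 0
        ov = overlap_bp(start, end, self.starts[lo:hi], self.ends[lo:hi])
        return int(ov.sum())

    def overlaps(self, start: int, end: int) -> bool:
        return self.covered_bp(start, end) > 0


class IntervalIndex:
    """Per-chromosome query index over a merged interval table."""

    def __init__(self, df: pd.DataFrame, merge: bool = True):
        src = merge_intervals(df) if merge else df
        self._by_chrom: dict[str, _ChromIndex] = {}
        for chrom, grp in src.groupby("chrom", sort=False):
            g = grp.sort_values("start_bp")
            self._by_chrom[str(chrom)] = _ChromIndex(
                g["start_bp"].to_numpy(), g["end_bp"].to_numpy()
            )

    def covered_bp(self, chrom, start: int, end: int) -> int:
        idx = self._by_chrom.get(str(chrom))
        return 0 if idx is None else idx.covered_bp(int(start), int(end))

    def covered_fraction(self, chrom, start: int, end: int) -> float:
        return self.covered_bp(chrom, start, end) / float(span_bp(start, end))

    def overlaps(self, chrom, start: int, end: int) -> bool:
        return self.covered_bp(chrom, start, end) > 0
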