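"""CNV call quality control, joining, annotation and classification.

The filtering rules follow the PennCNV-style protocol used in array CNV
studies of this design:

* calls are retained iff confidence >= 10, span >= 20 kb, >= 10 probes and
  < 50 % of the span overlapping exclusion regions (Ig/PAR/centromere-like
  gaps);
* adjacent same-state calls of one sample are joined when the gap between
  them is <= 20 % of the total covered region, iterated to a fixed point;
* samples with > 100 autosomal calls or an LRR standard deviation > 0.35
  are dropped with all their calls;
* surviving calls are annotated to genes within a 50-kb flank beyond the
  transcript span, flagged exonic when an exon is intersected, and
  classified rare when fewer than five reference-catalogue events overlap
  at least 50 % of the call span.

Coordinates are 1-based inclusive; span = end - start + 1 for every
filtering rule.  The kb figures printed in report tables use the
``end - start`` difference (see :func:`call_span_kb`).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import IntervalIndex, overlap_bp, span_bp

MIN_CONFIDENCE = 10.0
MIN_SPAN_BP = 20_000
MIN_SNPS = 10
MAX_EXCLUSION_FRACTION = 0.50
MAX_JOIN_GAP_FRACTION = 0.20
GENE_FLANK_BP = 50_000
RARE_MAX_EVENTS = 5
RARE_MIN_OVERLAP_FRACTION = 0.50
MAX_AUTOSOMAL_CALLS = 100
MAX_LRR_SD = 0.35


def qc_flags(calls: pd.DataFrame, exclusion_regions: pd.DataFrame,
             min_confidence: float = MIN_CONFIDENCE,
             min_span_bp: int = MIN_SPAN_BP, min_snps: int = MIN_SNPS,
             max_exclusion_fraction: float = MAX_EXCLUSION_FRACTION) -> pd.DataFrame:
    """Per-rule pass/fail flags for every call (thresholds inclusive)."""
    spans = span_bp(calls["start_bp"], calls["end_bp"])
    excl = IntervalIndex(exclusion_regions) if len(exclusion_regions) else None
    if excl is None:
        frac = np.zeros(len(calls))
    else:
        frac = np.array([
            excl.covered_fraction(c, s, e)
            for c, s, e in zip(calls["chrom"], calls["start_bp"], calls["end_bp"])
        ])
    return pd.DataFrame(
        {
            "pass_confidence": calls["confidence"].to_numpy() >= min_confidence,
            "pass_span": np.asarray(spans) >= min_span_bp,
            "pass_snps": calls["n_snps"].to_numpy() >= min_snps,
            "pass_exclusion": frac < max_exclusion_fraction,
        },
        index=calls.index,
    )


def filter_calls(calls: pd.DataFrame, exclusion_regions: pd.DataFrame,
                 **thresholds) -> pd.DataFrame:
    """Retain calls passing all four call-level rules."""
    flags = qc_flags(calls, exclusion_regions, **thresholds)
    return calls.loc[flags.all(axis=1)].copy()


def join_adjacent_calls(calls: pd.DataFrame,
                        max_gap_fraction: float = MAX_JOIN_GAP_FRACTION) -> pd.DataFrame:
    """Join same-sample/chrom/copy-number calls separated by small gaps.

    Two consecutive calls A, B merge into [A.start, B.end] when
    ``gap / (B.end - A.start + 1) <= max_gap_fraction`` with
    ``gap = B.start - A.end - 1`` (overlapping calls have gap <= 0 and
    always merge).  Applied left-to-right until a fixed point.  Merged
    probe counts add; merged confidence is the member maximum.
    """
    if len(calls) == 0:
        return calls.copy()
    out = []
    extra = [c for c in calls.columns
             if c not in ("sample_id", "chrom", "start_bp", "end_bp",
                          "copy_number", "n_snps", "confidence")]
    for (sid, chrom, cn), grp in calls.groupby(
            ["sample_id", "chrom", "copy_number"], sort=False):
        recs = grp.sort_values(["start_bp", "end_bp"]).to_dict("records")
        changed = True
        while changed:
            changed = False
            merged = [recs[0]]
            for b in recs[1:]:
                a = merged[-1]
                gap = b["start_bp"] - a["end_bp"] - 1
                total = b["end_bp"] - a["start_bp"] + 1
                if total > 0 and gap / total <= max_gap_fraction:
                    a["end_bp"] = max(a["end_bp"], b["end_bp"])
                    a["n_snps"] = a["n_snps"] + b["n_snps"]
                    a["confidence"] = max(a["confidence"], b["confidence"])
                    for c in extra:
                        av, bv = a.get(c), b.get(c)
                        if isinstance(av, (bool, np.bool_)):
                            a[c] = bool(av) or bool(bv)
                    changed = True
                else:
                    merged.append(b)
            recs = merged
        out.extend(recs)
    result = pd.DataFrame(out, columns=calls.columns)
    return result.sort_values(["sample_id", "chrom", "start_bp"],
                              kind="stable").reset_index(drop=True)


def filter_samples(calls: pd.DataFrame, lrr_sd_per_sample: pd.Series,
                   max_autosomal_calls: int = MAX_AUTOSOMAL_CALLS,
                   max_lrr_sd: float = MAX_LRR_SD):
    """Drop whole samples with excess autosomal calls or noisy LRR.

    Thresholds are strict: a sample is dropped iff its autosomal call
    count exceeds ``max_autosomal_calls`` OR its LRR SD exceeds
    ``max_lrr_sd``.  Only autosomal calls count; X-chromosome calls ride
    along with their sample's fate.
    """
    with_calls = calls["sample_id"].unique()
    missing = [s for s in with_calls if s not in lrr_sd_per_sample.index
               or pd.isna(lrr_sd_per_sample[s])]
    if missing:
        raise ValueError(f"no LRR SD for samples with calls: {missing[:5]}")
    auto_counts = (calls.loc[calls["chrom"].astype(str) != "X"]
                   .groupby("sample_id").size())
    dropped = set()
    for sid in with_calls:
        if auto_counts.get(sid, 0) > max_autosomal_calls:
            dropped.add(sid)
        elif lrr_sd_per_sample[sid] > max_lrr_sd:
            dropped.add(sid)
    kept_samples = [s for s in lrr_sd_per_sample.index if s not in dropped]
    kept_calls = calls.loc[~calls["sample_id"].isin(dropped)].copy()
    return kept_samples, kept_calls


def _tree_by_chrom(df: pd.DataFrame, pad: int = 0) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    # data carries a unique ordinal: IntervalTree has set semantics and
    # would otherwise collapse identical intervals (distinct events)
    for i, row in enumerate(df.itertuples(index=False)):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start_bp) - pad, int(row.end_bp) + 1 + pad, (i, row))
    return trees


def annotate_genes(calls: pd.DataFrame, genes: pd.DataFrame,
                   exons: pd.DataFrame,
                   flank_bp: int = GENE_FLANK_BP) -> pd.DataFrame:
    """Annotate calls to genes within ``flank_bp`` of the transcript span.

    Adds a ``genes`` column (comma-joined sorted symbols, "" when none)
    and an ``exonic`` flag set iff any exon interval intersects the call.
    """
    gene_trees = _tree_by_chrom(genes, pad=flank_bp)
    exon_trees = _tree_by_chrom(exons)
    hit_lists, exonic = [], []
    for call in calls.itertuples(index=False):
        gt = gene_trees.get(str(call.chrom))
        hits = (sorted({iv.data[1].gene for iv in
                        gt.overlap(call.start_bp, call.end_bp + 1)})
                if gt is not None else [])
        et = exon_trees.get(str(call.chrom))
        has_exon = bool(et is not None
                        and et.overlap(call.start_bp, call.end_bp + 1))
        hit_lists.append(",".join(hits))
        exonic.append(has_exon)
    out = calls.copy()
    out["genes"] = hit_lists
    out["exonic"] = exonic
    return out


def classify_rarity(calls: pd.DataFrame, reference_cnvs: pd.DataFrame,
                    max_events: int = RARE_MAX_EVENTS,
                    min_overlap_fraction: float = RARE_MIN_OVERLAP_FRACTION
                    ) -> pd.DataFrame:
    """Flag calls rare when < ``max_events`` reference events overlap them.

    An event qualifies when its intersection covers at least
    ``min_overlap_fraction`` of the *call's* span.  Reference rows carry
    an event ``count`` (several catalogued events at one locus); missing
    counts default to 1.
    """
    ref = reference_cnvs.copy()
    if "count" not in ref.columns:
        ref["count"] = 1
    trees = _tree_by_chrom(ref)
    n_overlaps, rare = [], []
    for call in calls.itertuples(index=False):
        t = trees.get(str(call.chrom))
        total = 0
        if t is not None:
            span = call.end_bp - call.start_bp + 1
            for iv in t.overlap(call.start_bp, call.end_bp + 1):
                ref_row = iv.data[1]
                ov = overlap_bp(call.start_bp, call.end_bp,
                                ref_row.start_bp, ref_row.end_bp)
                if ov / span >= min_overlap_fraction:
                    total += int(ref_row.count)
        n_overlaps.append(total)
        rare.append(total < max_events)
    out = calls.copy()
    out["ref_overlaps"] = n_overlaps
    out["rare"] = rare
    return out


def call_span_kb(start_bp: int, end_bp: int) -> int:
    """Reported length in kb: ``(end - start) / 1000`` rounded to integer.

    This is the printed-table convention (difference, not inclusive span);
    the inclusive span is used for filtering and burden, not here.
    """
    if end_bp < start_bp:
        raise ValueError("end_bp < start_bp")
    return int(np.rint((end_bp - start_bp) / 1000.0))


def run_call_qc(calls: pd.DataFrame, exclusion_regions: pd.DataFrame,
                lrr_sd_per_sample: pd.Series, genes: pd.DataFrame,
                exons: pd.DataFrame, reference_cnvs: pd.DataFrame):
    """Full QC chain: filter -> join -> sample QC -> annotate -> rarity.

    Returns ``(annotated_calls, kept_samples, counts)`` where ``counts``
    logs the per-stage call accounting.
    """
    counts = {"input": len(calls)}
    kept = filter_calls(calls, exclusion_regions)
    counts["after_call_filters"] = len(kept)
    joined = join_adjacent_calls(kept)
    counts["after_joining"] = len(joined)
    kept_samples, joined = filter_samples(joined, lrr_sd_per_sample)
    counts["after_sample_qc"] = len(joined)
    counts["samples_kept"] = len(kept_samples)
    annotated = annotate_genes(joined, genes, exons)
    annotated = classify_rarity(annotated, reference_cnvs)
    counts["annotated_to_genes"] = int((annotated["genes"] != "").sum())
    counts["annotated_to_exons"] = int(annotated["exonic"].sum())
    counts["rare"] = int(annotated["rare"].sum())
    return annotated, kept_samples, counts
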