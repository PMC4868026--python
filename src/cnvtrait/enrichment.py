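"""Interval-permutation enrichment of CNV calls against gene sets.

The test asks whether a collection of independent genomic intervals (CNV
calls of the cases) hits the genes of a set more often than random
intervals would.  The statistic per set is the number of intervals
overlapping at least one member gene (gene spans extended by the standard
50-kb flank).  The null replaces every interval with a random run of the
same number of consecutive *covered* probes — probes encompassed by CNV
calls — drawn uniformly among feasible positions, so the null intervals
match the observed ones in probe footprint and stay inside the CNV-prone
part of the genome.  Empirical p is (1 + exceedances) / (1 + permutations),
Bonferroni-corrected across the tested sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import merge_intervals
from .qc import GENE_FLANK_BP


@dataclass
class EnrichmentResult:
    set_name: str
    observed: int
    n_intervals: int
    p_empirical: float
    p_corrected: float
    n_perms: int


def independent_intervals(calls: pd.DataFrame, merge_per_sample: bool = True,
                          collapse_duplicates: bool = True) -> pd.DataFrame:
    """Reduce calls to independent intervals for the enrichment test.

    Overlapping calls of one sample are union-merged, and identical
    intervals recurring across (sibling) carriers collapse to one row.
    """
    df = calls[["sample_id", "chrom", "start_bp", "end_bp"]].copy()
    if merge_per_sample:
        parts = []
        for sid, grp in df.groupby("sample_id", sort=False):
            m = merge_intervals(grp)
            m["sample_id"] = sid
            parts.append(m)
        df = pd.concat(parts, ignore_index=True) if parts else df
    if collapse_duplicates:
        df = df.drop_duplicates(subset=["chrom", "start_bp", "end_bp"])
    return df[["chrom", "start_bp", "end_bp"]].reset_index(drop=True)


class _SetIntervals:
    """Merged per-chromosome gene-set intervals supporting bulk overlap tests."""

    def __init__(self, intervals: pd.DataFrame):
        self._by_chrom = {}
        merged = merge_intervals(intervals)
        for chrom, grp in merged.groupby("chrom", sort=False):
            self._by_chrom[str(chrom)] = (grp["start_bp"].to_numpy(),
                                          grp["end_bp"].to_numpy())

    def hits(self, chroms: np.ndarray, starts: np.ndarray,
             ends: np.ndarray) -> np.ndarray:
        out = np.zeros(len(starts), dtype=bool)
        for chrom in np.unique(chroms):
            se = self._by_chrom.get(str(chrom))
            if se is None:
                continue
            mask = chroms == chrom
            s, e = starts[mask], ends[mask]
            ms, me = se
            lo = np.searchsorted(me, s, side="left")
            hit = (lo < len(ms)) & (ms[np.minimum(lo, len(ms) - 1)] <= e)
            out[mask] = hit
        return out


def target_enrichment(intervals: pd.DataFrame, gene_sets: dict[str, list[str]],
                      genes: pd.DataFrame, covered_probes: pd.DataFrame,
                      n_perms: int = 1000, seed: int | None = None,
                      flank_bp: int = GENE_FLANK_BP) -> pd.DataFrame:
    """Permutation enrichment of intervals against each gene set.

    ``covered_probes`` is the (chrom, pos)-sorted manifest subset of
    probes encompassed by CNV calls; every tested interval must contain at
    least one of them (that footprint sizes its null replacements).
    Gene symbols absent from ``genes`` are ignored; an empty resolvable
    set is skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    cp = covered_probes.sort_values(["chrom", "pos"], kind="stable")
    chrom_arr = cp["chrom"].astype(str).to_numpy()
    pos_arr = cp["pos"].to_numpy()
    n_cov = len(cp)
    if n_cov == 0:
        raise ValueError("no covered probes")
    # ordinal ranges per chromosome for feasibility of k-probe runs
    chrom_bounds = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        chrom_bounds[chrom] = (idx[0], idx[-1])

    iv = intervals.reset_index(drop=True)
    iv_chrom = iv["chrom"].astype(str).to_numpy()
    iv_start = iv["start_bp"].to_numpy()
    iv_end = iv["end_bp"].to_numpy()
    k_probes = np.empty(len(iv), dtype=int)
    for i in range(len(iv)):
        mask = chrom_arr == iv_chrom[i]
        k = int(((pos_arr >= iv_start[i]) & (pos_arr <= iv_end[i]) & mask).sum())
        if k == 0:
            raise ValueError(
                f"interval {iv_chrom[i]}:{iv_start[i]}-{iv_end[i]} "
                f"contains no covered probe")
        k_probes[i] = k

    # feasible run starts per distinct footprint size
    feasible: dict[int, np.ndarray] = {}
    for k in np.unique(k_probes):
        ok = []
        for chrom, (lo, hi) in chrom_bounds.items():
            if hi - lo + 1 >= k:
                ok.append(np.arange(lo, hi - k + 2))
        feasible[int(k)] = np.concatenate(ok)

    gene_pos = genes.set_index("gene")[["chrom", "start_bp", "end_bp"]]
    results = []
    tested_sets = []
    for name, members in gene_sets.items():
        found = [g for g in members if g in gene_pos.index]
        if not found:
            warnings.warn(f"gene set {name!r} resolves to no genes; skipped")
            continue
        sub = gene_pos.loc[found].reset_index()
        sub["start_bp"] = sub["start_bp"] - flank_bp
        sub["end_bp"] = sub["end_bp"] + flank_bp
        tested_sets.append((name, _SetIntervals(sub)))

    # pre-draw null probe runs shared across sets (same null per set,
    # as a single permutation replaces the whole interval collection)
    null_starts = np.empty((n_perms, len(iv)), dtype=int)
    for i in range(len(iv)):
        null_starts[:, i] = rng.choice(feasible[int(k_probes[i])],
                                       size=n_perms)
    null_end_idx = null_starts + (k_probes - 1)[None, :]
    ns_chrom = chrom_arr[null_starts]
    ns_start = pos_arr[null_starts]
    ns_end = pos_arr[null_end_idx]

    for name, set_iv in tested_sets:
        observed = int(set_iv.hits(iv_chrom, iv_start, iv_end).sum())
        null_counts = np.empty(n_perms, dtype=int)
        for p in range(n_perms):
            null_counts[p] = int(set_iv.hits(ns_chrom[p], ns_start[p],
                                             ns_end[p]).sum())
        exceed = int((null_counts >= observed).sum())
        p_emp = (1.0 + exceed) / (1.0 + n_perms)
        results.append(EnrichmentResult(name, observed, len(iv), p_emp,
                                        min(1.0, p_emp * len(tested_sets)),
                                        n_perms))
    return pd.DataFrame([r.__dict__ for r in results])


def build_candidate_sets(term_table: dict[str, list[str]],
                         keywords: dict[str, list[str]]) -> dict[str, list[str]]:
    """Composite gene sets by case-insensitive keyword match on set names.

    ``term_table`` maps term/set names to member genes; each composite is
    the union of all sets whose name contains any of its keywords.
    """
    out: dict[str, list[str]] = {}
    for composite, words in keywords.items():
        genes: set[str] = set()
        for term, members in term_table.items():
            low = term.lower()
            if any(w.lower() in low for w in words):
                genes.update(members)
        if not genes:
            warnings.warn(f"keywords for {composite!r} matched no sets")
        out[composite] = sorted(genes)
    return out
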