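"""Screens of annotated CNV calls for co-segregation with reading disability.

Three complementary screens on the QC-passing, annotated calls:

* large events (> 500 kb) carried by cases, with carrier phenotype scores;
* events shared by two or more affected co-siblings of one sibship and
  absent from unaffected participants — within the family or cohort-wide
  ("strict", the default);
* events overlapping user-supplied candidate genes/regions (reading and
  language susceptibility loci, neuropsychiatric CNV regions), with a
  per-family co-segregation verdict.

Two calls count as "the same CNV" across individuals when they overlap
reciprocally by at least 50 % and are the same direction (loss vs gain);
clusters are single-linkage transitive closures of that relation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import reciprocal_overlap
from .qc import GENE_FLANK_BP
from .synthetic import baseline_copy_number

LARGE_MIN_KB = 500
RECIPROCAL_MIN = 0.50

PHENO_COLS = ("PC1", "IQadjPC1", "IBGdiscr")


def _direction(cn: int, chrom, sex: str) -> str:
    return "loss" if int(cn) < baseline_copy_number(chrom, sex) else "gain"


def _attach_phenotypes(report: pd.DataFrame, phenotypes: pd.DataFrame
                       ) -> pd.DataFrame:
    cols = [c for c in PHENO_COLS if c in phenotypes.columns]
    ph = phenotypes.set_index("sample_id")[cols] \
        if "sample_id" in phenotypes.columns else phenotypes[cols]
    return report.merge(ph, left_on="sample_id", right_index=True, how="left")


def find_large_case_cnvs(calls: pd.DataFrame, labels: pd.Series,
                         phenotypes: pd.DataFrame,
                         min_kb: float = LARGE_MIN_KB) -> pd.DataFrame:
    """Calls of case samples spanning strictly more than ``min_kb`` kb."""
    span = calls["end_bp"] - calls["start_bp"] + 1
    is_case = calls["sample_id"].map(labels).eq("case")
    report = calls.loc[is_case & (span > min_kb * 1000)].copy()
    report["length_kb"] = ((report["end_bp"] - report["start_bp"]) / 1000.0
                           ).round().astype(int)
    return _attach_phenotypes(report, phenotypes).reset_index(drop=True)


def _clusters(records: list[dict], min_reciprocal: float) -> list[list[int]]:
    """Single-linkage clusters under reciprocal overlap + same direction."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a["chrom"] != b["chrom"] or a["dir"] != b["dir"]:
                continue
            ro = reciprocal_overlap(a["start_bp"], a["end_bp"],
                                    b["start_bp"], b["end_bp"])
            if ro >= min_reciprocal:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _same_cnv_present(record: dict, pool: list[dict],
                      min_reciprocal: float) -> bool:
    for other in pool:
        if other["chrom"] != record["chrom"] or other["dir"] != record["dir"]:
            continue
        if reciprocal_overlap(record["start_bp"], record["end_bp"],
                              other["start_bp"], other["end_bp"]) >= min_reciprocal:
            return True
    return False


def find_shared_case_cnvs(calls: pd.DataFrame, families: pd.Series,
                          labels: pd.Series, sexes: pd.Series,
                          phenotypes: pd.DataFrame | None = None,
                          scope: str = "cohort",
                          min_reciprocal: float = RECIPROCAL_MIN) -> pd.DataFrame:
    """Events shared by >= 2 affected co-siblings, absent in the unaffected.

    ``scope="family"`` requires absence only in the unaffected siblings of
    the carrier family; ``scope="cohort"`` (strict, default) additionally
    requires absence in every unaffected participant cohort-wide.
    """
    if scope not in ("family", "cohort"):
        raise ValueError("scope must be 'family' or 'cohort'")
    recs = []
    for idx, call in calls.iterrows():
        sid = call["sample_id"]
        recs.append({
            "idx": idx, "sample_id": sid, "chrom": str(call["chrom"]),
            "start_bp": int(call["start_bp"]), "end_bp": int(call["end_bp"]),
            "cn": int(call["copy_number"]),
            "dir": _direction(call["copy_number"], call["chrom"],
                              sexes.get(sid, "F")),
            "family": families.get(sid), "label": labels.get(sid, "neither"),
        })
    unaffected_pool = [r for r in recs if r["label"] != "case"]

    out_rows = []
    by_family: dict = {}
    for r in recs:
        by_family.setdefault(r["family"], []).append(r)
    for fam, fam_recs in by_family.items():
        case_recs = [r for r in fam_recs if r["label"] == "case"]
        case_sibs = {r["sample_id"] for r in case_recs}
        if len(case_sibs) < 2:
            continue
        for cluster in _clusters(case_recs, min_reciprocal):
            members = [case_recs[i] for i in cluster]
            carriers = {m["sample_id"] for m in members}
            if len(carriers) < 2:
                continue
            pool = (unaffected_pool if scope == "cohort"
                    else [r for r in fam_recs if r["label"] != "case"])
            if any(_same_cnv_present(m, pool, min_reciprocal) for m in members):
                continue
            out_rows.extend(members)
    report = pd.DataFrame(out_rows)
    if len(report) == 0:
        return pd.DataFrame(columns=["sample_id", "family", "chrom",
                                     "start_bp", "end_bp", "cn", "dir"])
    report = calls.loc[report["idx"]].copy().assign(
        family=report["family"].to_numpy(), direction=report["dir"].to_numpy())
    if phenotypes is not None:
        report = _attach_phenotypes(report, phenotypes)
    return report.reset_index(drop=True)


def candidate_overlap(calls: pd.DataFrame, candidates: pd.DataFrame,
                      families: pd.Series, labels: pd.Series,
                      phenotypes: pd.DataFrame | None = None,
                      gene_flank_bp: int = GENE_FLANK_BP) -> pd.DataFrame:
    """Calls intersecting candidate loci, with a co-segregation verdict.

    ``candidates`` rows carry ``name, chrom, start_bp, end_bp`` and an
    ``is_gene`` flag; gene candidates are extended by the standard 50-kb
    flank before intersection.  The verdict is per (candidate, family):
    "co-segregation" when every carrier in the family is a case and at
    least one case carries; otherwise "no co-segregation".
    """
    rows = []
    for cand in candidates.itertuples(index=False):
        pad = gene_flank_bp if bool(getattr(cand, "is_gene", False)) else 0
        c_start, c_end = cand.start_bp - pad, cand.end_bp + pad
        hits = calls.loc[
            (calls["chrom"].astype(str) == str(cand.chrom))
            & (calls["start_bp"] <= c_end) & (calls["end_bp"] >= c_start)
        ]
        if len(hits) == 0:
            continue
        carrier_fams = hits["sample_id"].map(families)
        for fam in carrier_fams.unique():
            fam_hits = hits.loc[carrier_fams == fam]
            carrier_labels = fam_hits["sample_id"].map(labels)
            cosegregates = (carrier_labels == "case").all() and \
                (carrier_labels == "case").any()
            verdict = "co-segregation" if cosegregates else "no co-segregation"
            for _, h in fam_hits.iterrows():
                rows.append({**h.to_dict(), "candidate": cand.name,
                             "family": fam, "verdict": verdict})
    report = pd.DataFrame(rows)
    if len(report) and phenotypes is not None:
        report = _attach_phenotypes(report, phenotypes)
    return report
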