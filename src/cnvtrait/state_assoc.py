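"""Probe-wise CNV-state association with family permutations and meta-analysis.

Each probe gets a binary state per sample: CNV+ when a QC-passing call of
that sample covers it with a non-baseline copy number (baseline 2; 1 on
the male X), CNV- otherwise — deletions and duplications collapse into
one CNV+ state.  Association of a continuous score with the state is the
OLS slope of score on state, with significance from permutations that
respect sibship structure (scores shuffled within sibships, sibship score
blocks swapped across equal-size sibships).  X-chromosome probes are
tested per sex and the strata combined by the same sample-size-weighted
scheme used for cohorts: z_i = signed probit of the two-sided p,
Z = sum(sqrt(N_i) z_i) / sqrt(sum N_i).  Significant stretches of
consecutive probes are called as regions of CNV overlap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .families import FamilyPermuter
from .synthetic import baseline_copy_number

#: region scheme: (core p, core run length, flank p, extra flank probes)
STATE_REGION_SCHEME = (0.005, 2, 0.05, 2)
INTENSITY_REGION_SCHEME = (0.001, 2, 0.05, 2)

RESULT_COLUMNS = ["probe_id", "chrom", "pos", "p", "direction",
                  "n_informative", "N", "slope"]


# ---------------------------------------------------------------------------
# state matrix

def assign_probe_states(calls: pd.DataFrame, probes: pd.DataFrame,
                        sexes: pd.Series,
                        sample_ids=None) -> pd.DataFrame:
    """Samples x probes boolean CNV+ matrix from call intervals.

    A probe is CNV+ for a sample iff some call of that sample covers it
    with copy number != 2 (autosomes, female X) or != 1 (male X).  Calls
    on X for samples of unknown sex raise.
    """
    if sample_ids is None:
        sample_ids = calls["sample_id"].unique()
    probe_ids = probes["probe_id"].to_numpy()
    row_of = {sid: i for i, sid in enumerate(sample_ids)}
    probes_sorted = probes.reset_index(drop=True)
    pos_by_chrom, col0 = {}, {}
    for chrom, grp in probes_sorted.groupby("chrom", sort=False):
        pos_by_chrom[str(chrom)] = grp["pos"].to_numpy()
        col0[str(chrom)] = int(grp.index[0])

    states = np.zeros((len(sample_ids), len(probe_ids)), dtype=bool)
    for call in calls.itertuples(index=False):
        sid = call.sample_id
        if sid not in row_of:
            continue
        chrom = str(call.chrom)
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        if chrom == "X":
            sex = sexes.get(sid)
            if sex not in ("M", "F"):
                raise ValueError(f"X-chromosome call for sample {sid} "
                                 f"with unknown sex")
        else:
            sex = "F"  # irrelevant off X
        if int(call.copy_number) == baseline_copy_number(chrom, sex):
            continue
        lo = int(np.searchsorted(pos, call.start_bp, side="left"))
        hi = int(np.searchsorted(pos, call.end_bp, side="right"))
        if hi > lo:
            c0 = col0[chrom]
            states[row_of[sid], c0 + lo:c0 + hi] = True
    return pd.DataFrame(states, index=pd.Index(sample_ids, name="sample_id"),
                        columns=probe_ids)


def restrict_to_covered(states: pd.DataFrame) -> pd.DataFrame:
    """Keep only probes covered by at least one CNV (>= 1 CNV+ sample)."""
    return states.loc[:, states.any(axis=0)]


def cnv_plus_frequency(states: pd.DataFrame, probe_ids) -> dict:
    """CNV+ frequency (%) over a probe set: any-probe and per-probe range."""
    sub = states.loc[:, [p for p in probe_ids if p in states.columns]]
    if sub.shape[1] == 0 or sub.shape[0] == 0:
        return {"any_probe_pct": 0.0, "per_probe_min_pct": 0.0,
                "per_probe_max_pct": 0.0}
    per_probe = sub.mean(axis=0) * 100.0
    return {
        "any_probe_pct": float(sub.any(axis=1).mean() * 100.0),
        "per_probe_min_pct": float(per_probe.min()),
        "per_probe_max_pct": float(per_probe.max()),
    }


# ---------------------------------------------------------------------------
# permutation association

@dataclass
class AssocResult:
    probe_id: str | None
    p: float
    direction: int          # sign of the CNV+ effect on the score
    n_informative: int      # CNV+ carriers among tested samples
    N: int                  # samples tested
    slope: float
    n_perms_used: int = 0


_TIE_EPS = 1e-12


def _slopes(xc: np.ndarray, xx: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS slopes of each permuted y on each centered x column.

    xc: (n, m) centered predictors; xx: (m,) sums of squares;
    Y: (P, n) centered outcomes.  Returns (m, P).
    """
    return (xc.T @ Y.T) / xx[:, None]


def family_permutation_scan(states: pd.DataFrame, scores: pd.Series,
                            families: pd.Series, n_perms: int = 1000,
                            seed: int | None = None,
                            chunk: int = 1024) -> pd.DataFrame:
    """Permutation association of every probe column against one score.

    All samples with a non-missing score are used; one set of
    family-respecting permutations is shared across probes.  Monomorphic
    probes get p = 1, direction 0.
    """
    keep = scores.dropna().index.intersection(states.index)
    y = scores.loc[keep].to_numpy(dtype=float)
    fam = families.loc[keep].to_numpy()
    X = states.loc[keep]
    n = len(keep)
    if n < 4:
        raise ValueError("too few scored samples for association")
    rng = np.random.default_rng(seed)
    permuter = FamilyPermuter(fam)
    idx = permuter.indices(n_perms, rng)
    yc = y - y.mean()
    Y = yc[idx]

    probe_ids = X.columns.to_numpy()
    p_out = np.ones(len(probe_ids))
    slope_out = np.zeros(len(probe_ids))
    n_inf = np.zeros(len(probe_ids), dtype=int)
    for lo in range(0, len(probe_ids), chunk):
        cols = slice(lo, min(lo + chunk, len(probe_ids)))
        xb = X.iloc[:, cols].to_numpy(dtype=float)
        xc = xb - xb.mean(axis=0)
        xx = (xc ** 2).sum(axis=0)
        poly = xx > 0
        n_inf[cols] = (xb > 0).sum(axis=0)
        if not poly.any():
            continue
        b_obs = np.zeros(xb.shape[1])
        b_obs[poly] = (xc[:, poly].T @ yc) / xx[poly]
        B = _slopes(xc[:, poly], xx[poly], Y)
        thresh = np.abs(b_obs[poly])[:, None] * (1 - _TIE_EPS)
        exceed = (np.abs(B) >= thresh).sum(axis=1)
        p = np.ones(xb.shape[1])
        p[poly] = (1.0 + exceed) / (1.0 + n_perms)
        p_out[cols] = p
        slope_out[cols] = b_obs

    res = pd.DataFrame({
        "probe_id": probe_ids,
        "p": p_out,
        "direction": np.sign(slope_out).astype(int),
        "n_informative": n_inf,
        "N": n,
        "slope": slope_out,
    })
    res.loc[res["direction"] == 0, "p"] = 1.0
    return res


def family_permutation_test(state, scores: pd.Series, families: pd.Series,
                            n_perms: int = 10_000, seed: int | None = None,
                            adaptive: bool = True, min_exceedances: int = 100,
                            batch: int = 500) -> AssocResult:
    """Single-probe association with adaptive early stopping.

    Permutation batches stop once ``min_exceedances`` permuted slopes at
    least as extreme as the observed one have accumulated (the p estimate
    is then already stable) or ``n_perms`` is reached.
    """
    state = pd.Series(np.asarray(state, dtype=float),
                      index=scores.index if len(scores) == len(state)
                      else None)
    keep = scores.dropna().index
    x = state.loc[keep].to_numpy(dtype=float)
    y = scores.loc[keep].to_numpy(dtype=float)
    fam = families.loc[keep].to_numpy()
    if len(np.unique(x)) < 2:
        return AssocResult(None, 1.0, 0, int((x > 0).sum()), len(x), 0.0, 0)
    if pd.Series(fam).nunique() < 2:
        raise ValueError("permutation test needs >= 2 families")
    rng = np.random.default_rng(seed)
    permuter = FamilyPermuter(fam)
    xc = x - x.mean()
    xx = float((xc ** 2).sum())
    yc = y - y.mean()
    b_obs = float(xc @ yc / xx)

    exceed, done = 0, 0
    while done < n_perms:
        take = min(batch, n_perms - done)
        Y = yc[permuter.indices(take, rng)]
        b = (Y @ xc) / xx
        exceed += int((np.abs(b) >= abs(b_obs) * (1 - _TIE_EPS)).sum())
        done += take
        if adaptive and exceed >= min_exceedances:
            break
    p = (1.0 + exceed) / (1.0 + done)
    return AssocResult(None, p, int(np.sign(b_obs)), int((x > 0).sum()),
                       len(x), b_obs, done)


# ---------------------------------------------------------------------------
# meta-analysis (sample-size-weighted scheme)

def _signed_z(p: np.ndarray, direction: np.ndarray,
              clamp_p: float | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float).copy()
    if clamp_p is not None:
        p[p <= 0] = clamp_p
    z = stats.norm.isf(p / 2.0)
    return z * np.sign(direction)


def stouffer_combine(z_list, n_list) -> np.ndarray:
    """Z = sum(sqrt(N_i) z_i) / sqrt(sum N_i)."""
    num = sum(np.sqrt(n) * z for z, n in zip(z_list, n_list))
    den = np.sqrt(sum(n_list))
    return num / den


def meta_analyze(results_a: pd.DataFrame, results_b: pd.DataFrame,
                 suffixes=("_a", "_b"), min_p: float | None = None
                 ) -> pd.DataFrame:
    """Sample-size-weighted meta-analysis of two per-cohort result tables.

    Probes present in only one cohort are excluded.  Zero p values are
    clamped to ``min_p`` (default 1e-300) with a warning-free floor, since
    a permutation p of 0 cannot occur with the (1+k)/(1+n) estimator.
    """
    if min_p is None:
        min_p = 1e-300
    merged = results_a.merge(results_b, on="probe_id", suffixes=suffixes)
    if len(merged) == 0:
        return pd.DataFrame(columns=["probe_id", "Z", "p_meta"])
    za = _signed_z(merged[f"p{suffixes[0]}"], merged[f"direction{suffixes[0]}"],
                   clamp_p=min_p)
    zb = _signed_z(merged[f"p{suffixes[1]}"], merged[f"direction{suffixes[1]}"],
                   clamp_p=min_p)
    na = merged[f"N{suffixes[0]}"].to_numpy(dtype=float)
    nb = merged[f"N{suffixes[1]}"].to_numpy(dtype=float)
    Z = (np.sqrt(na) * za + np.sqrt(nb) * zb) / np.sqrt(na + nb)
    out = merged.copy()
    out["z" + suffixes[0]] = za
    out["z" + suffixes[1]] = zb
    out["Z"] = Z
    out["p_meta"] = 2.0 * stats.norm.sf(np.abs(Z))
    return out


def x_association(states: pd.DataFrame, scores: pd.Series,
                  families: pd.Series, sexes: pd.Series,
                  n_perms: int = 1000, seed: int | None = None):
    """Per-sex association of X probes, combined across sex strata.

    Each stratum runs the standard family permutation scan; strata without
    variation at a probe are excluded from the combination, and a probe
    monomorphic in both sexes is untested (absent from the combined
    table).
    """
    per_sex = {}
    for i, sex in enumerate(("M", "F")):
        ids = [s for s in states.index if sexes.get(s) == sex]
        if len(ids) >= 4:
            per_sex[sex] = family_permutation_scan(
                states.loc[ids], scores.loc[scores.index.intersection(ids)],
                families, n_perms=n_perms,
                seed=None if seed is None else seed + i)
    rows = []
    all_probes = states.columns
    by_sex = {s: r.set_index("probe_id") for s, r in per_sex.items()}
    for pid in all_probes:
        zs, ns = [], []
        for sex, res in by_sex.items():
            if pid not in res.index:
                continue
            row = res.loc[pid]
            if row["direction"] == 0:
                continue
            zs.append(float(_signed_z(np.array([row["p"]]),
                                      np.array([row["direction"]]))[0]))
            ns.append(float(row["N"]))
        if not zs:
            continue
        Z = float(stouffer_combine(zs, ns))
        rows.append((pid, Z, float(2.0 * stats.norm.sf(abs(Z))),
                     int(sum(ns)), len(zs)))
    combined = pd.DataFrame(rows, columns=["probe_id", "Z", "p_meta",
                                           "N", "n_strata"])
    return per_sex, combined


# ---------------------------------------------------------------------------
# region calling

def detect_regions(results: pd.DataFrame,
                   scheme: tuple[float, int, float, int] = STATE_REGION_SCHEME,
                   p_col: str = "p",
                   probe_index: dict | None = None) -> pd.DataFrame:
    """Call regions of consecutive associated probes.

    A region is a maximal run of consecutive tested probes with
    ``p < flank_p`` that (a) contains at least ``core_len`` consecutive
    probes with ``p < core_p`` and (b) has at least ``flank_len`` member
    probes beyond that core.  ``results`` must be ordered by genomic
    position and contain ``probe_id``, ``chrom``, ``pos`` and the p
    column; when ``probe_index`` maps probe_id -> manifest ordinal,
    untested probes break runs (a run cannot jump a gap in the manifest).
    """
    core_p, core_len, flank_p, flank_len = scheme
    if len(results) == 0:
        return _empty_regions()
    res = results.reset_index(drop=True)
    p = res[p_col].to_numpy(dtype=float)
    chrom = res["chrom"].astype(str).to_numpy()
    if probe_index is not None:
        ordinal = np.array([probe_index[pid] for pid in res["probe_id"]])
    else:
        ordinal = np.arange(len(res))

    regions = []
    run_start = None
    for i in range(len(res) + 1):
        in_run = (
            i < len(res) and p[i] < flank_p
            and (run_start is None or
                 (chrom[i] == chrom[i - 1] and ordinal[i] == ordinal[i - 1] + 1))
        )
        if in_run:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            regions.extend(_qualify_run(res, p, run_start, i,
                                        core_p, core_len, flank_len, p_col))
            run_start = None
        if i < len(res) and p[i] < flank_p:
            run_start = i
    return pd.DataFrame(regions, columns=_REGION_COLUMNS) if regions \
        else _empty_regions()


_REGION_COLUMNS = ["chrom", "start_bp", "end_bp", "n_probes",
                   "probe_ids", "p_min", "p_max"]


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(columns=_REGION_COLUMNS)


def _qualify_run(res, p, lo, hi, core_p, core_len, flank_len, p_col):
    """Check one maximal sub-flank run [lo, hi) against the core criteria."""
    run_len = hi - lo
    best_core = cur = 0
    for i in range(lo, hi):
        cur = cur + 1 if p[i] < core_p else 0
        best_core = max(best_core, cur)
    if best_core < core_len or run_len < core_len + flank_len:
        return []
    sub = res.iloc[lo:hi]
    return [(
        sub["chrom"].iloc[0], int(sub["pos"].iloc[0]), int(sub["pos"].iloc[-1]),
        run_len, ",".join(sub["probe_id"].astype(str)),
        float(sub[p_col].min()), float(sub[p_col].max()),
    )]


def bonferroni_alpha(base_alpha: float, n_traits: int, n_probes: int) -> float:
    """Genome-wide threshold: base alpha / (traits x probes tested)."""
    if n_traits <= 0 or n_probes <= 0:
        raise ValueError("counts must be positive")
    return base_alpha / (n_traits * n_probes)
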