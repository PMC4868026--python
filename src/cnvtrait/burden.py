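"""Per-sample CNV burden and its association with reading performance.

Burden is the per-sample number of QC-passing calls and their total
covered length, overall or restricted to a class (gene-annotated, exonic,
rare, or a length class: short < 100 kb, medium 100-500 kb, large
> 500 kb).  Because burden measures are non-normal and siblings are not
independent, association with continuous scores uses the median Spearman
rho over repeated random samplings of one individual per sibship, and
case/control burden uses logistic regression over the same resampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .families import one_per_family
from .intervals import span_bp

BURDEN_CLASSES = ("all", "gene", "exon", "rare", "short", "medium", "large")
SHORT_MAX_BP = 100_000
LARGE_MIN_BP = 500_000


@dataclass
class ResampledStat:
    statistic: str          # "rho" or "odds_ratio"
    point: float            # median over resamples
    p_median: float         # conservative summary (resamples overlap)
    n_resamples: int
    n_excluded: int = 0     # resamples dropped (e.g. complete separation)
    seed: int | None = None
    #: p of the first resample — a single representative one-per-family
    #: draw, whose null distribution is exactly uniform
    p_representative: float = float("nan")


def _class_mask(calls: pd.DataFrame, burden_class: str) -> np.ndarray:
    spans = np.asarray(span_bp(calls["start_bp"], calls["end_bp"]))
    if burden_class == "all":
        return np.ones(len(calls), dtype=bool)
    if burden_class == "gene":
        return (calls["genes"].fillna("") != "").to_numpy()
    if burden_class == "exon":
        return calls["exonic"].to_numpy(dtype=bool)
    if burden_class == "rare":
        return calls["rare"].to_numpy(dtype=bool)
    if burden_class == "short":
        return spans < SHORT_MAX_BP
    if burden_class == "medium":
        return (spans >= SHORT_MAX_BP) & (spans <= LARGE_MIN_BP)
    if burden_class == "large":
        return spans > LARGE_MIN_BP
    raise ValueError(f"unknown burden class {burden_class!r}; "
                     f"expected one of {BURDEN_CLASSES}")


def compute_burden(calls: pd.DataFrame, burden_class: str = "all",
                   sample_ids=None) -> pd.DataFrame:
    """Event count and total covered bp per sample for one class.

    ``sample_ids`` fixes the output index; samples without qualifying
    calls get (0, 0).
    """
    sub = calls.loc[_class_mask(calls, burden_class)]
    spans = span_bp(sub["start_bp"], sub["end_bp"])
    grouped = pd.DataFrame({
        "n_events": sub.groupby("sample_id").size(),
        "total_length_bp": pd.Series(np.asarray(spans), index=sub.index)
                             .groupby(sub["sample_id"]).sum(),
    })
    if sample_ids is None:
        sample_ids = calls["sample_id"].unique()
    out = grouped.reindex(sample_ids).fillna(0).astype(int)
    out.index.name = "sample_id"
    out["class"] = burden_class
    return out


def resampled_correlation(burden: pd.Series, scores: pd.Series,
                          families: pd.Series, n_resamples: int = 100,
                          seed: int | None = None,
                          method: str = "spearman") -> ResampledStat:
    """Median rank correlation over one-per-sibship random samplings."""
    df = pd.concat({"burden": burden, "score": scores,
                    "family": families}, axis=1).dropna()
    if df["family"].nunique() < 3:
        raise ValueError("resampled correlation needs >= 3 families")
    rng = np.random.default_rng(seed)
    draws = one_per_family(df["family"].to_numpy(), n_resamples, rng)
    b = df["burden"].to_numpy(dtype=float)
    s = df["score"].to_numpy(dtype=float)
    rhos, ps = [], []
    for row in draws:
        if np.ptp(b[row]) == 0 or np.ptp(s[row]) == 0:
            rho, p = 0.0, 1.0  # degenerate draw: constant measure
        elif method == "spearman":
            rho, p = stats.spearmanr(b[row], s[row])
        elif method == "pearson":
            rho, p = stats.pearsonr(b[row], s[row])
        else:
            raise ValueError(f"unknown method {method!r}")
        if np.isnan(rho):
            rho, p = 0.0, 1.0
        rhos.append(rho)
        ps.append(p)
    return ResampledStat("rho", float(np.median(rhos)), float(np.median(ps)),
                         n_resamples, seed=seed, p_representative=ps[0])


def case_control_burden(burden: pd.Series, labels: pd.Series,
                        families: pd.Series, n_resamples: int = 100,
                        seed: int | None = None,
                        max_retries: int = 50) -> ResampledStat:
    """Median odds ratio from logistic regressions of status on burden.

    Each resample keeps one member per sibship, restricted to labeled
    cases/controls; draws without both classes are redrawn (up to
    ``max_retries``).  Resamples with complete separation are excluded
    and counted.  A constant burden yields OR = 1, p = 1 by convention.
    """
    import statsmodels.api as sm

    df = pd.concat({"burden": burden, "label": labels,
                    "family": families}, axis=1).dropna()
    df = df[df["label"].isin(["case", "control"])]
    if df["family"].nunique() < 3:
        raise ValueError("case/control burden needs >= 3 labeled families")
    rng = np.random.default_rng(seed)
    fam = df["family"].to_numpy()
    y_all = (df["label"] == "case").to_numpy(dtype=float)
    x_all = df["burden"].to_numpy(dtype=float)

    ors, ps, n_excluded = [], [], 0
    for _ in range(n_resamples):
        row = None
        for _ in range(max_retries):
            cand = one_per_family(fam, 1, rng)[0]
            if 0 < y_all[cand].sum() < len(cand):
                row = cand
                break
        if row is None:
            n_excluded += 1
            continue
        x, y = x_all[row], y_all[row]
        if np.ptp(x) == 0:
            ors.append(1.0)
            ps.append(1.0)
            continue
        xs = (x - x.mean()) / x.std(ddof=0)
        X = sm.add_constant(xs)
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
            coef, p = float(fit.params[1]), float(fit.pvalues[1])
            if not np.isfinite(coef) or abs(coef) > 30:
                raise ValueError("separation")
            # report OR per raw burden unit
            ors.append(float(np.exp(coef / x.std(ddof=0))))
            ps.append(p)
        except Exception:
            n_excluded += 1
    if not ors:
        return ResampledStat("odds_ratio", float("nan"), float("nan"),
                             0, n_excluded, seed)
    return ResampledStat("odds_ratio", float(np.median(ors)),
                         float(np.median(ps)), len(ors), n_excluded, seed,
                         p_representative=ps[0])
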