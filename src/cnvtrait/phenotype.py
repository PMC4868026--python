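"""Composite reading/language scores and case/control labeling.

The continuous outcome of the study is the first principal component
(PC1) of six standardized reading/language measures, extracted from the
trait correlation matrix per cohort on complete cases only.  An
IQ-adjusted variant (IQadjPC1) takes the residuals of PC1 regressed on
performance IQ.  Dichotomous reading-disability status is assigned from
the distribution of a discriminant composite (IBGdiscr): the lowest
decile are "cases", the highest decile "controls"; a fixed-threshold mode
is also available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PC1_TRAITS = ("WRead", "WSpell", "PD", "PA", "OC", "NWR")


@dataclass
class Pc1Result:
    scores: pd.Series            # indexed like the input; NaN for incomplete cases
    variance_explained: float    # first eigenvalue / number of traits
    loadings: pd.Series          # trait -> loading on PC1 (first trait positive)


def derive_pc1(traits: pd.DataFrame, trait_cols=PC1_TRAITS) -> Pc1Result:
    """First principal component of the trait correlation matrix.

    Samples with any missing trait are excluded (listwise) and come back
    with a NaN score.  Scores are standardized to unit variance; the sign
    is fixed so the first trait's loading is positive (principal
    components are sign-ambiguous, and reading measures conventionally
    load positively on the shared-performance axis).
    """
    trait_cols = list(trait_cols)
    data = traits[trait_cols]
    complete = data.dropna()
    if len(complete) < 2:
        raise ValueError("PC1 needs at least 2 complete-case samples")
    values = complete.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [trait_cols[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant trait(s) {flat} cannot enter the PCA")
    z = (values - values.mean(axis=0)) / sd
    corr = (z.T @ z) / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    v1 = eigvec[:, -1]
    lam1 = float(eigval[-1])
    # loadings = component weights scaled to correlations with the traits
    loadings = v1 * np.sqrt(lam1)
    if loadings[0] < 0:
        loadings = -loadings
        v1 = -v1
    raw = z @ v1
    scores = raw / raw.std(ddof=1)
    out = pd.Series(np.nan, index=traits.index, name="PC1")
    out.loc[complete.index] = scores
    return Pc1Result(
        scores=out,
        variance_explained=lam1 / len(trait_cols),
        loadings=pd.Series(loadings, index=trait_cols, name="loading"),
    )


def adjust_for_iq(pc1: pd.Series, piq: pd.Series) -> pd.Series:
    """Residuals of PC1 regressed on performance IQ (intercept included).

    Defined only where both are present; residuals are uncorrelated with
    PIQ by OLS orthogonality.
    """
    paired = pd.concat({"pc1": pc1, "piq": piq}, axis=1).dropna()
    if len(paired) < 3:
        raise ValueError("IQ adjustment needs at least 3 paired observations")
    x = paired["piq"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant PIQ: degenerate regression")
    y = paired["pc1"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, deg=1)
    out = pd.Series(np.nan, index=pc1.index, name="IQadjPC1")
    out.loc[paired.index] = y - (slope * x + intercept)
    return out


def assign_case_control(scores: pd.Series, mode: str = "decile",
                        tail: float = 0.10,
                        thresholds: tuple[float, float] = (-1.4, 2.2)) -> pd.Series:
    """Label samples case / control / neither from the discriminant score.

    ``decile`` mode: at or below the lower ``tail`` percentile -> "case"
    (poor reading), at or above the upper -> "control"; ties at the
    boundary are included in the extreme group.  ``threshold`` mode uses
    fixed cutoffs: strictly below the lower one -> "case", strictly above
    the upper -> "control".  A degenerate (constant) distribution yields
    all "neither".
    """
    labels = pd.Series("neither", index=scores.index, name="label")
    clean = scores.dropna()
    if len(clean) == 0:
        return labels
    if mode == "decile":
        if len(clean) < 10:
            raise ValueError("decile labeling needs at least 10 scores")
        if clean.nunique() == 1:
            return labels
        lo = np.percentile(clean, 100 * tail)
        hi = np.percentile(clean, 100 * (1 - tail))
        if lo == hi:
            return labels
        labels.loc[clean.index[clean <= lo]] = "case"
        labels.loc[clean.index[clean >= hi]] = "control"
    elif mode == "threshold":
        lo, hi = thresholds
        labels.loc[clean.index[clean < lo]] = "case"
        labels.loc[clean.index[clean > hi]] = "control"
    else:
        raise ValueError(f"unknown case/control mode {mode!r}")
    return labels
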