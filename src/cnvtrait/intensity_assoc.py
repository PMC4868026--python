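"""Probe-wise association of continuous LRR intensity with reading scores.

The dosage-sensitive complement to the binary CNV-state test: per probe,
the score is regressed on the raw log R ratio with the first two
principal components of the LRR matrix as covariates (absorbing batch and
plate structure), and significance comes from the same family-respecting
permutation engine used for CNV state, applied to the
covariate-residualized score.  The rank correlation between LRR and the
score is reported as the direction/effect surrogate.  A PCA over the LRR
matrix also supplies sample outlier screening (robust z on the leading
components).  Only autosomal probes are tested.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .families import FamilyPermuter
from .state_assoc import INTENSITY_REGION_SCHEME, _TIE_EPS, detect_regions


@dataclass
class LrrPcaModel:
    scores: pd.DataFrame               # samples x components
    explained_variance_ratio: np.ndarray
    n_components: int


def lrr_pca(lrr: pd.DataFrame, n_components: int | None = None) -> LrrPcaModel:
    """SVD-based PCA of the sample-by-probe LRR matrix.

    Probes with any missing value are dropped; columns are centered.
    Default number of components is min(100, n_samples - 1).
    """
    if lrr.shape[0] < 3:
        raise ValueError("LRR PCA needs at least 3 samples")
    X = lrr.dropna(axis=1).to_numpy(dtype=float)
    k = min(n_components or 100, X.shape[0] - 1, X.shape[1])
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    scores = U[:, :k] * S[:k]
    return LrrPcaModel(
        scores=pd.DataFrame(scores, index=lrr.index,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance_ratio=var[:k] / var.sum(),
        n_components=k,
    )


def flag_lrr_outliers(model: LrrPcaModel, n_components: int = 2,
                      n_mads: float = 6.0) -> pd.Series:
    """Flag samples extreme on the leading LRR components.

    A sample is an outlier when |score - median| exceeds ``n_mads``
    robust standard deviations (median absolute deviation scaled by
    1.4826) on any of the first ``n_components`` components.
    """
    flags = np.zeros(len(model.scores), dtype=bool)
    for col in model.scores.columns[:n_components]:
        s = model.scores[col].to_numpy()
        med = np.median(s)
        mad = np.median(np.abs(s - med)) * 1.4826
        if mad == 0:
            continue
        flags |= np.abs(s - med) > n_mads * mad
    return pd.Series(flags, index=model.scores.index, name="lrr_outlier")


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def intensity_scan(lrr: pd.DataFrame, scores: pd.Series,
                   covariates: pd.DataFrame, families: pd.Series,
                   n_perms: int = 1000, seed: int | None = None,
                   chunk: int = 2048) -> pd.DataFrame:
    """Permutation association of every LRR column against one score.

    The score is residualized on the covariates (LRR PC1/PC2) once; the
    per-probe statistic is the OLS slope of the residualized score on the
    probe's LRR, with one shared set of family-respecting permutations.
    Zero-variance probes are untested (p NaN).
    """
    keep = scores.dropna().index.intersection(lrr.index)
    if len(keep) < 4:
        raise ValueError("too few scored samples for intensity association")
    y = scores.loc[keep].to_numpy(dtype=float)
    cov = covariates.loc[keep].to_numpy(dtype=float)
    fam = families.loc[keep].to_numpy()
    r = _residualize(y, cov)
    rng = np.random.default_rng(seed)
    permuter = FamilyPermuter(fam)
    idx = permuter.indices(n_perms, rng)
    rc = r - r.mean()
    R = rc[idx]

    X = lrr.loc[keep]
    probe_ids = X.columns.to_numpy()
    n = len(keep)
    p_out = np.full(len(probe_ids), np.nan)
    rho_out = np.full(len(probe_ids), np.nan)
    slope_out = np.zeros(len(probe_ids))

    y_rank = stats.rankdata(y)
    yr = (y_rank - y_rank.mean()) / y_rank.std()

    for lo in range(0, len(probe_ids), chunk):
        cols = slice(lo, min(lo + chunk, len(probe_ids)))
        xb = X.iloc[:, cols].to_numpy(dtype=float)
        xc = xb - xb.mean(axis=0)
        xx = (xc ** 2).sum(axis=0)
        poly = xx > 0
        if not poly.any():
            continue
        b_obs = np.zeros(xb.shape[1])
        b_obs[poly] = (xc[:, poly].T @ rc) / xx[poly]
        B = (xc[:, poly].T @ R.T) / xx[poly][:, None]
        thresh = np.abs(b_obs[poly])[:, None] * (1 - _TIE_EPS)
        exceed = (np.abs(B) >= thresh).sum(axis=1)
        p = np.full(xb.shape[1], np.nan)
        p[poly] = (1.0 + exceed) / (1.0 + n_perms)
        p_out[cols] = p
        slope_out[cols] = b_obs
        # Spearman rho of LRR with the *unadjusted* score, as direction
        xrank = stats.rankdata(xb[:, poly], axis=0)
        xrank = (xrank - xrank.mean(axis=0)) / xrank.std(axis=0)
        rho = np.full(xb.shape[1], np.nan)
        rho[poly] = (xrank * yr[:, None]).mean(axis=0)
        rho_out[cols] = rho

    return pd.DataFrame({
        "probe_id": probe_ids,
        "p": p_out,
        "rho_lrr": rho_out,
        "direction": np.sign(np.nan_to_num(rho_out)).astype(int),
        "N": n,
        "slope": slope_out,
    })


def intensity_association(lrr_column: pd.Series, scores: pd.Series,
                          covariates: pd.DataFrame, families: pd.Series,
                          n_perms: int = 1000, seed: int | None = None):
    """Single-probe wrapper around :func:`intensity_scan`."""
    df = intensity_scan(lrr_column.to_frame("probe"), scores, covariates,
                        families, n_perms=n_perms, seed=seed)
    return df.iloc[0]


def detect_intensity_regions(results: pd.DataFrame, p_col: str = "p",
                             probe_index: dict | None = None) -> pd.DataFrame:
    """Region calling with the intensity scheme (0.001 core, 0.05 flank)."""
    tested = results.dropna(subset=[p_col])
    return detect_regions(tested, scheme=INTENSITY_REGION_SCHEME,
                          p_col=p_col, probe_index=probe_index)
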