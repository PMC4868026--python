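"""Synthetic sibship cohorts with a known CNV and phenotype ground truth.

The generator emulates the kind of data produced by an Illumina-style SNP
array study of reading/language performance in sibling pairs recruited
through two ascertainment routes ("RD" and "ADHD" cohorts):

* a probe manifest, gene models with exons, exclusion regions
  (centromere-like gaps) and a reference CNV catalogue with event counts
  (standing in for a population CNV database);
* per-sample true CNV segments — a sparse background of private events, a
  handful of recurrent polymorphic loci, and one designated *causal*
  region whose carriers shift a latent reading/language factor;
* LRR/BAF intensity matrices rendered from the segments;
* PennCNV-like call records derived from the segments with boundary
  jitter, a confidence score and configurable false positives;
* a factor-structured phenotype table (six reading/language traits,
  verbal/performance IQ and a discriminant composite).

Every output is a deterministic function of the configured seed.  Ground
truth (``is_causal`` flags, carrier states) is carried through so that
downstream stages can be tested against what was planted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOME_DEFAULT = tuple(str(i) for i in range(1, 20))
TRAITS = ("WRead", "WSpell", "PD", "PA", "OC", "NWR")

#: Per-trait loadings of the latent factor, patterned on the loadings the
#: two ascertainment cohorts show on their first principal component.
DEFAULT_LOADINGS = {
    "RD": {"WRead": 0.918, "WSpell": 0.813, "PD": 0.895,
           "PA": 0.801, "OC": 0.764, "NWR": 0.493},
    "ADHD": {"WRead": 0.871, "WSpell": 0.764, "PD": 0.821,
             "PA": 0.744, "OC": 0.644, "NWR": 0.355},
}

#: Typical array LRR mean shift per copy number (diploid = 0).
DEFAULT_LRR_SHIFTS = {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}


def _rng(seed, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


def baseline_copy_number(chrom, sex: str) -> int:
    """Diploid baseline: 2 everywhere except male X (1)."""
    return 1 if (str(chrom) == "X" and sex == "M") else 2


@dataclass
class CohortConfig:
    """Cohort structure and genome scaffold of one simulated study."""

    n_families: int = 150
    sibship_size_range: tuple[int, int] = (2, 3)
    #: probability of each size in the range; uniform when None
    sibship_size_probs: tuple[float, ...] | None = (0.8, 0.2)
    cohort_split: float = 0.78  # fraction of sibships ascertained via "RD"
    n_probes_per_chrom: int = 1000
    chromosomes: tuple[str, ...] = AUTOSOME_DEFAULT + ("X",)
    probe_spacing_bp: int = 4000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.sibship_size_range
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if lo < 2 or hi < lo:
            raise ValueError("sibship sizes must be >= 2 and ordered")
        if self.sibship_size_probs is not None:
            probs = np.asarray(self.sibship_size_probs, dtype=float)
            if len(probs) != hi - lo + 1 or not math.isclose(probs.sum(), 1.0):
                raise ValueError("sibship_size_probs must match the size range and sum to 1")
        if not 0.0 <= self.cohort_split <= 1.0:
            raise ValueError("cohort_split must be in [0, 1]")
        if self.n_probes_per_chrom < 2:
            raise ValueError("need >= 2 probes per chromosome")


@dataclass
class CnvLandscapeConfig:
    """True CNV landscape: background events, recurrent loci, causal region."""

    background_rate: float = 5.0         # Poisson mean events per sample
    length_log_mean: float = math.log(65_000.0)
    length_log_sd: float = 0.8
    copy_number_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.04, 1: 0.48, 3: 0.40, 4: 0.08})
    family_sharing_prob: float = 0.3     # a sib inherits a background event
    n_recurrent_loci: int = 25
    recurrent_freq_range: tuple[float, float] = (0.01, 0.08)
    causal_chrom: str | None = "2"
    causal_start_bp: int | None = None   # None -> central ~30-probe window
    causal_end_bp: int | None = None
    causal_n_probes: int = 30
    causal_carrier_fraction: float = 0.05
    causal_sharing_prob: float = 0.0     # extra sib carriers beyond Bernoulli
    causal_copy_number: int = 1
    seed: int = 0


@dataclass
class CallEmissionConfig:
    """How true segments become PennCNV-like calls.

    Confidence defaults to an evidence-scaled score — proportional to the
    number of probes supporting the call, weighted by how far the state
    is from diploid, plus Gaussian noise — mimicking the log-likelihood
    behaviour of HMM callers (marginal short calls fail the >= 10 filter,
    large clean events do not).  Setting ``confidence_mean`` switches to
    a fixed normal distribution independent of the call.
    """

    boundary_jitter_probes: int = 1
    confidence_per_probe: float = 1.3
    confidence_sd: float = 5.0
    confidence_mean: float | None = None
    confidence_min: float = 0.5
    false_positive_rate: float = 0.5     # Poisson mean spurious calls/sample
    fp_length_log_mean: float = math.log(25_000.0)
    fp_length_log_sd: float = 0.6
    seed: int = 0

    #: evidence weight per copy-number state (distance from diploid)
    CN_WEIGHT = {0: 2.0, 1: 1.0, 2: 0.9, 3: 0.9, 4: 1.5}

    def draw_confidence(self, n_probes: int, cn: int,
                        rng: np.random.Generator) -> float:
        if self.confidence_mean is not None:
            mean = self.confidence_mean
        else:
            mean = self.confidence_per_probe * n_probes * self.CN_WEIGHT.get(cn, 1.0)
        return max(self.confidence_min,
                   float(rng.normal(mean, self.confidence_sd)))


@dataclass
class PhenoGenConfig:
    """Latent-factor phenotype model with a plantable CNV effect."""

    loadings: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_LOADINGS.items()})
    noise_sd: dict[str, float] | None = None  # None -> sqrt(1 - loading^2)
    family_icc: float = 0.4
    causal_beta: float = 0.0             # shift of the factor in carriers
    piq_factor_corr: float = 0.3
    viq_factor_corr: float = 0.5
    ibg_weights: dict[str, float] = field(
        default_factory=lambda: {"WRead": 0.5, "WSpell": 0.3, "OC": 0.2})
    missing_rate: float = 0.006
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.family_icc < 1.0:
            raise ValueError("family_icc must be in [0, 1)")
        for cohort, lam in self.loadings.items():
            if any(abs(v) > 1 for v in lam.values()):
                raise ValueError(f"loadings for {cohort} must be in [-1, 1]")


# ---------------------------------------------------------------------------
# cohort and genome scaffold

def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample and family tables: ids, sex, sibship and cohort labels."""
    rng = _rng(config.seed, 1)
    lo, hi = config.sibship_size_range
    sizes = rng.choice(np.arange(lo, hi + 1), size=config.n_families,
                       p=config.sibship_size_probs)
    cohorts = np.where(rng.random(config.n_families) < config.cohort_split,
                       "RD", "ADHD")
    fam_rows, sample_rows = [], []
    counter = 0
    for f in range(config.n_families):
        fam_id = f"F{f + 1:04d}"
        fam_rows.append((fam_id, int(sizes[f]), cohorts[f]))
        for _ in range(int(sizes[f])):
            counter += 1
            sex = "M" if rng.random() < 0.5 else "F"
            sample_rows.append((f"S{counter:04d}", fam_id, sex, cohorts[f]))
    samples = pd.DataFrame(sample_rows,
                           columns=["sample_id", "family_id", "sex", "cohort"])
    families = pd.DataFrame(fam_rows, columns=["family_id", "size", "cohort"])
    return samples, families


def generate_genome(config: CohortConfig):
    """Probe manifest, gene models, exclusion regions, reference CNVs."""
    rng = _rng(config.seed, 2)
    n = config.n_probes_per_chrom
    spacing = config.probe_spacing_bp
    chrom_len = (n + 2) * spacing

    probe_rows, gene_rows, exon_rows, excl_rows, ref_rows = [], [], [], [], []
    for chrom in config.chromosomes:
        pos = spacing * np.arange(1, n + 1) + rng.integers(0, spacing - 100, size=n)
        for i, p in enumerate(pos):
            probe_rows.append((f"rs{chrom}_{i + 1}", str(chrom), int(p)))

        n_genes = max(4, n // 35)
        for g in range(n_genes):
            g_len = int(rng.integers(20_000, 200_000))
            g_start = int(rng.integers(1, max(2, chrom_len - g_len)))
            g_end = g_start + g_len - 1
            name = f"G{chrom}_{g + 1}"
            n_ex = int(rng.integers(3, 11))
            cuts = np.sort(rng.choice(np.arange(g_start, g_end + 1), size=2 * n_ex,
                                      replace=False))
            exons = tuple((int(cuts[2 * k]), int(cuts[2 * k + 1]))
                          for k in range(n_ex))
            gene_rows.append((name, str(chrom), g_start, g_end, exons))
            for s, e in exons:
                exon_rows.append((name, str(chrom), s, e))

        cen = chrom_len // 2
        excl_rows.append((str(chrom), cen - 100_000, cen + 100_000, f"cen{chrom}"))
        tel = int(rng.integers(1, spacing * 3))
        excl_rows.append((str(chrom), 1, tel, f"telp{chrom}"))

        n_ref = max(5, n // 25)
        for r in range(n_ref):
            r_len = int(rng.integers(30_000, 300_000))
            r_start = int(rng.integers(1, max(2, chrom_len - r_len)))
            count = 1 + int(rng.geometric(0.10))
            ref_rows.append((str(chrom), r_start, r_start + r_len - 1, count))

    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])
    probes = probes.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    genes = pd.DataFrame(gene_rows,
                         columns=["gene", "chrom", "start_bp", "end_bp", "exons"])
    exclusions = pd.DataFrame(excl_rows,
                              columns=["chrom", "start_bp", "end_bp", "name"])
    reference_cnvs = pd.DataFrame(ref_rows,
                                  columns=["chrom", "start_bp", "end_bp", "count"])
    return probes, genes, exclusions, reference_cnvs


def exon_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Flatten the ``exons`` column into one interval row per exon."""
    rows = []
    for g in genes.itertuples(index=False):
        for s, e in g.exons:
            rows.append((g.gene, g.chrom, s, e))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start_bp", "end_bp"])


# ---------------------------------------------------------------------------
# CNV landscape

def _probe_arrays(probes: pd.DataFrame) -> dict[str, np.ndarray]:
    return {str(c): g["pos"].to_numpy() for c, g in probes.groupby("chrom", sort=False)}


def _x_adjusted_cn(cn: int, chrom, sex: str) -> int:
    """Map an autosome-style del/dup copy number onto the male-X baseline."""
    if str(chrom) != "X" or sex != "M":
        return cn
    return 0 if cn < 2 else cn - 1


def causal_region_bounds(probes: pd.DataFrame,
                         config: CnvLandscapeConfig) -> tuple[str, int, int]:
    """Resolve the causal region (explicit bounds or a central probe window)."""
    chrom = str(config.causal_chrom)
    pos = _probe_arrays(probes).get(chrom)
    if pos is None:
        raise ValueError(f"causal chromosome {chrom!r} has no probes")
    if config.causal_start_bp is not None and config.causal_end_bp is not None:
        start, end = int(config.causal_start_bp), int(config.causal_end_bp)
    else:
        # anchored away from the chromosome middle, where the genome
        # scaffold places its centromere-like exclusion region
        k = min(config.causal_n_probes, len(pos))
        lo = min(len(pos) // 4, len(pos) - k)
        start, end = int(pos[lo]), int(pos[lo + k - 1])
    inside = (pos >= start) & (pos <= end)
    if not inside.any():
        raise ValueError("causal region contains no probes")
    return chrom, start, end


def generate_cnv_landscape(samples: pd.DataFrame, probes: pd.DataFrame,
                           config: CnvLandscapeConfig) -> pd.DataFrame:
    """True CNV segments per sample (only non-baseline states are stored)."""
    rng = _rng(config.seed, 3)
    pos_by_chrom = _probe_arrays(probes)
    chroms = list(pos_by_chrom)
    n_per = np.array([len(pos_by_chrom[c]) for c in chroms])
    chrom_weights = n_per / n_per.sum()
    sex = samples.set_index("sample_id")["sex"]
    sibs = samples.groupby("family_id")["sample_id"].apply(list)
    fam_of = samples.set_index("sample_id")["family_id"]

    cn_values = np.array(list(config.copy_number_probs))
    cn_probs = np.array(list(config.copy_number_probs.values()))
    cn_probs = cn_probs / cn_probs.sum()

    rows: list[tuple] = []

    def add_segment(sid, chrom, start, end, cn, causal=False):
        rows.append((sid, str(chrom), int(start), int(end),
                     _x_adjusted_cn(int(cn), chrom, sex[sid]), bool(causal)))

    # --- causal region -----------------------------------------------------
    if config.causal_chrom is not None:
        chrom, start, end = causal_region_bounds(probes, config)
        ids = samples["sample_id"].to_numpy()
        carrier = rng.random(len(ids)) < config.causal_carrier_fraction
        carriers = set(ids[carrier])
        if config.causal_sharing_prob > 0:
            for sid in list(carriers):
                for sib in sibs[fam_of[sid]]:
                    if sib not in carriers and rng.random() < config.causal_sharing_prob:
                        carriers.add(sib)
        for sid in ids:
            if sid in carriers:
                add_segment(sid, chrom, start, end,
                            config.causal_copy_number, causal=True)

    # --- recurrent polymorphic loci ----------------------------------------
    for _ in range(config.n_recurrent_loci):
        chrom = chroms[rng.choice(len(chroms), p=chrom_weights)]
        pos = pos_by_chrom[chrom]
        anchor = int(rng.integers(0, len(pos)))
        length = float(rng.lognormal(config.length_log_mean, config.length_log_sd))
        start = int(pos[anchor])
        end = start + max(int(length), 1) - 1
        cn = int(rng.choice(cn_values, p=cn_probs))
        freq = rng.uniform(*config.recurrent_freq_range)
        ids = samples["sample_id"].to_numpy()
        hit = set(ids[rng.random(len(ids)) < freq])
        for sid in list(hit):
            for sib in sibs[fam_of[sid]]:
                if sib not in hit and rng.random() < config.family_sharing_prob:
                    hit.add(sib)
        for sid in ids:
            if sid in hit:
                add_segment(sid, chrom, start, end, cn)

    # --- private background events -----------------------------------------
    for sid in samples["sample_id"]:
        for _ in range(int(rng.poisson(config.background_rate))):
            chrom = chroms[rng.choice(len(chroms), p=chrom_weights)]
            pos = pos_by_chrom[chrom]
            anchor = int(rng.integers(0, len(pos)))
            length = float(rng.lognormal(config.length_log_mean, config.length_log_sd))
            start = int(pos[anchor])
            end = start + max(int(length), 1) - 1
            cn = int(rng.choice(cn_values, p=cn_probs))
            add_segment(sid, chrom, start, end, cn)
            for sib in sibs[fam_of[sid]]:
                if sib != sid and rng.random() < config.family_sharing_prob:
                    add_segment(sib, chrom, start, end, cn)

    segments = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_bp", "end_bp",
                       "copy_number", "is_causal"])
    return segments.sort_values(
        ["sample_id", "chrom", "start_bp"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# intensities

def render_intensities(samples: pd.DataFrame, segments: pd.DataFrame,
                       probes: pd.DataFrame, noise_sd: float = 0.15,
                       seed: int = 0, lrr_shifts: dict[int, float] | None = None,
                       sample_noise_sd: pd.Series | None = None,
                       return_baf: bool = False):
    """Render LRR (and optionally BAF) matrices from true segments.

    LRR mean per probe is the configured shift for the sample's copy number
    at that probe (0 for the diploid state), plus Gaussian noise.  A
    per-sample noise SD can be supplied to create noisy samples that the
    downstream sample QC should drop.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    shifts = dict(DEFAULT_LRR_SHIFTS if lrr_shifts is None else lrr_shifts)
    rng = _rng(seed, 4)
    probe_ids = probes["probe_id"].to_numpy()
    col_of = {pid: j for j, pid in enumerate(probe_ids)}
    pos_by_chrom = _probe_arrays(probes)
    first_col = {}
    for chrom, grp in probes.groupby("chrom", sort=False):
        first_col[str(chrom)] = col_of[grp["probe_id"].iloc[0]]

    ids = samples["sample_id"].to_numpy()
    row_of = {sid: i for i, sid in enumerate(ids)}
    base = np.zeros((len(ids), len(probe_ids)))
    cn_mat = np.full((len(ids), len(probe_ids)), 2, dtype=np.int8)
    for seg in segments.itertuples(index=False):
        pos = pos_by_chrom.get(str(seg.chrom))
        if pos is None:
            continue
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
        if hi <= lo:
            continue
        c0 = first_col[str(seg.chrom)]
        i = row_of[seg.sample_id]
        base[i, c0 + lo:c0 + hi] = shifts.get(int(seg.copy_number), 0.0)
        cn_mat[i, c0 + lo:c0 + hi] = int(seg.copy_number)

    if sample_noise_sd is None:
        sds = np.full(len(ids), float(noise_sd))
    else:
        sds = sample_noise_sd.reindex(ids).fillna(noise_sd).to_numpy(dtype=float)
        if (sds < 0).any():
            raise ValueError("negative per-sample noise SD")
    lrr = base + rng.standard_normal(base.shape) * sds[:, None]
    lrr_df = pd.DataFrame(lrr, index=pd.Index(ids, name="sample_id"),
                          columns=probe_ids)
    if not return_baf:
        return lrr_df

    # crude BAF clusters consistent with copy number
    baf = np.empty_like(base)
    u = rng.random(base.shape)
    levels = {
        1: np.array([0.0, 1.0]),
        2: np.array([0.0, 0.5, 1.0]),
        3: np.array([0.0, 1 / 3, 2 / 3, 1.0]),
        4: np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
    }
    weights = {
        1: np.array([0.5, 0.5]),
        2: np.array([0.25, 0.5, 0.25]),
        3: np.array([0.125, 0.375, 0.375, 0.125]),
        4: np.array([0.0625, 0.25, 0.375, 0.25, 0.0625]),
    }
    baf[:] = 0.5  # copy 0: no allelic signal
    for cn, lev in levels.items():
        mask = cn_mat == cn
        if not mask.any():
            continue
        cum = np.cumsum(weights[cn])
        pick = np.searchsorted(cum, u[mask])
        baf[mask] = lev[np.minimum(pick, len(lev) - 1)]
    baf = np.clip(baf + rng.standard_normal(base.shape) * 0.03, 0.0, 1.0)
    baf_df = pd.DataFrame(baf, index=pd.Index(ids, name="sample_id"),
                          columns=probe_ids)
    return lrr_df, baf_df


# ---------------------------------------------------------------------------
# call emission

def count_probes_in(probes: pd.DataFrame, chrom, start: int, end: int) -> int:
    pos = _probe_arrays(probes).get(str(chrom))
    if pos is None:
        return 0
    return int(np.searchsorted(pos, end, side="right")
               - np.searchsorted(pos, start, side="left"))


def emit_cnv_calls(segments: pd.DataFrame, probes: pd.DataFrame,
                   config: CallEmissionConfig,
                   samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """PennCNV-like call records derived from true segments.

    Call boundaries are snapped to probe positions and jittered by up to
    ``boundary_jitter_probes`` probes; probe counts are recomputed from the
    manifest; confidence is drawn from a clipped normal.  With jitter 0 and
    false-positive rate 0 the emitted calls are bijective with the input
    segments.  False-positive calls (drawn for the samples table, or for
    the segment carriers if no table is given) carry ``is_true = False``.
    """
    rng = _rng(config.seed, 5)
    pos_by_chrom = _probe_arrays(probes)
    rows = []
    for seg in segments.itertuples(index=False):
        pos = pos_by_chrom.get(str(seg.chrom))
        if pos is None:
            continue
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right")) - 1
        if hi < lo:
            continue
        j = config.boundary_jitter_probes
        if j > 0:
            lo = int(np.clip(lo + rng.integers(-j, j + 1), 0, len(pos) - 1))
            hi = int(np.clip(hi + rng.integers(-j, j + 1), 0, len(pos) - 1))
            if hi < lo:
                lo, hi = hi, lo
        conf = config.draw_confidence(hi - lo + 1, int(seg.copy_number), rng)
        rows.append((seg.sample_id, str(seg.chrom), int(pos[lo]), int(pos[hi]),
                     int(seg.copy_number), hi - lo + 1, conf,
                     True, bool(getattr(seg, "is_causal", False))))

    if config.false_positive_rate > 0:
        ids = (samples["sample_id"].to_numpy() if samples is not None
               else segments["sample_id"].unique())
        chroms = list(pos_by_chrom)
        n_per = np.array([len(pos_by_chrom[c]) for c in chroms])
        w = n_per / n_per.sum()
        for sid in ids:
            for _ in range(int(rng.poisson(config.false_positive_rate))):
                chrom = chroms[rng.choice(len(chroms), p=w)]
                pos = pos_by_chrom[chrom]
                lo = int(rng.integers(0, len(pos)))
                length = float(rng.lognormal(config.fp_length_log_mean,
                                             config.fp_length_log_sd))
                hi = int(np.searchsorted(pos, pos[lo] + length, side="right")) - 1
                hi = max(hi, lo)
                cn = int(rng.choice([1, 3]))
                conf = config.draw_confidence(hi - lo + 1, cn, rng)
                rows.append((sid, chrom, int(pos[lo]), int(pos[hi]), cn,
                             hi - lo + 1, conf, False, False))

    calls = pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "start_bp", "end_bp", "copy_number",
        "n_snps", "confidence", "is_true", "is_causal"])
    return calls.sort_values(["sample_id", "chrom", "start_bp"],
                             kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# phenotypes

def generate_phenotypes(samples: pd.DataFrame, carrier_states: pd.Series,
                        config: PhenoGenConfig) -> pd.DataFrame:
    """Factor-structured trait table with a planted carrier effect.

    Each trait is ``loading * F + noise`` where the latent factor ``F`` has
    within-sibship correlation ``family_icc`` and is shifted by
    ``causal_beta`` in carriers of the causal region.  Performance IQ is
    correlated with ``F`` at ``piq_factor_corr``; the discriminant
    composite is a fixed weighted sum of three traits, re-standardized.
    """
    rng = _rng(config.seed, 6)
    ids = samples["sample_id"].to_numpy()
    fam_codes = pd.Categorical(samples["family_id"]).codes
    fam_effect = rng.standard_normal(fam_codes.max() + 1)[fam_codes]
    ind_effect = rng.standard_normal(len(ids))
    icc = config.family_icc
    carrier = carrier_states.reindex(ids).fillna(False).to_numpy(dtype=bool)
    F = (math.sqrt(icc) * fam_effect + math.sqrt(1.0 - icc) * ind_effect
         + config.causal_beta * carrier)

    cohort = samples["cohort"].to_numpy()
    out = {"sample_id": ids}
    for trait in TRAITS:
        lam = np.array([config.loadings[c][trait] for c in cohort])
        if config.noise_sd is not None:
            sd = np.full(len(ids), config.noise_sd[trait])
        else:
            sd = np.sqrt(1.0 - lam ** 2)
        out[trait] = lam * F + sd * rng.standard_normal(len(ids))

    for name, r in (("VIQ", config.viq_factor_corr),
                    ("PIQ", config.piq_factor_corr)):
        out[name] = r * F + math.sqrt(1.0 - r * r) * rng.standard_normal(len(ids))

    pheno = pd.DataFrame(out)
    ibg = sum(w * pheno[t] for t, w in config.ibg_weights.items())
    pheno["IBGdiscr"] = (ibg - ibg.mean()) / ibg.std(ddof=1)

    if config.missing_rate > 0:
        for trait in TRAITS:
            mask = rng.random(len(ids)) < config.missing_rate
            pheno.loc[mask, trait] = np.nan
    pheno["true_factor"] = F
    pheno["is_carrier"] = carrier
    return pheno


# ---------------------------------------------------------------------------
# one-stop bundle

@dataclass
class SimulationConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    landscape: CnvLandscapeConfig = field(default_factory=CnvLandscapeConfig)
    calls: CallEmissionConfig = field(default_factory=CallEmissionConfig)
    phenotype: PhenoGenConfig = field(default_factory=PhenoGenConfig)
    lrr_noise_sd: float = 0.15
    noisy_sample_fraction: float = 0.02  # samples rendered with SD 0.5
    seed: int = 0

    def __post_init__(self):
        # one master seed fans out to every stage deterministically
        self.cohort.seed = self.seed
        self.landscape.seed = self.seed + 1
        self.calls.seed = self.seed + 2
        self.phenotype.seed = self.seed + 3


@dataclass
class SimulatedData:
    samples: pd.DataFrame
    families: pd.DataFrame
    probes: pd.DataFrame
    genes: pd.DataFrame
    exons: pd.DataFrame
    exclusions: pd.DataFrame
    reference_cnvs: pd.DataFrame
    segments: pd.DataFrame
    calls: pd.DataFrame
    lrr: pd.DataFrame
    phenotypes: pd.DataFrame
    carrier: pd.Series
    causal_region: tuple[str, int, int] | None


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Generate one fully linked study dataset from a single seed."""
    samples, families = generate_cohort(config.cohort)
    probes, genes, exclusions, reference_cnvs = generate_genome(config.cohort)
    segments = generate_cnv_landscape(samples, probes, config.landscape)

    carriers = set(segments.loc[segments["is_causal"], "sample_id"])
    carrier = pd.Series(samples["sample_id"].isin(carriers).to_numpy(),
                        index=samples["sample_id"], name="is_carrier")

    noise_rng = _rng(config.seed, 7)
    sds = pd.Series(config.lrr_noise_sd, index=samples["sample_id"], dtype=float)
    noisy = noise_rng.random(len(sds)) < config.noisy_sample_fraction
    sds[noisy] = 0.5
    lrr = render_intensities(samples, segments, probes,
                             noise_sd=config.lrr_noise_sd, seed=config.seed,
                             sample_noise_sd=sds)

    calls = emit_cnv_calls(segments, probes, config.calls, samples=samples)
    phenotypes = generate_phenotypes(samples, carrier, config.phenotype)

    causal = None
    if config.landscape.causal_chrom is not None:
        causal = causal_region_bounds(probes, config.landscape)

    return SimulatedData(
        samples=samples, families=families, probes=probes, genes=genes,
        exons=exon_table(genes), exclusions=exclusions,
        reference_cnvs=reference_cnvs, segments=segments, calls=calls,
        lrr=lrr, phenotypes=phenotypes, carrier=carrier, causal_region=causal)
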