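"""End-to-end orchestration: simulate -> scores -> QC -> all association stages.

:class:`RunConfig` gathers every threshold of the protocol with its
standard default (call confidence 10, 20 kb, 10 probes, 50 % exclusion
overlap, 20 % join gap, 50-kb gene flank, < 5 reference events for
rarity, > 100 autosomal calls, LRR SD > 0.35, 100/500-kb length classes,
the two region schemes, 100 burden resamples) alongside the simulation
settings, permutation counts and seeds.  :func:`run_pipeline` executes
the stages in order, writes every result table as TSV with an
audit-trail header naming the thresholds used, and is byte-identical
across runs with the same config.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import cosegregation, enrichment, intensity_assoc, io, phenotype, qc
from . import state_assoc
from .synthetic import SimulationConfig, simulate_dataset

log = logging.getLogger("cnvtrait")


@dataclass
class Thresholds:
    min_confidence: float = qc.MIN_CONFIDENCE
    min_span_bp: int = qc.MIN_SPAN_BP
    min_snps: int = qc.MIN_SNPS
    max_exclusion_fraction: float = qc.MAX_EXCLUSION_FRACTION
    max_join_gap_fraction: float = qc.MAX_JOIN_GAP_FRACTION
    gene_flank_bp: int = qc.GENE_FLANK_BP
    rare_max_events: int = qc.RARE_MAX_EVENTS
    max_autosomal_calls: int = qc.MAX_AUTOSOMAL_CALLS
    max_lrr_sd: float = qc.MAX_LRR_SD
    short_max_bp: int = burden_mod.SHORT_MAX_BP
    large_min_bp: int = burden_mod.LARGE_MIN_BP
    state_region_scheme: tuple = state_assoc.STATE_REGION_SCHEME
    intensity_region_scheme: tuple = state_assoc.INTENSITY_REGION_SCHEME


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    genome_build: str = "synthetic-1"
    traits: tuple[str, ...] = ("PC1", "IQadjPC1")
    n_perms_state: int = 2500
    n_perms_intensity: int = 2500
    n_perms_enrichment: int = 500
    n_resamples: int = 100
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = _sim_from_dict(self.simulation)
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        self.simulation.seed = self.seed
        self.simulation.__post_init__()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(dataclasses.asdict(self)), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sim_from_dict(d: dict) -> SimulationConfig:
    from .synthetic import (CallEmissionConfig, CnvLandscapeConfig,
                            CohortConfig, PhenoGenConfig)
    kwargs = dict(d)
    for key, cls in (("cohort", CohortConfig), ("landscape", CnvLandscapeConfig),
                     ("calls", CallEmissionConfig), ("phenotype", PhenoGenConfig)):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = dict(kwargs[key])
            for name, value in sub.items():
                if isinstance(value, list):
                    sub[name] = tuple(value)
            kwargs[key] = cls(**sub)
    return SimulationConfig(**kwargs)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _empty_assoc() -> pd.DataFrame:
    return pd.DataFrame(columns=["probe_id", "p", "direction",
                                 "n_informative", "N", "slope", "rho_lrr",
                                 "chrom", "pos", "cohort", "trait"])


def _threshold_notes(config: RunConfig) -> dict:
    notes = {"genome_build": config.genome_build, "seed": config.seed}
    notes.update({k: v for k, v in
                  dataclasses.asdict(config.thresholds).items()})
    return notes


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write result tables under ``out_dir``.

    Returns a dict of the in-memory results keyed by stage.  Tables are
    sorted deterministically; all randomness derives from the configured
    seeds, so a rerun with the same config is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes = _threshold_notes(config)
    th = config.thresholds
    results: dict = {}

    # ----- simulate --------------------------------------------------------
    sim = simulate_dataset(config.simulation)
    results["sim"] = sim
    log.info("simulated %d samples, %d probes, %d true segments, %d raw calls",
             len(sim.samples), len(sim.probes), len(sim.segments),
             len(sim.calls))
    io.write_table(sim.samples, out / "samples.tsv", notes)
    io.write_table(sim.probes, out / "probes.tsv", notes)
    io.write_penncnv_calls(sim.calls, out / "calls_raw.penncnv")
    io.write_bed(sim.exclusions, out / "exclusions.bed", ("name",))
    io.write_bed(sim.reference_cnvs, out / "reference_cnvs.bed", ("count",))

    # ----- phenotype scores ------------------------------------------------
    pheno = sim.phenotypes.copy()
    pheno["cohort"] = sim.samples.set_index("sample_id").loc[
        pheno["sample_id"], "cohort"].to_numpy()
    pc1 = pd.Series(np.nan, index=pheno.index)
    pca_info = {}
    for cohort, grp in pheno.groupby("cohort"):
        if grp[list(phenotype.PC1_TRAITS)].dropna().shape[0] < 10:
            log.warning("cohort %s too small for PC1; scores left missing",
                        cohort)
            continue
        res = phenotype.derive_pc1(grp)
        pc1.loc[grp.index] = res.scores
        pca_info[cohort] = {
            "variance_explained": res.variance_explained,
            "loadings": res.loadings.to_dict(),
            "n_complete": int(res.scores.notna().sum()),
        }
        log.info("PC1 (%s): %.1f%% variance over %d complete cases", cohort,
                 100 * res.variance_explained, res.scores.notna().sum())
    pheno["PC1"] = pc1
    adj = pd.Series(np.nan, index=pheno.index)
    for cohort, grp in pheno.groupby("cohort"):
        try:
            adj.loc[grp.index] = phenotype.adjust_for_iq(
                pheno.loc[grp.index, "PC1"], pheno.loc[grp.index, "PIQ"])
        except ValueError:
            log.warning("cohort %s too small for IQ adjustment", cohort)
    pheno["IQadjPC1"] = adj
    labels = phenotype.assign_case_control(
        pheno.set_index("sample_id")["IBGdiscr"])
    pheno["label"] = labels.loc[pheno["sample_id"]].to_numpy()
    results["phenotypes"] = pheno
    results["pca_info"] = pca_info
    io.write_table(pheno, out / "phenotypes.tsv", notes)

    # ----- CNV QC ----------------------------------------------------------
    lrr_sd = sim.lrr.loc[:, sim.probes.loc[sim.probes["chrom"] != "X",
                                           "probe_id"]].std(axis=1, ddof=1)
    annotated, kept_samples, counts = qc.run_call_qc(
        sim.calls, sim.exclusions, lrr_sd, sim.genes, sim.exons,
        sim.reference_cnvs)
    log.info("call QC accounting: %s", counts)
    results["calls_qc"] = annotated
    results["qc_counts"] = counts
    results["kept_samples"] = kept_samples
    io.write_table(annotated, out / "calls_qc.tsv", notes)

    meta_df = pd.DataFrame([counts]).T.rename(columns={0: "count"})
    io.write_table(meta_df.rename_axis("stage").reset_index(),
                   out / "qc_accounting.tsv", notes)

    samples_kept = sim.samples[sim.samples["sample_id"].isin(kept_samples)]
    ph = pheno.set_index("sample_id")
    fam = sim.samples.set_index("sample_id")["family_id"]
    sex = sim.samples.set_index("sample_id")["sex"]

    # ----- burden ----------------------------------------------------------
    burden_rows = []
    rng_seed = config.seed
    for burden_class in burden_mod.BURDEN_CLASSES:
        b = burden_mod.compute_burden(annotated, burden_class,
                                      sample_ids=samples_kept["sample_id"])
        for cohort in ("RD", "ADHD"):
            in_cohort = samples_kept.loc[samples_kept["cohort"] == cohort,
                                         "sample_id"]
            for trait in config.traits:
                for measure in ("n_events", "total_length_bp"):
                    try:
                        stat = burden_mod.resampled_correlation(
                            b.loc[in_cohort, measure], ph.loc[in_cohort, trait],
                            fam.loc[in_cohort], n_resamples=config.n_resamples,
                            seed=rng_seed + 11)
                    except ValueError:
                        continue
                    burden_rows.append((burden_class, cohort, trait, measure,
                                        stat.point, stat.p_median))
    burden_df = pd.DataFrame(burden_rows, columns=[
        "class", "cohort", "trait", "measure", "median_rho", "median_p"])
    results["burden"] = burden_df
    io.write_table(burden_df, out / "burden_correlations.tsv", notes)

    b_all = burden_mod.compute_burden(annotated, "all",
                                      sample_ids=samples_kept["sample_id"])
    cc_rows = []
    for measure in ("n_events", "total_length_bp"):
        try:
            stat = burden_mod.case_control_burden(
                b_all[measure], ph.loc[b_all.index, "label"],
                fam.loc[b_all.index], n_resamples=config.n_resamples,
                seed=rng_seed + 13)
            cc_rows.append((measure, stat.point, stat.p_median,
                            stat.n_resamples, stat.n_excluded))
        except ValueError:
            pass
    cc_df = pd.DataFrame(cc_rows, columns=["measure", "median_or", "median_p",
                                           "n_resamples", "n_excluded"])
    results["burden_case_control"] = cc_df
    io.write_table(cc_df, out / "burden_case_control.tsv", notes)

    # ----- state association ----------------------------------------------
    states = state_assoc.assign_probe_states(
        annotated, sim.probes, sex, sample_ids=samples_kept["sample_id"])
    covered = state_assoc.restrict_to_covered(states)
    autosomal_probe_ids = set(sim.probes.loc[sim.probes["chrom"] != "X",
                                             "probe_id"])
    covered_auto = covered.loc[:, [c for c in covered.columns
                                   if c in autosomal_probe_ids]]
    log.info("probes covered by CNV events: %d (%d autosomal)",
             covered.shape[1], covered_auto.shape[1])
    results["states"] = states

    probe_pos = sim.probes.set_index("probe_id")
    probe_ordinal = {pid: i for i, pid in enumerate(sim.probes["probe_id"])}

    per_cohort: dict = {}
    meta_tables: dict = {}
    region_tables = []
    for trait in config.traits:
        for cohort in ("RD", "ADHD"):
            ids = samples_kept.loc[samples_kept["cohort"] == cohort,
                                   "sample_id"]
            try:
                res = state_assoc.family_permutation_scan(
                    covered_auto.loc[ids], ph.loc[ids, trait], fam.loc[ids],
                    n_perms=config.n_perms_state, seed=config.seed + 21)
            except ValueError:
                log.warning("cohort %s too small for the %s state scan",
                            cohort, trait)
                per_cohort[(trait, cohort)] = _empty_assoc()
                continue
            res = res[res["direction"] != 0].copy()
            res["chrom"] = probe_pos.loc[res["probe_id"], "chrom"].to_numpy()
            res["pos"] = probe_pos.loc[res["probe_id"], "pos"].to_numpy()
            res["cohort"] = cohort
            res["trait"] = trait
            per_cohort[(trait, cohort)] = res
        meta = state_assoc.meta_analyze(per_cohort[(trait, "RD")],
                                        per_cohort[(trait, "ADHD")],
                                        suffixes=("_rd", "_adhd"))
        if len(meta):
            meta["chrom"] = probe_pos.loc[meta["probe_id"], "chrom"].to_numpy()
            meta["pos"] = probe_pos.loc[meta["probe_id"], "pos"].to_numpy()
            meta = meta.sort_values(["chrom", "pos"],
                                    kind="stable").reset_index(drop=True)
        meta_tables[trait] = meta
        for source, table, p_col in (
            ("meta", meta, "p_meta"),
            ("RD", per_cohort[(trait, "RD")], "p"),
            ("ADHD", per_cohort[(trait, "ADHD")], "p"),
        ):
            if len(table) == 0:
                continue
            ordered = table.sort_values(["chrom", "pos"], kind="stable")
            regions = state_assoc.detect_regions(
                ordered, scheme=th.state_region_scheme, p_col=p_col,
                probe_index=probe_ordinal)
            if len(regions):
                regions["trait"] = trait
                regions["source"] = source
                for i, reg in regions.iterrows():
                    freq = state_assoc.cnv_plus_frequency(
                        states, reg["probe_ids"].split(","))
                    regions.loc[i, "cnv_plus_pct"] = freq["any_probe_pct"]
                region_tables.append(regions)
        log.info("state GWAS (%s): %d meta probes", trait, len(meta))
    state_regions = (pd.concat(region_tables, ignore_index=True)
                     if region_tables else state_assoc._empty_regions())
    results["state_per_cohort"] = per_cohort
    results["state_meta"] = meta_tables
    results["state_regions"] = state_regions
    for trait, meta in meta_tables.items():
        io.write_table(meta, out / f"state_meta_{trait}.tsv", notes)
    for (trait, cohort), res in per_cohort.items():
        io.write_table(res, out / f"state_{cohort}_{trait}.tsv", notes)
    io.write_table(state_regions, out / "state_regions.tsv", notes)

    # ----- X chromosome ----------------------------------------------------
    x_probe_ids = [c for c in covered.columns if c not in autosomal_probe_ids]
    x_tables = {}
    if x_probe_ids:
        for trait in config.traits:
            _, combined = state_assoc.x_association(
                covered.loc[samples_kept["sample_id"], x_probe_ids],
                ph.loc[samples_kept["sample_id"], trait],
                fam, sex, n_perms=config.n_perms_state,
                seed=config.seed + 31)
            x_tables[trait] = combined
            io.write_table(combined, out / f"state_x_{trait}.tsv", notes)
    results["state_x"] = x_tables

    # ----- intensity association -------------------------------------------
    auto_cols = [p for p in sim.lrr.columns if p in autosomal_probe_ids]
    lrr_kept = sim.lrr.loc[samples_kept["sample_id"], auto_cols]
    pca = intensity_assoc.lrr_pca(lrr_kept)
    outliers = intensity_assoc.flag_lrr_outliers(pca)
    log.info("LRR PCA: %d components, %d outliers flagged",
             pca.n_components, int(outliers.sum()))
    clean_ids = outliers.index[~outliers]
    covs = pca.scores.loc[clean_ids, ["PC1", "PC2"]]
    int_results = {}
    int_region_tables = []
    for trait in config.traits:
        per_cohort_int = {}
        for cohort in ("RD", "ADHD"):
            ids = samples_kept.loc[samples_kept["cohort"] == cohort,
                                   "sample_id"]
            ids = [s for s in ids if s in set(clean_ids)]
            try:
                res = intensity_assoc.intensity_scan(
                    lrr_kept.loc[ids], ph.loc[ids, trait], covs.loc[ids],
                    fam.loc[ids], n_perms=config.n_perms_intensity,
                    seed=config.seed + 41)
            except ValueError:
                log.warning("cohort %s too small for the %s intensity scan",
                            cohort, trait)
                per_cohort_int[cohort] = _empty_assoc()
                continue
            res["chrom"] = probe_pos.loc[res["probe_id"], "chrom"].to_numpy()
            res["pos"] = probe_pos.loc[res["probe_id"], "pos"].to_numpy()
            res["cohort"] = cohort
            per_cohort_int[cohort] = res
        meta = state_assoc.meta_analyze(
            per_cohort_int["RD"].dropna(subset=["p"]),
            per_cohort_int["ADHD"].dropna(subset=["p"]),
            suffixes=("_rd", "_adhd"))
        if len(meta):
            meta["chrom"] = probe_pos.loc[meta["probe_id"], "chrom"].to_numpy()
            meta["pos"] = probe_pos.loc[meta["probe_id"], "pos"].to_numpy()
        int_results[trait] = {"per_cohort": per_cohort_int, "meta": meta}
        for source, table, p_col in (
            ("meta", meta, "p_meta"),
            ("RD", per_cohort_int["RD"], "p"),
            ("ADHD", per_cohort_int["ADHD"], "p"),
        ):
            if len(table) == 0:
                continue
            ordered = table.dropna(subset=[p_col]).sort_values(
                ["chrom", "pos"], kind="stable")
            regions = intensity_assoc.detect_intensity_regions(
                ordered, p_col=p_col, probe_index=probe_ordinal)
            if len(regions):
                regions["trait"] = trait
                regions["source"] = source
                int_region_tables.append(regions)
        io.write_table(per_cohort_int["RD"], out / f"intensity_RD_{trait}.tsv",
                       notes)
        io.write_table(per_cohort_int["ADHD"],
                       out / f"intensity_ADHD_{trait}.tsv", notes)
    intensity_regions = (pd.concat(int_region_tables, ignore_index=True)
                         if int_region_tables
                         else state_assoc._empty_regions())
    results["intensity"] = int_results
    results["intensity_regions"] = intensity_regions
    results["lrr_outliers"] = outliers
    io.write_table(intensity_regions, out / "intensity_regions.tsv", notes)

    # ----- co-segregation --------------------------------------------------
    labels_s = ph["label"]
    large = cosegregation.find_large_case_cnvs(annotated, labels_s, pheno)
    shared = cosegregation.find_shared_case_cnvs(annotated, fam, labels_s,
                                                 sex, phenotypes=pheno)
    candidates = _default_candidates(sim)
    cand = cosegregation.candidate_overlap(annotated, candidates, fam,
                                           labels_s, phenotypes=pheno)
    results["coseg_large"] = large
    results["coseg_shared"] = shared
    results["coseg_candidates"] = cand
    io.write_table(large, out / "coseg_large.tsv", notes)
    io.write_table(shared, out / "coseg_shared.tsv", notes)
    io.write_table(cand, out / "coseg_candidates.tsv", notes)

    # ----- enrichment ------------------------------------------------------
    case_ids = set(labels_s.index[labels_s == "case"])
    case_calls = annotated[annotated["sample_id"].isin(case_ids)]
    enr = pd.DataFrame()
    if len(case_calls):
        intervals = enrichment.independent_intervals(case_calls)
        covered_manifest = sim.probes[
            sim.probes["probe_id"].isin(covered.columns)]
        keep = []
        for i, row in intervals.iterrows():
            sub = covered_manifest[
                (covered_manifest["chrom"] == row["chrom"])
                & (covered_manifest["pos"] >= row["start_bp"])
                & (covered_manifest["pos"] <= row["end_bp"])]
            if len(sub):
                keep.append(i)
        intervals = intervals.loc[keep]
        gene_sets = _default_gene_sets(sim, config.seed)
        if len(intervals):
            enr = enrichment.target_enrichment(
                intervals, gene_sets, sim.genes, covered_manifest,
                n_perms=config.n_perms_enrichment, seed=config.seed + 51)
    results["enrichment"] = enr
    io.write_table(enr, out / "enrichment.tsv", notes)

    summary = {
        "counts": counts,
        "pca": _to_plain(pca_info),
        "n_state_regions": int(len(state_regions)),
        "n_intensity_regions": int(len(intensity_regions)),
        "causal_region": list(sim.causal_region) if sim.causal_region else None,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(_to_plain(summary), fh, indent=2, sort_keys=True)
    results["summary"] = summary
    return results


def _default_candidates(sim) -> pd.DataFrame:
    """Candidate list: the causal region plus the first genes per chromosome."""
    rows = []
    if sim.causal_region is not None:
        chrom, start, end = sim.causal_region
        rows.append(("causal_region", chrom, start, end, False))
    for gene in sim.genes.groupby("chrom", sort=True).head(1).itertuples(False):
        rows.append((gene.gene, gene.chrom, gene.start_bp, gene.end_bp, True))
    return pd.DataFrame(rows, columns=["name", "chrom", "start_bp",
                                       "end_bp", "is_gene"])


def _default_gene_sets(sim, seed: int) -> dict[str, list[str]]:
    """Demonstration gene sets: random partitions plus causal-region genes."""
    rng = np.random.default_rng(seed + 61)
    genes = sim.genes["gene"].tolist()
    shuffled = list(rng.permutation(genes))
    k = max(10, len(genes) // 6)
    sets = {f"random_set_{i + 1}": shuffled[i * k:(i + 1) * k]
            for i in range(4)}
    if sim.causal_region is not None:
        chrom, start, end = sim.causal_region
        near = sim.genes[
            (sim.genes["chrom"] == chrom)
            & (sim.genes["start_bp"] <= end + qc.GENE_FLANK_BP)
            & (sim.genes["end_bp"] >= start - qc.GENE_FLANK_BP)]
        causal_set = sorted(set(near["gene"]) | set(shuffled[:10]))
        sets["causal_neighborhood"] = causal_set
    return sets
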