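"""CNV burden correlations and gene-set enrichment of case calls.

Burden (event count, covered length) per class is correlated with PC1 by
the median Spearman rho over 100 one-per-sibship resamples; case calls
are tested for gene-set enrichment with probe-matched random intervals.
"""
import cnvtrait as ct

cfg = ct.SimulationConfig(seed=4)
cfg.cohort.n_families = 150
sim = ct.simulate_dataset(cfg)

lrr_sd = sim.lrr.std(axis=1, ddof=1)
annotated, kept, _ = ct.run_call_qc(sim.calls, sim.exclusions, lrr_sd,
                                    sim.genes, sim.exons,
                                    sim.reference_cnvs)
samples = sim.samples[sim.samples["sample_id"].isin(kept)]
ph = sim.phenotypes.set_index("sample_id").loc[samples["sample_id"]]
pc1 = ct.derive_pc1(ph).scores
fam = sim.samples.set_index("sample_id")["family_id"]

for cls in ("all", "gene", "rare", "short", "medium", "large"):
    b = ct.compute_burden(annotated, cls, sample_ids=samples["sample_id"])
    stat = ct.resampled_correlation(b["total_length_bp"], pc1,
                                    fam.loc[b.index], seed=0)
    print(f"burden ({cls:6s}) vs PC1: median rho {stat.point:+.3f}, "
          f"median p {stat.p_median:.2f}")

labels = ct.assign_case_control(ph["IBGdiscr"])
case_calls = annotated[annotated["sample_id"].isin(
    labels.index[labels == "case"])]
intervals = ct.independent_intervals(case_calls)
sex = sim.samples.set_index("sample_id")["sex"]
states = ct.assign_probe_states(annotated, sim.probes, sex,
                                sample_ids=samples["sample_id"])
covered_probes = sim.probes[sim.probes["probe_id"].isin(
    ct.restrict_to_covered(states).columns)]
intervals = intervals[[
    len(covered_probes[(covered_probes["chrom"] == r.chrom)
                       & (covered_probes["pos"] >= r.start_bp)
                       & (covered_probes["pos"] <= r.end_bp)]) > 0
    for r in intervals.itertuples()]]

gene_sets = {"set_A": list(sim.genes["gene"][:40]),
             "set_B": list(sim.genes["gene"][40:80])}
res = ct.target_enrichment(intervals, gene_sets, sim.genes, covered_probes,
                           n_perms=500, seed=0)
print(f"\n{len(intervals)} independent case intervals tested")
for r in res.itertuples():
    print(f"enrichment {r.set_name}: observed {r.observed} hits, "
          f"empirical p {r.p_empirical:.3f} "
          f"(Bonferroni {r.p_corrected:.3f})")
# Under the null (no planted clustering) rho hovers near 0 and the
# enrichment p values are unremarkable, mirroring a negative screen.
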