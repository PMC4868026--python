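import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cnvtrait as ct
from cnvtrait.synthetic import (CallEmissionConfig, CnvLandscapeConfig,
                                CohortConfig, PhenoGenConfig,
                                causal_region_bounds, count_probes_in,
                                emit_cnv_calls, exon_table,
                                generate_cnv_landscape, generate_cohort,
                                generate_genome, generate_phenotypes,
                                render_intensities)


def _tiny_cohort(**kw):
    defaults = dict(n_families=10, sibship_size_range=(2, 2),
                    sibship_size_probs=None, chromosomes=("1",),
                    n_probes_per_chrom=50, seed=5)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestCohort:
    def test_fixed_sibship_size_forces_sample_count(self):
        samples, families = generate_cohort(_tiny_cohort())
        assert len(samples) == 20 and len(families) == 10
        assert set(samples.columns) >= {"sample_id", "family_id", "sex",
                                        "cohort"}

    def test_same_seed_reproduces_tables(self):
        a, fa = generate_cohort(_tiny_cohort())
        b, fb = generate_cohort(_tiny_cohort())
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(fa, fb)

    def test_family_size_histogram_matches_sampling_distribution(self):
        cfg = _tiny_cohort(n_families=300, sibship_size_range=(2, 3),
                           sibship_size_probs=(0.7, 0.3))
        _, families = generate_cohort(cfg)
        n3 = (families["size"] == 3).sum()
        lo, hi = stats.binom.interval(0.999, 300, 0.3)
        assert lo <= n3 <= hi

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_families=0)
        with pytest.raises(ValueError):
            CohortConfig(sibship_size_range=(1, 2))
        with pytest.raises(ValueError):
            CohortConfig(sibship_size_range=(3, 2))


class TestGenome:
    def test_probe_positions_strictly_increasing(self):
        probes, *_ = generate_genome(_tiny_cohort(n_probes_per_chrom=1000))
        assert probes["pos"].is_monotonic_increasing
        assert probes["pos"].is_unique

    def test_exons_lie_within_gene_span(self):
        _, genes, _, _ = generate_genome(_tiny_cohort())
        exons = exon_table(genes)
        spans = genes.set_index("gene")
        for row in exons.itertuples(index=False):
            assert spans.loc[row.gene, "start_bp"] <= row.start_bp
            assert row.end_bp <= spans.loc[row.gene, "end_bp"]

    def test_reference_events_drive_rarity_counts(self):
        """k catalogued events fully covering a call -> classifier sees k."""
        probes, genes, excl, _ = generate_genome(_tiny_cohort())
        ref = pd.DataFrame({"chrom": ["1", "1"],
                            "start_bp": [10_000, 10_000],
                            "end_bp": [80_000, 90_000],
                            "count": [3, 4]})
        call = pd.DataFrame({"sample_id": ["A"], "chrom": ["1"],
                             "start_bp": [20_000], "end_bp": [60_000],
                             "copy_number": [1], "n_snps": [10],
                             "confidence": [20.0]})
        out = ct.classify_rarity(call, ref)
        # brute-force: both events cover 100% >= 50% of the call
        assert out.loc[0, "ref_overlaps"] == 7
        assert not out.loc[0, "rare"]


class TestLandscape:
    def _setup(self, **kw):
        cfg = _tiny_cohort(n_families=100, chromosomes=("1", "2"),
                           n_probes_per_chrom=200)
        samples, _ = generate_cohort(cfg)
        probes, *_ = generate_genome(cfg)
        land = CnvLandscapeConfig(background_rate=0.0, n_recurrent_loci=0,
                                  causal_chrom="2", seed=7, **kw)
        return samples, probes, land

    def test_zero_carrier_fraction_plants_nothing(self):
        samples, probes, land = self._setup(causal_carrier_fraction=0.0)
        seg = generate_cnv_landscape(samples, probes, land)
        assert len(seg) == 0

    def test_carrier_count_within_binomial_envelope(self):
        samples, probes, land = self._setup(causal_carrier_fraction=0.05)
        seg = generate_cnv_landscape(samples, probes, land)
        n = len(samples)
        lo, hi = stats.binom.interval(0.99, n, 0.05)
        assert lo <= seg["sample_id"].nunique() <= hi

    def test_full_sharing_makes_all_sibs_carriers(self):
        samples, probes, land = self._setup(causal_carrier_fraction=0.2,
                                            causal_sharing_prob=1.0)
        seg = generate_cnv_landscape(samples, probes, land)
        carriers = set(seg["sample_id"])
        fams = samples.set_index("sample_id")["family_id"]
        hit_fams = {fams[s] for s in carriers}
        expected = set(samples[samples["family_id"].isin(hit_fams)]
                       ["sample_id"])
        assert carriers == expected

    def test_causal_region_without_probes_raises(self):
        samples, probes, land = self._setup()
        land.causal_start_bp, land.causal_end_bp = 1, 10  # before 1st probe
        with pytest.raises(ValueError, match="no probes|no probe"):
            generate_cnv_landscape(samples, probes, land)

    def test_every_segment_contains_a_probe(self, small_sim):
        for seg in small_sim.segments.itertuples(index=False):
            assert count_probes_in(small_sim.probes, seg.chrom,
                                   seg.start_bp, seg.end_bp) >= 1


class TestIntensities:
    def _frame(self):
        probes = pd.DataFrame({"probe_id": [f"p{i}" for i in range(10)],
                               "chrom": "1",
                               "pos": np.arange(10) * 1000 + 500})
        samples = pd.DataFrame({"sample_id": ["A", "B"],
                                "family_id": ["F1", "F2"],
                                "sex": ["M", "F"], "cohort": ["RD", "RD"]})
        return samples, probes

    def test_noise_free_diploid_lrr_is_zero(self):
        samples, probes = self._frame()
        seg = pd.DataFrame(columns=["sample_id", "chrom", "start_bp",
                                    "end_bp", "copy_number", "is_causal"])
        lrr = render_intensities(samples, seg, probes, noise_sd=0.0, seed=1)
        assert (lrr.to_numpy() == 0).all()

    def test_deletion_lower_than_duplication(self):
        samples, probes = self._frame()
        seg = pd.DataFrame({
            "sample_id": ["A", "B"], "chrom": ["1", "1"],
            "start_bp": [0, 0], "end_bp": [10_000, 10_000],
            "copy_number": [1, 3], "is_causal": [False, False]})
        lrr = render_intensities(samples, seg, probes, noise_sd=0.0, seed=1)
        assert (lrr.loc["A"] < lrr.loc["B"]).all()

    def test_long_deletion_lowers_sample_mean(self):
        samples, probes = self._frame()
        seg = pd.DataFrame({
            "sample_id": ["A"], "chrom": ["1"], "start_bp": [0],
            "end_bp": [10_000], "copy_number": [1], "is_causal": [False]})
        lrr = render_intensities(samples, seg, probes, noise_sd=0.1, seed=1)
        assert lrr.loc["A"].mean() < lrr.loc["B"].mean()

    def test_negative_noise_rejected(self):
        samples, probes = self._frame()
        with pytest.raises(ValueError):
            render_intensities(samples, pd.DataFrame(
                columns=["sample_id", "chrom", "start_bp", "end_bp",
                         "copy_number", "is_causal"]),
                probes, noise_sd=-1.0)

    def test_baf_clusters_follow_copy_number(self):
        samples, probes = self._frame()
        seg = pd.DataFrame({
            "sample_id": ["A"], "chrom": ["1"], "start_bp": [0],
            "end_bp": [10_000], "copy_number": [1], "is_causal": [False]})
        _, baf = render_intensities(samples, seg, probes, noise_sd=0.0,
                                    seed=1, return_baf=True)
        # single-copy probes have no heterozygous (0.5) cluster
        assert not ((baf.loc["A"] > 0.2) & (baf.loc["A"] < 0.8)).any()


class TestCallEmission:
    def _fixture(self):
        cfg = _tiny_cohort(n_families=20, chromosomes=("1", "2"),
                           n_probes_per_chrom=300)
        samples, _ = generate_cohort(cfg)
        probes, *_ = generate_genome(cfg)
        land = CnvLandscapeConfig(background_rate=1.0, n_recurrent_loci=2,
                                  causal_chrom="1", seed=3)
        segments = generate_cnv_landscape(samples, probes, land)
        return samples, probes, segments

    def test_no_jitter_no_fp_is_bijective(self):
        samples, probes, segments = self._fixture()
        calls = emit_cnv_calls(segments, probes, CallEmissionConfig(
            boundary_jitter_probes=0, false_positive_rate=0.0, seed=1))
        assert len(calls) == len(segments)
        assert calls["is_true"].all()
        # same probe footprint as the source segment
        for seg, call in zip(
                segments.sort_values(["sample_id", "chrom", "start_bp"])
                .itertuples(index=False),
                calls.itertuples(index=False)):
            assert count_probes_in(probes, seg.chrom, seg.start_bp,
                                   seg.end_bp) == call.n_snps

    def test_probe_count_matches_manifest_scan(self):
        samples, probes, segments = self._fixture()
        calls = emit_cnv_calls(segments, probes,
                               CallEmissionConfig(seed=2))
        for call in calls.itertuples(index=False):
            assert call.n_snps == count_probes_in(
                probes, call.chrom, call.start_bp, call.end_bp)

    def test_confidence_pinned_below_ten_fails_filter(self):
        samples, probes, segments = self._fixture()
        calls = emit_cnv_calls(segments, probes, CallEmissionConfig(
            confidence_mean=5.0, confidence_sd=0.0,
            false_positive_rate=0.0, seed=1))
        kept = ct.filter_calls(calls, pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp"]))
        assert len(kept) == 0


class TestPhenotypes:
    def _samples(self, n_fam=150):
        cfg = _tiny_cohort(n_families=n_fam, chromosomes=("1",))
        samples, _ = generate_cohort(cfg)
        return samples

    def test_independent_sibs_when_icc_zero(self):
        samples = self._samples(300)
        carrier = pd.Series(False, index=samples["sample_id"])
        cfg = PhenoGenConfig(family_icc=0.0, missing_rate=0.0, seed=1)
        ph = generate_phenotypes(samples, carrier, cfg)
        sib = ph.merge(samples, on="sample_id").groupby("family_id")
        first = sib.nth(0).set_index("family_id")["WRead"]
        second = sib.nth(1).set_index("family_id")["WRead"]
        r = np.corrcoef(first, second)[0, 1]
        assert abs(r) < 0.15

    def test_equal_loadings_zero_noise_collapse_to_one_factor(self):
        samples = self._samples(30)
        carrier = pd.Series(False, index=samples["sample_id"])
        loadings = {c: {t: 0.7 for t in ct.synthetic.TRAITS}
                    for c in ("RD", "ADHD")}
        cfg = PhenoGenConfig(loadings=loadings,
                             noise_sd={t: 0.0 for t in ct.synthetic.TRAITS},
                             missing_rate=0.0, seed=1)
        ph = generate_phenotypes(samples, carrier, cfg)
        base = ph["WRead"]
        for t in ct.synthetic.TRAITS[1:]:
            assert np.allclose(ph[t], base)

    def test_planted_effect_recovered_within_two_se(self):
        samples = self._samples(300)  # ~600 samples
        rng = np.random.default_rng(3)
        carrier = pd.Series(rng.random(len(samples)) < 0.05,
                            index=samples["sample_id"])
        cfg = PhenoGenConfig(causal_beta=-0.8, missing_rate=0.0, seed=2)
        ph = generate_phenotypes(samples, carrier, cfg)
        f = ph.set_index("sample_id")["true_factor"]
        diff = f[carrier].mean() - f[~carrier].mean()
        se = np.sqrt(f[carrier].var() / carrier.sum()
                     + f[~carrier].var() / (~carrier).sum())
        assert diff == pytest.approx(-0.8, abs=2 * se)

    def test_discriminant_composite_is_weighted_sum(self):
        samples = self._samples(30)
        carrier = pd.Series(False, index=samples["sample_id"])
        cfg = PhenoGenConfig(missing_rate=0.0, seed=4)
        ph = generate_phenotypes(samples, carrier, cfg)
        raw = (0.5 * ph["WRead"] + 0.3 * ph["WSpell"] + 0.2 * ph["OC"])
        z = (raw - raw.mean()) / raw.std(ddof=1)
        assert np.allclose(ph["IBGdiscr"], z)


class TestDeterminism:
    def test_simulate_dataset_reproducible(self):
        cfg = ct.SimulationConfig(seed=9)
        cfg.cohort.n_families = 15
        cfg.cohort.chromosomes = ("1", "2")
        cfg.cohort.n_probes_per_chrom = 100
        a = ct.simulate_dataset(cfg)
        cfg2 = ct.SimulationConfig(seed=9)
        cfg2.cohort.n_families = 15
        cfg2.cohort.chromosomes = ("1", "2")
        cfg2.cohort.n_probes_per_chrom = 100
        b = ct.simulate_dataset(cfg2)
        pd.testing.assert_frame_equal(a.calls, b.calls)
        pd.testing.assert_frame_equal(a.lrr, b.lrr)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_causal_frequency_round_trip_without_jitter(self):
        """Planted carrier fraction reappears exactly in the state matrix."""
        cfg = ct.SimulationConfig(seed=11)
        cfg.cohort.n_families = 50
        cfg.cohort.chromosomes = ("1", "2")
        cfg.cohort.n_probes_per_chrom = 200
        cfg.calls.boundary_jitter_probes = 0
        cfg.calls.false_positive_rate = 0.0
        cfg.landscape.background_rate = 0.0
        cfg.landscape.n_recurrent_loci = 0
        sim = ct.simulate_dataset(cfg)
        sex = sim.samples.set_index("sample_id")["sex"]
        states = ct.assign_probe_states(sim.calls, sim.probes, sex,
                                        sample_ids=sim.samples["sample_id"])
        chrom, start, end = sim.causal_region
        probe = sim.probes[(sim.probes["chrom"] == chrom)
                           & (sim.probes["pos"] >= start)
                           & (sim.probes["pos"] <= end)]["probe_id"].iloc[0]
        assert states[probe].sum() == int(sim.carrier.sum())
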