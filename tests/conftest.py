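import numpy as np
import pandas as pd
import pytest

import cnvtrait as ct


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete simulated study reused across tests."""
    cfg = ct.SimulationConfig(seed=42)
    cfg.cohort.n_families = 60
    cfg.cohort.chromosomes = ("1", "2", "3", "X")
    cfg.cohort.n_probes_per_chrom = 400
    cfg.landscape.background_rate = 2.0
    cfg.landscape.n_recurrent_loci = 8
    cfg.phenotype.causal_beta = -0.8
    return ct.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_qc(small_sim):
    sim = small_sim
    lrr_sd = sim.lrr.std(axis=1, ddof=1)
    annotated, kept, counts = ct.run_call_qc(
        sim.calls, sim.exclusions, lrr_sd, sim.genes, sim.exons,
        sim.reference_cnvs)
    return annotated, kept, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_calls(rng, n=200, chroms=("1", "2"), samples=("S1", "S2", "S3")):
    """Random call table straddling every QC threshold."""
    chrom = rng.choice(chroms, n)
    start = rng.integers(1, 3_000_000, n)
    length = rng.choice(
        [5_000, 19_999, 20_000, 25_000, 150_000, 600_000], n)
    return pd.DataFrame({
        "sample_id": rng.choice(samples, n),
        "chrom": chrom,
        "start_bp": start,
        "end_bp": start + length - 1,
        "copy_number": rng.choice([0, 1, 3, 4], n),
        "n_snps": rng.integers(2, 40, n),
        "confidence": rng.uniform(0, 30, n).round(2),
    })
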