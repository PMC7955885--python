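import numpy as np
import pytest

from napustools import simulate as sim


@pytest.fixture(scope="session")
def pop_run(tmp_path_factory):
    """Small two-group panel with one strongly planted sweep window."""
    params = sim.PopSimParams(
        n_groups=2,
        samples_per_group=20,
        n_windows=30,
        window_len=10_000,
        snp_density=0.003,
        sweep_windows=((10, 0),),
        sweep_diversity_factor=0.95,
        sweep_divergence_shift=0.8,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("pop")
    return params, sim.simulate_populations(params, outdir)


@pytest.fixture(scope="session")
def satellite_run(tmp_path_factory):
    params = sim.SatelliteSimParams(
        monomer_len=176, n_copies=2000, substitution_rate_per_site=0.02,
        indel_rate=0.0, flank_len=20_000, seed=3,
    )
    outdir = tmp_path_factory.mktemp("sat")
    return params, sim.simulate_tandem_array_genome(params, outdir)


@pytest.fixture(scope="session")
def annot_run(tmp_path_factory):
    params = sim.AnnotSimParams(
        n_genes=40, n_nlr=12, n_pairs=3, pair_intergenic_dist=2000,
        chrom_len=1_000_000, seed=7,
    )
    outdir = tmp_path_factory.mktemp("annot")
    return params, sim.simulate_gene_annotation(params, outdir)


@pytest.fixture(scope="session")
def ltr_run(tmp_path_factory):
    params = sim.LTRSimParams(
        n_elements=200, ltr_len=1000, internal_len=1000,
        ages=(1e4, 5e5, 2e6), seed=5,
    )
    outdir = tmp_path_factory.mktemp("ltr")
    return params, sim.simulate_ltr_elements(params, outdir)


def brute_force_pi(haplotypes: np.ndarray) -> float:
    """All-pairs mean Hamming distance over haplotypes (sites x haps, -1 missing).

    Independent oracle for the per-window pi sum: for each site, counts
    differing pairs among non-missing calls over the number of such pairs,
    then sums over sites.
    """
    total = 0.0
    n_sites, n_h = haplotypes.shape
    for j in range(n_sites):
        calls = haplotypes[j]
        valid = [c for c in calls if c >= 0]
        n = len(valid)
        if n < 2:
            continue
        diff = sum(
            1 for a in range(n) for b in range(a + 1, n) if valid[a] != valid[b]
        )
        total += diff / (n * (n - 1) / 2)
    return total
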