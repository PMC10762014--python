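import pytest
from hypothesis import HealthCheck, settings

import archdelta as ad

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return ad.GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled generator config for fast unit tests."""
    return ad.SimulationConfig(
        chrom_lengths={"chr1": 10_000_000, "chr2": 5_000_000},
        n_ctcf_peaks=600, n_gained_peaks=30, n_k9_peaks=400,
        n_genes=300, n_repeats=500, n_up_genes=15, n_down_genes=8,
        n_up_repeats=20, n_down_repeats=10,
        n_switch_blocks=6, n_tad_boundaries=6,
        n_loops=80, n_loop_gain=8)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return ad.simulate_genome(small_config, seed=7)


@pytest.fixture(scope="session")
def small_tracks(small_truth):
    return {cond: ad.simulate_tracks(small_truth, cond, seed=7)
            for cond in ("WT", "KO")}


@pytest.fixture(scope="session")
def small_maps(small_truth):
    out = {}
    for cond in ("WT", "KO"):
        cmap, loops = ad.simulate_contacts(small_truth, cond, seed=7)
        out[cond] = cmap
    return out


# --- study-condition dataset shared by the acceptance tests ----------------

@pytest.fixture(scope="session")
def study_truth():
    return ad.simulate_genome(ad.SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def study_maps(study_truth):
    return {cond: ad.simulate_contacts(study_truth, cond, seed=1)[0]
            for cond in ("WT", "KO")}


@pytest.fixture(scope="session")
def study_tracks(study_truth):
    return {cond: ad.simulate_tracks(study_truth, cond, seed=1)
            for cond in ("WT", "KO")}


def planted_switch_bins(truth):
    out = {}
    for row in truth.switch_blocks.itertuples(index=False):
        for b in range(row.bin_start, row.bin_end):
            out[(row.chrom, b)] = row.direction
    return out
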