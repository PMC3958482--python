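"""Shared fixtures: a small simulated parental pair and hybrid genome."""

import pytest

import hybriseg as hs


@pytest.fixture(scope="session")
def small_pair() -> hs.ParentalGenomePair:
    """Four 12-kb chromosomes at the default coding/non-coding divergence."""
    return hs.simulate_parental_pair(seed=42, n_chromosomes=4, chromosome_length=12_000)


@pytest.fixture(scope="session")
def small_truth(small_pair) -> hs.HybridGenomeTruth:
    return hs.plant_hybrid_genome(
        small_pair, seed=43, n_translocations=2, telomere_zone=3000
    )


@pytest.fixture(scope="session")
def small_tracks(small_truth, small_pair):
    return hs.simulate_coverage(small_truth, small_pair, unit_depth=50.0, seed=44)


@pytest.fixture(scope="session")
def noise_free_tracks(small_truth, small_pair):
    return hs.simulate_coverage(small_truth, small_pair, unit_depth=50.0, noise_free=True)
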