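"""Shared fixtures: a small planted community and its simulated reads.

Desk-scale study conditions: 12 bees over four locations, 5 clusters of 4
strains one SNP from their founder, coverage 2,000 reads per (bee, marker).
Error-free reads make the truth set an exact oracle for the caller.
"""

import pytest

from mastkit import (
    CallerParams,
    ReadSimParams,
    call_strains,
    make_truth,
    pools_from_reads,
    simulate_reads,
)

LOCATIONS = {"Texas": 6, "Tennessee": 3, "Utah": 2, "Florida": 1}


@pytest.fixture(scope="session")
def small_truth():
    return make_truth(
        n_bees=12,
        locations=LOCATIONS,
        n_clusters=5,
        strains_per_cluster=4,
        within_cluster_snps=1,
        two_cluster_fraction=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_sim(small_truth):
    """Error-free reads at coverage 2,000 for the planted community."""
    return simulate_reads(
        small_truth,
        ReadSimParams(coverage_mean=2000.0, error_rate=0.0, seed=11),
    )


@pytest.fixture(scope="session")
def clean_table(small_truth, clean_sim):
    pools, _ = pools_from_reads(clean_sim.quality_reads(), small_truth.references)
    return call_strains(pools, small_truth.references, CallerParams())
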