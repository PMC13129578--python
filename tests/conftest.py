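import pytest
from hypothesis import HealthCheck, settings

from svtable import merge_cohort
from svtable import simulate as sim

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    """Two-contig genome small enough for exact, hand-checkable coordinates."""
    from svtable.model import ReferenceGenome

    return ReferenceGenome([("chr1", "AAAACCCCGGGGTTTT"), ("chr2", "ACGTACGT")])


@pytest.fixture(scope="session")
def sim_bundle():
    """Seeded synthetic cohort at the default study conditions (zero jitter)."""
    genome = sim.simulate_reference(2, 1_500_000, seed=11)
    truth = sim.plant_cohort(genome, seed=12)
    callsets = sim.truth_calls(truth, seed=13)
    cohort = merge_cohort(callsets)
    return genome, truth, callsets, cohort


@pytest.fixture(scope="session")
def sim_track(sim_bundle):
    genome = sim_bundle[0]
    return sim.simulate_gene_track(genome, n_genes=40, seed=14)
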