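import pytest

import mitocohort as mc
from mitocohort import simulate as sim


@pytest.fixture(scope="session")
def ref():
    return mc.load_reference()


@pytest.fixture(scope="session")
def space(ref):
    return mc.enumerate_substitution_space(ref)


@pytest.fixture(scope="session")
def fixtures(ref):
    return mc.make_fixture_suite(ref)


@pytest.fixture(scope="session")
def small_cohort(ref):
    """25 genomes carrying the standard panel plus one indel each way."""
    rcrs = ref.sequence
    cfg = sim.SimulationConfig(
        n_participants=25,
        variants=sim.default_variant_panel(),
        indels=(
            sim.PlantedIndel(8281, "deletion", rcrs[8280:8289], 0.25),
            sim.PlantedIndel(5740, "insertion", "TA", 0.2),
        ),
        ambiguity_rate=0.08,
        seed=42,
    )
    return sim.simulate_cohort(cfg, ref)


@pytest.fixture(scope="session")
def small_calls(ref, small_cohort):
    return mc.call_cohort(small_cohort.sequences, ref)
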