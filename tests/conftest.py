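import pytest

from fragexcess import FivePrimeProfile, FragmentationScenario


@pytest.fixture
def small_scenario() -> FragmentationScenario:
    """Desk-scale two-strain scenario with a planted mutant-only excess."""
    return FragmentationScenario(
        genome_length=10_000,
        n_shared_sites=500,
        lambda_shared=1.0,
        n_exclusive_sites=100,
        lambda_exclusive=1.0,
        n_replicates_per_strain=2,
        seed=11,
    )


@pytest.fixture
def null_scenario() -> FragmentationScenario:
    """Same regime with zero planted exclusive sites."""
    return FragmentationScenario(
        genome_length=10_000,
        n_shared_sites=500,
        lambda_shared=1.0,
        n_exclusive_sites=0,
        n_replicates_per_strain=2,
        seed=11,
    )


def profile(flat: dict) -> FivePrimeProfile:
    """Shorthand: build a profile from {(ref, strand, pos): count}."""
    return FivePrimeProfile(flat)
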