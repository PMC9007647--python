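import pytest

from epimmune.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (n=300, 40 planted pairs)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast small cohort for plumbing tests."""
    return generate_cohort(
        CohortConfig(
            n_samples=120,
            n_background_genes=300,
            n_planted_pairs=12,
            n_immune_genes_per_set=8,
            n_marker_probes=20,
            seed=7,
        )
    )
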