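import pytest

from splicevol.syn_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_basic():
    """Two-species cohort with all event types, PTC planting, mild signal."""
    return generate_cohort(
        CohortConfig(n_genes=40, seed=3, ptc_fraction=0.3, determinant_signal=1.0)
    )


@pytest.fixture(scope="session")
def cohort_signal():
    """Single-species cohort with a strong planted distance->AS signal."""
    return generate_cohort(
        CohortConfig(
            n_genes=150,
            seed=4,
            as_fraction=0.15,
            determinant_signal=4.0,
            as_type_mix={"IR": 0.0, "AltD": 0.2, "AltA": 0.8, "ES": 0.0},
            n_species=1,
        )
    )


@pytest.fixture(scope="session")
def cohort_two_species():
    """Two-species AltA-only cohort for conservation analyses."""
    return generate_cohort(
        CohortConfig(
            n_genes=120,
            seed=6,
            as_fraction=0.3,
            as_type_mix={"IR": 0.0, "AltD": 0.0, "AltA": 1.0, "ES": 0.0},
            divergence=0.01,
        )
    )
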