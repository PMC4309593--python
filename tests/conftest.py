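import numpy as np
import pytest

from founderhap.synthio import (
    PanelSpec,
    add_secondary_signature,
    enriched_reference_fixture,
    simulate_panel,
)


@pytest.fixture(scope="session")
def ref_panel():
    """Engineered enriched reference panel: 2,370 haplotypes, 24 mutation
    copies, 2 founder copies without the mutation, 3-SNP signature."""
    return enriched_reference_fixture()


@pytest.fixture(scope="session")
def ref_panel_one_fp():
    """Same panel but with a single mutation-free founder copy."""
    return enriched_reference_fixture(n_founder_nonmut=1)


@pytest.fixture(scope="session")
def ref_panel_two_signatures(ref_panel):
    panel, truth = ref_panel
    return add_secondary_signature(panel, truth)


@pytest.fixture()
def small_panel():
    spec = PanelSpec(
        n_individuals=200,
        n_snps=12,
        background_allele_freqs=0.2,
        founder_hap_freq=0.05,
        sensitivity_t=0.9,
        seed=5,
    )
    return simulate_panel(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
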