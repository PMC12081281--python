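import numpy as np
import pytest

import ptvherit as ph


@pytest.fixture(scope="session")
def two_group():
    """Single-sex case/control layout at a modest cohort size."""
    return ph.two_group_layout(1000, 9000)


@pytest.fixture(scope="session")
def fh_layout():
    """Model-3 layout: case/control split by family history."""
    return ph.with_family_history(ph.two_group_layout(2000, 18000), 0.12)


@pytest.fixture(scope="session")
def two_sex():
    return ph.two_sex_layout(500, 4500, 700, 6300)


@pytest.fixture(scope="session")
def sim_counts(two_group):
    """A reproducible simulated exome: 800 genes, alpha=0.05, eta=2."""
    prior = ph.SpikeSlabPrior(0.05, 2.0)
    effects = ph.sample_gene_effects(prior, 800, seed=42)
    counts = ph.simulate_summary_counts(effects, two_group, seed=43)
    return effects, counts
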