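import numpy as np
import pytest

from glidetree.simulate import DemographicScenario, simulate_coalescent


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_tree(rng, n_tips, pop_size=1.0, heterochronous=False):
    """Random coalescent time tree used as a generic fixture."""
    scenario = DemographicScenario("constant", n0=pop_size)
    heights = None
    if heterochronous:
        heights = np.concatenate([[0.0], rng.uniform(0, pop_size, n_tips - 1)])
    return simulate_coalescent(scenario, n_tips=n_tips,
                               sampling_heights=heights, rng=rng)


def random_alignment_columns(rng, n_taxa, n_sites):
    """Random iid nucleotide columns (no tree signal)."""
    alphabet = np.array(list("ACGT"))
    mat = alphabet[rng.integers(0, 4, size=(n_taxa, n_sites))]
    return ["".join(row) for row in mat]
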