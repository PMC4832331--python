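import numpy as np
import pytest

from ldcsig.synthetic import (
    SimulationParams,
    ToyDecamerSpec,
    gen_neighborhood_table,
    gen_toy_decamer,
    simulate_family,
)


@pytest.fixture(scope="session")
def small_family():
    """A 5+5-taxon family, 120 residues, planted signatures, no indels."""
    params = SimulationParams(
        n_taxa_per_group=5,
        sequence_length=120,
        signature_regions=((80, 85), (100, 110)),
        seed=42,
    )
    tree, groups, aln = simulate_family(params)
    return params, tree, groups, aln


@pytest.fixture(scope="session")
def full_length_family():
    """An 11+11-taxon family at the default (715-residue) conditions."""
    params = SimulationParams(seed=7)
    tree, groups, aln = simulate_family(params)
    return params, tree, groups, aln


@pytest.fixture(scope="session")
def concordant_inputs(small_family):
    params, tree, groups, aln = small_family
    records, injected = gen_neighborhood_table(list(aln.ids), groups, seed=5)
    assert not injected
    return aln, groups, records


@pytest.fixture()
def toy_decamer_pair():
    spec = ToyDecamerSpec(points_per_domain=6, ctd_stretch=4.0, seed=3)
    ref, moved = gen_toy_decamer(spec)
    return spec, ref, moved


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160415)
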