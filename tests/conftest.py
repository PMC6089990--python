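import pytest

from strainvar.consequences import annotate_variants
from strainvar.simulate import (
    MutationSpectrum,
    SimulationConfig,
    simulate_genome,
    simulate_mutagenesis,
)
from strainvar.variants import differential_variants
from strainvar.worked_examples import build_worked_bundle


@pytest.fixture(scope="session")
def worked_bundle():
    """Toy genes engineered for the canonical notation forms."""
    return build_worked_bundle(seed=7)


@pytest.fixture(scope="session")
def sim_bundle():
    """A medium synthetic strain pair with full category coverage."""
    cfg = SimulationConfig(
        seed=101,
        n_genes=24,
        n_chromosomes=2,
        n_background_variants=40,
        n_private_variants=80,
    )
    genome, genes = simulate_genome(cfg)
    parent, mutant, truth = simulate_mutagenesis(
        genome, genes, MutationSpectrum.ntg(), cfg
    )
    return {
        "cfg": cfg,
        "genome": genome,
        "genes": genes,
        "parent": parent,
        "mutant": mutant,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def sim_annotation(sim_bundle):
    diff = differential_variants(sim_bundle["mutant"], sim_bundle["parent"])
    result = annotate_variants(
        diff.variants, sim_bundle["genes"], sim_bundle["genome"]
    )
    return diff, result
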