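import numpy as np
import pytest

from edckit import synthetic
from edckit.features import build_beta_pssm


@pytest.fixture(scope="session")
def beta_pssm():
    return build_beta_pssm()


@pytest.fixture(scope="session")
def beta_motif():
    return synthetic.beta_consensus()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cluster():
    """A 5-gene cluster with mixed classes/strands, shared across tests."""
    specs = [
        synthetic.GeneSpec("gA", "SEDC", 110, {"G": 0.2, "S": 0.2}),
        synthetic.GeneSpec("gB", "SEDC", 95, {"P": 0.2}, "KCVPE", 4, strand="-"),
        synthetic.GeneSpec("gC", "CBP1B", 120, nterm_arm_length=9),
        synthetic.GeneSpec("gD", "SFTP", 160),
        synthetic.GeneSpec("gE", "pseudogene", 100, lesion_types=("stop",)),
    ]
    return synthetic.generate_edc_cluster(specs, spacing=1500, rng_seed=7)


@pytest.fixture(scope="session")
def demo_pair():
    """Source cluster + evolved second species (the 22-gene demo layout)."""
    from edckit.pipeline import demo_evolution_params, demo_gene_specs

    scaf, loci = synthetic.generate_edc_cluster(
        demo_gene_specs(), rng_seed=11, scaffold_id="spA_edc"
    )
    evolved = synthetic.evolve_species(
        (scaf, loci), demo_evolution_params(12), scaffold_id="spB_edc"
    )
    return scaf, loci, evolved
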