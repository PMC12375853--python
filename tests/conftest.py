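import numpy as np
import pytest

from magicpop.sim import (
    FieldDesign,
    build_funnel,
    default_marker_map,
    make_trait_architectures,
    simulate_founders,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_pop():
    """A modest MAGIC population shared across read-only tests."""
    rng = np.random.default_rng(11)
    mmap = default_marker_map(800, rng)
    founders = simulate_founders(mmap, rng)
    design = build_funnel(founders.founder_ids)
    return simulate_population(founders, design, 300, rng)


@pytest.fixture(scope="session")
def small_trial(small_pop):
    """Architectures + augmented-trial phenotypes for the shared population."""
    rng = np.random.default_rng(12)
    arch_dtf, arch_pht = make_trait_architectures(small_pop, rng)
    block_eff = rng.normal(0, 1.0, 8)
    block_eff -= block_eff.mean()
    field = FieldDesign(n_blocks=8, block_effects=block_eff)
    from magicpop.sim import simulate_phenotypes

    records = simulate_phenotypes(small_pop, [arch_dtf, arch_pht], field, rng)
    return {"records": records, "arch_dtf": arch_dtf, "arch_pht": arch_pht, "field": field}
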