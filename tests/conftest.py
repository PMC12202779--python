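import numpy as np
import pytest

from nichepart import (
    OtuTable,
    SampleMetadata,
    build_taxonomy,
    make_diet_profiles,
    simulate_dataset,
)
from nichepart.simulate import SimConfig, TaxonomySpec


@pytest.fixture
def small_table() -> OtuTable:
    """4 OTUs x 3 samples with hand-checkable counts."""
    counts = np.array([
        [5, 0, 2],
        [1, 3, 0],
        [0, 7, 1],
        [2, 0, 4],
    ])
    return OtuTable(("OTU_1", "OTU_2", "OTU_3", "OTU_4"),
                    ("s1", "s2", "s3"), counts)


@pytest.fixture(scope="session")
def sim_bundle():
    """One desk-scale simulated dataset shared across tests (seed 7)."""
    spec = TaxonomySpec(seed=7)
    cfg = SimConfig(seed=7)
    tax, tree = build_taxonomy(spec)
    truth = make_diet_profiles(tax, cfg, spec)
    table, meta = simulate_dataset(truth, cfg, tax=tax, tree=tree)
    return {"spec": spec, "cfg": cfg, "tax": tax, "tree": tree,
            "truth": truth, "table": table, "meta": meta}


@pytest.fixture
def three_group_meta() -> SampleMetadata:
    return SampleMetadata({f"{g}_{i}": g for g in ("a", "b", "c")
                           for i in range(4)})


def random_probability_vector(rng: np.random.Generator, n: int) -> np.ndarray:
    p = rng.dirichlet(np.full(n, 0.7))
    return p / p.sum()
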