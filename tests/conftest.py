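import json

import numpy as np
import pytest

from ghcnse.gem_io import MetabolicNetwork, Metabolite, Reaction
from ghcnse.synthetic import SyntheticSpec, generate_synthetic_gem


@pytest.fixture
def tiny_bigg_json(tmp_path):
    """Minimal BiGG JSON: metabolites a_c, b_c, c_c and one reaction."""

    def write(reactions=None, metabolites=("a_c", "b_c", "c_c"), name="toy"):
        if reactions is None:
            reactions = [
                {
                    "id": "r1",
                    "metabolites": {"a_c": -1.0, "b_c": -1.0, "c_c": 1.0},
                    "lower_bound": 0.0,
                    "upper_bound": 1000.0,
                }
            ]
        doc = {
            "id": name,
            "metabolites": [{"id": m, "compartment": m.rsplit("_", 1)[-1]} for m in metabolites],
            "reactions": reactions,
            "genes": [],
        }
        path = tmp_path / f"{name}.json"
        path.write_text(json.dumps(doc))
        return path

    return write


@pytest.fixture
def five_node_universe():
    """Universe m1..m5 with reactions R1={m1,m2,m3}, R2={m3,m4}; m5 isolated."""
    mets = [Metabolite(id=f"m{i}") for i in range(1, 6)]
    r1 = Reaction(id="R1", members=frozenset({"m1", "m2", "m3"}))
    r2 = Reaction(id="R2", members=frozenset({"m3", "m4"}))
    return MetabolicNetwork(metabolites=mets, reactions=[r1, r2], name="five")


@pytest.fixture(scope="session")
def small_gem():
    """A small community-structured GEM shared by slower tests."""
    return generate_synthetic_gem(
        SyntheticSpec(n_metabolites=24, n_reactions=30, n_modules=3, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
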