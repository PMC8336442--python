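import numpy as np
import pytest

from slkgnn import SyntheticSpec, generate_kg, plant_sl_labels


def write_kg_files(tmp_path, triplets, entities):
    """Write triplet/entity TSVs; returns (triplet_path, entity_path)."""
    tp = tmp_path / "triplets.tsv"
    ep = tmp_path / "entities.tsv"
    tp.write_text("head_id\trelation\ttail_id\n" + "".join(f"{h}\t{r}\t{t}\n" for h, r, t in triplets))
    ep.write_text("entity_id\tentity_type\n" + "".join(f"{e}\t{ty}\n" for e, ty in entities))
    return tp, ep


@pytest.fixture(scope="session")
def small_corpus():
    """A small planted-factor corpus shared by model/training tests."""
    spec = SyntheticSpec(n_genes=60, n_factors=8, n_distractor_entities=30,
                         n_pairs=400, seed=11)
    kg, assignment = generate_kg(spec)
    data = plant_sl_labels(assignment, spec, seed=11)
    return kg, assignment, data, spec


@pytest.fixture(scope="session")
def tiny_kg():
    """Ten genes wired to four factors plus a few distractors (for oracles)."""
    spec = SyntheticSpec(n_genes=10, n_factors=4, n_distractor_entities=6,
                         n_pairs=20, seed=3)
    kg, assignment = generate_kg(spec)
    return kg, assignment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
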