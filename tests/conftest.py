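import numpy as np
import pytest

from clumpnet import CountMatrix, Embedding, TFCatalog


@pytest.fixture(scope="session")
def planted():
    """The standard planted-regulator fixture (seed 0), shared read-only."""
    from clumpnet.simulate import planted3

    counts, emb, tfs, truth, cfg = planted3(seed=0)
    return {"counts": counts, "emb": emb, "tfs": tfs, "truth": truth, "cfg": cfg}


@pytest.fixture()
def tiny_counts():
    values = np.array([[0, 3, 1], [2, 1, 0], [4, 0, 2], [1, 1, 1]])
    return CountMatrix(values, [f"c{i}" for i in range(4)], ["g0", "g1", "g2"])


@pytest.fixture()
def tiny_embedding(tiny_counts):
    coords = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]])
    return Embedding(coords, tiny_counts.cell_ids)
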