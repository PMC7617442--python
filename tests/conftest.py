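import numpy as np
import pytest

import sesindex as si


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_area_adjacency():
    """Two mutually adjacent areas (smallest connected graph, d = (1, 1))."""
    return si.AdjacencyStructure(neighbours=[[1], [0]])


@pytest.fixture
def path3_adjacency():
    """Path graph 1–2–3."""
    return si.AdjacencyStructure(neighbours=[[1], [0, 2], [1]])


@pytest.fixture
def cycle4_adjacency():
    """4-cycle."""
    return si.AdjacencyStructure(neighbours=[[1, 3], [0, 2], [1, 3], [0, 2]])


def make_toy_dataset(spec: si.ModelSpec, n_areas: int = 2,
                     households_per_area: int = 2, seed: int = 5):
    """Tiny preprocessed dataset drawn from the generative model."""
    rng = np.random.default_rng(seed)
    a = np.repeat(np.arange(n_areas), households_per_area)
    p = spec.p
    dich = np.asarray(spec.is_dichotomous)
    y = np.where(dich, rng.integers(0, 2, (a.size, p)).astype(float),
                 rng.standard_normal((a.size, p)))
    meta = [si.VariableMeta(f"v{k}", "dichotomous" if dich[k] else "continuous")
            for k in range(p)]
    return si.preprocess(
        si.MixedDataset(area_ids=a, y=y, meta=meta))


@pytest.fixture
def toy_hs():
    """2-area HS toy problem with mixed variables plus a frozen state."""
    spec = si.ModelSpec(variant="HS", is_dichotomous=(True, True, False))
    adj = si.AdjacencyStructure(neighbours=[[1], [0]])
    data = make_toy_dataset(spec, n_areas=2, households_per_area=2)
    state = si.initialize(data, spec, seed=7)
    state.iota = 0.4
    return data, adj, spec, state
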