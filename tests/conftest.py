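import numpy as np
import pytest

from graphsurv.graphs import ImagingGraph, build_adjacency
from graphsurv.model import ModelConfig, SurvivalModel


def make_grid_graph(rows: int, cols: int, dim: int, seed: int = 0,
                    connectivity: int = 8) -> ImagingGraph:
    rng = np.random.default_rng(seed)
    coords = np.stack(np.meshgrid(np.arange(rows), np.arange(cols),
                                  indexing="ij"), axis=-1).reshape(-1, 2)
    adjacency = build_adjacency(coords, connectivity)
    feats = rng.standard_normal((rows * cols, dim)).astype(np.float32)
    return ImagingGraph(feats, adjacency, coords, slide_id=f"grid{rows}x{cols}")


@pytest.fixture
def tiny_graph():
    """2 x 3 grid, 6 nodes, 8-connectivity."""
    return make_grid_graph(2, 3, dim=8, seed=3)


@pytest.fixture
def small_ism():
    cfg = ModelConfig(in_features=8, hidden_dim=16, n_mixer_layers=2,
                      n_signatures=0, attn_hidden_dim=8, dropout=0.0, seed=11)
    return SurvivalModel(cfg)


@pytest.fixture
def small_fsm():
    cfg = ModelConfig(in_features=8, hidden_dim=16, n_mixer_layers=2,
                      n_signatures=3, signature_lengths=(4, 5, 6),
                      attn_hidden_dim=8, dropout=0.0, seed=12)
    return SurvivalModel(cfg)


@pytest.fixture
def fsm_signatures():
    rng = np.random.default_rng(5)
    return [rng.standard_normal(p) for p in (4, 5, 6)]
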