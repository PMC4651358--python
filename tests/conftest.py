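"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import swarmstate as ss
from swarmstate.tracks_io import Species
from swarmstate.vectors import InteractionDataset, InteractionRow


@pytest.fixture(scope="session")
def small_env():
    """10x10-cell raster, 6 classes, 48 h of thermal stack."""
    return ss.simulate_environment((500.0, 500.0), 50.0, 6, seed=11, hours=48)


@pytest.fixture(scope="session")
def small_swarm(small_env):
    """Short two-species swarm run (8 sheep + 4 deer, 30 h, noiseless)."""
    params = ss.SwarmParams(n_sheep=8, n_deer=4)
    return ss.simulate_swarm(params, small_env, hours=30, seed=12)


@pytest.fixture(scope="session")
def small_dataset(small_swarm):
    return ss.assemble_dataset(small_swarm, Species.SHEEP, m=1, n=1)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    dic = ss.candidate_dictionary(small_dataset, 30, seed=13)
    return ss.select_model(small_dataset, dic, max_size=8)


def make_regression_dataset(seed: int, n_rows: int = 300, n_dict: int = 8,
                            noise: float = 0.5):
    """Synthetic one-step dataset whose displacements come from a known
    odd RBF surface built over a known candidate dictionary.

    Returns (dataset, dictionary, true_indices). Used by selection and
    recovery tests; the truth is exactly representable by the equivariant
    model class.
    """
    rng = np.random.default_rng(seed)
    kinds = ("gaussian", "wavelet", "tophat")
    dic = [ss.BasisFunction(kind=kinds[i % 3],
                            centre=tuple(rng.uniform(-50, 50, 2)),
                            scale=float(rng.uniform(15, 40)))
           for i in range(n_dict)]
    true_idx = sorted(rng.choice(n_dict, size=rng.integers(1, 3), replace=False).tolist())
    wts = rng.uniform(3.0, 6.0, len(true_idx)) * rng.choice([-1, 1], len(true_idx))
    lin = rng.uniform(-0.05, 0.05, 2)

    def odd(b, X):
        return 0.5 * (ss.evaluate_basis(b, X) - ss.evaluate_basis(b, -X))

    def surface(X):
        out = X @ lin
        for j, wt in zip(true_idx, wts):
            out = out + wt * odd(dic[j], X)
        return out

    V = rng.uniform(-60, 60, (n_rows, 2))
    R = np.array([[0.0, -1.0], [1.0, 0.0]])
    dx, dy = surface(V), surface(V @ R)        # f(v), f(R^-1 v)
    noise_xy = rng.normal(0, noise, (n_rows, 2))
    rows = [
        InteractionRow(target_id=f"a{i}", time=pd.Timestamp("2008-01-01"),
                       v=V[i], w=np.zeros(0),
                       y=np.array([dx[i], dy[i]]) + noise_xy[i],
                       position=np.zeros(2), m=1, n=0)
        for i in range(n_rows)
    ]
    ds = InteractionDataset(rows=rows, focal_species=Species.SHEEP, m=1, n=0)
    return ds, dic, true_idx
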