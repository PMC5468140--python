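import numpy as np
import pandas as pd
import pytest

import pellethglm as ph


def lattice_units(side: int, spacing: float = 250.0, year: int = 2010) -> pd.DataFrame:
    """Square lattice of plots; at 250 m spacing each interior plot has four
    neighbors under the 350-m rule (diagonals are ~354 m away)."""
    xs = np.repeat(np.arange(side) * spacing, side)
    ys = np.tile(np.arange(side) * spacing, side)
    return pd.DataFrame({
        "plot_id": [f"p{i}" for i in range(side * side)],
        "x": xs, "y": ys, "year": year,
    })


@pytest.fixture(scope="session")
def lattice32():
    units = lattice_units(32)
    return units, ph.build_adjacency(units)


@pytest.fixture(scope="session")
def lattice45():
    units = lattice_units(45)
    return units, ph.build_adjacency(units)


def edgeless_units(n: int, year: int = 2010) -> pd.DataFrame:
    """Plots spaced 1 km apart in a line: no pair within 350 m."""
    return pd.DataFrame({
        "plot_id": [f"e{i}" for i in range(n)],
        "x": np.arange(n) * 1000.0, "y": 0.0, "year": year,
    })


def newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 60) -> np.ndarray:
    """Independent plain-logistic Newton-Raphson oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = mu * (1.0 - mu)
        step = np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


@pytest.fixture(scope="session")
def tiny_design():
    """Scaled-down two-scale survey design for pipeline-level tests."""
    return ph.make_study_design(local_half_extent=500.0, n_squares=5,
                                region_radius=6000.0, seed=0)
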