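"""Plain-text serialization: plots/records CSV, adjacency as Matrix Market,
fits as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .design import AdjacencyMatrix
from .hglm import HGLMFit

__all__ = [
    "write_plots", "read_plots", "write_records", "read_records",
    "write_adjacency", "read_adjacency", "write_fit",
]


def write_plots(plots, path) -> None:
    if not isinstance(plots, pd.DataFrame):
        plots = pd.DataFrame([{"plot_id": p.plot_id, "x": p.x, "y": p.y,
                               "scale": p.scale, "site": p.site} for p in plots])
    plots.to_csv(path, index=False, columns=["plot_id", "x", "y", "scale", "site"])


def read_plots(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = {"plot_id", "x", "y", "scale", "site"} - set(df.columns)
    if missing:
        raise ValueError(f"plots file lacks columns {sorted(missing)}")
    return df


def write_records(records: pd.DataFrame, path) -> None:
    cols = [c for c in ("plot_id", "year", "pellets", "groups", "presence")
            if c in records.columns]
    records.to_csv(path, index=False, columns=cols)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = {"plot_id", "year", "groups"} - set(df.columns)
    if missing:
        raise ValueError(f"records file lacks columns {sorted(missing)}")
    return df


def write_adjacency(adj: AdjacencyMatrix, path) -> None:
    """Write D in Matrix Market coordinate/pattern/symmetric form."""
    scipy.io.mmwrite(str(path), sp.coo_matrix(adj.matrix), field="pattern",
                     symmetry="symmetric")


def read_adjacency(path, units: pd.DataFrame | None = None,
                   threshold: float = 350.0) -> AdjacencyMatrix:
    mat = scipy.io.mmread(str(path)).tocsr()
    mat.data = (mat.data != 0).astype(float)
    if units is None:
        units = pd.DataFrame({"plot_id": [str(i) for i in range(mat.shape[0])],
                              "x": 0.0, "y": 0.0})
    return AdjacencyMatrix(matrix=mat, units=units, threshold=threshold)


def write_fit(fit: HGLMFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), sort_keys=True, indent=2))
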