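"""Survey layouts, spatial neighborhood structure, and covariate screening.

The field design this module reproduces has two scales:

* a *local* scale: plots on parallel transects (300 m between transects,
  100 m between plots along a transect) covering the wind-farm mountains;
* a *regional* scale: 1 x 1 km squares scattered over the calving range,
  with 20 plots every 200 m along each square's perimeter.

Plot-year units are linked by a binary neighborhood matrix D (two units are
neighbors when their plot centers lie within 350 m of each other, by default
only within the same survey year), which parameterizes the conditional
autoregressive (CAR) random-effect covariance tau * (I - rho*D)^-1 used by
the spatial model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "Plot",
    "AdjacencyMatrix",
    "PlacementError",
    "generate_local_grid",
    "generate_regional_squares",
    "build_adjacency",
    "sqrt_distance_covariate",
    "compute_vif",
    "apply_class_merge",
    "VEGETATION_CLASSES",
]

#: Closed domain of merged vegetation classes.
VEGETATION_CLASSES = ("forest", "clear_cut", "young_forest", "mire", "other")


class PlacementError(RuntimeError):
    """Rejection sampling could not place all regional squares."""


@dataclass(frozen=True)
class Plot:
    """A single circular survey plot identified by its center coordinates."""

    plot_id: str
    x: float
    y: float
    scale: str  # "local" | "regional"
    site: str  # "Storliden" | "Jokkmokksliden" | "region"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"plot {self.plot_id}: coordinates must be finite")
        if self.scale not in ("local", "regional"):
            raise ValueError(f"plot {self.plot_id}: unknown scale {self.scale!r}")


@dataclass
class AdjacencyMatrix:
    """Symmetric binary neighbor structure over plot-year units.

    ``matrix`` is a sparse CSR matrix with zero diagonal; ``units`` is a
    DataFrame aligned with the matrix rows, carrying at least ``plot_id``,
    ``x``, ``y`` and (when year-blocked) ``year``.
    """

    matrix: sp.csr_matrix
    units: pd.DataFrame
    threshold: float
    block_by_year: bool = True
    _eigs: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.matrix.nnz // 2

    def eigenvalues(self) -> np.ndarray:
        """All eigenvalues of D, computed blockwise when year-blocked.

        D is block-diagonal across years under the default blocking rule, so
        the spectrum is the union of the (dense) block spectra.  Cached.
        """
        if "all" not in self._eigs:
            vals = []
            for idx in self._year_blocks():
                block = self.matrix[np.ix_(idx, idx)].toarray()
                vals.append(np.linalg.eigvalsh(block))
            self._eigs["all"] = np.concatenate(vals) if vals else np.zeros(0)
        return self._eigs["all"]

    def _year_blocks(self) -> list[np.ndarray]:
        if self.block_by_year and "year" in self.units.columns:
            return [
                np.flatnonzero((self.units["year"] == y).to_numpy())
                for y in sorted(self.units["year"].unique())
            ]
        return [np.arange(self.n)]

    def subset(self, rows: np.ndarray) -> "AdjacencyMatrix":
        """Restrict to a subset of unit rows (e.g. after dropping NA rows)."""
        rows = np.asarray(rows)
        return AdjacencyMatrix(
            matrix=self.matrix[np.ix_(rows, rows)].tocsr(),
            units=self.units.iloc[rows].reset_index(drop=True),
            threshold=self.threshold,
            block_by_year=self.block_by_year,
        )


def generate_local_grid(
    center_x: float,
    center_y: float,
    half_extent: float,
    transect_spacing: float = 300.0,
    plot_spacing: float = 100.0,
    *,
    site: str = "Storliden",
    prefix: str | None = None,
) -> list[Plot]:
    """Lay parallel transects over the square ``center +- half_extent``.

    Transects run along the y axis and are laid from the west edge of the
    extent eastwards every ``transect_spacing`` meters; plots are placed
    from the south edge every ``plot_spacing`` meters.  The plot count is
    therefore ``(floor(2h/ts)+1) * (floor(2h/ps)+1)`` for half-extent h.
    """
    if half_extent < 0:
        raise ValueError("half_extent must be >= 0")
    if transect_spacing <= 0 or plot_spacing <= 0:
        raise ValueError("spacings must be > 0")
    prefix = prefix if prefix is not None else site[:2].upper()
    side = 2.0 * half_extent
    xs = center_x - half_extent + transect_spacing * np.arange(int(side / transect_spacing) + 1)
    ys = center_y - half_extent + plot_spacing * np.arange(int(side / plot_spacing) + 1)
    plots = []
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            plots.append(Plot(f"{prefix}-{i:02d}-{j:02d}", float(x), float(y), "local", site))
    return plots


def _square_perimeter(cx: float, cy: float, side: float, spacing: float) -> np.ndarray:
    """Plot coordinates every ``spacing`` m along a square perimeter, corners
    counted once, starting at the SW corner and walking counterclockwise."""
    n_per_side = int(round(side / spacing))
    h = side / 2.0
    pts = []
    for k in range(n_per_side):  # south edge, W->E
        pts.append((cx - h + k * spacing, cy - h))
    for k in range(n_per_side):  # east edge, S->N
        pts.append((cx + h, cy - h + k * spacing))
    for k in range(n_per_side):  # north edge, E->W
        pts.append((cx + h - k * spacing, cy + h))
    for k in range(n_per_side):  # west edge, N->S
        pts.append((cx - h, cy + h - k * spacing))
    return np.asarray(pts)


def generate_regional_squares(
    n_squares: int = 29,
    side: float = 1000.0,
    perimeter_spacing: float = 200.0,
    min_separation: float = 1400.0,
    region_radius: float = 15000.0,
    seed: int | None = 0,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    max_attempts: int = 10_000,
) -> list[Plot]:
    """Randomly place perimeter-sampled squares within a disc.

    Square centers are drawn uniformly in the disc of ``region_radius`` by
    rejection sampling; a candidate is accepted when every plot of the new
    square is at least ``min_separation`` from every already-placed plot.
    """
    if side <= 0 or perimeter_spacing <= 0:
        raise ValueError("side and perimeter_spacing must be > 0")
    if abs(side / perimeter_spacing - round(side / perimeter_spacing)) > 1e-9:
        raise ValueError("side must be divisible by perimeter_spacing")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_squares:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n_squares} squares with min_separation="
                f"{min_separation} m inside radius {region_radius} m after "
                f"{max_attempts} attempts ({len(placed)} placed)"
            )
        attempts += 1
        r = region_radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cx, cy = center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)
        cand = _square_perimeter(cx, cy, side, perimeter_spacing)
        ok = True
        for prev in placed:
            d2 = ((cand[:, None, :] - prev[None, :, :]) ** 2).sum(axis=2)
            if d2.min() < min_separation**2:
                ok = False
                break
        if ok:
            placed.append(cand)
    plots = []
    for s, pts in enumerate(placed):
        for k, (x, y) in enumerate(pts):
            plots.append(Plot(f"RG-{s:02d}-{k:02d}", float(x), float(y), "regional", "region"))
    return plots


def build_adjacency(
    units: pd.DataFrame,
    threshold: float = 350.0,
    block_by_year: bool = True,
) -> AdjacencyMatrix:
    """Build the binary neighborhood matrix D over plot-year units.

    Two units are neighbors iff their plot centers are within ``threshold``
    meters (inclusive) and, under the default blocking rule, belong to the
    same survey year.  The diagonal is zero.

    ``units`` needs columns ``plot_id``, ``x``, ``y`` and, if year blocking
    is requested and present, ``year``.
    """
    units = units.reset_index(drop=True)
    for col in ("plot_id", "x", "y"):
        if col not in units.columns:
            raise ValueError(f"units table lacks required column {col!r}")
    if not np.isfinite(units[["x", "y"]].to_numpy()).all():
        raise ValueError("unit coordinates must be finite")
    key_cols = ["plot_id", "year"] if "year" in units.columns else ["plot_id"]
    if units.duplicated(subset=key_cols).any():
        dupes = units.loc[units.duplicated(subset=key_cols), key_cols]
        raise ValueError(f"duplicate (plot, year) units: {dupes.values[:5].tolist()}")

    n = len(units)
    use_blocks = block_by_year and "year" in units.columns
    if use_blocks:
        groups = [np.flatnonzero((units["year"] == y).to_numpy())
                  for y in sorted(units["year"].unique())]
    else:
        groups = [np.arange(n)]

    rows, cols = [], []
    for idx in groups:
        xy = units.loc[idx, ["x", "y"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        # inclusive threshold: pad the radius by a relative epsilon so that
        # pairs at exactly `threshold` are kept despite float rounding
        pairs = tree.query_pairs(threshold * (1.0 + 1e-12), output_type="ndarray")
        if len(pairs):
            rows.extend(idx[pairs[:, 0]])
            cols.extend(idx[pairs[:, 1]])
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    data = np.ones(2 * len(rows))
    mat = sp.coo_matrix(
        (data, (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    mat.data[:] = 1.0  # defensive: collapse accidental duplicates
    return AdjacencyMatrix(matrix=mat, units=units, threshold=threshold,
                           block_by_year=use_blocks)


def sqrt_distance_covariate(distance: float | np.ndarray) -> float | np.ndarray:
    """Square root of a distance expressed in units of 100 m.

    The transform damps the influence of far-away features: a step from
    0 to 100 m changes the covariate by 1.0, while the same 100 m step at
    10 km changes it by ~0.05.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = np.sqrt(d / 100.0)
    return float(out) if np.isscalar(distance) or out.ndim == 0 else out


def compute_vif(design_columns, threshold: float = 3.0) -> pd.DataFrame:
    """Variance inflation factors with removal flags.

    VIF_j = 1 / (1 - R2_j), with R2_j the coefficient of determination from
    the least-squares regression of column j on all remaining columns (with
    an intercept).  Exactly collinear columns get ``inf`` and are flagged.
    """
    X = np.asarray(design_columns, dtype=float)
    if isinstance(design_columns, pd.DataFrame):
        names = list(design_columns.columns)
    else:
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than columns")
    n, p = X.shape
    vifs = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        tss = np.sum((y - y.mean()) ** 2)
        if tss <= 0:
            vifs[j] = np.inf  # constant column: perfectly explained by intercept
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.DataFrame({"vif": vifs, "flagged": vifs >= threshold}, index=names)


def apply_class_merge(raw_class: str, mapping: dict) -> str:
    """Map a raw landcover code to one of the five merged vegetation classes.

    The merged domain is closed (`VEGETATION_CLASSES`); a mapping whose image
    leaves it is a configuration error, and unmapped codes raise rather than
    falling back silently.
    """
    bad = set(mapping.values()) - set(VEGETATION_CLASSES)
    if bad:
        raise ValueError(f"mapping image contains labels outside the merged domain: {sorted(bad)}")
    try:
        return mapping[raw_class]
    except KeyError:
        raise KeyError(f"unmapped raw vegetation class: {raw_class!r}") from None
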