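"""Model specification and design-matrix assembly.

A :class:`ModelSpec` is an ordered list of terms (intercept, continuous,
categorical with an explicit reference level, and continuous x categorical
interactions written ``"a:b"``).  :func:`build_model_frame` turns a tidy
plot-year table into a response vector and dense design matrix, tracking
which columns belong to which term so that term-level tests and the
hierarchy rule of backward elimination can operate on named terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Term", "ModelSpec", "ModelFrame", "build_model_frame"]


@dataclass(frozen=True)
class Term:
    name: str
    kind: str = "continuous"  # intercept | continuous | categorical | interaction
    reference: str | None = None
    forced: bool = False

    def __post_init__(self):
        if self.kind not in ("intercept", "continuous", "categorical", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical term {self.name!r} needs a reference level")
        if self.kind == "interaction" and ":" not in self.name:
            raise ValueError("interaction terms are written 'a:b'")

    @property
    def parents(self) -> tuple[str, ...]:
        return tuple(self.name.split(":")) if self.kind == "interaction" else ()


@dataclass(frozen=True)
class ModelSpec:
    """Ordered fixed-effect structure with hierarchy invariants."""

    terms: tuple[Term, ...]

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate terms in model spec")
        for t in self.terms:
            for p in t.parents:
                if p not in names:
                    raise ValueError(
                        f"interaction {t.name!r} lacks parent main effect {p!r}")

    def __iter__(self):
        return iter(self.terms)

    def get(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def drop(self, name: str) -> "ModelSpec":
        t = self.get(name)
        if t.forced:
            raise ValueError(f"term {name!r} is forced and cannot be dropped")
        return ModelSpec(tuple(x for x in self.terms if x.name != name))

    def interactions_involving(self, name: str) -> list[Term]:
        return [t for t in self.terms if name in t.parents]

    @staticmethod
    def pellet_default() -> "ModelSpec":
        """The full fixed-effect structure of the pellet-presence model:
        vegetation (reference mire), sqrt-distance to turbine, development
        phase (reference preconstruction), previous-season precipitation,
        and the distance x phase interactions."""
        return ModelSpec((
            Term("intercept", "intercept", forced=True),
            Term("distance", "continuous"),
            Term("phase", "categorical", reference="preconstruction"),
            Term("vegetation", "categorical", reference="mire"),
            Term("precipitation", "continuous"),
            Term("distance:phase", "interaction"),
        ))


@dataclass
class ModelFrame:
    """Response + design matrix, with row links back to adjacency units."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    term_columns: dict  # term name -> list of column indices
    row_index: np.ndarray  # indices into the adjacency unit table
    references: dict = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)


def _dummy_columns(s: pd.Series, name: str, reference: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(map(str, s.dropna().unique()))
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present in {name!r} "
                         f"(levels: {levels})")
    keep = [lv for lv in levels if lv != reference]
    cols = np.column_stack([(s.astype(str) == lv).to_numpy(float) for lv in keep]) \
        if keep else np.zeros((len(s), 0))
    return cols, [f"{name}[{lv}]" for lv in keep]


def build_model_frame(
    df: pd.DataFrame,
    spec: ModelSpec,
    response: str = "presence",
) -> ModelFrame:
    """Assemble a model frame from a tidy plot-year table.

    ``df`` rows must be aligned with the adjacency unit table; rows with a
    missing response or missing covariates are dropped (and counted in
    ``n_dropped``) with the adjacency to be subset accordingly via
    ``row_index``.
    """
    needed = {response}
    for t in spec:
        if t.kind in ("continuous", "categorical"):
            needed.add(t.name)
        elif t.kind == "interaction":
            needed.update(t.parents)
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"data table lacks columns: {sorted(missing)}")

    ok = df[sorted(needed)].notna().all(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d rows with missing response/covariates", n_dropped)
    sub = df.loc[ok]
    row_index = np.flatnonzero(ok)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    term_columns: dict[str, list[int]] = {}
    references: dict[str, str] = {}

    def add(term: Term, cols: np.ndarray, colnames: list[str]):
        start = sum(b.shape[1] for b in blocks)
        blocks.append(np.atleast_2d(cols))
        names.extend(colnames)
        term_columns[term.name] = list(range(start, start + len(colnames)))

    for t in spec:
        if t.kind == "intercept":
            add(t, np.ones((len(sub), 1)), ["intercept"])
        elif t.kind == "continuous":
            add(t, sub[t.name].to_numpy(float)[:, None], [t.name])
        elif t.kind == "categorical":
            cols, colnames = _dummy_columns(sub[t.name], t.name, t.reference)
            references[t.name] = t.reference
            add(t, cols, colnames)
        else:  # interaction
            a, b = t.parents
            ta, tb = spec.get(a), spec.get(b)
            if ta.kind == "categorical" and tb.kind == "categorical":
                raise NotImplementedError("categorical x categorical interactions")
            if tb.kind == "categorical":
                cont, cat, cat_term = a, b, tb
            elif ta.kind == "categorical":
                cont, cat, cat_term = b, a, ta
            else:
                prod = (sub[a].to_numpy(float) * sub[b].to_numpy(float))[:, None]
                add(t, prod, [t.name])
                continue
            dummies, dnames = _dummy_columns(sub[cat], cat, cat_term.reference)
            cont_v = sub[cont].to_numpy(float)[:, None]
            add(t, dummies * cont_v,
                [f"{cont}:{dn}" for dn in dnames])

    X = np.hstack(blocks) if blocks else np.zeros((len(sub), 0))
    y = sub[response].to_numpy(float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("response values must lie in [0, 1]")
    return ModelFrame(y=y, X=X, columns=names, term_columns=term_columns,
                      row_index=row_index, references=references,
                      n_dropped=n_dropped)
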