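"""Backward elimination under the model-hierarchy principle, and the two
sensitivity refits (year-wise phases; an added random year effect).

Terms are removed one at a time: at each step the currently least
significant droppable term with p above the threshold (10% by default) is
deleted and the model refit.  A main effect is droppable only once every
interaction involving it has been deleted, so the final model always obeys
the hierarchy principle.  For multi-level factors the term-level p is, by
default, the largest single-coefficient Wald p among the factor's
non-reference levels; a joint Wald chi-square option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AdjacencyMatrix
from .frames import ModelFrame, ModelSpec, Term, build_model_frame
from .hglm import HGLMFit, fit_spatial_binomial_hglm, term_pvalue

logger = logging.getLogger(__name__)

__all__ = ["FrameBuilder", "EliminationTrail", "backward_eliminate",
           "sensitivity_refit"]


class FrameBuilder:
    """Callable turning a ModelSpec into a ModelFrame over a fixed table."""

    def __init__(self, df: pd.DataFrame, response: str = "presence"):
        self.df = df
        self.response = response

    def __call__(self, spec: ModelSpec) -> ModelFrame:
        return build_model_frame(self.df, spec, response=self.response)


@dataclass
class EliminationTrail:
    """Ordered record of backward-elimination steps."""

    steps: list  # (step, term, p, action)
    final_spec: ModelSpec
    final_fit: HGLMFit
    aborted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "term", "p", "action"])


def _droppable(spec: ModelSpec) -> list[Term]:
    out = []
    for t in spec:
        if t.forced:
            continue
        if t.kind != "interaction" and spec.interactions_involving(t.name):
            continue  # hierarchy: parents of retained interactions stay
        out.append(t)
    return out


def backward_eliminate(
    spec: ModelSpec,
    frame_builder,
    adjacency: AdjacencyMatrix,
    alpha: float = 0.10,
    *,
    term_p_method: str = "max",
    fit_kwargs: dict | None = None,
) -> EliminationTrail:
    """Hierarchy-respecting backward elimination at level ``alpha``.

    One term is dropped per refit.  Ties on p are broken by preferring
    interactions over main effects, then the later-listed term.  The
    degenerate levels are conventions: ``alpha >= 1`` strips the model down
    to its forced terms, ``alpha <= 0`` disables elimination entirely.
    """
    fit_kwargs = fit_kwargs or {}
    steps = []
    current = spec
    step = 0
    try:
        fit = fit_spatial_binomial_hglm(frame_builder(current), adjacency,
                                        **fit_kwargs)
    except Exception as exc:  # pragma: no cover - initial fit must succeed
        raise RuntimeError(f"initial model fit failed: {exc}") from exc

    while alpha > 0:
        cands = _droppable(current)
        if not cands:
            break
        pvals = {t.name: term_pvalue(fit, t.name, method=term_p_method)
                 for t in cands}
        over = [t for t in cands if pvals[t.name] > alpha or alpha >= 1.0]
        if not over:
            break
        pos = {name: i for i, name in enumerate(current.names)}
        # least significant first; ties: interactions first, later-listed first
        over.sort(key=lambda t: (pvals[t.name], t.kind == "interaction", pos[t.name]),
                  reverse=True)
        victim = over[0]
        step += 1
        steps.append((step, victim.name, pvals[victim.name], "dropped"))
        logger.info("step %d: dropping %s (p=%.4f)", step, victim.name,
                    pvals[victim.name])
        current = current.drop(victim.name)
        try:
            fit = fit_spatial_binomial_hglm(frame_builder(current), adjacency,
                                            **fit_kwargs)
        except Exception as exc:
            logger.warning("fit failed after dropping %s: %s", victim.name, exc)
            steps.append((step + 1, victim.name, np.nan, "abort"))
            return EliminationTrail(steps=steps, final_spec=current,
                                    final_fit=fit, aborted=True)
    return EliminationTrail(steps=steps, final_spec=current, final_fit=fit)


def sensitivity_refit(
    final_spec: ModelSpec,
    df: pd.DataFrame,
    adjacency: AdjacencyMatrix,
    variant: str,
    *,
    response: str = "presence",
    fit_kwargs: dict | None = None,
) -> HGLMFit:
    """Refit the final model under one of the two sensitivity variants.

    ``yearwise_phases``
        Replace the phase factor by {2010, 2011, 2012, operation}: the
        first three survey years enter as free levels (reference 2010)
        while the operation years stay pooled.  Interactions with phase
        follow the replacement.
    ``random_year``
        Keep the fixed structure but add an exchangeable normal random
        intercept per survey year alongside the CAR effect.
    """
    fit_kwargs = fit_kwargs or {}
    if variant == "yearwise_phases":
        df = df.copy()
        df["phase_year"] = [
            "operation" if ph == "operation" else str(int(yr))
            for yr, ph in zip(df["year"], df["phase"])
        ]
        terms = []
        for t in final_spec:
            if t.name == "phase":
                terms.append(Term("phase_year", "categorical", reference="2010"))
            elif t.kind == "interaction" and "phase" in t.parents:
                other = [p for p in t.parents if p != "phase"][0]
                terms.append(Term(f"{other}:phase_year", "interaction"))
            else:
                terms.append(t)
        spec2 = ModelSpec(tuple(terms))
        frame = build_model_frame(df, spec2, response=response)
        return fit_spatial_binomial_hglm(frame, adjacency, **fit_kwargs)

    if variant == "random_year":
        frame = build_model_frame(df, final_spec, response=response)
        years = sorted(df["year"].iloc[frame.row_index].unique())
        if len(years) <= 6:
            logger.warning(
                "random-year variance is estimated from only %d year levels; "
                "treat the variance component with caution", len(years))
        yv = df["year"].iloc[frame.row_index].to_numpy()
        Z = np.column_stack([(yv == y).astype(float) for y in years])
        return fit_spatial_binomial_hglm(frame, adjacency, Z_extra=Z,
                                         **fit_kwargs)

    raise ValueError(f"unknown sensitivity variant {variant!r}; "
                     "expected 'yearwise_phases' or 'random_year'")
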