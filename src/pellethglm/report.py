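"""Coefficient tables aligned across analysis subsets, and the end-to-end
pipeline (simulate or load -> frames -> selection -> fits -> tables ->
optional power).

The headline output mirrors the published layout: one column per analysis
subset (combined, region, and the two local mountains), rows for every
term significant in at least one subset, reference-category rows rendered
as ``0.00 (-)``, and a footer carrying the mean-model dispersion, the CAR
dispersions tau and rho, and the number of observations used.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import ModelSpec, Term, build_model_frame
from .hglm import HGLMFit, fit_spatial_binomial_hglm, wald_test
from .power import power_study
from .selection import FrameBuilder, backward_eliminate
from .simulate import GeneratorParams, make_study_design, simulate_survey
from .survey import round_half_away

logger = logging.getLogger(__name__)

__all__ = ["make_coefficient_table", "run_pipeline", "DEFAULT_CONFIG",
           "validate_config"]


def _fmt(x: float, dec: int = 2) -> str:
    return f"{round_half_away(float(x), dec):.{dec}f}"


def make_coefficient_table(fits: dict[str, HGLMFit], alpha: float = 0.05) -> pd.DataFrame:
    """Align fitted models into one table, one column per fit.

    Every coefficient significant at ``alpha`` in at least one fit appears
    as a row in all columns; coefficients absent from a fit render blank.
    Reference categories render as ``0.00 (-)``.  Estimates are rounded
    half-away-from-zero to 2 decimals; significant entries are starred.
    A footer reports phi, tau, rho and the observation count per fit.
    """
    if not fits:
        raise ValueError("empty fit set")
    keep: list[str] = []
    for fit in fits.values():
        for name in fit.beta.index:
            if name in keep:
                continue
            if wald_test(fit, name)[3] < alpha:
                keep.append(name)
    # preserve the column order of the first fit that mentions each term
    ordered: list[str] = []
    for fit in fits.values():
        for name in fit.beta.index:
            if name in keep and name not in ordered:
                ordered.append(name)

    # reference-category rows: insert "term[ref]" right after the term's
    # last retained level, rendered as 0.00 (-) wherever the fit has the term
    rows = {}
    for name in ordered:
        row = {}
        for label, fit in fits.items():
            if name in fit.beta.index:
                est, se, _, pval = wald_test(fit, name)
                star = "*" if pval < alpha else ""
                row[label] = f"{_fmt(est)}{star} ({_fmt(se)})"
            else:
                row[label] = ""
        rows[name] = row
    display_order = list(ordered)
    for label, fit in fits.items():
        for term, ref in fit.references.items():
            ref_name = f"{term}[{ref}]"
            levels_kept = [nm for nm in display_order
                           if nm.startswith(f"{term}[") and nm != ref_name]
            if not levels_kept:
                continue
            if ref_name not in rows:
                rows[ref_name] = {}
                display_order.insert(
                    display_order.index(levels_kept[-1]) + 1, ref_name)
            for lab, f2 in fits.items():
                if term in f2.references:
                    rows[ref_name][lab] = "0.00 (-)"
                else:
                    rows[ref_name].setdefault(lab, "")
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(fits.keys())).loc[display_order]
    table = table.fillna("")

    footer = {}
    for label, fit in fits.items():
        footer[label] = {
            "dispersion": _fmt(fit.phi), "tau": _fmt(fit.tau),
            "rho": _fmt(fit.rho), "n_obs": str(fit.n_obs),
        }
    foot = pd.DataFrame(footer)
    foot.index = [f"<{k}>" for k in foot.index]
    return pd.concat([table, foot])


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "local_half_extent": 1500.0,
        "n_squares": 29,
        "region_radius": 15000.0,
    },
    "generator": {},  # overrides for GeneratorParams fields
    "model": {
        "alpha_select": 0.10,
        "term_p_method": "max",
        "select": True,
        "response": "presence",
        # fixed-effect structure; None means ModelSpec.pellet_default()
        # (vegetation ref "mire", phase ref "preconstruction",
        #  interaction "distance:phase")
        "terms": None,
    },
    "power": {
        "enabled": False,
        "terms": ["distance:phase[construction]", "distance:phase[operation]"],
        "n_sim": 50,
        "alpha": 0.05,
    },
}

_ALLOWED_KEYS = {
    "": set(DEFAULT_CONFIG),
    "design": set(DEFAULT_CONFIG["design"]),
    "model": set(DEFAULT_CONFIG["model"]),
    "power": set(DEFAULT_CONFIG["power"]),
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if key not in _ALLOWED_KEYS[""]:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(val, dict) and key in _ALLOWED_KEYS:
            for k2 in val:
                if key != "generator" and k2 not in _ALLOWED_KEYS[key]:
                    raise ValueError(f"unknown config key {key}.{k2}")
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


SUBSETS = {
    "combined": lambda cov: np.ones(len(cov), dtype=bool),
    "region": lambda cov: (cov["scale"] == "regional").to_numpy(),
    "storliden": lambda cov: (cov["site"] == "Storliden").to_numpy(),
    "jokkmokksliden": lambda cov: (cov["site"] == "Jokkmokksliden").to_numpy(),
}


def run_pipeline(config: dict | None = None, out_dir: str | Path = "pipeline_out"):
    """Run the full analysis on a simulated survey and write all artifacts.

    Stages: simulate the two-scale survey, build the four analysis subsets
    (combined / region / the two local mountains), optionally run backward
    elimination per subset, fit the spatial HGLM, assemble the aligned
    coefficient table, and (if enabled) run the Monte Carlo power study.
    Deterministic given the config; rerunning writes byte-identical JSON.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config: {json.dumps(cfg, sort_keys=True)}"]

    seed = int(cfg["seed"])
    design = make_study_design(seed=seed, **cfg["design"])
    gen_kwargs = dict(cfg["generator"])
    params = GeneratorParams(seed=seed, **gen_kwargs)

    try:
        records, covariates, adjacency = simulate_survey(design, params)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    records.to_csv(out / "records.csv", index=False)
    covariates.to_csv(out / "covariates.csv", index=False)
    from . import io as _io
    _io.write_adjacency(adjacency, out / "adjacency.mtx")
    (out / "provenance.json").write_text(json.dumps({
        "seed": seed, "design": cfg["design"],
        "generator": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in gen_kwargs.items()},
        "tau": params.tau, "rho": params.rho,
    }, sort_keys=True, indent=2))
    log_lines.append(f"simulated {len(records)} plot-year records, "
                     f"{design.n_plots} plots, seed={seed}")

    df = covariates.copy()
    df["presence"] = records["presence"].to_numpy().astype(float)
    excluded = df["phase"] == "excluded"
    df.loc[excluded, "presence"] = np.nan
    log_lines.append(f"excluded {int(excluded.sum())} records from non-analysis years")

    if cfg["model"]["terms"]:
        spec0 = ModelSpec(tuple(
            Term(t["name"], t.get("kind", "continuous"),
                 reference=t.get("reference"), forced=bool(t.get("forced")))
            for t in cfg["model"]["terms"]))
    else:
        spec0 = ModelSpec.pellet_default()
    response = cfg["model"]["response"]
    fits: dict[str, HGLMFit] = {}
    for label, selector in SUBSETS.items():
        mask = selector(covariates)
        sub = df.loc[mask].reset_index(drop=True)
        sub_adj = adjacency.subset(np.flatnonzero(mask))
        builder = FrameBuilder(sub, response=response)
        try:
            if cfg["model"]["select"]:
                trail = backward_eliminate(
                    spec0, builder, sub_adj,
                    alpha=cfg["model"]["alpha_select"],
                    term_p_method=cfg["model"]["term_p_method"])
                trail.to_frame().to_csv(out / f"selection_{label}.csv", index=False)
                fits[label] = trail.final_fit
                log_lines.append(
                    f"{label}: dropped {[s[1] for s in trail.steps]}, "
                    f"n_obs={trail.final_fit.n_obs}")
            else:
                fits[label] = fit_spatial_binomial_hglm(
                    build_model_frame(sub, spec0, response=response), sub_adj)
                log_lines.append(f"{label}: fitted full model, "
                                 f"n_obs={fits[label].n_obs}")
        except Exception as exc:
            raise RuntimeError(f"stage 'fit:{label}' failed: {exc}") from exc
        (out / f"fit_{label}.json").write_text(
            json.dumps(fits[label].to_dict(), sort_keys=True, indent=2))

    table = make_coefficient_table(fits)
    table.to_csv(out / "coefficient_table.csv")
    log_lines.append("coefficient table written")

    results = {"fits": {k: f.to_dict() for k, f in fits.items()}}
    if cfg["power"]["enabled"]:
        try:
            pw = power_study(params, design, list(cfg["power"]["terms"]),
                             n_sim=int(cfg["power"]["n_sim"]),
                             alpha=float(cfg["power"]["alpha"]), seed=seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'power' failed: {exc}") from exc
        results["power"] = {k: v.to_dict() for k, v in pw.items()}
        pd.DataFrame([v.to_dict() for v in pw.values()]).to_csv(
            out / "power.csv", index=False)
        log_lines.append(f"power study: {results['power']}")

    (out / "results.json").write_text(json.dumps(results, sort_keys=True, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return fits, table
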