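"""The full analysis pipeline: geography and tempo of a radiation.

Chains every stage in order -- rasterise localities, overlap matrix, ARC
with permutation significance and the zero/complete-overlap indicators,
area-age regression, between-clade area comparison, LTT, diversification
model selection with the simulated rate-constancy null, tree-shape
statistics with the per-branch shift test, and clade rate estimates -- and
writes a single JSON report plus per-stage TSV tables.  All randomness is
derived from one seed via named per-stage substreams.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arc, diversification as dv, geo, io, treeshape
from ._random import stage_rng, stage_seed
from .chronogram import Chronogram

log = logging.getLogger("sympatree")

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    tree_path: str
    out_dir: str
    localities_path: str | None = None
    ranges_path: str | None = None  # precomputed RangeMap JSON; skips rasterisation
    posterior_path: str | None = None
    outgroup: list[str] = field(default_factory=list)
    cell_deg: float = 0.025
    radius_km: float = 4.0
    n_perm: int = 999
    n_sim: int = 1000
    n_extant: int | None = None  # total extant species; default = sampled
    seed: int = 0
    #: clade name -> {"tips": [...], "missing": int}
    clades: dict = field(default_factory=dict)
    epsilons: tuple[float, ...] = (0.0, 0.5)
    ultrametric_tol: float = 1e-6
    plots: bool = False


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "units": {
        "ages": "Myr", "areas": "km2", "rates": "per Myr"}}

    chron = _load(cfg)
    rangemap, overlaps, areas = _geography(cfg, chron, out, report)
    _arc_stage(cfg, chron, overlaps, areas, out, report)
    bt = _diversification_stage(cfg, chron, out, report)
    _treeshape_stage(cfg, chron, report)
    _clade_rates_stage(cfg, chron, report)
    if cfg.plots:
        _plots_stage(chron, bt, report, out)

    io.write_json(report, out / "report.json")
    return report


@_stage("load")
def _load(cfg: RunConfig):
    if not cfg.localities_path and not cfg.ranges_path:
        raise ValueError("either localities_path or ranges_path is required")
    for p in (cfg.tree_path, cfg.localities_path, cfg.ranges_path,
              cfg.posterior_path):
        if p and not Path(p).exists():
            raise FileNotFoundError(p)
    return io.read_chronogram(
        cfg.tree_path, tol=cfg.ultrametric_tol, outgroup=cfg.outgroup
    )


@_stage("geography")
def _geography(cfg, chron, out, report):
    from pathlib import Path as _P

    n_localities = None
    if cfg.ranges_path:
        rangemap = geo.RangeMap.from_json(_P(cfg.ranges_path).read_text())
    else:
        localities = io.read_localities(cfg.localities_path)
        n_localities = len(localities)
        grid = geo.GridSpec(cell_deg=cfg.cell_deg, radius_km=cfg.radius_km)
        rangemap = geo.rasterize_ranges(localities, grid)
    extra = set(rangemap.species) - set(chron.tip_labels)
    missing = set(chron.tip_labels) - set(rangemap.species)
    if extra or missing:
        raise ValueError(
            f"species mismatch: geography-only {sorted(extra)}, "
            f"tree-only {sorted(missing)}"
        )
    for sp in sorted(rangemap.species):
        log.info("range: %s occupies %d quadrats", sp, len(rangemap[sp]))
    overlaps = geo.overlap_matrix(rangemap)
    areas = {
        sp: geo.range_area_km2(rangemap, sp) for sp in rangemap.species
    }
    (out / "ranges.json").write_text(rangemap.to_json())
    (out / "overlaps.tsv").write_text(overlaps.to_tsv())
    report["geography"] = {
        "n_species": len(rangemap.species),
        "n_localities": n_localities,
        "range_source": "precomputed" if cfg.ranges_path else "rasterized",
        "areas_km2": {sp: round(v, 3) for sp, v in sorted(areas.items())},
    }
    return rangemap, overlaps, areas


@_stage("arc")
def _arc_stage(cfg, chron, overlaps, areas, out, report):
    seed = int(stage_seed(cfg.seed, "arc").generate_state(1)[0] % 2**31)
    section = {}
    for response in arc.RESPONSES:
        res = arc.arc_permutation_test(
            chron, overlaps, n_perm=cfg.n_perm, seed=seed, response=response
        )
        section[response] = {
            "slope": res.slope,
            "intercept": res.intercept,
            "p_slope": res.p_slope,
            "p_intercept": res.p_intercept,
            "n_permutations": res.n_permutations,
            "seed": seed,
        }
    mo = section["mean_overlap"]
    section["classification"] = arc.classify_speciation_mode(
        mo["slope"], mo["intercept"]
    )
    table = arc.arc_node_table(chron, overlaps.reorder(chron.tip_labels))
    io.write_tsv(table, out / "arc_nodes.tsv")
    fit = arc.area_age_regression(areas, chron)
    io.write_tsv(fit.table, out / "area_age.tsv")
    section["area_age"] = {
        "slope_km2_per_myr": fit.slope,
        "intercept_km2": fit.intercept,
        "pearson_r": fit.r,
    }
    comparisons = {}
    for name, spec in cfg.clades.items():
        tips = set(spec["tips"])
        inside = [areas[t] for t in tips if t in areas]
        outside = [areas[t] for t in areas if t not in tips]
        if inside and outside:
            comparisons[name] = {
                "n_inside": len(inside),
                "n_outside": len(outside),
                "mean_inside_km2": float(np.mean(inside)),
                "mean_outside_km2": float(np.mean(outside)),
                "ranksum_p": arc.compare_area_sets(inside, outside),
            }
    if comparisons:
        section["area_comparisons"] = comparisons
    report["arc"] = section


@_stage("diversification")
def _diversification_stage(cfg, chron, out, report):
    bt = dv.branching_times(chron)
    ltt = dv.ltt_curve(bt)
    io.write_tsv(
        pd.DataFrame(ltt, columns=["age_myr", "lineages"]), out / "ltt.tsv"
    )
    fits = [
        dv.fit_pure_birth(bt),
        dv.fit_birth_death(bt),
        dv.fit_yule_2_rate(bt),
    ]
    table = [
        {
            "model": f.model,
            "params": {k: round(v, 6) for k, v in f.params.items()},
            "logL": f.logL,
            "AICc": f.aicc,
            "k": f.n_params,
        }
        for f in fits
    ]
    observed = dv.delta_aicc(dv.best_constant_fit(bt), fits[2])
    seed = int(stage_seed(cfg.seed, "divnull").generate_state(1)[0] % 2**31)
    n_extant = cfg.n_extant or chron.n_tips
    null = dv.delta_aicc_null_test(
        chron, n_extant=n_extant, n_sampled=chron.n_tips,
        n_sim=cfg.n_sim, seed=seed,
    )
    report["diversification"] = {
        "n_tips": chron.n_tips,
        "crown_age_myr": chron.crown_age,
        "model_fits": table,
        "delta_aicc": observed,
        "null_test": {
            "p": null.p,
            "observed": null.observed,
            "lambda_hat": null.lambda_hat,
            "n_extant": null.n_extant,
            "n_sampled": null.n_sampled,
            "n_sim": null.n_sim,
            "seed": seed,
        },
    }
    return bt


@_stage("treeshape")
def _treeshape_stage(cfg, chron, report):
    stats = treeshape.shape_statistics(chron)
    seed = int(stage_seed(cfg.seed, "treeshape").generate_state(1)[0] % 2**31)
    section = {
        "n_tips": stats.n_tips,
        "colless": stats.colless,
        "b1": stats.b1,
        "colless_erm_p": treeshape.erm_pvalue(
            "colless", stats.colless, stats.n_tips, n_sim=cfg.n_sim, seed=seed
        ),
        "b1_erm_p": treeshape.erm_pvalue(
            "b1", stats.b1, stats.n_tips, n_sim=cfg.n_sim, seed=seed + 1
        ),
    }
    branches = treeshape.delta1_all_branches(chron)
    if branches:
        tips, d1 = max(branches, key=lambda tb: tb[1])
        shift = treeshape.delta1_shift_test(
            chron, set(tips), n_sim=cfg.n_sim, seed=seed + 2
        )
        section["max_delta1"] = {
            "clade": list(tips),
            "delta1": shift.delta1,
            "p": shift.p,
            "n_sim": shift.n_sim,
        }
        section["delta1_branches"] = [
            {"clade": list(t), "delta1": v} for t, v in branches
        ]
    report["treeshape"] = section


@_stage("clade_rates")
def _clade_rates_stage(cfg, chron, report):
    if not cfg.clades:
        return
    rates = {}
    posterior = None
    if cfg.posterior_path:
        posterior = io.read_posterior_trees(
            cfg.posterior_path, tol=cfg.ultrametric_tol,
            outgroup=cfg.outgroup,
        )
    for name, spec in cfg.clades.items():
        tips = [t for t in spec["tips"] if t in set(chron.tip_labels)]
        if len(tips) < 2:
            continue
        missing = int(spec.get("missing", 0))
        node = chron.mrca(tips)
        if set(Chronogram.leaf_labels_under(node)) != set(tips):
            rates[name] = {"error": "clade not monophyletic in main tree"}
            continue
        entry = {"n_sampled": len(tips), "missing": missing,
                 "crown_age_myr": node.age}
        for eps in cfg.epsilons:
            est = dv.ms_rate(len(tips) + missing, node.age, epsilon=eps)
            entry[f"r_eps{eps:g}"] = est.r
        if posterior:
            ests, skipped = dv.posterior_rate_distribution(
                posterior, tips, missing=missing, epsilon=cfg.epsilons[0]
            )
            entry["posterior"] = {
                "n_trees": len(posterior),
                "n_skipped": skipped,
                "rate_mean": float(np.mean([e.r for e in ests]))
                if ests else None,
                "rate_sd": float(np.std([e.r for e in ests]))
                if ests else None,
            }
        rates[name] = entry
    report["clade_rates"] = rates


@_stage("plots")
def _plots_stage(chron, bt, report, out):
    from . import plotting

    plotting.ltt_plot(bt, out / "ltt.svg")
    plotting.arc_plot(
        report["arc"]["mean_overlap"], out / "arc.svg",
        table_path=out / "arc_nodes.tsv",
    )
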