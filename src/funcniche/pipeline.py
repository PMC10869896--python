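"""One-shot analysis pipeline reproducing the full study workflow.

Order of stages: traits -> PCA functional space -> niche metrics
(FIde/FRic/FOve, bootstrap CIs, PERMANOVA) -> microhabitat screening ->
per-group GLM/AICc/model-averaging -> hierarchical partitioning -> DCA
gate -> RDA with permutation test.

A single global seed fans out to per-stage child seeds (stage-name
hashed), so each stage is reproducible independently of execution order.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .functional_space import build_space, trait_axis_correlations
from .habitat import (all_subsets, correlation_screen, hierarchical_partition,
                      model_average, normality_screen, ENV_VARS)
from .io import read_individuals, read_transects
from .niche import bootstrap_metric, fide, fove, fric, permanova
from .ordination import dca_gradient_length, forward_select, rda, rda_permutation_test
from .traits import GROUPS, compute_traits, standardize

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    individuals_path: str | Path | None = None
    transects_path: str | Path | None = None
    seed: int = 0
    n_boot: int = 10_000
    n_perm: int = 999
    family: str = "poisson"
    avg_scope: str = "all"
    collinearity_threshold: float = 0.9
    bootstrap_sizes: tuple[int, ...] | None = None  # default: sorted group sizes
    out_dir: str | Path | None = None
    keep_rules: dict | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be positive")
        if not 0 < self.collinearity_threshold <= 1:
            raise ValueError("collinearity_threshold must be in (0, 1]")


def run_pipeline(
    config: PipelineConfig,
    individuals: pd.DataFrame | None = None,
    transects: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Run the full analysis; returns a results bundle (JSON-ready dict).

    Input tables may be passed in memory or read from the configured
    paths.  When ``config.out_dir`` is set, the summary JSON and the
    per-stage CSV tables are written there.
    """
    results: dict[str, Any] = {"version": __version__, "seed": config.seed}

    def _stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(name, exc) from exc
        return wrap

    # ------------------------------------------------------------- inputs
    run = _stage("read")
    if individuals is None:
        if config.individuals_path is None:
            raise PipelineError("read", ValueError("no individual table provided"))
        individuals = run(read_individuals, config.individuals_path)
    if transects is None:
        if config.transects_path is None:
            raise PipelineError("read", ValueError("no transect table provided"))
        transects = run(read_transects, config.transects_path)
    results["n_individuals"] = int(len(individuals))
    results["n_transects"] = int(len(transects))
    groups = individuals["group"].to_numpy()
    results["group_sizes"] = {g: int((groups == g).sum()) for g in GROUPS}

    # ------------------------------------------------------------- traits
    run = _stage("traits")
    raw = run(compute_traits, individuals)
    z = run(standardize, raw)

    # ----------------------------------------------------- functional space
    run = _stage("functional_space")
    space = run(build_space, z)
    loadings_rp = run(trait_axis_correlations, space, z)
    results["functional_space"] = {
        "eigenvalues": space.eigenvalues.tolist(),
        "retained_axes": space.retained_axes,
        "explained_pct": space.explained_pct.tolist(),
    }

    # ------------------------------------------------------- niche metrics
    run = _stage("niche_metrics")
    coords = space.coordinates.to_numpy()
    pts = {g: coords[groups == g] for g in GROUPS if (groups == g).any()}
    pooled = coords
    niche: dict[str, Any] = {}
    niche["fide"] = {g: run(fide, p).tolist() for g, p in pts.items()}
    niche["fric_pct"] = {g: run(fric, p, pooled) for g, p in pts.items()}
    niche["fove"] = {}
    keys = sorted(pts)
    for i, ga in enumerate(keys):
        for gb in keys[i + 1:]:
            niche["fove"][f"{ga}|{gb}"] = run(fove, pts[ga], pts[gb])
    perm = run(permanova, coords, groups, n_perm=config.n_perm,
               seed=stage_seed(config.seed, "permanova"))
    niche["permanova"] = {"pseudo_F": perm.pseudo_F, "p": perm.p,
                          "n_perm": perm.n_perm}

    sizes = config.bootstrap_sizes
    if sizes is None:
        sizes = tuple(sorted({len(p) for p in pts.values()}))
    niche["bootstrap"] = {}
    for sub_n in sizes:
        for metric in ("fric", "fove"):
            res = run(bootstrap_metric, pts, metric, sub_n,
                      n_reps=config.n_boot,
                      seed=stage_seed(config.seed, f"boot-{metric}-{sub_n}"),
                      pooled_points=pooled)
            for label, br in res.items():
                niche["bootstrap"][f"{metric}:{label}:n={sub_n}"] = {
                    "ci_low": br.ci_low, "ci_high": br.ci_high,
                    "median": br.median, "n_reps": br.n_reps,
                }
    results["niche"] = niche

    # ---------------------------------------------------------- screening
    run = _stage("screening")
    env = transects.set_index("transect")[ENV_VARS]
    norm = run(normality_screen, env)
    screen = run(correlation_screen, env, norm,
                 threshold=config.collinearity_threshold,
                 keep_rules=config.keep_rules)
    results["screening"] = {"kept": screen.kept, "dropped": screen.dropped}

    # ------------------------------------------------------ habitat models
    run = _stage("habitat_models")
    kept = list(screen.kept)
    # the full model must stay estimable (k = p + 1 <= n - 1): if the
    # screen left more predictors than the transect count supports, keep
    # collapsing the most collinear ones
    max_p = len(env) - 2
    while len(kept) > max_p:
        mean_r = {v: screen.corr.loc[v, [c for c in kept if c != v]].abs().mean()
                  for v in kept}
        drop = max(kept, key=lambda v: (mean_r[v], v))
        logger.info("habitat_models: dropping %s (mean |r| %.3f) to keep the "
                    "full model estimable with %d transects", drop, mean_r[drop],
                    len(env))
        kept.remove(drop)
    results["screening"]["model_predictors"] = kept
    env_kept = env[kept]
    habitat: dict[str, Any] = {}
    for g in GROUPS:
        col = f"count_{g}"
        if col not in transects.columns:
            continue
        counts = transects.set_index("transect")[col].reindex(env.index).to_numpy()
        table = run(all_subsets, counts, env_kept, family=config.family)
        avg = run(model_average, table, scope=config.avg_scope)
        part = run(hierarchical_partition, counts, env_kept, family=config.family)
        habitat[g] = {
            "n_models": int((table.table["status"] == "ok").sum()),
            "best_subset": list(table.best) if table.best else None,
            "ambiguous": table.ambiguous,
            "averaged": avg.to_dict(orient="index"),
            "partition": part.table.to_dict(orient="index"),
            "full_gof": part.full_gof,
        }
    results["habitat"] = habitat

    # ---------------------------------------------------------- ordination
    run = _stage("ordination")
    dca = run(dca_gradient_length, z.data)
    env_ind = individuals[["id", "transect"]].merge(
        env_kept.reset_index(), on="transect").set_index("id")[kept]
    env_ind = env_ind.loc[z.ids]
    env_z = (env_ind - env_ind.mean()) / env_ind.std(ddof=1)
    rda_res = run(rda, z.data, env_z)
    perm_test = run(rda_permutation_test, z.data, env_z, n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "rda-perm"))
    selected = run(forward_select, z.data, env_z, n_perm=config.n_perm,
                   seed=stage_seed(config.seed, "rda-forward"))
    results["ordination"] = {
        "dca_axis1_gradient_length": dca.axis1_gradient_length,
        "model_recommendation": dca.recommendation,
        "canonical_eigenvalues": rda_res.canonical_eigenvalues.tolist(),
        "pct_of_total": rda_res.pct_of_total.tolist(),
        "perm_test": perm_test,
        "significant_variables": selected,
    }

    # -------------------------------------------------------------- output
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        z.data.to_csv(out / "traits_standardized.csv")
        space.coordinates.to_csv(out / "pc_coordinates.csv")
        space.loadings.to_csv(out / "pc_loadings.csv")
        loadings_rp.to_csv(out / "pc_trait_correlations.csv")
        rda_res.axis_scores.to_csv(out / "rda_site_scores.csv")
        rda_res.env_scores.to_csv(out / "rda_env_scores.csv")
        rda_res.trait_scores.to_csv(out / "rda_trait_scores.csv")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(results, fh, indent=2, default=_jsonable)
        logger.info("pipeline outputs written to %s", out)
    return results


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
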