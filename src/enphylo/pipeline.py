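"""End-to-end orchestration: clean → fit → evaluate → project → summarize.

A :class:`RunConfig` carries every tunable constant of the workflow
(background size, collinearity cutoff, tier bounds, tree replicates,
bootstrap settings, AUC acceptance threshold, threshold schemes, dispersal
rate and horizon, master seed).  One master seed spawns stable per-stage,
per-species sub-seeds by hashing the species id, so adding a species never
perturbs the results of others.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import diversity as dv
from . import enfa as ef
from . import ensemble as es
from . import geodata as gd
from . import phylo_niche as pn
from . import projection as pj
from .errors import EnphyloError, InputError, ModelRejectedError
from .synthetic import Fixture, ScenarioSet


@dataclass
class RunConfig:
    """All workflow constants with their documented defaults."""

    background_n: int = 10_000
    r_threshold: float = 0.7
    tier_rare_max: int = 14          # < 15 cells -> imputation route
    tier_esm_max: int = 30           # 15..30 -> ESM; above -> SDM
    presence_target: int = 5
    tree_reps: int = 50
    cv_reps: int = 10
    split: float = 0.8
    auc_min: float = 0.7
    thresholds: tuple[str, ...] = pj.SCHEMES
    dispersal_rate: float = 1.0      # km / yr
    years: tuple[int, int] = (2010, 2070)
    s_axes: int = 2
    k_spec: int = 2
    rf_trees: int = 500
    learner_kinds: tuple[str, ...] = es.LEARNER_KINDS
    moran_background_n: int = 100
    moran_permutations: int = 99
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.split < 1):
            raise InputError("split must be in (0, 1)")
        if self.dispersal_rate < 0:
            raise InputError("dispersal_rate must be non-negative")
        if self.years[1] <= self.years[0]:
            raise InputError("years must be increasing")
        if self.background_n < 1 or self.cv_reps < 1 or self.tree_reps < 1:
            raise InputError("counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg


def species_seed(master_seed: int, stage: str, species_id: str = "") -> int:
    """Stable per-stage, per-species sub-seed (< 2**31)."""
    key = f"{master_seed}:{stage}:{species_id}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass
class SpeciesResult:
    species_id: str
    tier: str
    n_cells: int
    auc: float | None = None
    tss: float | None = None
    boyce: float | None = None
    chosen_tree_index: int | None = None
    rejected: bool = False
    note: str = ""


@dataclass
class RunResult:
    """Everything a finished run produced, plus the manifest."""

    config: RunConfig
    retained_layers: list[str]
    species: dict[str, SpeciesResult]
    binary_maps: dict[str, dict[pj.PredictionKey, np.ndarray]]
    diversity: dict[tuple, dv.DiversityMaps]
    interaction_summaries: dict[str, pd.DataFrame]
    moran: pd.DataFrame | None
    manifest: dict


def run_pipeline(
    fixture: Fixture,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    species_subset: Sequence[str] | None = None,
) -> RunResult:
    """Run the full workflow on a simulated (or loaded) study system.

    ``fixture`` bundles the current stack, scenario stacks, occurrences
    and the phylogeny.  ``species_subset`` restricts modelling to the
    named species (all by default).  When ``out_dir`` is given, grids,
    evaluation tables and the manifest are written there.
    """
    cfg = config or RunConfig()
    cfg.validate()
    stack = fixture.stack
    scenarios = fixture.scenarios
    tree = fixture.truth.tree
    occurrences = fixture.occurrences
    if species_subset is not None:
        occurrences = {s: occurrences[s] for s in species_subset}

    manifest: dict = {"seed": cfg.seed, "stages": {}}

    # -- background & collinearity -------------------------------------
    background = gd.sample_background(
        stack, min(cfg.background_n, len(stack.valid_cells())),
        seed=species_seed(cfg.seed, "background"),
    )
    retained = gd.collinearity_filter(stack, background.cell_ids,
                                      cfg.r_threshold)
    sub = stack.subset(retained)
    manifest["stages"]["screening"] = {
        "background_n": background.count, "retained_layers": retained,
    }

    # -- standardization (shared across every scenario stack) ----------
    std, std_current = ef.standardize(sub, background)
    std_stacks = {
        key: std.apply(scn.subset(retained))
        for key, scn in scenarios.stacks.items()
    }
    std_stacks[("current", None, None)] = std_current

    # -- tiers ----------------------------------------------------------
    tiers = {
        sp: es.assign_tier(sp, len(occ.cell_ids))
        for sp, occ in occurrences.items()
    }
    manifest["stages"]["tiers"] = {
        sp: t.tier for sp, t in sorted(tiers.items())
    }

    # -- ENFA donors & trait table --------------------------------------
    donor_models: dict[str, ef.EnfaModel] = {}
    for sp, occ in occurrences.items():
        if len(occ.cell_ids) > cfg.tier_rare_max:
            donor_models[sp] = ef.fit_enfa(
                std_current, occ.cell_ids, background.cell_ids, cfg.k_spec
            )
    trait_table = pn.build_trait_table(donor_models, cfg.s_axes)

    # -- per-species fits ------------------------------------------------
    results: dict[str, SpeciesResult] = {}
    scorers: dict[str, object] = {}
    for sp, occ in sorted(occurrences.items()):
        tier = tiers[sp].tier
        res = SpeciesResult(sp, tier, len(occ.cell_ids))
        sp_seed = species_seed(cfg.seed, "fit", sp)
        try:
            if tier == es.TIER_ENPHYLO:
                if len(trait_table.observed_species) < 3:
                    raise InputError("too few ENFA donors for imputation")
                fit = pn.fit_enphylo(
                    sp, occ.cell_ids, tree, trait_table, std_current,
                    background.cell_ids, n_tree_reps=cfg.tree_reps,
                    seed=sp_seed, cv_reps=cfg.cv_reps, auc_min=cfg.auc_min,
                )
                scorers[sp] = pn.enfa_scorer(fit.model)
                res.auc = fit.eval_record.auc_mean
                res.tss = fit.eval_record.tss_mean
                res.boyce = fit.eval_record.boyce_mean
                res.chosen_tree_index = fit.chosen_tree_index
            elif tier == es.TIER_ESM:
                scorer, records = es.fit_esm(
                    occ.cell_ids, background.cell_ids, std_current,
                    cfg.learner_kinds, seed=sp_seed, n_reps=cfg.cv_reps,
                    n_trees=cfg.rf_trees, auc_min=cfg.auc_min,
                )
                scorers[sp] = scorer
                passing = [r for _, _, r in records if r.pass_flag]
                res.auc = float(np.mean([r.auc_mean for r in passing]))
                res.tss = float(np.mean([r.tss_mean for r in passing]))
                res.boyce = float(np.nanmean([r.boyce_mean for r in passing]))
            else:  # SDM
                scored = []
                rng = np.random.default_rng(sp_seed)
                for kind in cfg.learner_kinds:
                    k_seed = int(rng.integers(2**31))
                    fitter = es.make_learner_fitter(
                        kind, std_current, n_trees=cfg.rf_trees
                    )
                    rec = es.bootstrap_evaluate(
                        fitter, occ.cell_ids, background.cell_ids,
                        std_current, n_reps=cfg.cv_reps, seed=k_seed,
                        auc_min=cfg.auc_min,
                    )
                    if rec.pass_flag:
                        scorer = es.fit_learner(
                            kind, occ.cell_ids, background.cell_ids,
                            std_current, seed=k_seed, n_trees=cfg.rf_trees,
                        )
                        scored.append((scorer, rec))
                scorers[sp] = es.ensemble_average(scored)
                res.auc = float(np.mean([r.auc_mean for _, r in scored]))
                res.tss = float(np.mean([r.tss_mean for _, r in scored]))
                res.boyce = float(np.nanmean([r.boyce_mean for _, r in scored]))
        except (ModelRejectedError, InputError) as exc:
            res.rejected = True
            res.note = str(exc)
        results[sp] = res

    modelled = [sp for sp in results if not results[sp].rejected]
    manifest["stages"]["fits"] = {
        "modelled": len(modelled),
        "rejected": sorted(sp for sp in results if results[sp].rejected),
    }

    # -- projection ------------------------------------------------------
    keys = pj.enumerate_predictions(
        len(cfg.thresholds),
        n_gcm=len({k[1] for k in scenarios.keys() if k[1]}),
        n_ssp=len({k[2] for k in scenarios.keys() if k[2]}),
    )
    binary_maps: dict[str, dict[pj.PredictionKey, np.ndarray]] = {}
    for sp in modelled:
        occ = occurrences[sp]
        scorer = scorers[sp]
        pres_scores = scorer.score_cells(std_current, occ.cell_ids)
        bg_scores = scorer.score_cells(std_current, background.cell_ids)
        rules = {
            scheme: pj.compute_threshold(scheme, pres_scores, bg_scores)
            for scheme in cfg.thresholds
        }
        constraint = pj.dispersal_mask(
            occ, cfg.dispersal_rate, cfg.years[0], cfg.years[1], stack
        )
        grids = {
            key: scorer.score_grid(std_stacks[key])
            for key in scenarios.keys()
        }
        maps: dict[pj.PredictionKey, np.ndarray] = {}
        for scenario, gcm, ssp, scheme in keys:
            suit = grids[(scenario, gcm, ssp)]
            bmap = pj.binarize(suit, rules[scheme])
            maps[(scenario, gcm, ssp, scheme)] = pj.apply_dispersal(
                bmap, constraint
            )
        binary_maps[sp] = maps

    # -- diversity & interactions ----------------------------------------
    diversity: dict[tuple, dv.DiversityMaps] = {}
    future_keys = [k for k in keys if k[0] != "current"]
    for scenario, gcm, ssp, scheme in future_keys:
        cur = {sp: binary_maps[sp][("current", None, None, scheme)]
               for sp in binary_maps}
        fut = {sp: binary_maps[sp][(scenario, gcm, ssp, scheme)]
               for sp in binary_maps}
        if cur:
            diversity[(scenario, gcm, ssp, scheme)] = dv.stack_diversity(cur, fut)

    interaction_summaries: dict[str, pd.DataFrame] = {}
    ssps = sorted({k[2] for k in scenarios.keys() if k[2]})
    gcms = sorted({k[1] for k in scenarios.keys() if k[1]})
    for ssp in ssps:
        rasters: list[dv.InteractionRaster] = []
        for gcm in gcms:
            for scheme in cfg.thresholds:
                key_a = ("lulc", None, ssp, scheme)
                key_b = ("climate", gcm, ssp, scheme)
                key_c = ("both", gcm, ssp, scheme)
                if not all(k in diversity for k in (key_a, key_b, key_c)):
                    continue
                for mode, attr in (("loss", "L"), ("gain", "G")):
                    rasters.append(dv.InteractionRaster.from_counts(
                        getattr(diversity[key_a], attr),
                        getattr(diversity[key_b], attr),
                        getattr(diversity[key_c], attr),
                        mode,
                    ))
        if rasters:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    interaction_summaries[ssp] = dv.interaction_summary(rasters)
                except InputError:
                    pass

    # -- residual spatial autocorrelation ---------------------------------
    moran_rows = []
    for sp in modelled:
        occ = occurrences[sp]
        scorer = scorers[sp]
        rng = np.random.default_rng(species_seed(cfg.seed, "moran", sp))
        bg_cells = background.cell_ids
        if len(bg_cells) > cfg.moran_background_n:
            idx = rng.choice(len(bg_cells), cfg.moran_background_n,
                             replace=False)
            bg_cells = [bg_cells[i] for i in idx]
        cells = occ.cell_ids + bg_cells
        y = np.r_[np.ones(len(occ.cell_ids)), np.zeros(len(bg_cells))]
        scores = scorer.score_cells(std_current, cells)
        pts = np.array([stack.cell_center(c) for c in cells])
        span = max(stack.nrows, stack.ncols) * stack.cell_size
        breaks = np.linspace(0, span / 2, 6)[1:]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cg = dv.morans_correlogram(
                    pts, y - scores, np.r_[0.0, breaks],
                    n_permutations=cfg.moran_permutations,
                    seed=species_seed(cfg.seed, "moran_perm", sp),
                )
            moran_rows.append({
                "species": sp, "mean_I": cg.attrs["mean_I"],
                "frac_significant": cg.attrs["frac_significant"],
            })
        except InputError:
            continue
    moran = pd.DataFrame(moran_rows) if moran_rows else None
    if moran is not None and len(moran):
        manifest["stages"]["moran"] = {
            "mean_I": float(moran["mean_I"].mean()),
            "frac_significant": float(moran["frac_significant"].mean()),
        }

    manifest["stages"]["projection"] = {
        "keys_per_species": len(keys),
        "species_projected": len(binary_maps),
    }
    manifest["species"] = {
        sp: {
            "tier": r.tier, "n_cells": r.n_cells, "auc": r.auc,
            "tss": r.tss, "boyce": r.boyce, "rejected": r.rejected,
            "chosen_tree_index": r.chosen_tree_index, "note": r.note,
        }
        for sp, r in sorted(results.items())
    }
    manifest["config"] = asdict(cfg)

    result = RunResult(cfg, retained, results, binary_maps, diversity,
                       interaction_summaries, moran, manifest)
    if out_dir is not None:
        _write_outputs(result, fixture, Path(out_dir))
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not serializable: {type(o)}")


def _write_outputs(result: RunResult, fixture: Fixture, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True,
                   default=_json_default)
    )
    rows = [
        {"species": sp, "tier": r.tier, "n_cells": r.n_cells, "auc": r.auc,
         "tss": r.tss, "boyce": r.boyce, "rejected": r.rejected}
        for sp, r in sorted(result.species.items())
    ]
    pd.DataFrame(rows).to_csv(out / "evaluation.csv", index=False)
    for ssp, df in result.interaction_summaries.items():
        df.to_csv(out / f"interactions_{ssp}.csv")
    if result.moran is not None:
        result.moran.to_csv(out / "moran.csv", index=False)
    grids = out / "grids"
    grids.mkdir(exist_ok=True)
    stack = fixture.stack
    for key, dmaps in result.diversity.items():
        scenario, gcm, ssp, scheme = key
        tag = "__".join(str(p) for p in key)
        for name, grid in (("SR_current", dmaps.SR_current),
                           ("SR_future", dmaps.SR_future),
                           ("L", dmaps.L), ("G", dmaps.G),
                           ("delta", dmaps.delta)):
            gd.write_layer(grids / f"{name}__{tag}.asc",
                           grid.astype(float), stack.cell_size,
                           stack.origin, stack.nodata_mask)
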