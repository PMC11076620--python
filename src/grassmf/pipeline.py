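"""End-to-end orchestration: simulate -> preprocess -> multivariate model
-> path analysis -> multifunctionality, with a reproducible run manifest.

A run is fully described by a :class:`RunConfig` (loadable from YAML).  One
global seed is split into per-stage streams via ``numpy.random.SeedSequence``
(design, management, indicators, model initialisation, bootstrap); rerunning
with an identical config reproduces every output bit-for-bit.  The manifest
records the seed, a SHA-256 hash of the canonical config, stage row counts,
and the package version.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .latent_model import (
    build_design_matrix,
    effect_table,
    forward_select,
    screen_interactions,
    significant_counts,
)
from .multifunctionality import multifunctionality_report
from .path_effects import ASPECT_COLUMNS, decompose_effects, fit_path_model, select_sem_targets
from .preprocessing import preprocess_indicators
from .services import default_service_map, read_service_map
from .synthetic_data import (
    default_effect_spec,
    generate_design,
    generate_indicators,
    generate_management,
    scale_cells,
    write_dataset,
)

log = logging.getLogger(__name__)

ENV_CANDIDATES = ("soil_pH", "sand", "elevation", "inclination", "northness")


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "run_output"
    seed: int = 0
    n_pairs: int = 18
    cell_scale: float = 1.0
    service_map_path: str | None = "<default>"  # None is invalid; default map marker
    n_latent: int = 2
    tol: float = 1e-8
    max_iter: int = 2000
    select_env: bool = True
    screen_aspect_interactions: bool = True
    n_bootstrap: int = 10_000
    ci_level: float = 0.95
    bootstrap_unit: str = "pair"
    aicc_observations: str = "cells"

    def validate(self) -> None:
        if self.service_map_path is None:
            raise ConfigError("config field 'service_map_path' is missing")
        if self.n_pairs < 1:
            raise ConfigError("config field 'n_pairs' must be >= 1")
        if self.n_latent < 0:
            raise ConfigError("config field 'n_latent' must be >= 0")
        if self.n_bootstrap < 1:
            raise ConfigError("config field 'n_bootstrap' must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ConfigError("config field 'ci_level' must be in (0, 1)")
        if self.bootstrap_unit not in ("plot", "pair"):
            raise ConfigError("config field 'bootstrap_unit' must be 'plot' or 'pair'")
        if self.aicc_observations not in ("cells", "plots"):
            raise ConfigError("config field 'aicc_observations' must be 'cells' or 'plots'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to the outdir).

    Stage outputs (all delimited text): design/management/indicators CSVs,
    the preprocessed matrix, the coefficient/CI table of the multivariate
    model, the model-selection history, the long-format path-effect table,
    and the MLRR table for all three contrasts.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    seed_design, seed_mgmt, seed_ind, seed_model, seed_boot = seeds

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": asdict(config),
        "stages": {},
    }

    service_map = (
        default_service_map()
        if config.service_map_path == "<default>"
        else read_service_map(config.service_map_path)
    )

    # --- stage 1: simulate -------------------------------------------------
    cells = scale_cells(factor=config.cell_scale)
    design = generate_design(n_pairs=config.n_pairs, cell_counts=cells, seed=seed_design)
    effects = default_effect_spec()
    management = generate_management(design, seed=seed_mgmt)
    indicators = generate_indicators(design, management, effects, seed=seed_ind)
    write_dataset(outdir, design, management, indicators, effects, service_map)
    manifest["stages"]["simulate"] = {
        "n_plots": len(design),
        "n_farms": design["farm_id"].nunique(),
        "n_pairs": design["pair_id"].nunique(),
        "seeds": {"design": seed_design, "management": seed_mgmt, "indicators": seed_ind},
    }

    # --- stage 2: preprocess ----------------------------------------------
    pre = preprocess_indicators(indicators, service_map)
    pre.rename_axis("plot_id").to_csv(outdir / "preprocessed.csv")
    manifest["stages"]["preprocess"] = {"n_indicators": pre.shape[1]}

    # --- stage 3: multivariate latent-variable model -----------------------
    x_base = build_design_matrix(design)
    blocks = design["pair_id"]
    fit_kwargs = dict(
        n_latent=config.n_latent,
        tol=config.tol,
        max_iter=config.max_iter,
        seed=seed_model,
        aicc_observations=config.aicc_observations,
    )
    y = pre.set_axis(design.index, axis=0)
    if config.select_env:
        from .preprocessing import standardize_env

        env = standardize_env(design[list(ENV_CANDIDATES)].astype(float))
        selection = forward_select(y, x_base, env, blocks=blocks, **fit_kwargs)
        selection.history.to_csv(outdir / "model_selection.csv", index=False)
        fit = selection.fit
        x_current = pd.concat([x_base, env[selection.selected]], axis=1)
        selected_env = selection.selected
    else:
        from .latent_model import fit_gllvm

        fit = fit_gllvm(y, x_base, blocks=blocks, **fit_kwargs)
        x_current, selected_env = x_base, []

    interaction_winner = None
    if config.screen_aspect_interactions:
        screen = screen_interactions(y, x_current, blocks=blocks, **fit_kwargs)
        interaction_winner = screen.winner
        screen.table.to_csv(outdir / "interaction_screen.csv", index=False)
        if screen.winner == "interactions":
            fit = screen.interaction_fit

    effects_tbl = effect_table(fit)
    effects_tbl.to_csv(outdir / "gllvm_effects.csv", index=False)
    manifest["stages"]["latent_model"] = {
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "aicc": float(fit.aicc),
        "log_likelihood": float(fit.log_likelihood),
        "pair_variance": float(fit.pair_variance),
        "selected_env": selected_env,
        "interaction_winner": interaction_winner,
    }

    # --- stage 4: path analysis -------------------------------------------
    targets = select_sem_targets(effects_tbl)
    sem_data = design.merge(management, on="plot_id")
    sem_rows = []
    pre_by_plot = pre.copy()
    for ind_name in targets:
        data = sem_data.assign(**{ind_name: pre_by_plot[ind_name].to_numpy()})
        pfit = fit_path_model(data, ind_name)
        for aspect in ASPECT_COLUMNS:
            sem_rows.append(decompose_effects(pfit, aspect).to_frame())
    sem_table = (
        pd.concat(sem_rows, ignore_index=True)
        if sem_rows
        else pd.DataFrame(columns=["indicator", "aspect", "component", "estimate", "significant"])
    )
    sem_table.to_csv(outdir / "sem_effects.csv", index=False)
    manifest["stages"]["path_analysis"] = {"n_indicators_modelled": len(targets)}

    # --- stage 5: multifunctionality ---------------------------------------
    reports = {}
    frames = []
    for i, aspect in enumerate(ASPECT_COLUMNS):
        rep = multifunctionality_report(
            indicators,
            design,
            aspect,
            service_map,
            B=config.n_bootstrap,
            level=config.ci_level,
            seed=seed_boot + i,
            unit=config.bootstrap_unit,
        )
        reports[aspect] = rep
        frames.append(rep.to_frame())
    multifun_table = pd.concat(frames, ignore_index=True)
    multifun_table.to_csv(outdir / "multifun.csv", index=False)
    manifest["stages"]["multifunctionality"] = {
        "B": config.n_bootstrap,
        "seed": seed_boot,
        "n_redrawn": {a: reports[a].n_redrawn for a in reports},
    }

    manifest["outputs"] = sorted(p.name for p in outdir.glob("*.csv"))
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def report(outdir) -> str:
    """Human-readable summary of a completed run directory."""
    outdir = Path(outdir)
    lines = ["grassmf run summary", "===================", ""]
    manifest_path = outdir / "manifest.yaml"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        lines.append(f"seed {manifest['seed']}, config hash {manifest['config_hash']}")
        lines.append("")

    effects_path = outdir / "gllvm_effects.csv"
    if effects_path.exists():
        tbl = pd.read_csv(effects_path)
        counts = significant_counts(tbl[tbl["predictor"].isin(ASPECT_COLUMNS)])
        lines.append("significant indicator effects per management aspect:")
        for _, row in counts.iterrows():
            lines.append(
                f"  {row['predictor']}: {row['n_significant']} of "
                f"{tbl['indicator'].nunique()} ({row['n_positive']} up, {row['n_negative']} down)"
            )
        lines.append("")

    sem_path = outdir / "sem_effects.csv"
    if sem_path.exists():
        sem = pd.read_csv(sem_path)
        if len(sem) == 0:
            lines.append("path analysis: no indicators with significant aspect effects; stage not run")
        else:
            n_ind = sem["indicator"].nunique()
            lines.append(f"path analysis over {n_ind} indicators (standardized total effects):")
            totals = sem[sem["component"] == "total"]
            for aspect, grp in totals.groupby("aspect"):
                lines.append(
                    f"  {aspect}: mean |total| = {grp['estimate'].abs().mean():.3f}, "
                    f"{int(grp['significant'].sum())} significant"
                )
        lines.append("")

    multifun_path = outdir / "multifun.csv"
    if multifun_path.exists():
        mf = pd.read_csv(multifun_path)
        lines.append("multifunctionality (MLRR percent effects, 95% bootstrap CI):")
        for _, row in mf[mf["scope"].isin(["category", "overall"])].iterrows():
            ci = (
                f" [CI {row['ci_low']:+.3f}, {row['ci_high']:+.3f}]"
                if np.isfinite(row["ci_low"])
                else ""
            )
            lines.append(
                f"  {row['aspect']} / {row['name']}: MLRR {row['estimate']:+.3f}"
                f" ({row['percent']:+.1f}%){ci}"
            )
        # single-service dominance within categories
        svc = mf[mf["scope"] == "service"]
        sm = default_service_map()
        cat_of = sm.groupby("cices_service")["category"].first()
        for aspect, grp in svc.groupby("aspect"):
            vals = grp.set_index("name")["estimate"]
            for c in cat_of.unique():
                members = vals[[s for s in vals.index if cat_of.get(s) == c]].abs()
                tot = members.sum()
                if tot > 0 and (members / tot > 0.5).any():
                    dom = members.idxmax()
                    lines.append(
                        f"  note: {aspect}/{c} dominated by service '{dom}' "
                        f"({100 * members.max() / tot:.0f}% of summed |LRR|)"
                    )
        lines.append("")

    truth_path = outdir / "true_effects.yaml"
    if truth_path.exists() and multifun_path.exists():
        with open(truth_path) as fh:
            truth = yaml.safe_load(fh)
        mf = pd.read_csv(multifun_path)
        sm = default_service_map()
        lines.append("generator-truth recovery (overall MLRR vs. truth):")
        from .services import service_weight_matrix

        a = service_weight_matrix(sm)
        signs = np.where(sm.set_index("indicator")["disservice_flag"], -1.0, 1.0)
        for aspect in ASPECT_COLUMNS:
            mult = pd.Series(truth["multipliers"][aspect]).reindex(a.columns)
            true_overall = float((a @ (np.log(mult) * signs)).mean())
            est = mf[(mf["aspect"] == aspect) & (mf["scope"] == "overall")]["estimate"].iloc[0]
            lines.append(f"  {aspect}: estimated {est:+.3f}, truth {true_overall:+.3f}")
        lines.append("")

    return "\n".join(lines)
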