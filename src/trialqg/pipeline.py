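"""End-to-end orchestration: simulate/load → ANOVA → genetic summary →
correlations → stepwise → clustering, with every artifact on disk.

The pipeline is a plain function over a :class:`RunConfig`; the CLI in
:mod:`trialqg.cli` is a thin wrapper around it.  Outputs are TSV/JSON so
every file round-trips through pandas, and a run manifest records the
seed, the configuration hash and package versions for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .anova import combined_anova, rcbd_anova
from .cluster import cluster_accessions
from .covcorr import trait_correlations
from .errors import ConfigError
from .genetics import DEFAULT_SELECTION_INTENSITY, percent_reduction, summarize_trial
from .simulate import SyntheticTrialSpec, bluegrass_like_spec, generate_trial
from .stepwise import DEFAULT_ALPHA, yield_regression
from .trial import PhenotypeTable, read_phenotypes, write_phenotypes

log = logging.getLogger("trialqg")

STAGES = ("simulate", "anova", "genparams", "corr", "stepwise", "cluster")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``input_path`` (a long-format phenotype CSV/TSV) or
    ``synthetic_spec`` must be provided; with neither, a bluegrass-like
    synthetic trial is generated at ``seed``.
    """

    outdir: Path
    input_path: Path | None = None
    synthetic_spec: SyntheticTrialSpec | None = None
    stages: tuple = STAGES
    seed: int = 0
    k: float = DEFAULT_SELECTION_INTENSITY
    strict_printed_ga: bool = False
    alpha_enter: float = DEFAULT_ALPHA
    alpha_stay: float = DEFAULT_ALPHA
    n_groups: int = 3
    response_traits: tuple = ("FY", "DY")
    control_regime: str | None = None
    make_figures: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}; valid: {STAGES}")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigError(f"input path does not exist: {self.input_path}")


def _config_hash(cfg: RunConfig) -> str:
    payload = {
        k: str(v)
        for k, v in vars(cfg).items()
        if k not in {"synthetic_spec"}
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the requested stages; returns {artifact name: path}.

    Any stage error propagates as the underlying exception with the
    stage named in the log, so shell callers exit non-zero.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- input ------------------------------------------------------
    if cfg.input_path is not None:
        table = read_phenotypes(cfg.input_path)
        log.info("loaded %d rows from %s", len(table.data), cfg.input_path)
    else:
        spec = cfg.synthetic_spec or bluegrass_like_spec(seed=cfg.seed)
        table = generate_trial(spec, seed=cfg.seed)
        log.info("stage simulate: generated %d rows (seed=%d)", len(table.data), cfg.seed)
        if "simulate" in cfg.stages:
            artifacts["phenotypes"] = write_phenotypes(table, out / "phenotypes.csv")

    control = cfg.control_regime or table.regimes[0]
    stress = [r for r in table.regimes if r != control]

    # --- per-environment and combined ANOVA -------------------------
    if "anova" in cfg.stages:
        per_env = []
        for trait in table.traits:
            for year in table.years:
                for regime in table.regimes:
                    a = rcbd_anova(table, trait, year, regime)
                    t = a.to_frame()
                    t.insert(0, "regime", regime)
                    t.insert(0, "year", year)
                    t.insert(0, "trait", trait)
                    per_env.append(t)
        env_df = pd.concat(per_env, ignore_index=True)
        p = out / "anova_per_environment.tsv"
        env_df.to_csv(p, sep="\t", index=False)
        artifacts["anova_per_environment"] = p
        log.info("stage anova: %d per-environment tables", len(per_env))

        if len(table.years) >= 2 and len(table.regimes) >= 2:
            combined = []
            for trait in table.traits:
                c = combined_anova(table, trait).to_frame()
                c.insert(0, "trait", trait)
                combined.append(c)
            cdf = pd.concat(combined, ignore_index=True)
            p = out / "anova_combined.tsv"
            cdf.to_csv(p, sep="\t", index=False)
            cdf.to_json(out / "anova_combined.json", orient="records", indent=1)
            artifacts["anova_combined"] = p

    # --- genetic parameters ------------------------------------------
    if "genparams" in cfg.stages:
        summary = summarize_trial(table, k=cfg.k, strict_printed_form=cfg.strict_printed_ga)
        p = out / "genetic_summary.tsv"
        summary.to_csv(p, sep="\t", index=False, float_format="%.6g")
        artifacts["genetic_summary"] = p
        log.info("stage genparams: %d summary rows", len(summary))

        if stress:
            red_rows = []
            for trait in table.traits:
                for year in table.years:
                    mc = table.subset(trait=trait, year=year, regime=control)["value"].mean()
                    for s in stress:
                        ms = table.subset(trait=trait, year=year, regime=s)["value"].mean()
                        red_rows.append(
                            dict(
                                trait=trait, year=year, control=control, stress=s,
                                mean_control=mc, mean_stress=ms,
                                reduction_pct=percent_reduction(mc, ms),
                            )
                        )
            p = out / "stress_reductions.tsv"
            pd.DataFrame(red_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
            artifacts["stress_reductions"] = p

    # --- correlations -------------------------------------------------
    if "corr" in cfg.stages and len(table.traits) >= 2:
        for regime in table.regimes:
            cm = trait_correlations(table, regime=regime)
            for name, mat in [("phenotypic", cm.r_p), ("genotypic", cm.r_g)]:
                p = out / f"corr_{name}_{regime}.tsv"
                mat.to_csv(p, sep="\t", float_format="%.6g")
                artifacts[f"corr_{name}_{regime}"] = p
            if cfg.make_figures:
                from .plots import plot_correlation_triangles

                p = out / f"corr_triangles_{regime}.png"
                plot_correlation_triangles(cm, p, title=f"trait correlations, {regime}")
                artifacts[f"corr_figure_{regime}"] = p
        log.info("stage corr: matrices for %d regime(s)", len(table.regimes))

    # --- stepwise ------------------------------------------------------
    if "stepwise" in cfg.stages:
        responses = [t for t in cfg.response_traits if t in table.traits]
        predictors = [t for t in table.traits if t not in cfg.response_traits]
        rows = []
        for regime in table.regimes:
            for resp in responses:
                if not predictors:
                    continue
                res = yield_regression(
                    table, resp, predictors, regime,
                    alpha_enter=cfg.alpha_enter, alpha_stay=cfg.alpha_stay,
                )
                t = res.steps.copy()
                t.insert(0, "response", resp)
                t.insert(0, "regime", regime)
                t["intercept"] = res.intercept
                rows.append(t)
        if rows:
            sdf = pd.concat(rows, ignore_index=True)
            p = out / "stepwise.tsv"
            sdf.to_csv(p, sep="\t", index=False, float_format="%.6g")
            artifacts["stepwise"] = p
            log.info("stage stepwise: %d fitted models", len(rows))

    # --- clustering ----------------------------------------------------
    if "cluster" in cfg.stages:
        group_rows = []
        for regime in table.regimes:
            means = table.genotype_means(regime=regime)
            res = cluster_accessions(means, n_groups=min(cfg.n_groups, len(means)))
            g = res.groups.rename("group").reset_index()
            g.insert(1, "regime", regime)
            group_rows.append(g)
            if cfg.make_figures:
                from .plots import plot_cluster_heatmap

                p = out / f"cluster_heatmap_{regime}.png"
                plot_cluster_heatmap(res, p, title=f"trait profiles, {regime}")
                artifacts[f"cluster_figure_{regime}"] = p
        gdf = pd.concat(group_rows, ignore_index=True)
        p = out / "cluster_groups.tsv"
        gdf.to_csv(p, sep="\t", index=False)
        artifacts["cluster_groups"] = p
        log.info("stage cluster: %d accessions grouped", gdf["genotype"].nunique())

    # --- manifest ------------------------------------------------------
    manifest = {
        "package": "trialqg",
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "config_hash": _config_hash(cfg),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "n_rows": int(len(table.data)),
        "traits": table.traits,
        "years": table.years,
        "regimes": table.regimes,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = mpath
    return artifacts
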