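"""End-to-end genetic-evaluation workflow.

Stages, in order: data intake (files or a simulation scenario), pedigree
validation and statistics, trait derivation and outlier QC, descriptive
summaries, fixed-effect screening, multivariate model fitting over a
candidate menu with AIC ranking, genetic parameters, breeding values and
genetic trends.  Every stage writes a delimited-text artifact into the
output directory plus a JSON manifest (seed, config hash, package
versions); a stage failure halts the run with the stage name, retaining
artifacts already written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blup import solve_mme, trend_table
from .design import pedigree_structures
from .models import model_preset
from .pedigree import (
    inbreeding,
    pedigree_statistics,
    read_pedigree,
    sort_topological,
    validate_and_repair,
)
from .reml import fit_reml, genetic_parameters, select_model
from .traits import derive_traits, filter_outliers, screen_fixed_effects, summary_table


@dataclass
class PipelineConfig:
    output_dir: str
    pedigree_file: str | None = None
    phenotype_file: str | None = None
    scenario: str | None = None  # "default" or None
    scenario_overrides: dict = field(default_factory=dict)
    seed: int = 1
    traits: list = field(default_factory=lambda: ["BWT", "WWT"])
    qc_sd_multiplier: float = 3.0
    screen_factors: list = field(
        default_factory=lambda: ["birth_year", "birth_month", "sex", "birth_type",
                                 "dam_age", "parity"]
    )
    models: list = field(default_factory=lambda: ["model1", "model2", "model3", "model4"])
    reml: dict = field(default_factory=dict)
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _intake(cfg: PipelineConfig):
    if (cfg.scenario is None) == (cfg.pedigree_file is None):
        raise ValueError("exactly one input mode: scenario OR pedigree+phenotype files")
    if cfg.scenario is not None:
        from .simulate import SimulationScenario, default_scenario, simulate_dataset

        sc = default_scenario()
        for k, v in cfg.scenario_overrides.items():
            setattr(sc, k, np.asarray(v) if isinstance(getattr(sc, k), np.ndarray) else v)
        ped, phen, bvs = simulate_dataset(sc, seed=cfg.seed)
        return ped, phen, bvs
    ped = read_pedigree(cfg.pedigree_file)
    ped, report = validate_and_repair(ped)
    ped = sort_topological(ped)
    phen = pd.read_csv(cfg.phenotype_file, parse_dates=["birth_date"])
    return ped, phen, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns a dict of in-memory artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "intake"
    try:
        ped, phen, bvs = _intake(cfg)
        bundle["pedigree"] = ped
        bundle["phenotypes_raw"] = phen

        stage = "pedigree_stats"
        F = inbreeding(ped)
        stats = pedigree_statistics(ped, F)
        stats.to_series().to_csv(out / "pedigree_stats.csv", header=False)
        bundle["pedigree_stats"] = stats

        stage = "derive_traits"
        phen, skip_log = derive_traits(phen)
        skip_log.to_csv(out / "derive_skipped.csv", index=False)

        stage = "qc"
        removal_logs = []
        all_traits = [t for t in ["BWT", "WWT", "PWGR", "PWKR", "PWGE"] if t in phen]
        for t in all_traits:
            kept, removed = filter_outliers(phen[t], cfg.qc_sd_multiplier)
            phen[t] = kept
            removed["trait"] = t
            removal_logs.append(removed)
        qc_log = pd.concat(removal_logs, ignore_index=True)
        qc_log.to_csv(out / "qc_removals.csv", index=False)
        bundle["phenotypes"] = phen
        bundle["qc_log"] = qc_log

        stage = "summary"
        summ = summary_table(phen, all_traits)
        summ.to_csv(out / "trait_summary.csv")
        bundle["summary"] = summ

        stage = "screening"
        screens = {}
        sig = {}
        for t in cfg.traits:
            res = screen_fixed_effects(phen, cfg.screen_factors, t)
            screens[t] = res
            sig[t] = res["significant"]
            res["anova"].to_csv(out / f"screen_anova_{t}.csv")
            res["ls_means"].to_csv(out / f"screen_lsmeans_{t}.csv", index=False)
        bundle["screening"] = screens

        stage = "model_fitting"
        structures = pedigree_structures(ped)
        fixed = {t: sig[t] or ["sex"] for t in cfg.traits}
        candidates = [model_preset(m, cfg.traits, fixed) for m in cfg.models]
        if len(candidates) > 1:
            ranking = select_model(candidates, phen, ped, structures=structures,
                                   **cfg.reml)
            fits = ranking.attrs["fits"]
            best_name = ranking["model"].iloc[0]
        else:
            vc = fit_reml(candidates[0], phen, ped, structures=structures, **cfg.reml)
            fits = {candidates[0].name: vc}
            ranking = pd.DataFrame(
                [dict(model=candidates[0].name, logL=vc.logL,
                      P=vc.n_free_parameters, AIC=vc.AIC, converged=vc.converged,
                      dAIC=0.0)]
            )
            best_name = candidates[0].name
        ranking.to_csv(out / "model_comparison.csv", index=False)
        bundle["model_comparison"] = ranking
        best = fits[best_name]
        bundle["fits"] = fits

        stage = "genetic_parameters"
        gp = genetic_parameters(best)
        gp.table.to_csv(out / "genetic_parameters.csv")
        if gp.r_a is not None:
            gp.r_a.to_csv(out / "genetic_correlations_autosomal.csv")
        if gp.r_s is not None:
            gp.r_s.to_csv(out / "genetic_correlations_xlinked.csv")
        bundle["genetic_parameters"] = gp

        stage = "blup"
        ebv = solve_mme(best, phen, ped, structures=structures)
        ebv.to_csv(out / "ebv.csv")
        bundle["ebv"] = ebv

        stage = "trends"
        trends = trend_table(ebv, cfg.traits)
        trends.to_csv(out / "genetic_trends.csv", index=False)
        bundle["trends"] = trends

        stage = "manifest"
        manifest = dict(
            package_version=__version__,
            seed=cfg.seed,
            config_hash=cfg.digest(),
            numpy=np.__version__,
            pandas=pd.__version__,
            stages=list(bundle.keys()),
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle["manifest"] = manifest
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    return bundle


def make_report(bundle: dict) -> str:
    """Human-readable summary of a pipeline bundle."""
    lines = ["hircus genetic-evaluation report", "=" * 34, ""]
    if "pedigree_stats" in bundle:
        st = bundle["pedigree_stats"]
        lines += ["Pedigree", "-" * 8, st.to_series().to_string(), ""]
    if "summary" in bundle:
        lines += ["Trait summary", "-" * 13, bundle["summary"].round(3).to_string(), ""]
    if "model_comparison" in bundle:
        lines += ["Model comparison (AIC)", "-" * 22,
                  bundle["model_comparison"].round(2).to_string(index=False), ""]
    if "genetic_parameters" in bundle:
        lines += ["Genetic parameters", "-" * 18,
                  bundle["genetic_parameters"].table.round(3).to_string(), ""]
    if "trends" in bundle:
        tr = bundle["trends"]
        if len(tr):
            lines += ["Genetic trends (per year)", "-" * 25,
                      tr.round(5).to_string(index=False), ""]
        else:
            lines += ["Genetic trends: no breeding values available", ""]
    if "ebv" not in bundle or bundle.get("ebv") is None:
        lines += ["Breeding values: absent", ""]
    return "\n".join(lines)
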