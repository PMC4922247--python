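"""End-to-end orchestration: simulate -> respirometry -> phenotype -> HMM ->
activity -> mixed models, as one reproducible run.

Every stage logs row counts and drop reasons; the run writes a manifest
(config hash, seed, package version) sufficient to reproduce it, a cohort
accounting summary (tagged -> predated -> transmitter failure -> analysed),
and the three report tables: PCA loadings, the model-selection grid, and
the optimal-model summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hmm import ActivityHMM
from .lmm import model_select
from .phenotype import corrected_trait_table
from .respirometry import TraitConfig, traits_from_trace, traits_table
from .synthetic import SimConfig, generate_cohort, phenotype_table, \
    simulate_respirometry_trace, simulate_track
from .trajectory import ActivityConfig, activity_table

logger = logging.getLogger(__name__)

ACTIVITY_MEASURES = ("a_day", "u_max", "u_inst", "ar_day")


@dataclass
class PipelineConfig:
    """One config object for a full synthetic run.

    The exclusion counts emulate the field outcome of the emulated study:
    of the tagged cohort, some fish are eaten by pike (their tracks merge
    with a predator's and are excluded) and some transmitters fail on
    release; only the remainder is analysed.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    traits: TraitConfig = field(default_factory=TraitConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    n_predated: int = 3
    n_transmitter_failures: int = 4
    hmm_restarts: int = 3
    hmm_seed: int = 11
    lmm_seed: int = 0
    out_dir: str = "scopetrack_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim.get("lake_boundary"), list):
            sim["lake_boundary"] = tuple(tuple(p) for p in sim["lake_boundary"])
        return cls(
            sim=SimConfig(**sim),
            traits=TraitConfig(**d.pop("traits", {})),
            activity=ActivityConfig(**d.pop("activity", {})),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced, plus the accounting that explains it."""

    config: PipelineConfig
    cohort_accounting: dict
    traits: pd.DataFrame
    covariates: pd.DataFrame
    pca_loadings: pd.DataFrame
    daily_activity: pd.DataFrame
    speeds: pd.DataFrame
    selection_tables: dict
    optimal_summaries: dict
    manifest: dict


def apply_cohort_exclusions(
    fish_ids: list[str], n_predated: int, n_failed: int, seed: int
) -> dict:
    """Field-season bookkeeping: tagged -> predated -> failed -> analysed."""
    if n_predated + n_failed > len(fish_ids):
        raise ValueError("cannot exclude more fish than were tagged")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    order = rng.permutation(len(fish_ids))
    predated = sorted(fish_ids[i] for i in order[:n_predated])
    failed = sorted(fish_ids[i] for i in order[n_predated : n_predated + n_failed])
    analysed = sorted(set(fish_ids) - set(predated) - set(failed))
    return {
        "n_tagged": len(fish_ids),
        "n_predated": len(predated),
        "n_transmitter_failures": len(failed),
        "n_analysed": len(analysed),
        "predated": predated,
        "failed": failed,
        "analysed": analysed,
    }


def run(config: PipelineConfig, write: bool = True) -> RunReport:
    """Execute the full synthetic pipeline under one config."""
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: cohort + lab phase -------------------------------------
    phenotypes = generate_cohort(config.sim)
    pheno_df = phenotype_table(phenotypes)
    logger.info("stage simulate: %d fish generated", len(phenotypes))

    all_traits = []
    for p in phenotypes:
        trace = simulate_respirometry_trace(p, config.sim)
        all_traits.append(traits_from_trace(trace, config.traits))
    traits_df = traits_table(all_traits)
    logger.info(
        "stage respirometry: %d fish, %d cycles rejected in total",
        len(traits_df), int(traits_df["n_rejected"].sum()),
    )

    covariates, pca = corrected_trait_table(traits_df, pheno_df)
    logger.info("stage phenotype: PCA cumulative variance (3 axes) = %.1f%%",
                pca.cumulative[2])

    # --- stage 2: field phase --------------------------------------------
    accounting = apply_cohort_exclusions(
        [p.fish_id for p in phenotypes],
        config.n_predated,
        config.n_transmitter_failures,
        config.sim.seed,
    )
    logger.info(
        "cohort accounting: %d tagged - %d predated - %d failed = %d analysed",
        accounting["n_tagged"], accounting["n_predated"],
        accounting["n_transmitter_failures"], accounting["n_analysed"],
    )
    analysed = set(accounting["analysed"])
    tracks = [
        simulate_track(p, config.sim) for p in phenotypes if p.fish_id in analysed
    ]
    fixes = pd.concat([t.fixes for t in tracks], ignore_index=True)
    release_times = {t.fish_id: t.release_time for t in tracks}
    logger.info("stage track: %d fixes for %d fish", len(fixes), len(tracks))

    hmm = ActivityHMM.from_fixes(
        fixes.drop(columns=["true_state"], errors="ignore"),
        burst_interval=config.sim.burst_interval,
    )
    hmm_fit = hmm.fit(n_restarts=config.hmm_restarts, seed=config.hmm_seed)
    p_active = hmm_fit.posterior_table()
    logger.info("stage hmm: llf=%.1f, stationary P(active)=%.3f",
                hmm_fit.llf, hmm_fit.spec.stationary_active)

    daily, speeds = activity_table(fixes, release_times, p_active, config.activity)
    logger.info("stage activity: %d fish-days, %d speed pairs (%d retained)",
                len(daily), len(speeds), int(speeds["retained"].sum()))

    # --- stage 3: mixed models -------------------------------------------
    obs = _observation_tables(daily, speeds, covariates)
    selection_tables, optimal = {}, {}
    for measure in ACTIVITY_MEASURES:
        data = obs[measure]
        if data["fish_id"].nunique() < 3:
            logger.warning("measure %s: too few fish, models skipped", measure)
            continue
        try:
            sel = model_select(
                data, response="value", measure=measure, seed=config.lmm_seed
            )
        except Exception as exc:  # noqa: BLE001
            logger.warning("model selection failed for %s: %s", measure, exc)
            continue
        selection_tables[measure] = sel.table
        best = sel.best_reml
        optimal[measure] = {
            "model": sel.best_name,
            "params": best.params.to_dict(),
            "bse": best.bse.to_dict(),
            "sigma_a": best.sigma_a,
            "sigma_j_median": float(best.sigma_j.median()),
            "sigma_j_min": float(best.sigma_j.min()),
            "sigma_j_max": float(best.sigma_j.max()),
            "icc": best.icc_summary(),
        }
        logger.info("measure %s: selected %s, median ICC %.3f",
                    measure, sel.best_name, best.icc_summary()["median"])

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "n_fish": config.sim.n_fish,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
    }
    report = RunReport(
        config=config,
        cohort_accounting=accounting,
        traits=traits_df,
        covariates=covariates,
        pca_loadings=pca.loadings_report(),
        daily_activity=daily,
        speeds=speeds,
        selection_tables=selection_tables,
        optimal_summaries=optimal,
        manifest=manifest,
    )
    if write:
        _write_report(report, out)
    return report


def _observation_tables(daily, speeds, covariates, min_obs: int = 3) -> dict:
    """Per-measure long tables joining activity observations to covariates.

    Fish contributing fewer than ``min_obs`` observations to a measure are
    dropped from that measure's model (their residual SD is unidentifiable).
    """
    out = {}
    for measure in ("a_day", "u_max", "ar_day"):
        df = daily[["fish_id", "day", measure]].dropna()
        df = df.rename(columns={measure: "value"})
        out[measure] = df.merge(covariates, on="fish_id", how="inner")
    sp = speeds.loc[speeds["retained"], ["fish_id", "day", "u_inst"]].rename(
        columns={"u_inst": "value"}
    )
    out["u_inst"] = sp.merge(covariates, on="fish_id", how="inner")
    for measure, df in out.items():
        counts = df.groupby("fish_id")["value"].size()
        keep = counts[counts >= min_obs].index
        if len(keep) < df["fish_id"].nunique():
            logger.warning(
                "measure %s: dropped %d fish with <%d observations",
                measure, df["fish_id"].nunique() - len(keep), min_obs,
            )
        out[measure] = df[df["fish_id"].isin(keep)]
    return out


def _write_report(report: RunReport, out: Path) -> None:
    report.traits.to_csv(out / "traits.csv", index=False)
    report.covariates.to_csv(out / "covariates.csv", index=False)
    report.pca_loadings.to_csv(out / "pca_loadings.csv")
    report.daily_activity.to_csv(out / "daily_activity.csv", index=False)
    report.speeds.to_csv(out / "u_inst.csv", index=False)
    for measure, table in report.selection_tables.items():
        table.to_csv(out / f"selection_{measure}.csv", index=False)
    with open(out / "optimal_models.json", "w") as fh:
        json.dump(report.optimal_summaries, fh, indent=2)
    with open(out / "cohort_accounting.json", "w") as fh:
        json.dump(report.cohort_accounting, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
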