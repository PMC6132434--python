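"""Pipeline configuration, validation and file plumbing.

All tabular I/O is comma-delimited UTF-8 with a header row.  The phenotype
table carries person_id, study_id, age, sex and any subset of the outcome
columns (wc, sbp, hdl, ldl, trig, insulin, glucose); activity summaries come
from :mod:`isosub.epochs`.  Sex is coded 0 = female (reference), 1 = male.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import epochs, models, reference, reporting, simulate
from .exceptions import ConfigurationError, InputError

log = logging.getLogger("isosub")

__all__ = ["PipelineConfig", "assign_age_group", "validate_inputs",
           "run_pipeline", "load_config"]

PHENOTYPE_COLUMNS = ["person_id", "study_id", "age", "sex"]


@dataclass
class PipelineConfig:
    """Everything the five pipeline stages need, loadable from YAML."""

    out_dir: Path = Path("results")
    epoch_input: Optional[Path] = None
    phenotype_input: Optional[Path] = None
    seed: int = 0
    # epoch processing
    epoch: epochs.EpochConfig = field(default_factory=epochs.EpochConfig)
    # modelling
    outcomes: tuple[str, ...] = ("wc",)
    strata: tuple[str, ...] = models.AGE_GROUPS
    estimator: str = "random_effects_gls"
    variance: str = "cluster_robust"
    exposure_unit: float = 10.0
    # simulation (used by the simulate/run commands)
    n_studies: int = 13
    persons_per_study: int = 20
    n_days: int = 3
    nonwear_blocks: int = 1

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            n_studies=self.n_studies, persons_per_study=self.persons_per_study,
            n_days=self.n_days, nonwear_blocks=self.nonwear_blocks,
            seed=self.seed)

    def digest(self) -> str:
        payload = yaml.safe_dump({k: str(v) for k, v in dataclasses.asdict(self).items()},
                                 sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path=None, **overrides) -> PipelineConfig:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    thresholds = epochs.IntensityThresholds(
        sedentary_max=int(raw.pop("sedentary_max", 100)),
        light_max=int(raw.pop("light_max", 2295)))
    epoch_keys = {f.name for f in dataclasses.fields(epochs.EpochConfig)} - {"thresholds"}
    epoch_raw = {k: raw.pop(k) for k in list(raw) if k in epoch_keys}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.epoch = epochs.EpochConfig(thresholds=thresholds, **epoch_raw)
    cfg.out_dir = Path(cfg.out_dir)
    if cfg.epoch_input is not None:
        cfg.epoch_input = Path(cfg.epoch_input)
    if cfg.phenotype_input is not None:
        cfg.phenotype_input = Path(cfg.phenotype_input)
    for t in ("outcomes", "strata"):
        setattr(cfg, t, tuple(getattr(cfg, t)))
    return cfg


def assign_age_group(age: float) -> str:
    """children < 10, adolescents 10 to < 15, older >= 15 years."""
    if age < 10:
        return "children"
    if age < 15:
        return "adolescents"
    return "older"


def validate_inputs(phenotypes: pd.DataFrame, summaries: pd.DataFrame
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Join phenotypes with activity summaries into a modelling table.

    Returns the validated cohort plus a human-readable issue report.  Hard
    errors: duplicated person ids.  Reported but non-fatal: join misses,
    ages outside [4, 18] (rows rejected), compositions that do not sum to
    wear time (rows rejected).
    """
    issues: list[str] = []
    for name, df in (("phenotype", phenotypes), ("summary", summaries)):
        dup = df["person_id"][df["person_id"].duplicated()]
        if len(dup):
            raise InputError(f"duplicate person_id in {name} table: "
                             f"{sorted(set(dup))[:10]}")
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in phenotypes.columns]
    if missing_cols:
        raise InputError(f"phenotype table lacks columns {missing_cols}")

    merged = phenotypes.merge(summaries, on="person_id", how="outer",
                              indicator=True)
    for pid in merged.loc[merged["_merge"] == "left_only", "person_id"]:
        issues.append(f"{pid}: phenotype row without accelerometer summary; excluded")
    for pid in merged.loc[merged["_merge"] == "right_only", "person_id"]:
        issues.append(f"{pid}: accelerometer summary without phenotype row; excluded")
    cohort = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()

    lo, hi = reference.AGE_RANGE
    bad_age = (cohort["age"] < lo) | (cohort["age"] > hi)
    for row in cohort.loc[bad_age].itertuples():
        issues.append(f"{row.person_id}: age {row.age} outside [{lo}, {hi}]; rejected")
    cohort = cohort[~bad_age].copy()

    cohort = cohort.rename(columns={"mean_sedentary": "sed", "mean_lpa": "lpa",
                                    "mean_mvpa": "mvpa", "mean_wear": "wear"})
    gap = (cohort["sed"] + cohort["lpa"] + cohort["mvpa"] - cohort["wear"]).abs()
    bad_sum = gap > 1e-6
    for row in cohort.loc[bad_sum].itertuples():
        issues.append(f"{row.person_id}: sedentary+LPA+MVPA != wear "
                      f"(off by {gap[row.Index]:.3g} min); rejected")
    cohort = cohort[~bad_sum].copy()

    cohort["age_group"] = cohort["age"].map(assign_age_group)
    cohort = cohort.reset_index(drop=True)
    return cohort, issues


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """simulate (when no inputs are configured) -> process -> fit -> report.

    Returns the paths of every artifact written.  Deterministic given the
    seed; the seed, config hash and per-stage row counts are logged.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d config=%s", config.seed, config.digest())
    artifacts: dict[str, Path] = {}

    epoch_path, pheno_path = config.epoch_input, config.phenotype_input
    if epoch_path is None or pheno_path is None:
        _stage("simulate")
        sim = config.simulation_config()
        cohort = simulate.simulate_cohort(sim)
        plans = simulate.plan_days(cohort, sim)
        rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 3]))
        streams = []
        by_person: dict[str, list] = {}
        for p in plans:
            by_person.setdefault(p.person_id, []).append(p)
        for pid, pl in by_person.items():
            streams.append(simulate.realize_person_stream(
                pl, config.epoch.thresholds, rng))
        with_outcomes = simulate.simulate_outcomes(cohort, sim)
        pheno_cols = PHENOTYPE_COLUMNS + [o for o in models.OUTCOMES
                                          if o in with_outcomes.columns]
        epoch_path = out / "epoch_stream.csv"
        pheno_path = out / "phenotypes.csv"
        epochs.write_epoch_stream(streams, epoch_path)
        with_outcomes[pheno_cols].to_csv(pheno_path, index=False)
        artifacts["epoch_stream"] = epoch_path
        artifacts["phenotypes"] = pheno_path
        log.info("simulated %d persons across %d studies", len(cohort), sim.n_studies)

    _stage("process")
    series_list = epochs.read_epoch_stream(epoch_path)
    all_days, all_summaries = [], []
    for series in series_list:
        days, summary = epochs.process_series(series, config.epoch)
        all_days.extend(days)
        all_summaries.append(summary)
    days_df = epochs.day_records_to_frame(all_days)
    summaries_df = epochs.summaries_to_frame(all_summaries)
    artifacts["day_records"] = out / "day_records.csv"
    artifacts["summaries"] = out / "activity_summaries.csv"
    days_df.to_csv(artifacts["day_records"], index=False)
    summaries_df.to_csv(artifacts["summaries"], index=False)
    log.info("processed %d persons -> %d day records (%d valid), %d summaries",
             len(series_list), len(days_df), int(days_df["valid"].sum()),
             len(summaries_df))

    _stage("fit")
    phenotypes = pd.read_csv(pheno_path, dtype={"person_id": str})
    cohort_table, issues = validate_inputs(phenotypes, summaries_df)
    for issue in issues:
        log.warning("validate: %s", issue)
    log.info("validated cohort: %d rows used, %d excluded",
             len(cohort_table), len(phenotypes) - len(cohort_table))
    outcomes = []
    for o in config.outcomes:
        if o in cohort_table.columns:
            outcomes.append(o)
        else:
            log.warning("outcome %r missing from phenotype table; skipped", o)
    results = models.run_framework(
        cohort_table, outcomes, config.strata, estimator=config.estimator,
        variance=config.variance, exposure_unit=config.exposure_unit)
    tidy = pd.concat([r.tidy() for r in results], ignore_index=True)
    artifacts["tidy_results"] = out / "model_results.csv"
    tidy.to_csv(artifacts["tidy_results"], index=False)
    log.info("fitted %d models (%d coefficient rows)", len(results), len(tidy))

    _stage("report")
    rel = reporting.relative_effects_frame(results)
    artifacts["relative_effects"] = out / "relative_effects.csv"
    rel.to_csv(artifacts["relative_effects"], index=False)
    tables = "\n\n".join(reporting.render_table(results, o) for o in outcomes)
    artifacts["tables"] = out / "tables.txt"
    artifacts["tables"].write_text(tables + "\n")
    log.info("wrote %d artifacts to %s", len(artifacts), out)
    return artifacts
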