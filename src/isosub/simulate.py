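"""Synthetic cohort and epoch-stream generator.

Emulates the statistical structure of the pooled ICAD sample the analysis
assumes: ~13 study clusters, ages 4-18 in three age groups, per-group
behaviour distributions calibrated to the published descriptives, study-level
random intercepts on outcomes, and 60-s epoch streams whose processed daily
summaries recover the generated compositions exactly.

Behaviour compositions are drawn as independent truncated normals per group
and closed by defining wear time as their sum, which keeps every person
exactly on the sed + LPA + MVPA == wear constraint the models rely on.
Outcomes follow the partition-model data-generating process: linear in the
three behaviours (per 10 min/day), plus sex, an optional waist-circumference
covariate, a Normal study intercept and Normal residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .epochs import EpochSeries, IntensityThresholds
from .exceptions import ConfigurationError, InputError

__all__ = [
    "TrueModel",
    "SimulationConfig",
    "DayPlan",
    "default_true_models",
    "simulate_cohort",
    "plan_days",
    "realize_epoch_stream",
    "realize_person_stream",
    "simulate_outcomes",
    "simulate_dataset",
]

AGE_GROUPS = reference.AGE_GROUPS
_GROUP_MIX = tuple(reference.GROUP_N[g] / sum(reference.GROUP_N.values())
                   for g in AGE_GROUPS)


@dataclass(frozen=True)
class TrueModel:
    """Planted linear model for one outcome (units per 10 min/day)."""

    intercept: float
    b_sed: float
    b_lpa: float
    b_mvpa: float
    sex_effect: float = 0.0     # male minus female (sex coded 0 = F, 1 = M)
    wc_effect: float = 0.0      # per cm of waist circumference; ignored for WC itself


def default_true_models() -> dict[str, dict[str, TrueModel]]:
    """Planted effects for waist circumference, calibrated to the published
    pooled-analysis coefficients.

    The adolescent partition sedentary coefficient (0.035 cm per 10 min/day)
    anchors the scale; the MVPA and LPA coefficients are placed so the
    substitution contrasts b_mvpa - b_sed = -0.589 and b_lpa - b_sed = -0.046
    match the published ISM estimates exactly.  Per-group intercepts are
    solved so the simulated group means land on the published WC means.
    """
    b = reference.WC_ADOLESCENT_PLANTED
    sex_effect = 2.0  # cm, boys minus girls; descriptive-scale choice
    models = {}
    for group in AGE_GROUPS:
        beh = reference.BEHAVIOUR_CALIBRATION[group]
        mean_wc = reference.OUTCOME_CALIBRATION["wc"][group][0]
        intercept = (mean_wc
                     - b["b_sed"] * beh["sed"][0] / 10
                     - b["b_lpa"] * beh["lpa"][0] / 10
                     - b["b_mvpa"] * beh["mvpa"][0] / 10
                     - 0.5 * sex_effect)
        models[group] = TrueModel(intercept=intercept, sex_effect=sex_effect,
                                  b_sed=b["b_sed"], b_lpa=b["b_lpa"],
                                  b_mvpa=b["b_mvpa"])
    return {"wc": models}


TrueModelSpec = Union[TrueModel, Mapping[str, TrueModel]]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the published pooled-sample conditions: 13 studies,
    18,200 persons, the published age-group mix and per-group behaviour
    means/SDs, and planted waist-circumference effects equal to the
    published substitution coefficients.  Study-intercept and residual SDs
    are not published; the defaults derived here are order-of-magnitude
    choices (see docs/methods.md).
    """

    n_studies: int = 13
    persons_per_study: int = 1400
    age_group_mix: tuple[float, float, float] = _GROUP_MIX
    behaviour_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: reference.BEHAVIOUR_CALIBRATION)
    true_models: Mapping[str, TrueModelSpec] = field(default_factory=default_true_models)
    study_intercept_sd: Mapping[str, float] = field(default_factory=dict)
    residual_sd: Mapping[str, float] = field(default_factory=dict)
    lognormal_outcomes: frozenset[str] = frozenset()
    n_days: int = 4
    nonwear_blocks: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.persons_per_study < 1:
            raise ConfigurationError("need at least one study and one person per study")
        if abs(sum(self.age_group_mix) - 1.0) > 1e-9 or min(self.age_group_mix) < 0:
            raise ConfigurationError("age_group_mix must be non-negative and sum to 1")
        for group, params in self.behaviour_params.items():
            for name, (mean, sd) in params.items():
                if sd < 0:
                    raise ConfigurationError(f"{group}/{name}: SD must be >= 0")
                if mean < 0 and (sd == 0 or -mean / sd > 8):
                    raise ConfigurationError(
                        f"{group}/{name}: mean {mean} is infeasibly far below the "
                        f"truncation bound 0 for SD {sd}")
        if self.n_days < 1 or self.nonwear_blocks < 0:
            raise ConfigurationError("n_days must be >= 1 and nonwear_blocks >= 0")

    # Variance components are unpublished; fall back to fractions of the
    # published pooled outcome SDs so magnitudes stay plausible.
    def residual_sd_for(self, outcome: str) -> float:
        if outcome in self.residual_sd:
            return self.residual_sd[outcome]
        sds = [sd for (_, sd) in reference.OUTCOME_CALIBRATION[outcome].values()]
        return 0.85 * float(np.mean(sds))

    def study_sd_for(self, outcome: str) -> float:
        if outcome in self.study_intercept_sd:
            return self.study_intercept_sd[outcome]
        sds = [sd for (_, sd) in reference.OUTCOME_CALIBRATION[outcome].values()]
        return 0.25 * float(np.mean(sds))

    def true_model_for(self, outcome: str, group: str) -> TrueModel:
        spec = self.true_models[outcome]
        if isinstance(spec, TrueModel):
            return spec
        return spec[group]


@dataclass(frozen=True)
class DayPlan:
    """One person-day to be realised as an epoch stream."""

    person_id: str
    date: pd.Timestamp
    sed: int
    lpa: int
    mvpa: int
    nonwear_schedule: tuple[int, ...]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic substreams per pipeline stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated below at 0."""
    if sd == 0:
        if mean < 0:
            raise ConfigurationError(f"degenerate draw at negative mean {mean}")
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw the cohort: study labels, ages, sex, and behaviour compositions.

    Returns one row per person with columns study_id, person_id, age,
    age_group, sex (0 = female, 1 = male), sed, lpa, mvpa, wear (min/day),
    where wear == sed + lpa + mvpa by construction.
    """
    rng = _rng(config, 0)
    n = config.n_studies * config.persons_per_study
    study_idx = np.repeat(np.arange(config.n_studies), config.persons_per_study)
    group_codes = rng.choice(len(AGE_GROUPS), size=n, p=config.age_group_mix)
    sex = rng.integers(0, 2, size=n)

    age = np.empty(n)
    sed = np.empty(n)
    lpa = np.empty(n)
    mvpa = np.empty(n)
    for gi, group in enumerate(AGE_GROUPS):
        sel = group_codes == gi
        m = int(sel.sum())
        lo, hi = reference.AGE_GROUP_BOUNDS[group]
        age[sel] = rng.uniform(lo, hi, size=m)
        params = config.behaviour_params[group]
        sed[sel] = _truncated_normal(rng, *params["sed"], m)
        lpa[sel] = _truncated_normal(rng, *params["lpa"], m)
        mvpa[sel] = _truncated_normal(rng, *params["mvpa"], m)

    return pd.DataFrame({
        "study_id": [f"study{int(i) + 1:02d}" for i in study_idx],
        "person_id": [f"S{int(i) + 1:02d}P{j:05d}" for j, i in enumerate(study_idx)],
        "age": age,
        "age_group": [AGE_GROUPS[c] for c in group_codes],
        "sex": sex.astype(np.int64),
        "sed": sed,
        "lpa": lpa,
        "mvpa": mvpa,
        "wear": sed + lpa + mvpa,
    })


def plan_days(cohort: pd.DataFrame, config: SimulationConfig,
              start_date: str = "2005-06-06") -> list[DayPlan]:
    """Integer day compositions plus a non-wear schedule for each person-day.

    Each day repeats the person's rounded mean composition; the remainder of
    the 24 h is scheduled as up to ``nonwear_blocks`` zero-count blocks of
    >= 60 min (unscheduled remainder is simply not recorded, as when a
    device is started late or stopped early).
    """
    rng = _rng(config, 2)
    base = pd.Timestamp(start_date)
    plans: list[DayPlan] = []
    for row in cohort.itertuples(index=False):
        sed, lpa, mvpa = (int(round(row.sed)), int(round(row.lpa)),
                          int(round(row.mvpa)))
        wear = sed + lpa + mvpa
        if wear > 1440:
            raise ConfigurationError(
                f"person {row.person_id}: daily composition {wear} min exceeds 24 h")
        leftover = 1440 - wear
        k = min(config.nonwear_blocks, leftover // 60)
        for d in range(config.n_days):
            if k > 0:
                extra = rng.multinomial(leftover - 60 * k, np.full(k, 1.0 / k))
                schedule = tuple(int(60 + e) for e in extra)
            else:
                schedule = ()
            plans.append(DayPlan(person_id=row.person_id,
                                 date=base + pd.Timedelta(days=d),
                                 sed=sed, lpa=lpa, mvpa=mvpa,
                                 nonwear_schedule=schedule))
    return plans


def _split_bouts(total: int, rng, min_bout: int) -> list[int]:
    """Random composition of ``total`` into bouts of >= min_bout minutes."""
    if total <= 0:
        return []
    max_bouts = max(1, total // max(min_bout, 1))
    n_bouts = 1 + int(rng.integers(0, min(max_bouts, max(1, total // 10)) ))
    n_bouts = min(n_bouts, max_bouts)
    cuts = rng.multinomial(total - min_bout * n_bouts, np.full(n_bouts, 1.0 / n_bouts))
    return [min_bout + int(c) for c in cuts]


def realize_epoch_stream(composition: tuple[int, int, int],
                         nonwear_schedule: Sequence[int] = (),
                         thresholds: IntensityThresholds = IntensityThresholds(),
                         seed=None,
                         person_id: str = "sim",
                         date: str | pd.Timestamp = "2005-06-06",
                         max_interrupt: int = 2) -> EpochSeries:
    """Emit one day's 60-s epoch stream realising an exact composition.

    Exactly ``composition`` = (sedentary, LPA, MVPA) minutes fall in each
    intensity band, arranged as shuffled bouts; every wear epoch is strictly
    positive, so the scheduled zero blocks (each >= 60 min, separated by
    more than ``max_interrupt`` wear epochs) are recovered by non-wear
    detection without absorption or merging, and processing the stream
    returns the composition exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sed, lpa, mvpa = (int(composition[0]), int(composition[1]), int(composition[2]))
    if min(sed, lpa, mvpa) < 0:
        raise InputError("composition minutes must be non-negative")
    schedule = [int(b) for b in nonwear_schedule]
    if any(b < 60 for b in schedule):
        raise InputError("non-wear blocks shorter than 60 min would not be detected")
    wear = sed + lpa + mvpa
    if wear + sum(schedule) > 1440:
        raise InputError(
            f"composition ({wear} min wear) plus non-wear ({sum(schedule)} min) "
            f"exceeds 24 h")

    # counts within each band's range; sedentary epochs are kept non-zero so
    # wear time contains no zero runs at all
    bands = []
    if sed:
        bands += [(0, c) for c in rng.integers(1, thresholds.sedentary_max + 1, sed)]
    if lpa:
        bands += [(1, c) for c in rng.integers(thresholds.sedentary_max + 1,
                                               thresholds.light_max + 1, lpa)]
    if mvpa:
        bands += [(2, c) for c in rng.integers(thresholds.light_max + 1,
                                               thresholds.light_max + 5001, mvpa)]

    min_sep = max_interrupt + 1
    # group each band's epochs into bouts, then shuffle bout order
    bouts: list[list[int]] = []
    order = rng.permutation(3)
    by_band = {b: [int(c) for bb, c in bands if bb == b] for b in range(3)}
    for b in order:
        vals = by_band[int(b)]
        for size in _split_bouts(len(vals), rng,
                                 min_bout=min(min_sep, max(len(vals), 1))):
            bouts.append(vals[:size])
            vals = vals[size:]
    rng.shuffle(bouts)

    # choose gap positions for the non-wear blocks such that the wear epochs
    # between any two blocks exceed the interruption allowance
    n_gaps = len(bouts) + 1
    chosen: list[int] = []
    if schedule:
        if wear == 0:
            if len(schedule) > 1:
                raise InputError("multiple non-wear blocks need wear time between them")
            chosen = [0]
        else:
            sizes = [len(b) for b in bouts]
            prefix = np.concatenate([[0], np.cumsum(sizes)])
            for g in rng.permutation(n_gaps):
                ok = all(abs(prefix[g] - prefix[h]) >= min_sep for h in chosen)
                if ok and g not in chosen:
                    chosen.append(int(g))
                if len(chosen) == len(schedule):
                    break
            if len(chosen) < len(schedule):
                # random placement failed; spacing-greedy over sorted gaps
                # maximises the number of admissible positions
                chosen = []
                for g in range(n_gaps):
                    if not chosen or prefix[g] - prefix[chosen[-1]] >= min_sep:
                        chosen.append(g)
                    if len(chosen) == len(schedule):
                        break
            if len(chosen) < len(schedule):
                raise InputError(
                    "composition incompatible with non-wear schedule: not enough "
                    "wear time to separate the scheduled blocks")
    block_at = dict(zip(sorted(chosen), rng.permutation(len(schedule))))

    counts: list[int] = []
    for g in range(n_gaps):
        if g in block_at:
            counts.extend([0] * schedule[int(block_at[g])])
        if g < len(bouts):
            counts.extend(int(c) for c in bouts[g])

    start = pd.Timestamp(date).normalize()
    ts = pd.date_range(start, periods=len(counts), freq="60s")
    return EpochSeries(person_id, 60, ts, np.asarray(counts, dtype=np.int64))


def realize_person_stream(plans: Sequence[DayPlan],
                          thresholds: IntensityThresholds = IntensityThresholds(),
                          seed=None) -> EpochSeries:
    """Concatenate one person's realised days into a single stream."""
    if not plans:
        raise InputError("no day plans supplied")
    pid = plans[0].person_id
    if any(p.person_id != pid for p in plans):
        raise InputError("plans span multiple persons")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = [realize_epoch_stream((p.sed, p.lpa, p.mvpa), p.nonwear_schedule,
                                  thresholds, rng, pid, p.date)
             for p in plans]
    return EpochSeries(
        pid, 60,
        pd.DatetimeIndex(np.concatenate([p.timestamps.values for p in parts])),
        np.concatenate([p.counts for p in parts]),
    )


def simulate_outcomes(cohort: pd.DataFrame, config: SimulationConfig,
                      true_models: Optional[Mapping[str, TrueModelSpec]] = None
                      ) -> pd.DataFrame:
    """Attach simulated outcome columns to a cohort.

    outcome = intercept + b_sed*(S/10) + b_lpa*(L/10) + b_mvpa*(M/10)
              + sex_effect*sex + wc_effect*WC (non-WC outcomes)
              + study intercept ~ N(0, study_sd^2) + residual ~ N(0, sd^2).
    Outcomes listed in ``config.lognormal_outcomes`` interpret that linear
    predictor on the natural-log scale and are exponentiated (right-skew,
    e.g. insulin).
    """
    rng = _rng(config, 1)
    models = config.true_models if true_models is None else true_models
    out = cohort.copy()
    studies = pd.factorize(out["study_id"])[0]
    n_studies = int(studies.max()) + 1
    n = len(out)

    # WC first: it is a covariate for every other outcome
    names = sorted(models, key=lambda o: (o != "wc", o))
    for outcome in names:
        eta = np.zeros(n)
        for group in AGE_GROUPS:
            sel = (out["age_group"] == group).to_numpy()
            if not sel.any():
                continue
            tm = (models[outcome] if isinstance(models[outcome], TrueModel)
                  else models[outcome][group])
            eta[sel] = (tm.intercept
                        + tm.b_sed * out.loc[sel, "sed"].to_numpy() / 10
                        + tm.b_lpa * out.loc[sel, "lpa"].to_numpy() / 10
                        + tm.b_mvpa * out.loc[sel, "mvpa"].to_numpy() / 10
                        + tm.sex_effect * out.loc[sel, "sex"].to_numpy())
            if outcome != "wc" and tm.wc_effect and "wc" in out.columns:
                eta[sel] += tm.wc_effect * out.loc[sel, "wc"].to_numpy()
        u = rng.normal(0.0, config.study_sd_for(outcome), n_studies)
        eps = rng.normal(0.0, config.residual_sd_for(outcome), n)
        values = eta + u[studies] + eps
        out[outcome] = np.exp(values) if outcome in config.lognormal_outcomes else values
    return out


def simulate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Cohort with behaviours and all configured outcomes; one call, one seed."""
    return simulate_outcomes(simulate_cohort(config), config)
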