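"""Three-step substitution modelling framework.

Single-factor, partition and isotemporal substitution (ISM) linear models of
cardiometabolic outcomes on accelerometer-measured time use, estimated
either by pooled OLS or by random-intercept feasible GLS with the study as
the panel, with cluster-robust (sandwich, by study) or conventional
variance.

The ISM follows the standard construction: all behaviours except the one
being displaced enter the model together with total monitor wear time, so
each retained behaviour's coefficient is the effect of reallocating time
into it from the dropped behaviour, total time held constant.  Because wear
time equals the sum of the behaviours, the ISM is an exact linear
reparameterization of the partition model: the ISM coefficient for
behaviour j with k dropped equals b_j - b_k from the partition fit.

Exposures are divided by 10 before fitting so coefficients are per
10 min/day reallocated.  Estimation reuses :mod:`statsmodels` OLS and its
sandwich machinery; the random-effects step (Swamy-Arora variance
components + quasi-demeaning) is implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (ConfigurationError, DegenerateFitError,
                         EstimationError, InputError, RankDeficiencyError)

__all__ = [
    "EXPOSURES", "OUTCOMES", "AGE_GROUPS",
    "ModelSpec", "FitResult",
    "scale_exposures", "build_design", "fit", "run_framework",
    "interaction_screen", "vif_tolerance", "log_sensitivity",
    "significance_flag",
]

EXPOSURES = ("sed", "lpa", "mvpa")
OUTCOMES = ("wc", "sbp", "hdl", "ldl", "trig", "insulin", "glucose")
AGE_GROUPS = ("children", "adolescents", "older")

MODEL_CLASSES = ("single", "partition", "isotemporal")
ESTIMATORS = ("random_effects_gls", "pooled_ols")
VARIANCES = ("cluster_robust", "conventional")


def significance_flag(p: float) -> str:
    """'**' for p <= 0.001, '*' for p < 0.05, '' otherwise."""
    if p <= 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression.

    ``covariates`` defaults to sex plus waist circumference; WC is always
    removed when it is the outcome.  ``include_wear`` is forced True for
    isotemporal and False for partition models; for single-factor models it
    is a switch (default False).
    """

    model_class: str
    outcome: str
    exposure: Optional[str] = None        # single-factor models only
    dropped: Optional[str] = None         # isotemporal models only
    exposure_unit: float = 10.0
    stratum: Optional[str] = None
    covariates: tuple[str, ...] = ("sex", "wc")
    include_wear: Optional[bool] = None
    estimator: str = "random_effects_gls"
    variance: str = "cluster_robust"
    log_outcome: bool = False

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ConfigurationError(f"unknown model class {self.model_class!r}")
        if self.estimator not in ESTIMATORS:
            raise ConfigurationError(f"unknown estimator {self.estimator!r}")
        if self.variance not in VARIANCES:
            raise ConfigurationError(f"unknown variance {self.variance!r}")
        if self.exposure_unit <= 0:
            raise ConfigurationError("exposure_unit must be positive minutes")
        if self.model_class == "single":
            if self.exposure not in EXPOSURES:
                raise ConfigurationError("single-factor model needs exposure in "
                                         f"{EXPOSURES}, got {self.exposure!r}")
        if self.model_class == "isotemporal":
            if self.dropped not in EXPOSURES:
                raise ConfigurationError("isotemporal model needs dropped in "
                                         f"{EXPOSURES}, got {self.dropped!r}")
            if self.include_wear is False:
                raise ConfigurationError("isotemporal models keep wear time constant; "
                                         "include_wear cannot be False")
        if self.model_class == "partition" and self.include_wear:
            raise ConfigurationError("partition models omit wear time "
                                     "(it is the sum of the behaviours)")

    @property
    def wear_in_design(self) -> bool:
        if self.model_class == "isotemporal":
            return True
        if self.model_class == "partition":
            return False
        return bool(self.include_wear)

    def exposure_terms(self) -> tuple[str, ...]:
        if self.model_class == "single":
            return (self.exposure,)
        if self.model_class == "partition":
            return EXPOSURES
        return tuple(e for e in EXPOSURES if e != self.dropped)

    def effective_covariates(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariates if c != self.outcome)


@dataclass
class FitResult:
    """Estimated coefficients and diagnostics for one :class:`ModelSpec`."""

    spec: ModelSpec
    params: pd.DataFrame          # index term; beta, se, ci_low, ci_high, p, flag
    n_obs: int
    n_clusters: int
    sigma_study: Optional[float]  # random-intercept SD (random effects only)
    sigma_resid: Optional[float]
    theta_range: Optional[tuple[float, float]]  # quasi-demeaning fractions
    mean_vif: float
    min_tolerance: float
    outcome_mean: float           # observed outcome mean over fitted rows

    def beta(self, term: str) -> float:
        return float(self.params.loc[term, "beta"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def tidy(self) -> pd.DataFrame:
        """One row per term, in the documented tidy-results column order."""
        df = self.params.reset_index(names="term")
        df.insert(0, "model_class", self.spec.model_class)
        df.insert(1, "outcome", self.spec.outcome)
        df.insert(2, "stratum", self.spec.stratum or "all")
        df.insert(3, "dropped", self.spec.dropped or "")
        df["n"] = self.n_obs
        df["clusters"] = self.n_clusters
        df["mean_vif"] = self.mean_vif
        df["min_tolerance"] = self.min_tolerance
        return df


# ---------------------------------------------------------------------------

def scale_exposures(table: pd.DataFrame, unit: float = 10.0) -> pd.DataFrame:
    """Divide the behaviour columns (and wear) by ``unit`` minutes."""
    if unit <= 0:
        raise ConfigurationError("unit must be positive minutes")
    out = table.copy()
    for col in (*EXPOSURES, "wear"):
        if col in out.columns:
            out[col] = out[col] / unit
    return out


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name a minimal set of offending columns by greedy elimination
        offending = []
        cols = list(X.columns)
        while np.linalg.matrix_rank(X[cols].to_numpy(dtype=float)) < len(cols):
            for c in reversed(cols):
                rest = [k for k in cols if k != c]
                if np.linalg.matrix_rank(X[rest].to_numpy(dtype=float)) == \
                        np.linalg.matrix_rank(X[cols].to_numpy(dtype=float)):
                    offending.append(c)
                    cols = rest
                    break
        raise RankDeficiencyError(offending or list(X.columns))


def build_design(spec: ModelSpec, table: pd.DataFrame,
                 extra_terms: Sequence[str] = ()
                 ) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Complete-case outcome vector, design matrix and study labels.

    The table must carry exposures already in the model's unit (``fit``
    scales min/day input itself).  Columns: retained exposures, wear when
    the model class calls for it, covariates, then an intercept.
    """
    df = table
    if spec.stratum is not None:
        df = df[df["age_group"] == spec.stratum]
        if len(df) == 0:
            raise InputError(f"empty stratum {spec.stratum!r}")
    terms = list(spec.exposure_terms())
    if spec.wear_in_design:
        terms.append("wear")
    terms += list(spec.effective_covariates()) + list(extra_terms)
    missing = [t for t in terms + [spec.outcome] if t not in df.columns]
    if missing:
        raise InputError(f"table lacks columns {missing}")
    sub = df[[spec.outcome, *terms, "study_id"]].dropna()
    y = sub[spec.outcome].astype(float)
    if not np.isfinite(y.to_numpy()).all():
        raise InputError(f"non-finite values in outcome {spec.outcome!r}")
    X = sub[terms].astype(float).copy()
    X["const"] = 1.0
    _check_rank(X)
    return y, X, sub["study_id"]


# ---------------------------------------------------------------------------
# estimation

def _swamy_arora(y: np.ndarray, X: np.ndarray, groups: np.ndarray
                 ) -> tuple[float, float, np.ndarray]:
    """Swamy-Arora variance components and per-group quasi-demeaning theta.

    sigma_e^2 comes from the within (fixed-effects) residuals; sigma_u^2
    from the between regression on group means, debiased by sigma_e^2 over
    the harmonic-mean group size and floored at zero.
    """
    codes, uniques = pd.factorize(groups)
    G = len(uniques)
    n, k = X.shape
    sizes = np.bincount(codes).astype(float)

    # within step
    ymean = np.bincount(codes, weights=y) / sizes
    y_w = y - ymean[codes]
    X_w = np.empty_like(X)
    for j in range(k):
        cm = np.bincount(codes, weights=X[:, j]) / sizes
        X_w[:, j] = X[:, j] - cm[codes]
    keep = X_w.std(axis=0) > 1e-12          # drop group-invariant columns
    Xw = X_w[:, keep]
    if Xw.shape[1]:
        beta_w, *_ = np.linalg.lstsq(Xw, y_w, rcond=None)
        resid_w = y_w - Xw @ beta_w
        k_w = np.linalg.matrix_rank(Xw)
    else:
        resid_w, k_w = y_w, 0
    dof_w = n - G - k_w
    if dof_w <= 0:
        raise EstimationError("not enough observations for within variance")
    sigma_e2 = float(resid_w @ resid_w) / dof_w

    if G == 1:
        return 0.0, sigma_e2, np.zeros(1)

    # between step on group means
    yb = ymean
    Xb = np.column_stack([np.bincount(codes, weights=X[:, j]) / sizes
                          for j in range(k)])
    k_b = np.linalg.matrix_rank(Xb)
    if G > k_b:
        beta_b, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        resid_b = yb - Xb @ beta_b
        s_b2 = float(resid_b @ resid_b) / (G - k_b)
        t_harm = G / float(np.sum(1.0 / sizes))
        sigma_u2 = max(0.0, s_b2 - sigma_e2 / t_harm)
    else:
        sigma_u2 = 0.0   # too few clusters to separate the components
    denom = sigma_e2 + sizes * sigma_u2
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom > 0, 1.0 - np.sqrt(sigma_e2 / np.where(denom > 0, denom, 1.0)), 0.0)
    return sigma_u2, sigma_e2, theta


def _estimate(y: pd.Series, X: pd.DataFrame, studies: pd.Series,
              estimator: str, variance: str):
    codes, uniques = pd.factorize(studies)
    G = len(uniques)
    if variance == "cluster_robust" and G < 2:
        raise EstimationError(
            "cluster-robust variance needs at least 2 study clusters")
    if len(y) <= X.shape[1]:
        raise EstimationError("fewer observations than design columns")

    sigma_u = sigma_e = None
    theta_rng = None
    ya, Xa = y.to_numpy(dtype=float), X.to_numpy(dtype=float)
    if estimator == "random_effects_gls":
        sigma_u2, sigma_e2, theta = _swamy_arora(ya, Xa, codes)
        sizes = np.bincount(codes).astype(float)
        ym = np.bincount(codes, weights=ya) / sizes
        ya = ya - theta[codes] * ym[codes]
        Xt = np.empty_like(Xa)
        for j in range(Xa.shape[1]):
            cm = np.bincount(codes, weights=Xa[:, j]) / sizes
            Xt[:, j] = Xa[:, j] - theta[codes] * cm[codes]
        Xa = Xt
        sigma_u, sigma_e = math.sqrt(sigma_u2), math.sqrt(sigma_e2)
        theta_rng = (float(theta.min()), float(theta.max()))

    model = sm.OLS(ya, pd.DataFrame(Xa, columns=X.columns))
    if variance == "cluster_robust":
        # normal reference distribution; small-cluster caveats documented
        res = model.fit(cov_type="cluster", cov_kwds={"groups": codes},
                        use_t=False)
    else:
        res = model.fit()
    return res, G, sigma_u, sigma_e, theta_rng


def vif_tolerance(X: pd.DataFrame, exposure_cols: Sequence[str]
                  ) -> tuple[pd.DataFrame, float, float]:
    """Variance inflation factor and tolerance per exposure column.

    VIF_j = 1 / (1 - R^2_j) from regressing exposure j on all other
    non-intercept columns (with intercept); tolerance_j = 1 / VIF_j.
    """
    _check_rank(X)
    others_all = [c for c in X.columns if c != "const"]
    rows = []
    for col in exposure_cols:
        others = [c for c in others_all if c != col]
        yj = X[col].to_numpy(dtype=float)
        Zj = X[others + ["const"]].to_numpy(dtype=float) if others else \
            X[["const"]].to_numpy(dtype=float)
        bj, *_ = np.linalg.lstsq(Zj, yj, rcond=None)
        resid = yj - Zj @ bj
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 0.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
        vif = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        rows.append({"term": col, "vif": vif, "tolerance": 1.0 / vif})
    table = pd.DataFrame(rows).set_index("term")
    return table, float(table["vif"].mean()), float(table["tolerance"].min())


def fit(spec: ModelSpec, table: pd.DataFrame,
        extra_terms: Sequence[str] = ()) -> FitResult:
    """Estimate one model.  ``table`` carries exposures in min/day."""
    scaled = scale_exposures(table, spec.exposure_unit)
    y, X, studies = build_design(spec, scaled, extra_terms)
    if spec.log_outcome:
        bad = y[y <= 0]
        if len(bad):
            raise InputError(
                f"log transform needs a strictly positive outcome; offending "
                f"rows: {list(bad.index[:10])}")
        y = np.log(y)
    if float(np.var(y)) == 0.0:
        raise DegenerateFitError(f"outcome {spec.outcome!r} is constant")

    res, G, sigma_u, sigma_e, theta_rng = _estimate(
        y, X, studies, spec.estimator, spec.variance)

    ci = res.conf_int(alpha=0.05)
    params = pd.DataFrame({
        "beta": res.params,
        "se": res.bse,
        "ci_low": ci[0] if isinstance(ci, pd.DataFrame) else ci[:, 0],
        "ci_high": ci[1] if isinstance(ci, pd.DataFrame) else ci[:, 1],
        "p": res.pvalues,
    })
    params.index = X.columns
    params["flag"] = [significance_flag(p) for p in params["p"]]

    vif_cols = [c for c in spec.exposure_terms() if c in X.columns]
    if spec.wear_in_design:
        vif_cols.append("wear")
    _, mean_vif, min_tol = vif_tolerance(X, vif_cols)

    return FitResult(
        spec=spec, params=params, n_obs=int(res.nobs), n_clusters=G,
        sigma_study=sigma_u, sigma_resid=sigma_e, theta_range=theta_rng,
        mean_vif=mean_vif, min_tolerance=min_tol,
        outcome_mean=float(np.mean(np.exp(y) if spec.log_outcome else y)),
    )


# ---------------------------------------------------------------------------
# framework drivers

def run_framework(table: pd.DataFrame,
                  outcomes: Sequence[str],
                  strata: Sequence[str] = AGE_GROUPS,
                  estimator: str = "random_effects_gls",
                  variance: str = "cluster_robust",
                  exposure_unit: float = 10.0) -> list[FitResult]:
    """All three model classes for each outcome x stratum.

    Per cell: three single-factor fits (one per behaviour), one partition
    fit, and three isotemporal fits (each behaviour dropped in turn) —
    seven :class:`FitResult` objects mirroring one published table block.
    """
    results: list[FitResult] = []
    common = dict(estimator=estimator, variance=variance,
                  exposure_unit=exposure_unit)
    for outcome in outcomes:
        for stratum in strata:
            for exposure in EXPOSURES:
                results.append(fit(ModelSpec("single", outcome, exposure=exposure,
                                             stratum=stratum, **common), table))
            results.append(fit(ModelSpec("partition", outcome,
                                         stratum=stratum, **common), table))
            for dropped in EXPOSURES:
                results.append(fit(ModelSpec("isotemporal", outcome, dropped=dropped,
                                             stratum=stratum, **common), table))
    return results


def interaction_screen(table: pd.DataFrame, outcome: str, stratum: str,
                       estimator: str = "random_effects_gls",
                       variance: str = "cluster_robust",
                       exposure_unit: float = 10.0) -> float:
    """Wald p-value for a sex x MVPA interaction added to the partition model."""
    df = table[table["age_group"] == stratum]
    if df["sex"].nunique() < 2:
        raise InputError(f"stratum {stratum!r} contains a single sex")
    augmented = table.copy()
    augmented["sex_x_mvpa"] = augmented["sex"] * augmented["mvpa"]
    spec = ModelSpec("partition", outcome, stratum=stratum, estimator=estimator,
                     variance=variance, exposure_unit=exposure_unit)
    result = fit(spec, augmented, extra_terms=("sex_x_mvpa",))
    return result.p("sex_x_mvpa")


def log_sensitivity(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """Refit with the natural-log outcome (sensitivity for skewed outcomes)."""
    return fit(replace(spec, log_outcome=True), table)
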