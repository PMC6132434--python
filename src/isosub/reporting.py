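"""Presentation of fitted reallocation effects.

Absolute coefficients with 95% CIs, relative effects as a percentage of the
age-group outcome mean, and text tables shaped like the published ones
(single / partition / isotemporal blocks with the dropped behaviour's cell
marked "Dropped").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import InputError
from .models import EXPOSURES, FitResult

__all__ = ["RelativeEffect", "relative_effect", "relative_effects_frame",
           "render_table", "RISK_DIRECTION"]

#: +1 when a higher value is better (HDL-C), -1 when higher is worse.
RISK_DIRECTION = {
    "wc": -1, "sbp": -1, "hdl": +1, "ldl": -1,
    "trig": -1, "insulin": -1, "glucose": -1,
}

EXPOSURE_LABELS = {"sed": "Sedentary", "lpa": "LPA", "mvpa": "MVPA"}


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def relative_effect(beta: float, stratum_mean: float) -> float:
    """|beta| as a percent of the stratum outcome mean, half-up to 1 decimal."""
    if not stratum_mean > 0:
        raise InputError(f"stratum mean must be positive, got {stratum_mean}")
    return _round_half_up(100.0 * abs(beta) / stratum_mean, 1)


@dataclass(frozen=True)
class RelativeEffect:
    outcome: str
    stratum: str
    term: str
    beta: float
    stratum_mean: float
    relative_pct: float
    direction: str       # "favourable" | "unfavourable"

    @classmethod
    def from_beta(cls, outcome: str, stratum: str, term: str,
                  beta: float, stratum_mean: float) -> "RelativeEffect":
        risk = RISK_DIRECTION.get(outcome, -1)
        favourable = beta * risk >= 0
        return cls(outcome, stratum, term, beta, stratum_mean,
                   relative_effect(beta, stratum_mean),
                   "favourable" if favourable else "unfavourable")


def relative_effects_frame(results: Iterable[FitResult],
                           stratum_means: Optional[dict] = None) -> pd.DataFrame:
    """Relative effects for every exposure term of every fit.

    ``stratum_means`` maps (outcome, stratum) to the mean used as the
    denominator; when absent, the observed outcome mean among the rows that
    entered the fit is used.
    """
    rows = []
    for res in results:
        key = (res.spec.outcome, res.spec.stratum)
        mean = (stratum_means or {}).get(key, res.outcome_mean)
        for term in res.spec.exposure_terms():
            rel = RelativeEffect.from_beta(res.spec.outcome, res.spec.stratum or "all",
                                           term, res.beta(term), mean)
            rows.append({"model_class": res.spec.model_class,
                         "outcome": rel.outcome, "stratum": rel.stratum,
                         "dropped": res.spec.dropped or "", "term": rel.term,
                         "beta": rel.beta, "stratum_mean": rel.stratum_mean,
                         "relative_pct": rel.relative_pct,
                         "direction": rel.direction})
    return pd.DataFrame(rows)


def _cell(res: Optional[FitResult], term: str) -> str:
    if res is None:
        return ""
    if term not in res.params.index:
        return "Dropped"
    beta = res.beta(term)
    lo, hi = res.ci(term)
    flag = res.params.loc[term, "flag"]
    return f"{beta:.3f} ({lo:.3f} to {hi:.3f}){flag}"


def render_table(results: Sequence[FitResult], outcome: str) -> str:
    """Text table for one outcome: one block per stratum, rows Single /
    Partition / Reduce sedentary / Reduce LPA / Reduce MVPA, columns the
    three behaviours.  Coefficients as "beta (low to high)" to 3 decimals
    with significance flags; missing model classes render blank with a
    warning."""
    sel = [r for r in results if r.spec.outcome == outcome]
    strata = []
    for r in sel:
        if r.spec.stratum not in strata:
            strata.append(r.spec.stratum)
    header = f"{'':<22}" + "".join(f"{EXPOSURE_LABELS[e]:>34}" for e in EXPOSURES)
    lines = [f"Outcome: {outcome}", header]
    for stratum in strata:
        block = [r for r in sel if r.spec.stratum == stratum]
        singles = {r.spec.exposure: r for r in block if r.spec.model_class == "single"}
        partition = next((r for r in block if r.spec.model_class == "partition"), None)
        isms = {r.spec.dropped: r for r in block if r.spec.model_class == "isotemporal"}
        n = max((r.n_obs for r in block), default=0)
        lines.append(f"{stratum or 'all'} (n={n})")
        missing = [name for name, got in
                   (("single", singles), ("partition", partition), ("isotemporal", isms))
                   if not got]
        if missing:
            warnings.warn(f"{outcome}/{stratum}: missing model classes {missing}")
        row = [f"{'  Single':<22}"]
        for e in EXPOSURES:
            row.append(f"{_cell(singles.get(e), e):>34}")
        lines.append("".join(row))
        row = [f"{'  Partition':<22}"]
        for e in EXPOSURES:
            row.append(f"{_cell(partition, e):>34}")
        lines.append("".join(row))
        lines.append("  Isotemporal substitution")
        for dropped in EXPOSURES:
            label = f"    Reduce {'sedentary' if dropped == 'sed' else EXPOSURE_LABELS[dropped]}"
            row = [f"{label:<22}"]
            for e in EXPOSURES:
                row.append(f"{_cell(isms.get(dropped), e):>34}")
            lines.append("".join(row))
    return "\n".join(lines)
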