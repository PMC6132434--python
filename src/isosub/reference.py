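"""Published reference values from the pooled ICAD isotemporal analysis.

The International Children's Accelerometry Database (ICAD) pooled analysis
of time-use reallocation and cardiometabolic risk is the study this package
emulates; its data are access-restricted, so its *published* descriptive
statistics and coefficients serve two roles here:

* calibration targets for the synthetic cohort generator
  (:mod:`isosub.simulate`), and
* inputs to worked examples — the published isotemporal-substitution (ISM)
  coefficients combined with age-group outcome means reproduce the analysis'
  headline relative effects through
  :func:`isosub.reporting.relative_effect`.

All behaviours are min/day; coefficients are outcome units per 10 min/day
reallocated.  Insulin is kept in the units the source tables print
(labelled mmol/L there; the magnitudes suggest pmol/L — values are passed
through untouched).
"""

from __future__ import annotations

from types import MappingProxyType

AGE_GROUPS = ("children", "adolescents", "older")

#: Age-group boundaries in years: children < 10, adolescents 10 to < 15,
#: older adolescents >= 15; the pooled sample spans ages 4-18.
AGE_RANGE = (4.0, 18.0)
AGE_GROUP_BOUNDS = MappingProxyType({
    "children": (4.0, 10.0),
    "adolescents": (10.0, 15.0),
    "older": (15.0, 18.0),
})

#: Published per-group sample sizes (cardiometabolic subsample, n = 18,200).
GROUP_N = MappingProxyType({"children": 4971, "adolescents": 10836, "older": 2393})

#: Behaviour means (SDs) in min/day by age group.  Wear time is recorded for
#: day-length scheduling; within the generator wear == sed + lpa + mvpa.
BEHAVIOUR_CALIBRATION = MappingProxyType({
    "children":    {"sed": (313.0, 95.0), "lpa": (405.0, 72.0),
                    "mvpa": (56.0, 31.0), "wear": (779.0, 68.0)},
    "adolescents": {"sed": (372.0, 82.0), "lpa": (361.0, 65.0),
                    "mvpa": (54.0, 29.0), "wear": (790.0, 60.0)},
    "older":       {"sed": (455.0, 102.0), "lpa": (318.0, 83.0),
                    "mvpa": (39.0, 29.0), "wear": (815.0, 77.0)},
})

#: Outcome means (SDs) by age group, in the outcome's units.
OUTCOME_CALIBRATION = MappingProxyType({
    "wc":      {"children": (59.1, 8.2), "adolescents": (68.6, 10.8), "older": (78.1, 14.4)},
    "sbp":     {"children": (99.0, 8.9), "adolescents": (105.5, 9.8), "older": (110.6, 10.8)},
    "hdl":     {"children": (1.53, 0.32), "adolescents": (1.43, 0.34), "older": (1.35, 0.30)},
    "ldl":     {"children": (2.57, 0.75), "adolescents": (2.41, 0.67), "older": (2.39, 0.69)},
    "insulin": {"children": (34.8, 24.7), "adolescents": (66.9, 54.4), "older": (74.3, 64.6)},
    "trig":    {"children": (0.74, 0.37), "adolescents": (0.86, 0.45), "older": (0.90, 0.50)},
    "glucose": {"children": (4.94, 0.52), "adolescents": (5.16, 0.82), "older": (5.14, 0.50)},
})

#: Published headline reallocation effects: ISM coefficient (outcome units per
#: 10 min/day moved from ``source`` into ``target``) paired with the
#: age-group outcome mean it is expressed relative to.  These nine pairs
#: reproduce the analysis' published relative-effect percentages exactly;
#: the published glucose percentages do not reproduce from the printed
#: coefficients and are deliberately not included (see docs/methods.md).
WORKED_EXAMPLES = (
    # (outcome, stratum, source, target, beta, stratum_mean, stratum_n)
    ("wc",      "children",    "sed", "mvpa", -0.287, 59.1, 4971),
    ("wc",      "adolescents", "sed", "mvpa", -0.589, 68.6, 10836),
    ("wc",      "older",       "sed", "mvpa", -0.814, 78.1, 1896),
    ("sbp",     "adolescents", "sed", "mvpa", -0.084, 105.5, 8100),
    ("hdl",     "children",    "lpa", "mvpa", 0.010, 1.53, 3112),
    ("ldl",     "children",    "sed", "mvpa", -0.022, 2.57, 2428),
    ("ldl",     "adolescents", "sed", "mvpa", -0.012, 2.41, 1166),
    ("trig",    "adolescents", "sed", "mvpa", -0.019, 0.86, 1160),
    ("insulin", "children",    "sed", "mvpa", -0.850, 34.8, 2151),
)

#: Published ISM contrasts for waist circumference in adolescents, used as
#: the generator's default planted effects: with the published partition
#: sedentary coefficient 0.035 as anchor, b_mvpa - b_sed = -0.589 and
#: b_lpa - b_sed = -0.046 hold exactly.
WC_ADOLESCENT_PLANTED = MappingProxyType({
    "b_sed": 0.035,
    "b_lpa": 0.035 - 0.046,
    "b_mvpa": 0.035 - 0.589,
})
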