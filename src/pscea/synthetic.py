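"""Synthetic digitized curves and parameter tables.

The CodeBreak 200 trial (NCT04303780) published no digitized-coordinate
data, so this module generates stand-ins with the statistical structure
the analysis expects: lognormal survival curves calibrated to the trial's
printed progression-free-survival summaries (median 5.6 months and 24.8%
at 12 months for sotorasib; 4.5 months and 10.1% for docetaxel), with
plot-digitizer error emulated as additive Gaussian noise on the survival
scale followed by running-minimum monotonization.

Overall-survival summaries are not reproduced in the available source
text; synthetic OS curves use medians of 10.65 (sotorasib) and 11.3
(docetaxel) months with the same lognormal sigma as the arm's PFS curve,
which keeps S_OS >= S_PFS at every time (the curves are parallel on the
log-time probit scale).  The parameter table carries the published cost
and utility inputs verbatim and marks every quantity the source does not
print (follow-up and hospitalization costs, adverse-event incidences,
US drug costs) as synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .curves import DigitizedCurve
from .sensitivity import ParamSpec
from .survival import ParametricFit

__all__ = [
    "CurveRecipe",
    "TrialBundle",
    "lognormal_from_summaries",
    "lognormal_fit",
    "generate_km_points",
    "trial_like_bundle",
    "parameter_table",
    "TRIAL_SUMMARIES",
]

#: published PFS summaries: (median months, survival at 12 months)
TRIAL_SUMMARIES = {
    "sotorasib": {"pfs_median": 5.6, "pfs_12mo": 0.248},
    "docetaxel": {"pfs_median": 4.5, "pfs_12mo": 0.101},
}

#: synthetic OS medians (months); not printed in the available source text
SYNTHETIC_OS_MEDIANS = {"sotorasib": 10.65, "docetaxel": 11.3}


@dataclass(frozen=True)
class CurveRecipe:
    """How to generate one synthetic digitized curve."""

    family: str
    params: Mapping[str, float]
    n_points: int = 40
    t_max: float = 18.0
    noise_sd: float = 0.01
    seed: int = 0
    arm: str = "arm"
    endpoint: str = "PFS"

    def __post_init__(self) -> None:
        if self.n_points < 5:
            raise ValueError("need at least 5 points")
        if self.noise_sd < 0 or self.t_max <= 0:
            raise ValueError("noise_sd must be >= 0 and t_max > 0")


@dataclass(frozen=True)
class TrialBundle:
    """Four synthetic digitized curves plus a parameter table."""

    curves: Mapping[tuple, DigitizedCurve]  # keyed (arm, endpoint)
    parameters: pd.DataFrame
    specs: tuple
    calibration: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


def lognormal_from_summaries(median: float, s_at_t: float, t: float) -> tuple:
    """Lognormal (mu, sigma) reproducing a median and one landmark rate.

    mu = ln(median); sigma = (ln t − mu)/z with z the standard-normal
    quantile of 1 − S(t).  Requires t beyond the median with S(t) below
    one half, otherwise the pair is infeasible (sigma would be negative
    or unbounded).
    """
    if median <= 0 or t <= median:
        raise ValueError("landmark time must exceed the (positive) median")
    if not 0 < s_at_t < 0.5:
        raise ValueError("landmark survival must lie strictly between 0 and 0.5")
    mu = np.log(median)
    z = stats.norm.ppf(1.0 - s_at_t)
    sigma = (np.log(t) - mu) / z
    return float(mu), float(sigma)


def lognormal_fit(mu: float, sigma: float) -> ParametricFit:
    """Wrap analytic lognormal parameters as a fit object usable anywhere
    a fitted curve is (n/rss/aic are placeholders: nothing was fitted)."""
    return ParametricFit(
        family="lognormal",
        params={"mu": float(mu), "sigma": float(sigma)},
        k=2,
        rss=0.0,
        aic=float("-inf"),
        n=0,
    )


def generate_km_points(recipe: CurveRecipe) -> DigitizedCurve:
    """Evenly spaced synthetic digitized points on (0, t_max].

    Survival = S(t) + seeded Gaussian noise (sd = noise_sd), clamped to
    [0, 1] and monotonized by running minimum — the signature of reading
    coordinates off a stepped KM plot by hand.
    """
    from .survival import survival_value

    fit = ParametricFit(
        family=recipe.family,
        params=dict(recipe.params),
        k=len(recipe.params),
        rss=0.0,
        aic=float("nan"),
        n=0,
    )
    t = np.linspace(recipe.t_max / recipe.n_points, recipe.t_max, recipe.n_points)
    s = np.asarray(survival_value(fit, t), dtype=float)
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        s = s + rng.normal(0.0, recipe.noise_sd, size=s.size)
    s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    return DigitizedCurve(arm=recipe.arm, endpoint=recipe.endpoint, times=t, survival=s)


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------

# Published cost/utility inputs (China perspective unless noted), USD.
# Columns: name, arm, category, base, low, high, distribution, role.
_PUBLISHED_ROWS = [
    # drug acquisition cost per cycle
    ("C_Sotorasib", "sotorasib", "drug", 16892.82, 13514.256, 20271.384, "gamma", "drug_cost.sotorasib"),
    ("C_Docetaxel", "docetaxel", "drug", 228.41, 11.83, 2556.05, "gamma", "drug_cost.docetaxel"),
    # state utilities (China)
    ("U_PFS", "", "state_utility", 0.804, 0.536, 0.84, "beta", "utility.pfs"),
    ("U_PD", "", "state_utility", 0.321, 0.031, 0.321, "beta", "utility.pd"),
    # grade >=3 adverse-event utility decrements
    ("U_Diarrhea_S", "sotorasib", "ae_utility", 0.22, 0.18, 0.26, "beta", "ae_disutility.sotorasib.diarrhea"),
    ("U_Fatigue_S", "sotorasib", "ae_utility", 0.29, 0.23, 0.35, "beta", "ae_disutility.sotorasib.fatigue"),
    ("U_Nausea_S", "sotorasib", "ae_utility", 0.02, 0.016, 0.024, "beta", "ae_disutility.sotorasib.nausea"),
    ("U_Anaemia_S", "sotorasib", "ae_utility", 0.07, 0.06, 0.09, "beta", "ae_disutility.sotorasib.anaemia"),
    ("U_DecreasedAppetite_S", "sotorasib", "ae_utility", 0.39, 0.12, 0.47, "beta", "ae_disutility.sotorasib.decreased_appetite"),
    ("U_Diarrhea_D", "docetaxel", "ae_utility", 0.22, 0.18, 0.26, "beta", "ae_disutility.docetaxel.diarrhea"),
    ("U_Fatigue_D", "docetaxel", "ae_utility", 0.29, 0.23, 0.35, "beta", "ae_disutility.docetaxel.fatigue"),
    ("U_Nausea_D", "docetaxel", "ae_utility", 0.20, 0.16, 0.24, "beta", "ae_disutility.docetaxel.nausea"),
    ("U_Anaemia_D", "docetaxel", "ae_utility", 0.07, 0.06, 0.09, "beta", "ae_disutility.docetaxel.anaemia"),
    ("U_Neutropenia_D", "docetaxel", "ae_utility", 0.35, 0.28, 0.42, "beta", "ae_disutility.docetaxel.neutropenia"),
    ("U_Mucositis_D", "docetaxel", "ae_utility", 0.53, 0.47, 0.57, "beta", "ae_disutility.docetaxel.stomatitis"),
    ("U_FebrileNeutropenia_D", "docetaxel", "ae_utility", 0.47, 0.38, 0.56, "beta", "ae_disutility.docetaxel.febrile_neutropenia"),
    ("U_Pneumonia_D", "docetaxel", "ae_utility", 0.50, 0.40, 0.60, "beta", "ae_disutility.docetaxel.pneumonia"),
    # grade >=3 adverse-event management costs (distribution as published)
    ("C_Diarrhoea_S", "sotorasib", "ae_cost", 1209.58, 967.66, 1451.50, "beta", "ae_cost.sotorasib.diarrhea"),
    ("C_Fatigue_S", "sotorasib", "ae_cost", 1185.92, 948.74, 1423.10, "beta", "ae_cost.sotorasib.fatigue"),
    ("C_Nausea_S", "sotorasib", "ae_cost", 1209.58, 967.66, 1451.50, "beta", "ae_cost.sotorasib.nausea"),
    ("C_Anaemia_S", "sotorasib", "ae_cost", 5394.51, 4315.61, 6473.41, "beta", "ae_cost.sotorasib.anaemia"),
    ("C_DecreasedAppetite_S", "sotorasib", "ae_cost", 1209.58, 967.66, 1451.50, "beta", "ae_cost.sotorasib.decreased_appetite"),
    ("C_Diarrhoea_D", "docetaxel", "ae_cost", 1209.58, 967.66, 1451.50, "beta", "ae_cost.docetaxel.diarrhea"),
    ("C_Fatigue_D", "docetaxel", "ae_cost", 1185.92, 948.74, 1423.10, "beta", "ae_cost.docetaxel.fatigue"),
    ("C_Nausea_D", "docetaxel", "ae_cost", 1209.58, 967.66, 1451.50, "beta", "ae_cost.docetaxel.nausea"),
    ("C_Anaemia_D", "docetaxel", "ae_cost", 5394.51, 4315.61, 6473.41, "beta", "ae_cost.docetaxel.anaemia"),
    ("C_Stomatitis_D", "docetaxel", "ae_cost", 1638.38, 1310.70, 1966.06, "beta", "ae_cost.docetaxel.stomatitis"),
    ("C_Asthenia_D", "docetaxel", "ae_cost", 1185.92, 948.74, 1423.10, "beta", "ae_cost.docetaxel.asthenia"),
    ("C_Neutropenia_D", "docetaxel", "ae_cost", 2449.99, 1959.99, 2939.99, "beta", "ae_cost.docetaxel.neutropenia"),
    ("C_NeuropathyPeripheral_D", "docetaxel", "ae_cost", 1453.53, 1162.82, 1744.24, "beta", "ae_cost.docetaxel.neuropathy_peripheral"),
    ("C_Myalgia_D", "docetaxel", "ae_cost", 1932.79, 1546.23, 2319.35, "beta", "ae_cost.docetaxel.myalgia"),
    ("C_Arthralgia_D", "docetaxel", "ae_cost", 1932.79, 1546.23, 2319.35, "beta", "ae_cost.docetaxel.arthralgia"),
    ("C_FebrileNeutropenia_D", "docetaxel", "ae_cost", 2449.99, 1959.99, 2939.99, "beta", "ae_cost.docetaxel.febrile_neutropenia"),
    ("C_Pneumonia_D", "docetaxel", "ae_cost", 1789.55, 1431.64, 2147.46, "beta", "ae_cost.docetaxel.pneumonia"),
    # state costs (distribution as published)
    ("C_BestSupportive", "", "other_cost", 4221.0, 3377.0, 5065.0, "beta", "bsc_cost"),
    ("C_Terminal", "", "other_cost", 17185.0, 13748.0, 20622.0, "beta", "terminal_cost"),
]

# US-perspective state utilities (published); same bounds as the source study
_US_UTILITY_ROWS = [
    ("U_PFS", "", "state_utility", 0.754, 0.536, 0.84, "beta", "utility.pfs"),
    ("U_PD", "", "state_utility", 0.095, 0.031, 0.321, "beta", "utility.pd"),
]

# Synthetic placeholders for quantities the source uses but does not print.
# Bounds follow the default ±20% rule.  AE incidences are grade >=3,
# loosely shaped on the trial's safety profile; follow-up covers imaging
# (brain MRI, bone scan, CT) per cycle.
_SYNTHETIC_ROWS_CHINA = [
    ("C_Followup", "", "other_cost", 289.0, 231.2, 346.8, "gamma", "followup_cost"),
    ("C_Hospitalization", "", "other_cost", 217.0, 173.6, 260.4, "gamma", "hospitalization_cost"),
]
_SYNTHETIC_ROWS_US = [
    ("C_Sotorasib", "sotorasib", "drug", 17900.0, 14320.0, 21480.0, "gamma", "drug_cost.sotorasib"),
    ("C_Docetaxel", "docetaxel", "drug", 1050.0, 840.0, 1260.0, "gamma", "drug_cost.docetaxel"),
    ("C_Followup", "", "other_cost", 520.0, 416.0, 624.0, "gamma", "followup_cost"),
    ("C_Hospitalization", "", "other_cost", 1240.0, 992.0, 1488.0, "gamma", "hospitalization_cost"),
]
_SYNTHETIC_AE_INCIDENCE = [
    ("sotorasib", "diarrhea", 0.12),
    ("sotorasib", "fatigue", 0.04),
    ("sotorasib", "nausea", 0.02),
    ("sotorasib", "anaemia", 0.03),
    ("sotorasib", "decreased_appetite", 0.02),
    ("docetaxel", "diarrhea", 0.02),
    ("docetaxel", "fatigue", 0.06),
    ("docetaxel", "nausea", 0.02),
    ("docetaxel", "anaemia", 0.05),
    ("docetaxel", "stomatitis", 0.02),
    ("docetaxel", "asthenia", 0.04),
    ("docetaxel", "neutropenia", 0.22),
    ("docetaxel", "neuropathy_peripheral", 0.02),
    ("docetaxel", "myalgia", 0.01),
    ("docetaxel", "arthralgia", 0.01),
    ("docetaxel", "febrile_neutropenia", 0.08),
    ("docetaxel", "pneumonia", 0.03),
]


def parameter_table(perspective: str = "china") -> pd.DataFrame:
    """Parameter table for one perspective, published values verbatim and
    unprinted inputs flagged ``synthetic``."""
    if perspective not in ("china", "us"):
        raise ValueError("perspective must be 'china' or 'us'")
    rows = []

    def add(tup, synthetic):
        name, arm, cat, base, low, high, dist, role = tup
        rows.append(
            {
                "name": name,
                "arm": arm,
                "category": cat,
                "base": base,
                "low": low,
                "high": high,
                "distribution": dist,
                "role": role,
                "synthetic": synthetic,
            }
        )

    skip_for_us = {"utility.pfs", "utility.pd", "drug_cost.sotorasib", "drug_cost.docetaxel"}
    for tup in _PUBLISHED_ROWS:
        if perspective == "us" and tup[7] in skip_for_us:
            continue
        add(tup, synthetic=False)
    if perspective == "us":
        for tup in _US_UTILITY_ROWS:
            add(tup, synthetic=False)
        for tup in _SYNTHETIC_ROWS_US:
            add(tup, synthetic=True)
    else:
        for tup in _SYNTHETIC_ROWS_CHINA:
            add(tup, synthetic=True)
    for arm, event, inc in _SYNTHETIC_AE_INCIDENCE:
        lo, hi = 0.8 * inc, min(1.2 * inc, 1.0)
        add(
            (f"P_{event}_{arm[0].upper()}", arm, "ae_incidence", inc, lo, hi, "beta",
             f"ae_incidence.{arm}.{event}"),
            synthetic=True,
        )
    return pd.DataFrame(rows)


def table_to_specs(table: pd.DataFrame) -> tuple:
    """ParamSpec list for the sensitivity analyses, one per table row.

    The published table assigns "Beta" to several monetary rows; a beta
    distribution cannot represent values outside [0, 1], so such rows are
    sampled as gamma (the standard family for costs) while the table keeps
    the label as printed.
    """
    specs = []
    for _, r in table.iterrows():
        dist = str(r["distribution"])
        if dist == "beta" and not (0 <= float(r["low"]) and float(r["high"]) <= 1):
            dist = "gamma"
        specs.append(
            ParamSpec(
                name=str(r["name"]),
                base=float(r["base"]),
                low=float(r["low"]),
                high=float(r["high"]),
                distribution=dist,
                role=str(r["role"]),
                synthetic=bool(r["synthetic"]),
            )
        )
    return tuple(specs)


def trial_like_bundle(
    seed: int = 0,
    perspective: str = "china",
    noise_sd: float = 0.01,
    n_points: int = 40,
    pfs_t_max: float = 18.0,
    os_t_max: float = 24.0,
) -> TrialBundle:
    """Complete synthetic workspace: four digitized curves calibrated to
    the trial's printed PFS summaries (OS medians synthetic) plus the
    perspective's parameter table."""
    ss = np.random.SeedSequence(seed)
    curve_seeds = ss.generate_state(4)
    curves = {}
    calibration = {}
    for i, arm in enumerate(("sotorasib", "docetaxel")):
        summ = TRIAL_SUMMARIES[arm]
        mu, sigma = lognormal_from_summaries(summ["pfs_median"], summ["pfs_12mo"], 12.0)
        calibration[arm] = {
            "pfs_mu": mu,
            "pfs_sigma": sigma,
            "os_mu": float(np.log(SYNTHETIC_OS_MEDIANS[arm])),
            "os_sigma": sigma,  # parallel on the probit scale: keeps OS >= PFS
        }
        curves[(arm, "PFS")] = generate_km_points(
            CurveRecipe(
                family="lognormal",
                params={"mu": mu, "sigma": sigma},
                n_points=n_points,
                t_max=pfs_t_max,
                noise_sd=noise_sd,
                seed=int(curve_seeds[2 * i] % 2**31),
                arm=arm,
                endpoint="PFS",
            )
        )
        curves[(arm, "OS")] = generate_km_points(
            CurveRecipe(
                family="lognormal",
                params={"mu": calibration[arm]["os_mu"], "sigma": sigma},
                n_points=n_points,
                t_max=os_t_max,
                noise_sd=noise_sd,
                seed=int(curve_seeds[2 * i + 1] % 2**31),
                arm=arm,
                endpoint="OS",
            )
        )
    table = parameter_table(perspective)
    return TrialBundle(
        curves=curves,
        parameters=table,
        specs=table_to_specs(table),
        calibration=calibration,
    )
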