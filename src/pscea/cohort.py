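"""Three-state partitioned-survival cohort model.

State occupancy is read directly off the two fitted curves at each cycle:
PFS = S_PFS(t), progressed disease PD = max(0, S_OS(t) − S_PFS(t)),
death = 1 − S_OS(t).  Costs and quality-adjusted life-years accumulate
per cycle with annual discounting; drug cost accrues while progression
free (treat-to-progression), best-supportive-care cost in the progressed
state, terminal-care cost once per new death, and grade >=3 adverse-event
costs once up front weighted by incidence.

Where the two extrapolations cross (S_PFS > S_OS in the tail), PD is
clipped at zero and death set to 1 − PFS so occupancy still sums to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .survival import ParametricFit, survival_value

__all__ = [
    "ModelConfig",
    "UtilitySet",
    "CostSet",
    "AdverseEvent",
    "CohortTrace",
    "ArmResult",
    "discount_factor",
    "docetaxel_dose",
    "state_membership",
    "build_trace",
    "run_arm",
]

DAYS_PER_MONTH = 30.4375  # 365.25 / 12
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ModelConfig:
    """Cohort-model run settings.

    Defaults: monthly cycles (30.4375 days) for 120 cycles — a 10-year
    horizon, long enough for second-line NSCLC survival to run out — with
    half-cycle correction on and annual discounting of 5%/year (the usual
    China-perspective rate; the US preset uses 3%).
    """

    cycle_length_days: float = DAYS_PER_MONTH
    n_cycles: int = 120
    discount_rate_cost: float = 0.05
    discount_rate_qaly: float = 0.05
    half_cycle_correction: bool = True
    apply_ae_disutility: bool = False
    currency_per_usd: float = 6.92  # RMB per USD, January-2023 rate

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        for r in (self.discount_rate_cost, self.discount_rate_qaly):
            if not 0 <= r <= 0.2:
                raise ValueError("annual discount rates must lie in [0, 0.2]")

    @property
    def cycle_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class AdverseEvent:
    """One grade >=3 adverse event: trial incidence, per-event management
    cost, and (optional) utility decrement."""

    label: str
    incidence: float
    unit_cost: float = 0.0
    disutility: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.incidence <= 1:
            raise ValueError(f"{self.label}: incidence must lie in [0, 1]")
        if self.unit_cost < 0:
            raise ValueError(f"{self.label}: negative cost")


@dataclass(frozen=True)
class UtilitySet:
    u_pfs: float
    u_pd: float
    ae_disutilities: tuple = ()

    def __post_init__(self) -> None:
        for u in (self.u_pfs, self.u_pd):
            if not 0 <= u <= 1:
                raise ValueError("state utilities must lie in [0, 1]")
        if self.u_pd > self.u_pfs:
            warnings.warn(
                "u_pd exceeds u_pfs; progressed disease rated better than "
                "progression-free — check inputs",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CostSet:
    """Per-cycle and one-time cost inputs for one arm, in USD."""

    drug_cost_per_cycle: float
    followup_cost_per_cycle: float = 0.0
    hospitalization_cost_per_cycle: float = 0.0
    bsc_cost_per_cycle: float = 0.0
    terminal_cost: float = 0.0
    ae_events: tuple = ()

    def __post_init__(self) -> None:
        for name in (
            "drug_cost_per_cycle",
            "followup_cost_per_cycle",
            "hospitalization_cost_per_cycle",
            "bsc_cost_per_cycle",
            "terminal_cost",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy fractions and new-death increments."""

    cycle: np.ndarray
    time_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    new_deaths: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "time_months": self.time_months,
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
                "new_deaths": self.new_deaths,
            }
        )


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one arm with per-component breakdowns."""

    total_cost: float
    total_qaly: float
    cost_breakdown: Mapping[str, float]
    qaly_breakdown: Mapping[str, float]
    trace: CohortTrace | None = None


def discount_factor(annual_rate: float, elapsed_years) -> float:
    """Standard annual compound discounting, 1/(1+r)^years."""
    years = np.asarray(elapsed_years, dtype=float)
    if annual_rate < 0 or np.any(years < 0):
        raise ValueError("discount rate and elapsed time must be non-negative")
    out = (1.0 + annual_rate) ** (-years)
    return float(out) if np.isscalar(elapsed_years) else out


def docetaxel_dose(
    bsa_m2: float,
    dose_per_m2: float,
    fixed_dose_mg: float | None = None,
    vial_size_mg: float | None = None,
) -> float:
    """Per-administration docetaxel dose in mg.

    BSA-based dosing (dose_per_m2 × body surface area) with optional
    rounding up to whole vials; a fixed-dose override represents the flat
    140 mg per administration used in the source costing.
    """
    if fixed_dose_mg is not None:
        if fixed_dose_mg <= 0:
            raise ValueError("fixed dose must be positive")
        dose = fixed_dose_mg
    else:
        if bsa_m2 <= 0 or dose_per_m2 <= 0:
            raise ValueError("BSA and dose per m2 must be positive")
        dose = dose_per_m2 * bsa_m2
    if vial_size_mg is not None:
        if vial_size_mg <= 0:
            raise ValueError("vial size must be positive")
        dose = np.ceil(dose / vial_size_mg) * vial_size_mg
    return float(dose)


def state_membership(pfs_fit: ParametricFit, os_fit: ParametricFit, t):
    """Occupancy (pfs, pd, dead) at time t months; sums to one.

    Incoherent extrapolation tails (S_PFS > S_OS) clip PD at zero and
    absorb the excess into the death state.
    """
    s_pfs = survival_value(pfs_fit, t)
    s_os = survival_value(os_fit, t)
    pfs = np.asarray(s_pfs, dtype=float)
    pd_ = np.maximum(np.asarray(s_os, dtype=float) - pfs, 0.0)
    dead = 1.0 - pfs - pd_
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(pfs), float(pd_), float(dead)
    return pfs, pd_, dead


def build_trace(
    config: ModelConfig, pfs_fit: ParametricFit, os_fit: ParametricFit
) -> CohortTrace:
    """Evaluate occupancy at each cycle over the horizon.

    With half-cycle correction the curves are read at cycle midpoints
    (c − ½)·cycle length, otherwise at cycle ends.  New deaths per cycle
    are first differences of the death state, floored at zero.
    """
    c = np.arange(1, config.n_cycles + 1)
    offset = 0.5 if config.half_cycle_correction else 0.0
    t = (c - offset) * config.cycle_months
    pfs, pd_, dead = state_membership(pfs_fit, os_fit, t)
    new_deaths = np.maximum(np.diff(dead, prepend=0.0), 0.0)
    return CohortTrace(
        cycle=c, time_months=t, pfs=pfs, pd=pd_, dead=dead, new_deaths=new_deaths
    )


def run_arm(
    config: ModelConfig,
    costs: CostSet,
    utilities: UtilitySet,
    pfs_fit: ParametricFit,
    os_fit: ParametricFit,
) -> ArmResult:
    """Accumulate discounted costs and QALYs for one arm over the horizon.

    Drug cost follows progression-free occupancy (treatment runs to
    progression); follow-up and hospitalization follow everyone alive;
    best supportive care follows the progressed state; terminal care is
    charged once per new death; adverse-event costs (and, when enabled,
    utility decrements over one cycle) are one-time, incidence-weighted,
    applied undiscounted at model start.
    """
    trace = build_trace(config, pfs_fit, os_fit)
    alive = trace.pfs + trace.pd
    years = trace.time_months / 12.0
    disc_c = discount_factor(config.discount_rate_cost, years)
    disc_q = discount_factor(config.discount_rate_qaly, years)

    cost_breakdown = {
        "drug": float(np.sum(disc_c * costs.drug_cost_per_cycle * trace.pfs)),
        "followup": float(np.sum(disc_c * costs.followup_cost_per_cycle * alive)),
        "hospitalization": float(
            np.sum(disc_c * costs.hospitalization_cost_per_cycle * alive)
        ),
        "bsc": float(np.sum(disc_c * costs.bsc_cost_per_cycle * trace.pd)),
        "terminal": float(np.sum(disc_c * costs.terminal_cost * trace.new_deaths)),
        "ae": float(sum(e.incidence * e.unit_cost for e in costs.ae_events)),
    }

    cyc_years = config.cycle_years
    qaly_breakdown = {
        "pfs": float(np.sum(disc_q * cyc_years * utilities.u_pfs * trace.pfs)),
        "pd": float(np.sum(disc_q * cyc_years * utilities.u_pd * trace.pd)),
    }
    if config.apply_ae_disutility:
        # one-time decrement: incidence-weighted utility loss over one cycle
        qaly_breakdown["ae_disutility"] = -float(
            sum(e.incidence * e.disutility * cyc_years for e in utilities.ae_disutilities)
        )

    return ArmResult(
        total_cost=float(sum(cost_breakdown.values())),
        total_qaly=float(sum(qaly_breakdown.values())),
        cost_breakdown=cost_breakdown,
        qaly_breakdown=qaly_breakdown,
        trace=trace,
    )
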