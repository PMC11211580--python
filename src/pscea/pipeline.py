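"""Run configuration and end-to-end orchestration.

Ties the stages together: load (or generate) digitized curves, fit and
select survival families per arm and endpoint, build the partitioned-
survival traces, accumulate discounted costs and QALYs, compare arms
against the WTP band, and run the deterministic and probabilistic
sensitivity analyses.  Every emitted artifact is a delimited table or
JSON manifest; all randomness flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import AdverseEvent, ArmResult, CostSet, ModelConfig, UtilitySet, run_arm
from .curves import DigitizedCurve, read_curve, write_curve
from .economics import CEComparison, WTPBand, compare, interpret, wtp_thresholds
from .sensitivity import (
    ceac,
    ceac_crossover,
    ceac_frame,
    one_way,
    run_psa,
    tornado_frame,
)
from .survival import (
    FitSelection,
    enforce_endpoint_coherence,
    fit_all,
    fit_report,
    select_by_aic,
)
from .synthetic import table_to_specs, trial_like_bundle

ARMS = ("sotorasib", "docetaxel")
ENDPOINTS = ("PFS", "OS")

#: perspective presets; every field overridable in the config file
PRESETS = {
    "china": {
        "gdp_per_capita": 12374.81,
        "currency_per_usd": 6.92,
        "bsa_m2": 1.72,
        "discount_rate": 0.05,
    },
    "us": {
        "gdp_per_capita": 76348.0,
        "currency_per_usd": 1.0,
        "bsa_m2": 1.82,
        "discount_rate": 0.03,
    },
}


class ConfigurationError(ValueError):
    """Invalid or incomplete run configuration; message lists every
    missing piece at once."""


@dataclass(frozen=True)
class RunConfig:
    perspective: str = "china"
    gdp_per_capita: float = PRESETS["china"]["gdp_per_capita"]
    wtp_multipliers: tuple = (1.0, 3.0)
    model: ModelConfig = field(default_factory=ModelConfig)
    curve_paths: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    parameter_path: str | None = None
    bsa_m2: float = PRESETS["china"]["bsa_m2"]
    docetaxel_fixed_dose_mg: float | None = 140.0
    psa_n_draws: int = 1000
    seed: int = 20240614
    lambda_max: float = 250_000.0
    lambda_step: float = 2500.0

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.arange(0.0, self.lambda_max + self.lambda_step / 2, self.lambda_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"] = dataclasses.asdict(self.model)
        d["wtp_multipliers"] = list(self.wtp_multipliers)
        d["curve_paths"] = {a: dict(v) for a, v in self.curve_paths.items()}
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def config_from_dict(raw: Mapping) -> RunConfig:
    perspective = raw.get("perspective", "china")
    preset = PRESETS.get(perspective, PRESETS["china"])
    model_raw = dict(raw.get("model", {}))
    model_raw.setdefault("discount_rate_cost", preset["discount_rate"])
    model_raw.setdefault("discount_rate_qaly", preset["discount_rate"])
    model_raw.setdefault("currency_per_usd", preset["currency_per_usd"])
    psa = raw.get("psa", {})
    return RunConfig(
        perspective=perspective,
        gdp_per_capita=float(raw.get("gdp_per_capita", preset["gdp_per_capita"])),
        wtp_multipliers=tuple(raw.get("wtp_multipliers", (1.0, 3.0))),
        model=ModelConfig(**model_raw),
        curve_paths=raw.get("curves", {}),
        parameter_path=raw.get("parameters"),
        bsa_m2=float(raw.get("bsa_m2", preset["bsa_m2"])),
        docetaxel_fixed_dose_mg=raw.get("docetaxel_fixed_dose_mg", 140.0),
        psa_n_draws=int(psa.get("n_draws", 1000)),
        seed=int(psa.get("seed", raw.get("seed", 20240614))),
        lambda_max=float(psa.get("lambda_max", 250_000.0)),
        lambda_step=float(psa.get("lambda_step", 2500.0)),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def load_curves(config: RunConfig, base_dir: Path | None = None) -> dict:
    base = Path(base_dir) if base_dir else Path(".")
    missing = []
    curves = {}
    for arm in ARMS:
        for ep in ENDPOINTS:
            rel = config.curve_paths.get(arm, {}).get(ep.lower())
            if rel is None:
                missing.append(f"curves.{arm}.{ep.lower()}")
                continue
            path = base / rel
            if not path.exists():
                missing.append(str(path))
                continue
            curves[(arm, ep)] = read_curve(path, arm, ep)
    if missing:
        raise ConfigurationError("missing inputs: " + ", ".join(missing))
    return curves


# ---------------------------------------------------------------------------
# parameter-table assembly
# ---------------------------------------------------------------------------

def _role_values(table: pd.DataFrame, overrides: Mapping[str, float]) -> dict:
    values = {}
    for _, row in table.iterrows():
        values[row["role"]] = float(overrides.get(row["name"], row["base"]))
    return values


def assemble_inputs(
    table: pd.DataFrame, overrides: Mapping[str, float] | None = None
) -> dict:
    """Build per-arm (CostSet, UtilitySet) pairs from a parameter table,
    optionally with named-parameter overrides (sensitivity sweeps)."""
    vals = _role_values(table, overrides or {})
    out = {}
    for arm in ARMS:
        prefix_cost = f"ae_cost.{arm}."
        prefix_inc = f"ae_incidence.{arm}."
        prefix_dis = f"ae_disutility.{arm}."
        events = sorted(
            {r.split(".", 2)[2] for r in vals if r.startswith((prefix_cost, prefix_inc))}
        )
        ae_events = tuple(
            AdverseEvent(
                label=e,
                incidence=min(max(vals.get(prefix_inc + e, 0.0), 0.0), 1.0),
                unit_cost=vals.get(prefix_cost + e, 0.0),
                disutility=vals.get(prefix_dis + e, 0.0),
            )
            for e in events
        )
        costs = CostSet(
            drug_cost_per_cycle=vals.get(f"drug_cost.{arm}", 0.0),
            followup_cost_per_cycle=vals.get("followup_cost", 0.0),
            hospitalization_cost_per_cycle=vals.get("hospitalization_cost", 0.0),
            bsc_cost_per_cycle=vals.get("bsc_cost", 0.0),
            terminal_cost=vals.get("terminal_cost", 0.0),
            ae_events=ae_events,
        )
        utilities = UtilitySet(
            u_pfs=min(max(vals.get("utility.pfs", 0.0), 0.0), 1.0),
            u_pd=min(max(vals.get("utility.pd", 0.0), 0.0), 1.0),
            ae_disutilities=ae_events,
        )
        out[arm] = (costs, utilities)
    return out


# ---------------------------------------------------------------------------
# base case and closures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseCaseResult:
    selections: Mapping[tuple, FitSelection]
    arm_results: Mapping[str, ArmResult]
    comparison: CEComparison
    band: WTPBand
    decision: str
    coherence: Mapping[str, object]

    def comparison_frame(self) -> pd.DataFrame:
        rows = []
        for arm in ARMS:
            res = self.arm_results[arm]
            rows.append(
                {
                    "arm": arm,
                    "cost": res.total_cost,
                    "qaly": res.total_qaly,
                    "incr_cost": self.comparison.delta_cost if arm == ARMS[0] else np.nan,
                    "incr_qaly": self.comparison.delta_qaly if arm == ARMS[0] else np.nan,
                    "icer": (
                        self.comparison.icer
                        if arm == ARMS[0] and self.comparison.icer is not None
                        else np.nan
                    ),
                    "status": self.comparison.status if arm == ARMS[0] else "",
                    "decision": self.decision if arm == ARMS[0] else "",
                }
            )
        return pd.DataFrame(rows)


def fit_selections(curves: Mapping[tuple, DigitizedCurve]) -> dict:
    selections = {}
    for key, curve in curves.items():
        fits, failures = fit_all(curve)
        selections[key] = select_by_aic(fits, failures)
    return selections


def run_base_case(
    config: RunConfig,
    curves: Mapping[tuple, DigitizedCurve],
    table: pd.DataFrame,
    selections: Mapping[tuple, FitSelection] | None = None,
) -> BaseCaseResult:
    """Fit, trace, accumulate, compare — the deterministic base case."""
    if selections is None:
        selections = fit_selections(curves)
    inputs = assemble_inputs(table)
    grid = np.arange(1, config.model.n_cycles + 1) * config.model.cycle_months
    results, coherence = {}, {}
    for arm in ARMS:
        pfs_fit = selections[(arm, "PFS")].best_fit
        os_fit = selections[(arm, "OS")].best_fit
        coherence[arm] = enforce_endpoint_coherence(os_fit, pfs_fit, grid)
        costs, utilities = inputs[arm]
        results[arm] = run_arm(config.model, costs, utilities, pfs_fit, os_fit)
    cmp_ = compare(results[ARMS[0]], results[ARMS[1]])
    band = wtp_thresholds(config.gdp_per_capita, config.wtp_multipliers)
    decision = interpret(cmp_, band)
    return BaseCaseResult(
        selections=dict(selections),
        arm_results=results,
        comparison=cmp_,
        band=band,
        decision=decision,
        coherence=coherence,
    )


def make_eval_arms(config: RunConfig, selections, table: pd.DataFrame):
    """Closure evaluating both arms under named-parameter overrides —
    the single entry point the DSA and PSA share."""
    fits = {
        arm: (selections[(arm, "PFS")].best_fit, selections[(arm, "OS")].best_fit)
        for arm in ARMS
    }

    def eval_arms(overrides: Mapping[str, float]):
        inputs = assemble_inputs(table, overrides)
        out = []
        for arm in ARMS:
            costs, utilities = inputs[arm]
            out.append(run_arm(config.model, costs, utilities, *fits[arm]))
        return tuple(out)

    return eval_arms


def make_model_closure(config: RunConfig, selections, table: pd.DataFrame):
    eval_arms = make_eval_arms(config, selections, table)

    def model(overrides: Mapping[str, float]) -> CEComparison:
        intervention, comparator = eval_arms(overrides)
        return compare(intervention, comparator)

    return model


# ---------------------------------------------------------------------------
# full run with artifacts
# ---------------------------------------------------------------------------

def run_full(
    config: RunConfig,
    curves: Mapping[tuple, DigitizedCurve],
    table: pd.DataFrame,
    out_dir,
) -> dict:
    """One invocation producing every artifact: fit reports, traces, base
    case, tornado, PSA draws, CEAC — plus a JSON manifest.  Completed
    artifacts are kept when a later stage fails; failures are enumerated
    in the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written, errors = [], {}

    selections = fit_selections(curves)
    for (arm, ep), sel in selections.items():
        path = out / f"fits_{arm}_{ep.lower()}.csv"
        fit_report(sel).to_csv(path, index=False)
        written.append(path.name)

    base = run_base_case(config, curves, table, selections=selections)
    for arm in ARMS:
        trace = base.arm_results[arm].trace
        path = out / f"trace_{arm}.csv"
        trace.to_frame().to_csv(path, index=False)
        written.append(path.name)
    base.comparison_frame().to_csv(out / "base_case.csv", index=False)
    written.append("base_case.csv")

    specs = table_to_specs(table)
    model = make_model_closure(config, selections, table)
    try:
        entries = one_way(specs, model)
        tornado_frame(entries, specs).to_csv(out / "tornado.csv", index=False)
        written.append("tornado.csv")
    except Exception as exc:
        errors["tornado"] = str(exc)

    try:
        psa = run_psa(
            specs,
            make_eval_arms(config, selections, table),
            n_draws=config.psa_n_draws,
            seed=config.seed,
        )
        psa.to_frame().to_csv(out / "psa_draws.csv", index=False)
        written.append("psa_draws.csv")
        points = ceac(psa, config.lambda_grid)
        ceac_frame(points).to_csv(out / "ceac.csv", index=False)
        written.append("ceac.csv")
        crossover = ceac_crossover(points)
    except Exception as exc:
        errors["psa"] = str(exc)
        crossover = None

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "perspective": config.perspective,
        "decision": base.decision,
        "icer": base.comparison.icer,
        "ceac_crossover": crossover,
        "artifacts": written,
        "errors": errors,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def write_workspace(bundle, out_dir, config: RunConfig | None = None) -> Path:
    """Emit a ready-to-run workspace: curve files, parameter table, and a
    config file pointing at them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve_paths: dict = {}
    for (arm, ep), curve in bundle.curves.items():
        rel = f"{arm}_{ep.lower()}.csv"
        write_curve(curve, out / rel)
        curve_paths.setdefault(arm, {})[ep.lower()] = rel
    bundle.parameters.to_csv(out / "parameters.csv", index=False)
    cfg = config or RunConfig()
    raw = cfg.to_dict()
    raw["curves"] = curve_paths
    raw["parameters"] = "parameters.csv"
    raw["psa"] = {
        "n_draws": raw.pop("psa_n_draws"),
        "seed": raw.pop("seed"),
        "lambda_max": raw.pop("lambda_max"),
        "lambda_step": raw.pop("lambda_step"),
    }
    raw.pop("curve_paths")
    raw.pop("parameter_path")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    return out / "config.yaml"


def pfs_recovery(
    median: float,
    s_at_12mo: float,
    seeds,
    arm: str = "arm",
    noise_sd: float = 0.01,
    n_points: int = 40,
    t_max: float = 18.0,
) -> pd.DataFrame:
    """Calibration-recovery experiment for one arm's PFS curve.

    For each seed: build the lognormal implied by the published median and
    12-month rate, digitize it with noise, fit all seven families, select
    by AIC, and read the selected fit's median and 12-month survival back.
    Returns one row per seed.
    """
    from .survival import median_survival, survival_value
    from .synthetic import CurveRecipe, generate_km_points, lognormal_from_summaries

    mu, sigma = lognormal_from_summaries(median, s_at_12mo, 12.0)
    rows = []
    for seed in seeds:
        curve = generate_km_points(
            CurveRecipe(
                family="lognormal",
                params={"mu": mu, "sigma": sigma},
                n_points=n_points,
                t_max=t_max,
                noise_sd=noise_sd,
                seed=int(seed),
                arm=arm,
                endpoint="PFS",
            )
        )
        fits, failures = fit_all(curve)
        sel = select_by_aic(fits, failures)
        rows.append(
            {
                "seed": int(seed),
                "family": sel.best,
                "median": median_survival(sel.best_fit),
                "s_12mo": survival_value(sel.best_fit, 12.0),
            }
        )
    return pd.DataFrame(rows)


def synth_workspace(seed: int, out_dir, perspective: str = "china") -> Path:
    """Generate a complete synthetic workspace in one call."""
    bundle = trial_like_bundle(seed=seed, perspective=perspective)
    preset = PRESETS[perspective]
    cfg = RunConfig(
        perspective=perspective,
        gdp_per_capita=preset["gdp_per_capita"],
        bsa_m2=preset["bsa_m2"],
        model=ModelConfig(
            discount_rate_cost=preset["discount_rate"],
            discount_rate_qaly=preset["discount_rate"],
            currency_per_usd=preset["currency_per_usd"],
        ),
        seed=seed,
    )
    return write_workspace(bundle, out_dir, cfg)
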