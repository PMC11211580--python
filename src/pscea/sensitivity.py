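"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis sweeps each parameter to its low and high
bound with everything else at base and records the ICER spread.
Probabilistic sensitivity analysis (second-order Monte Carlo) jointly
samples every parameter from its assigned distribution — beta for
[0,1]-bounded quantities, gamma for non-negative ones, moment-matched to
the base value and a standard deviation read from the bounds as a 95%
interval — and re-evaluates both arms per draw.  The cost-effectiveness
acceptability curve (CEAC) is the fraction of draws in which the
intervention has the higher net monetary benefit at each
willingness-to-pay value.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import CEComparison

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PsaRun",
    "CeacPoint",
    "default_bounds",
    "one_way",
    "moment_match",
    "run_psa",
    "ceac",
    "ceac_crossover",
    "DEFAULT_LAMBDA_GRID",
]

#: 0 to 250,000 $/QALY in 2,500 steps — spans both countries' 3×GDP
DEFAULT_LAMBDA_GRID = np.arange(0, 250_001, 2500, dtype=float)


class PsaError(RuntimeError):
    """Too many failed draws for the run to be trustworthy."""


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain model input: base value, bounds, and PSA distribution.

    ``role`` is a dotted pointer into the model inputs (e.g.
    ``drug_cost.sotorasib`` or ``utility.pfs``) that the model closure
    understands; ``distribution`` is beta (bounded quantities) or gamma
    (non-negative quantities).
    """

    name: str
    base: float
    low: float
    high: float
    distribution: str
    role: str = ""
    synthetic: bool = False

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.distribution not in ("beta", "gamma"):
            raise ValueError(f"{self.name}: distribution must be beta or gamma")
        if self.distribution == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires values in [0, 1]")
        if self.distribution == "gamma" and self.low < 0:
            raise ValueError(f"{self.name}: gamma requires non-negative values")


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float
    error: str | None = None

    @property
    def spread(self) -> float:
        if self.error is not None:
            return float("nan")
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PsaRun:
    """Per-draw costs and QALYs for both arms plus the sampled parameters."""

    n_draws: int
    seed: int
    cost_intervention: np.ndarray
    qaly_intervention: np.ndarray
    cost_comparator: np.ndarray
    qaly_comparator: np.ndarray
    parameters: pd.DataFrame
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "cost_intervention": self.cost_intervention,
                "qaly_intervention": self.qaly_intervention,
                "cost_comparator": self.cost_comparator,
                "qaly_comparator": self.qaly_comparator,
            }
        )
        return pd.concat([out, self.parameters.reset_index(drop=True)], axis=1)


@dataclass(frozen=True)
class CeacPoint:
    wtp: float
    p_intervention: float

    @property
    def p_comparator(self) -> float:
        return 1.0 - self.p_intervention


def default_bounds(base: float, is_utility: bool = False) -> tuple:
    """±20% bounds for parameters whose source gives no interval; utility
    upper bounds are capped at 1."""
    low, high = 0.8 * base, 1.2 * base
    if is_utility:
        high = min(high, 1.0)
    return (low, high)


def one_way(
    specs: Sequence[ParamSpec],
    model: Callable[[Mapping[str, float]], CEComparison],
) -> list:
    """Sweep each parameter to its bounds, all others at base; entries are
    returned in tornado order (largest ICER spread first).  A model failure
    at a bound flags the entry rather than dropping it."""

    def icer_at(name: str, value: float) -> float:
        cmp_ = model({name: value})
        if cmp_.icer is None:
            # dominance carries sign information: dominant = favorable
            return -np.inf if cmp_.status == "dominant" else np.inf
        return cmp_.icer

    entries = []
    for spec in specs:
        try:
            lo = icer_at(spec.name, spec.low)
            hi = icer_at(spec.name, spec.high)
            entries.append(TornadoEntry(spec.name, lo, hi))
        except Exception as exc:  # flagged, not dropped
            entries.append(TornadoEntry(spec.name, np.nan, np.nan, error=str(exc)))
    entries.sort(key=lambda e: (np.isnan(e.spread), -(e.spread if np.isfinite(e.spread) else np.inf)))
    return entries


@dataclass(frozen=True)
class MatchedDistribution:
    """Sampling distribution for one parameter after moment matching."""

    kind: str  # beta | gamma | uniform | point
    params: tuple

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.params[0])
        if self.kind == "beta":
            return rng.beta(*self.params, size=size)
        if self.kind == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size=size)
        if self.kind == "uniform":
            return rng.uniform(*self.params, size=size)
        raise ValueError(self.kind)

    @property
    def mean(self) -> float:
        if self.kind == "point":
            return self.params[0]
        if self.kind == "beta":
            a, b = self.params
            return a / (a + b)
        if self.kind == "gamma":
            return self.params[0] * self.params[1]
        lo, hi = self.params
        return (lo + hi) / 2.0


def moment_match(spec: ParamSpec) -> MatchedDistribution:
    """Distribution parameters matched to the spec's mean and a standard
    deviation of (high − low)/(2·1.96), reading the bounds as a 95%
    interval.

    Beta: α = m·(m(1−m)/s² − 1), β = (1−m)·(same); infeasible variance
    (s² ≥ m(1−m)) falls back to uniform(low, high) with a warning.
    Gamma: shape = m²/s², scale = s²/m.
    """
    m = spec.base
    s = (spec.high - spec.low) / (2 * 1.96)
    if s == 0 or m == 0:
        return MatchedDistribution("point", (m,))
    s2 = s * s
    if spec.distribution == "beta":
        if s2 >= m * (1 - m):
            warnings.warn(
                f"{spec.name}: beta variance infeasible (s²={s2:.4g} ≥ m(1−m)); "
                "falling back to uniform(low, high)",
                stacklevel=2,
            )
            return MatchedDistribution("uniform", (spec.low, spec.high))
        nu = m * (1 - m) / s2 - 1
        return MatchedDistribution("beta", (m * nu, (1 - m) * nu))
    return MatchedDistribution("gamma", (m * m / s2, s2 / m))


def _substream(seed: int, name: str) -> np.random.Generator:
    # per-parameter stream keyed on the name so adding/removing one
    # parameter leaves every other parameter's draws untouched
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


def run_psa(
    specs: Sequence[ParamSpec],
    eval_arms: Callable[[Mapping[str, float]], tuple],
    n_draws: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.01,
) -> PsaRun:
    """Second-order Monte Carlo over all parameters.

    ``eval_arms(overrides)`` must return ((cost, qaly) intervention,
    (cost, qaly) comparator) — both arms re-evaluated under the same
    jointly sampled parameter set.  Reproducible given ``seed``.  More
    than ``max_failure_fraction`` failed draws aborts the run.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    draws = {
        spec.name: moment_match(spec).sample(_substream(seed, spec.name), n_draws)
        for spec in specs
    }
    params = pd.DataFrame(draws)
    ci = np.empty(n_draws)
    qi = np.empty(n_draws)
    cc = np.empty(n_draws)
    qc = np.empty(n_draws)
    failures = []
    for i in range(n_draws):
        overrides = {name: float(col[i]) for name, col in draws.items()}
        try:
            (ci[i], qi[i]), (cc[i], qc[i]) = _as_pairs(eval_arms(overrides))
        except Exception as exc:
            ci[i] = qi[i] = cc[i] = qc[i] = np.nan
            failures.append((i, str(exc)))
    if len(failures) > max_failure_fraction * n_draws:
        raise PsaError(
            f"{len(failures)}/{n_draws} draws failed; first: {failures[0]}"
        )
    return PsaRun(
        n_draws=n_draws,
        seed=seed,
        cost_intervention=ci,
        qaly_intervention=qi,
        cost_comparator=cc,
        qaly_comparator=qc,
        parameters=params,
        n_failed=len(failures),
    )


def _as_pairs(result):
    a, b = result
    if hasattr(a, "total_cost"):
        a = (a.total_cost, a.total_qaly)
    if hasattr(b, "total_cost"):
        b = (b.total_cost, b.total_qaly)
    return (float(a[0]), float(a[1])), (float(b[0]), float(b[1]))


def ceac(psa: PsaRun, lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID) -> list:
    """Acceptability-curve points: at each λ the fraction of draws where
    the intervention has strictly higher net monetary benefit (ties count
    to the comparator)."""
    lam = np.asarray(lambda_grid, dtype=float)
    ok = ~np.isnan(psa.cost_intervention)
    if not ok.any():
        raise ValueError("PSA run has no successful draws")
    nmb_i = lam[:, None] * psa.qaly_intervention[ok] - psa.cost_intervention[ok]
    nmb_c = lam[:, None] * psa.qaly_comparator[ok] - psa.cost_comparator[ok]
    p = (nmb_i > nmb_c).mean(axis=1)
    return [CeacPoint(float(l), float(pi)) for l, pi in zip(lam, p)]


def ceac_crossover(points: Sequence[CeacPoint]) -> float | None:
    """Smallest grid λ at which the intervention reaches probability 0.5;
    None when the curve never gets there."""
    if len(points) < 2:
        raise ValueError("need at least two CEAC points")
    for pt in points:
        if pt.p_intervention >= 0.5:
            return pt.wtp
    return None


def tornado_frame(entries: Sequence[TornadoEntry], specs: Sequence[ParamSpec]) -> pd.DataFrame:
    """Plot-ready tornado table (sorted by spread, descending)."""
    bounds = {s.name: (s.low, s.high) for s in specs}
    rows = []
    for e in entries:
        lo, hi = bounds.get(e.name, (np.nan, np.nan))
        rows.append(
            {
                "name": e.name,
                "low": lo,
                "high": hi,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "spread": e.spread,
                "error": e.error or "",
            }
        )
    return pd.DataFrame(rows)


def ceac_frame(points: Sequence[CeacPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lambda": [p.wtp for p in points],
            "p_intervention": [p.p_intervention for p in points],
            "p_comparator": [p.p_comparator for p in points],
        }
    )
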