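"""Digitized Kaplan-Meier curve container and delimited-text I/O.

A digitized curve is the (time, survival) coordinate list a plot
digitizer extracts from a published KM figure: times in months,
survival probabilities in [0, 1], one curve per arm and endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: survival increases up to this size are treated as digitizer jitter and clamped
_MONOTONE_TOL = 1e-9


class CurveError(ValueError):
    """Raised when digitized coordinates violate the curve invariants."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time, survival) coordinates for one arm and endpoint.

    Invariants enforced at construction: times strictly increasing and
    non-negative; survival in [0, 1] and non-increasing (plateaus allowed;
    increases up to 1e-9 are clamped, anything larger is rejected).
    """

    arm: str
    endpoint: str
    times: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float).copy()
        if t.ndim != 1 or s.shape != t.shape:
            raise CurveError("times and survival must be 1-D arrays of equal length")
        if t.size == 0:
            raise CurveError("curve has no points")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(s)):
            raise CurveError("non-finite coordinates")
        if np.any(t < 0):
            raise CurveError("negative times")
        if np.any(np.diff(t) <= 0):
            raise CurveError("times must be strictly increasing")
        if np.any(s < 0) or np.any(s > 1):
            raise CurveError("survival values outside [0, 1]")
        rises = np.diff(s)
        if np.any(rises > _MONOTONE_TOL):
            raise CurveError("survival increases beyond tolerance")
        # clamp sub-tolerance digitizer jitter to a running minimum
        s = np.minimum.accumulate(s)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})


def read_curve(path, arm: str, endpoint: str) -> DigitizedCurve:
    """Read a digitized curve from delimited text (comma or tab).

    Expects a header with ``time_months`` and ``survival`` columns.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"time_months", "survival"} - set(df.columns)
    if missing:
        raise CurveError(f"{path}: missing columns {sorted(missing)}")
    return DigitizedCurve(
        arm=arm,
        endpoint=endpoint,
        times=df["time_months"].to_numpy(float),
        survival=df["survival"].to_numpy(float),
    )


def write_curve(curve: DigitizedCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)
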