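"""Time-signal curve container and delimited-text I/O.

First-pass perfusion analysis operates on one-dimensional signal-intensity
curves sampled on a uniform time grid: the arterial input function (AIF)
extracted from the blood pool and the tissue response extracted from the
myocardium. Curves are exchanged as two-column delimited text files with
header ``time_s,value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignalCurve", "read_curve", "write_curve"]

#: relative tolerance on grid uniformity
_DT_RTOL = 1e-9


@dataclass
class SignalCurve:
    """A signal-intensity curve on a uniform time grid.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing with uniform spacing.
    values : array of float
        Signal intensity at each sample (arbitrary units).
    baseline_window : (int, int), optional
        Half-open index range ``[start, stop)`` of samples used to estimate
        the pre-contrast baseline. ``None`` means "use a leading default".
    """

    times: np.ndarray
    values: np.ndarray
    baseline_window: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size < 8:
            raise ValueError("a signal curve needs at least 8 samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        dt = steps[0]
        if not np.allclose(steps, dt, rtol=_DT_RTOL, atol=0.0):
            raise ValueError(
                "non-uniform time grid: perfusion quantification requires "
                "uniformly sampled curves (relative tolerance 1e-9)"
            )
        if self.baseline_window is not None:
            lo, hi = self.baseline_window
            if not (0 <= lo < hi <= self.times.size):
                raise ValueError(
                    f"baseline_window {self.baseline_window} outside curve "
                    f"of length {self.times.size}"
                )
            self.baseline_window = (int(lo), int(hi))

    @property
    def dt(self) -> float:
        """Uniform sample spacing in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return int(self.times.size)

    def baseline_stats(self, default_n: int = 5) -> tuple[float, float]:
        """Mean and SD of the baseline segment.

        Falls back to the first ``default_n`` samples when no explicit
        window is set.
        """
        if self.baseline_window is not None:
            lo, hi = self.baseline_window
        else:
            lo, hi = 0, min(default_n, self.n)
        seg = self.values[lo:hi]
        sd = float(seg.std(ddof=1)) if seg.size > 1 else 0.0
        return float(seg.mean()), sd

    def with_values(self, values: np.ndarray) -> "SignalCurve":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values})


def write_curve(curve: SignalCurve, path: str | Path) -> None:
    """Write a curve as ``time_s,value`` delimited text."""
    curve.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_curve(
    path: str | Path, baseline_window: tuple[int, int] | None = None
) -> SignalCurve:
    """Read a ``time_s,value`` delimited-text curve file."""
    df = pd.read_csv(path)
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"curve file {path} lacks columns: {sorted(missing)}")
    return SignalCurve(
        times=df["time_s"].to_numpy(),
        values=df["value"].to_numpy(),
        baseline_window=baseline_window,
    )
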