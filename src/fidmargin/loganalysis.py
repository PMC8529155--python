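"""In-treatment motion analysis from tracking log traces.

Treatment logs provide time-stamped 3D coordinates of the tracked
fiducial centroid over one fraction.  Per axis, the signal is segmented
into breathing cycles at successive prominent maxima; each cycle's
amplitude is its max - min, and the fraction amplitude is the mean of
the per-cycle amplitudes (robust to baseline drift).  Pretreatment
(4D-CT) and in-treatment amplitudes are compared with a paired
two-tailed t-test.

Log format: a generic delimited text table with columns
``time_s, x_mm, y_mm, z_mm`` (and optionally ``fraction_id``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "LogTrace",
    "FractionAmplitudes",
    "PairedTestResult",
    "read_log_csv",
    "fraction_amplitude",
    "paired_t_test",
]

AMPLITUDE_METHODS = ("cycle_mean", "global_range", "percentile_95_5")


@dataclass
class LogTrace:
    """Time-stamped tracked 3D coordinates of one treatment fraction."""

    fraction_id: str
    time_s: np.ndarray        # (n,)
    position_mm: np.ndarray   # (n, 3)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.position_mm = np.asarray(self.position_mm, float)
        if self.position_mm.ndim != 2 or self.position_mm.shape[1] != 3:
            raise ValueError("position_mm must have shape (n, 3)")
        if self.time_s.shape[0] != self.position_mm.shape[0]:
            raise ValueError("time and position lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time stamps must be strictly increasing")


@dataclass
class FractionAmplitudes:
    fraction_id: str
    amplitude_mm: np.ndarray  # (3,)
    n_cycles: np.ndarray      # (3,) cycles used per axis


@dataclass
class PairedTestResult:
    n: int
    mean_diff_mm: np.ndarray
    sd_diff_mm: np.ndarray
    t_statistic: np.ndarray
    dof: int
    p_value: np.ndarray
    degenerate: np.ndarray    # per-axis flag: zero-variance differences


def read_log_csv(path) -> list[LogTrace]:
    """Read one or more fraction traces from a delimited log file."""
    df = pd.read_csv(path)
    required = {"time_s", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"log file must have columns {sorted(required)}")
    if "fraction_id" not in df.columns:
        df["fraction_id"] = "fraction_1"
    traces = []
    for fid, grp in df.groupby("fraction_id", sort=False):
        traces.append(
            LogTrace(
                fraction_id=str(fid),
                time_s=grp["time_s"].to_numpy(),
                position_mm=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            )
        )
    return traces


def fraction_amplitude(
    trace: LogTrace,
    method: str = "cycle_mean",
    min_prominence_mm: float = 1.0,
) -> FractionAmplitudes:
    """Per-axis breathing amplitude of one treatment fraction.

    ``cycle_mean`` (default): split each axis signal at successive maxima
    with prominence >= ``min_prominence_mm``; per-cycle amplitude is the
    max - min within the cycle; the fraction amplitude is their mean.
    ``global_range``: max - min over the whole trace.
    ``percentile_95_5``: 95th - 5th percentile over the whole trace.
    """
    if method not in AMPLITUDE_METHODS:
        raise ValueError(f"method must be one of {AMPLITUDE_METHODS}")
    amp = np.zeros(3)
    ncyc = np.zeros(3, dtype=int)
    for ax in range(3):
        x = trace.position_mm[:, ax]
        if method == "global_range":
            amp[ax] = x.max() - x.min()
            continue
        if method == "percentile_95_5":
            amp[ax] = np.percentile(x, 95) - np.percentile(x, 5)
            continue
        if x.max() - x.min() < min_prominence_mm:
            # axis essentially still: amplitude is its (sub-prominence) range
            amp[ax] = x.max() - x.min()
            continue
        peaks, _ = signal.find_peaks(x, prominence=min_prominence_mm)
        if peaks.size < 3:  # k maxima delimit k-1 full cycles
            raise ValueError(
                f"fraction {trace.fraction_id!r}, axis {ax}: fewer than 2 "
                "complete breathing cycles detected; consider lowering "
                f"min_prominence_mm (currently {min_prominence_mm} mm)"
            )
        cycles = [x[peaks[i]:peaks[i + 1] + 1] for i in range(peaks.size - 1)]
        amp[ax] = float(np.mean([c.max() - c.min() for c in cycles]))
        ncyc[ax] = len(cycles)
    if method == "cycle_mean" and not ncyc.any():
        raise ValueError(
            f"fraction {trace.fraction_id!r}: no axis shows at least 2 "
            "breathing cycles (trace may be static); consider lowering "
            f"min_prominence_mm (currently {min_prominence_mm} mm)"
        )
    return FractionAmplitudes(fraction_id=trace.fraction_id,
                              amplitude_mm=amp, n_cycles=ncyc)


def paired_t_test(pre, during) -> PairedTestResult:
    """Paired two-tailed t-test of in-treatment vs pretreatment amplitudes.

    Differences d = during - pre; t = mean(d) / (sd(d)/sqrt(n)) with
    sample sd (n-1 denominator); two-tailed p from Student's t with
    n-1 degrees of freedom.  ``pre`` and ``during`` are (n,) or (n, 3)
    arrays; per-axis results are returned for the latter.
    """
    pre = np.atleast_2d(np.asarray(pre, float))
    during = np.atleast_2d(np.asarray(during, float))
    if pre.shape[0] == 1:
        pre, during = pre.T, during.T
    if pre.shape != during.shape:
        raise ValueError("pre and during must have equal shapes")
    n = pre.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = during - pre
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    dof = n - 1
    t = np.zeros_like(mean)
    p = np.ones_like(mean)
    degenerate = np.zeros(mean.shape, dtype=bool)
    nonzero_sd = sd > 0
    t[nonzero_sd] = mean[nonzero_sd] / (sd[nonzero_sd] / np.sqrt(n))
    p[nonzero_sd] = 2.0 * stats.t.sf(np.abs(t[nonzero_sd]), dof)
    zero_sd = ~nonzero_sd
    # sd=0, mean!=0: the difference is an exact constant -> flag, p=0
    degenerate[zero_sd & (mean != 0)] = True
    p[zero_sd & (mean != 0)] = 0.0
    t[zero_sd & (mean != 0)] = np.inf * np.sign(mean[zero_sd & (mean != 0)])
    # sd=0, mean=0: identical measurements -> t=0, p=1 (already set)
    return PairedTestResult(
        n=n,
        mean_diff_mm=mean,
        sd_diff_mm=sd,
        t_statistic=t,
        dof=dof,
        p_value=p,
        degenerate=degenerate,
    )
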