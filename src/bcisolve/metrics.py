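"""Benchmark deviation metrics: RD, MAPE and MAD.

RD is the signed relative deviation in percent, (calc - ref)/ref * 100,
so a calculated value below the reference is negative.  MAPE is the mean
of |RD| over a paired series, and MAD is the mean absolute deviation in
the input units (the convention used for harmonic vibrational
frequencies, where a percentage would mix scales across modes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairedSeries",
    "MetricsReport",
    "UndefinedMetricError",
    "relative_deviation",
    "rd_series",
    "mape",
    "mad",
    "metrics_report",
    "read_pairs_csv",
]


class UndefinedMetricError(ValueError):
    """A relative metric was requested with a zero reference value."""


@dataclass
class PairedSeries:
    """Labeled reference/calculated value pairs in a common unit."""

    labels: list[str]
    ref: np.ndarray
    calc: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=float)
        self.calc = np.asarray(self.calc, dtype=float)
        if not (len(self.labels) == self.ref.size == self.calc.size):
            raise ValueError("labels, ref and calc must have equal lengths")
        if self.ref.size == 0:
            raise ValueError("series must contain at least one pair")
        if not (np.isfinite(self.ref).all() and np.isfinite(self.calc).all()):
            raise ValueError("ref and calc must be finite")

    def __len__(self) -> int:
        return self.ref.size


@dataclass
class MetricsReport:
    labels: list[str]
    rd: np.ndarray  # percent, signed, per entry
    mape: float  # percent
    mad: float  # input units

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "rd_percent": self.rd})


def relative_deviation(ref: float, calc: float) -> float:
    """Signed percent deviation of calc from ref: 100 (calc - ref)/ref."""
    if ref == 0:
        raise UndefinedMetricError("relative deviation undefined for ref = 0")
    return 100.0 * (calc - ref) / ref


def rd_series(series: PairedSeries) -> np.ndarray:
    if np.any(series.ref == 0):
        bad = [l for l, r in zip(series.labels, series.ref) if r == 0]
        raise UndefinedMetricError(f"zero reference value(s) for {bad}")
    return 100.0 * (series.calc - series.ref) / series.ref


def mape(series: PairedSeries) -> float:
    """Mean absolute percentage deviation: mean of |RD| over the series."""
    return float(np.mean(np.abs(rd_series(series))))


def mad(series: PairedSeries) -> float:
    """Mean absolute deviation in input units; shift-invariant in both columns."""
    return float(np.mean(np.abs(series.calc - series.ref)))


def metrics_report(series: PairedSeries) -> MetricsReport:
    rd = rd_series(series)
    return MetricsReport(
        labels=list(series.labels),
        rd=rd,
        mape=float(np.mean(np.abs(rd))),
        mad=mad(series),
    )


def read_pairs_csv(path) -> PairedSeries:
    """Read a CSV with columns label, ref, calc into a PairedSeries."""
    df = pd.read_csv(path, comment="#")
    missing = {"label", "ref", "calc"} - set(df.columns)
    if missing:
        raise ValueError(f"CSV missing column(s): {sorted(missing)}")
    return PairedSeries(
        labels=[str(x) for x in df["label"]],
        ref=df["ref"].to_numpy(dtype=float),
        calc=df["calc"].to_numpy(dtype=float),
    )
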