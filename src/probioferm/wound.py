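"""Scratch-assay wound-closure kinetics.

A scratch (wound-healing) assay tracks the open wound area A(t) of a cell
monolayer gap from time-lapse images.  Closure percent is

    closure(t) = 100 * (A0 - A(t)) / A0

with A0 the area at time zero.  Crossing times to fixed closure thresholds
(e.g. 20/60/80%) are read off each field-of-view curve by linear
interpolation between the bracketing samples, then summarized per treatment
group as mean +/- sd over fields (fields that never reach a threshold are
censored: excluded from the mean and counted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClosureCurve",
    "ClosureSummary",
    "closure_percent",
    "time_to_closure",
    "summarize_groups",
    "curves_from_frame",
]


def closure_percent(a0: float, at: float) -> float:
    """Percent wound closure from the t0 area and the current area."""
    if a0 <= 0:
        raise ValueError("initial wound area must be positive")
    if at < 0:
        raise ValueError("wound area cannot be negative")
    return 100.0 * (a0 - at) / a0


@dataclass
class ClosureCurve:
    """Wound area versus time for one field of view (arbitrary area units)."""

    field_id: str
    times: np.ndarray  # h, strictly increasing from 0
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.shape != self.areas.shape:
            raise ValueError("times and areas must have equal length")
        if self.times.size == 0 or self.times[0] != 0.0:
            raise ValueError("curve must start at t = 0")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.areas[0] <= 0:
            raise ValueError("area at t0 must be positive")
        if (self.areas < 0).any():
            raise ValueError("areas cannot be negative")

    @property
    def a0(self) -> float:
        return float(self.areas[0])

    def closure(self, envelope: bool = False) -> np.ndarray:
        """Closure-percent curve; ``envelope`` applies a running max
        (monotone envelope) to de-noise non-monotone curves."""
        c = 100.0 * (self.a0 - self.areas) / self.a0
        return np.maximum.accumulate(c) if envelope else c


def time_to_closure(
    curve: ClosureCurve, threshold: float, envelope: bool = False
) -> float | None:
    """First time the closure curve crosses ``threshold`` percent.

    Linear interpolation between the bracketing samples; ``None`` marks a
    censored field (threshold never reached within the watch window).
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100) percent")
    c = curve.closure(envelope=envelope)
    t = curve.times
    above = c >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (threshold - c[i - 1]) / (c[i] - c[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


@dataclass
class ClosureSummary:
    """Per-threshold crossing-time statistics over the fields of one group."""

    group: str
    thresholds: list[float]
    mean: dict[float, float | None]
    sd: dict[float, float | None]  # None when fewer than 2 uncensored fields
    n: dict[float, int]
    censored: dict[float, int]

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "per_threshold": {
                str(th): {
                    "mean_h": self.mean[th],
                    "sd_h": self.sd[th],
                    "n": self.n[th],
                    "censored": self.censored[th],
                }
                for th in self.thresholds
            },
        }


def _summarize(
    group: str,
    curves: Sequence[ClosureCurve],
    thresholds: Sequence[float],
    envelope: bool,
) -> ClosureSummary:
    mean, sd, n, cens = {}, {}, {}, {}
    for th in thresholds:
        times = [time_to_closure(c, th, envelope=envelope) for c in curves]
        hit = np.array([t for t in times if t is not None], dtype=float)
        cens[th] = sum(t is None for t in times)
        n[th] = hit.size
        mean[th] = float(hit.mean()) if hit.size else None
        sd[th] = float(hit.std(ddof=1)) if hit.size >= 2 else None
    return ClosureSummary(
        group=group, thresholds=list(thresholds), mean=mean, sd=sd, n=n, censored=cens
    )


def summarize_groups(
    ctr: Sequence[ClosureCurve],
    trt: Sequence[ClosureCurve],
    thresholds: Sequence[float] = (20.0, 60.0, 80.0),
    envelope: bool = False,
) -> dict:
    """Treatment-versus-control closure-time summary.

    Returns both group summaries plus treatment/control ratios of the mean
    crossing times (None where either group is fully censored).
    """
    if not ctr or not trt:
        raise ValueError("each group needs at least one curve")
    s_ctr = _summarize("control", ctr, thresholds, envelope)
    s_trt = _summarize("treatment", trt, thresholds, envelope)
    ratios = {}
    for th in thresholds:
        m_c, m_t = s_ctr.mean[th], s_trt.mean[th]
        ratios[th] = (m_t / m_c) if (m_c and m_t is not None) else None
    return {"control": s_ctr, "treatment": s_trt, "time_ratio_trt_over_ctr": ratios}


def summary_to_json(summary: dict, path) -> None:
    payload = {
        "control": summary["control"].to_dict(),
        "treatment": summary["treatment"].to_dict(),
        "time_ratio_trt_over_ctr": {
            str(k): v for k, v in summary["time_ratio_trt_over_ctr"].items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def curves_from_frame(df: pd.DataFrame, group: str | None = None) -> list[ClosureCurve]:
    """Build curves from a long table with columns group, field_id, t_h, area."""
    if group is not None:
        df = df[df["group"] == group]
    curves = []
    for fid, sub in df.groupby("field_id"):
        sub = sub.sort_values("t_h")
        curves.append(
            ClosureCurve(
                field_id=str(fid),
                times=sub["t_h"].to_numpy(),
                areas=sub["area"].to_numpy(),
            )
        )
    return curves
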