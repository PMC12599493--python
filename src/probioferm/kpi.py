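"""Process key-performance indicators: yields, productivities, fold changes.

Yield is product formed per substrate consumed (g/g, deliberately not capped
at 1: lactic acid bacteria co-catabolize amino acids from the nitrogen
sources into lactate, so apparent yields above 1 g/g are real).
Productivity is titer over process duration, g/(L h).  Fold changes between
process records are reported under an explicit, test-visible rounding
convention because published comparisons mix precisions (e.g. 6.68-fold
alongside 2.5-fold and 13-fold).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "ProcessRecord",
    "FoldConvention",
    "KPIReport",
    "compute_yield",
    "compute_productivity",
    "fold_change",
    "build_comparison",
    "trajectory_kpis",
    "DEFAULT_CONVENTION",
    "PRECISE_CONVENTION",
]


@dataclass(frozen=True)
class ProcessRecord:
    """One fermentation outcome row (bottle, batch or fed-batch)."""

    label: str
    medium: str = ""
    mode: str = "batch"  # batch | fedbatch | bottle
    od600: float | None = None
    dcw: float | None = None  # g/L
    eps: float | None = None  # g/L
    viability: float | None = None  # CFU/mL
    lactate: float | None = None  # g/L
    substrate_consumed: float | None = None  # g/L
    duration: float | None = None  # h

    def metric(self, name: str) -> float:
        if name == "yield":
            return compute_yield(self.lactate, self.substrate_consumed)
        if name == "productivity":
            return compute_productivity(self.lactate, self.duration)
        if not hasattr(self, name):
            raise KeyError(f"unknown metric {name!r}")
        value = getattr(self, name)
        if value is None:
            raise KeyError(f"record {self.label!r} has no value for {name!r}")
        return float(value)


def compute_yield(lactate_produced: float, substrate_consumed: float) -> float:
    """Product yield Y_P/S = lactate / substrate consumed (g/g), uncapped."""
    if substrate_consumed is None or substrate_consumed <= 0:
        raise ValueError("yield undefined: substrate consumed must be positive")
    return float(lactate_produced) / float(substrate_consumed)


def compute_productivity(lactate: float, duration: float) -> float:
    """Volumetric productivity = titer / duration, g/(L h)."""
    if duration is None or duration <= 0:
        raise ValueError("productivity undefined: duration must be positive")
    return float(lactate) / float(duration)


def _round_half_up(x: float, decimals: int) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class FoldConvention:
    """Rounding rule for reported fold changes.

    Values at or above ``integer_from`` round to the nearest integer;
    smaller values keep ``decimals_below`` decimal places (half-up).
    """

    decimals_below: int = 1
    integer_from: float = 10.0

    def apply(self, x: float) -> float:
        if x >= self.integer_from:
            return float(_round_half_up(x, 0))
        return _round_half_up(x, self.decimals_below)


DEFAULT_CONVENTION = FoldConvention(decimals_below=1, integer_from=10.0)
PRECISE_CONVENTION = FoldConvention(decimals_below=2, integer_from=10.0)


def fold_change(
    numerator: float,
    denominator: float,
    convention: FoldConvention = DEFAULT_CONVENTION,
) -> float:
    """Ratio of two process metrics, rounded per the stated convention."""
    if denominator <= 0:
        raise ValueError("fold change undefined for non-positive denominator")
    return convention.apply(numerator / denominator)


@dataclass
class KPIReport:
    """Per-record KPIs and pairwise fold-change tables."""

    table: pd.DataFrame  # long: metric, record, value, baseline, baseline_value,
    #                      fold_raw, fold
    pairwise: dict[str, pd.DataFrame]  # metric -> raw ratio matrix
    convention: FoldConvention = DEFAULT_CONVENTION

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "convention": {
                "decimals_below": self.convention.decimals_below,
                "integer_from": self.convention.integer_from,
            },
            "table": self.table.to_dict(orient="records"),
            "pairwise": {
                m: df.to_dict(orient="index") for m, df in self.pairwise.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_csv(cls, path, convention: FoldConvention = DEFAULT_CONVENTION) -> "KPIReport":
        table = pd.read_csv(path)
        pairwise: dict[str, pd.DataFrame] = {}
        for metric, sub in table.groupby("metric"):
            labels = list(sub["record"])
            values = dict(zip(sub["record"], sub["value"]))
            pairwise[metric] = _pairwise_matrix(labels, values)
        return cls(table=table, pairwise=pairwise, convention=convention)


def _pairwise_matrix(labels: Sequence[str], values: dict[str, float]) -> pd.DataFrame:
    data = {
        a: {b: (values[a] / values[b] if values[b] else float("nan")) for b in labels}
        for a in labels
    }
    return pd.DataFrame(data).T  # rows: numerator record, cols: denominator


def build_comparison(
    records: Sequence[ProcessRecord],
    baseline: str,
    metrics: Sequence[str],
    convention: FoldConvention = DEFAULT_CONVENTION,
) -> KPIReport:
    """Fold-change comparison of every record against a baseline record.

    ``metrics`` may name record fields (dcw, eps, lactate, od600, viability)
    or the derived metrics ``yield`` and ``productivity``.
    """
    by_label = {r.label: r for r in records}
    if baseline not in by_label:
        raise KeyError(f"baseline {baseline!r} not among records {sorted(by_label)}")
    rows = []
    pairwise: dict[str, pd.DataFrame] = {}
    for metric in metrics:
        values = {r.label: r.metric(metric) for r in records}
        base_val = values[baseline]
        for r in records:
            raw = values[r.label] / base_val if base_val else float("nan")
            rows.append(
                {
                    "metric": metric,
                    "record": r.label,
                    "value": values[r.label],
                    "baseline": baseline,
                    "baseline_value": base_val,
                    "fold_raw": raw,
                    "fold": convention.apply(raw) if base_val else float("nan"),
                }
            )
        pairwise[metric] = _pairwise_matrix([r.label for r in records], values)
    return KPIReport(table=pd.DataFrame(rows), pairwise=pairwise, convention=convention)


def records_from_csv(path) -> list[ProcessRecord]:
    """Read process records from a CSV mirroring the summary-table columns."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {"label": row["label"]}
        for col in (
            "medium", "mode", "od600", "dcw", "eps", "viability",
            "lactate", "substrate_consumed", "duration",
        ):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = row[col]
        out.append(ProcessRecord(**kwargs))
    return out


def trajectory_kpis(traj, Y_check: float | None = None) -> dict[str, float]:
    """KPIs from a simulated trajectory's mass balances.

    Yield uses total product mass formed over total substrate mass consumed
    (initial charge + feed - residual), matching how the wet-lab yield is
    defined from titers and consumption.
    """
    f = traj.frame
    first, last = f.iloc[0], f.iloc[-1]
    product_mass = last.P_g_per_L * last.V_L - first.P_g_per_L * first.V_L
    substrate_mass = (
        first.S_g_per_L * first.V_L + last.glucose_fed_g - last.S_g_per_L * last.V_L
    )
    duration = last.t_h - first.t_h
    return {
        "yield_g_per_g": product_mass / substrate_mass if substrate_mass > 0 else float("nan"),
        "productivity_g_per_L_h": last.P_g_per_L / duration if duration > 0 else float("nan"),
        "titer_g_per_L": float(last.P_g_per_L),
        "biomass_g_per_L": float(last.X_gDCW_per_L),
        "eps_g_per_L": float(last.E_g_per_L),
    }
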