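"""Two-level Plackett-Burman screening designs and factor-effect estimation.

A Plackett-Burman (PB) design estimates many main effects from few runs by
assigning each factor to a column of a normalized Hadamard matrix: every
coded column is balanced (equal counts of -1 and +1) and any two columns are
orthogonal.  Center-point runs (all factors at mid-level) are appended to
detect curvature; the fitted model is

    y = b0 + sum_i b_i * z_i + b_cp * center_indicator + eps

on coded levels ``z_i = (natural - center) / half_range``.  A factor's
*standardized effect* is the t-ratio ``b_i / SE(b_i)``, compared against the
two-sided Student-t quantile at the chosen alpha ("significance margin", the
reference line of a Pareto chart).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as student_t

SUPPORTED_BASE_RUNS = (8, 12, 16, 20, 24, 36)

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "ScreeningFit",
    "build_pb_design",
    "fit_screening",
    "critical_margin",
    "evaluate_regression",
    "effect_summary",
    "SUPPORTED_BASE_RUNS",
]


class DesignError(ValueError):
    """Raised for unsupported or inconsistent design requests."""


@dataclass(frozen=True)
class FactorSpec:
    """One screened medium component with its low / center / high levels (g/L)."""

    name: str
    code: str
    low_level: float
    center_level: float
    high_level: float

    def __post_init__(self) -> None:
        if not (self.low_level <= self.center_level <= self.high_level):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low <= center <= high, "
                f"got {self.low_level}, {self.center_level}, {self.high_level}"
            )
        if self.high_level <= self.low_level:
            raise ValueError(f"factor {self.name!r}: zero level range")

    @property
    def half_range(self) -> float:
        return (self.high_level - self.low_level) / 2.0

    @property
    def midpoint(self) -> float:
        return (self.high_level + self.low_level) / 2.0

    @property
    def is_true_center(self) -> bool:
        """Whether the declared center level is the exact low/high midpoint."""
        return abs(self.center_level - self.midpoint) <= 1e-9

    def to_natural(self, coded: np.ndarray) -> np.ndarray:
        """Map coded levels in {-1, 0, +1} to natural concentrations."""
        coded = np.asarray(coded, dtype=float)
        natural = self.midpoint + coded * self.half_range
        # a true center run sits at the declared center, not the midpoint
        return np.where(coded == 0, self.center_level, natural)


# ---------------------------------------------------------------------------
# Hadamard constructions.  All sizes are built from number-theoretic
# constructions (Paley I/II, Sylvester) and validated against the
# orthogonality invariant; no layout is pinned.
# ---------------------------------------------------------------------------

def _jacobsthal(q: int) -> np.ndarray:
    residues = {(i * i) % q for i in range(1, q)}
    Q = np.zeros((q, q), dtype=int)
    for i in range(q):
        for j in range(q):
            if i != j:
                Q[i, j] = 1 if (j - i) % q in residues else -1
    return Q


def _paley_i(q: int) -> np.ndarray:
    """Hadamard matrix of order q + 1 for prime q = 3 (mod 4)."""
    Q = _jacobsthal(q)
    n = q + 1
    S = np.zeros((n, n), dtype=int)
    S[0, 1:] = 1
    S[1:, 0] = -1
    S[1:, 1:] = Q
    return S + np.eye(n, dtype=int)


def _paley_ii(q: int) -> np.ndarray:
    """Hadamard matrix of order 2(q + 1) for prime q = 1 (mod 4)."""
    Q = _jacobsthal(q)
    n = q + 1
    S = np.zeros((n, n), dtype=int)
    S[0, 1:] = 1
    S[1:, 0] = 1
    S[1:, 1:] = Q
    H2 = np.array([[1, 1], [1, -1]])
    K = np.array([[1, -1], [-1, -1]])
    return np.kron(S, H2) + np.kron(np.eye(n, dtype=int), K)


def _sylvester(order: int) -> np.ndarray:
    H = np.array([[1]])
    while H.shape[0] < order:
        H = np.block([[H, H], [H, -H]])
    return H


def hadamard_matrix(order: int) -> np.ndarray:
    """Validated Hadamard matrix for any supported PB base-run count."""
    if order in (8, 12, 20, 24):
        H = _paley_i(order - 1)
    elif order == 16:
        H = _sylvester(16)
    elif order == 36:
        H = _paley_ii(17)
    else:
        raise DesignError(
            f"unsupported base-run count {order}; supported sizes are "
            f"{SUPPORTED_BASE_RUNS}"
        )
    if not np.array_equal(H @ H.T, order * np.eye(order, dtype=int)):
        raise AssertionError(f"Hadamard construction failed for order {order}")
    return H


@dataclass
class DesignMatrix:
    """A coded screening design: base runs at +/-1 plus optional center runs."""

    factors: list[FactorSpec]
    coded: np.ndarray  # (n_runs, n_factors) int in {-1, 0, +1}
    is_center: np.ndarray  # (n_runs,) bool
    run_order: np.ndarray  # permutation applied to the standard order
    n_base_runs: int
    seed: int | None = None

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def codes(self) -> list[str]:
        return [f.code for f in self.factors]

    @property
    def has_center(self) -> bool:
        return bool(self.is_center.any())

    def natural_levels(self) -> pd.DataFrame:
        """Run sheet in natural concentration units (g/L)."""
        data = {
            f.code: f.to_natural(self.coded[:, j])
            for j, f in enumerate(self.factors)
        }
        df = pd.DataFrame(data)
        df.insert(0, "run_order", np.arange(1, self.n_runs + 1))
        df["is_center"] = self.is_center.astype(int)
        return df

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coded, columns=self.codes)
        df.insert(0, "run_order", np.arange(1, self.n_runs + 1))
        df["is_center"] = self.is_center.astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: Sequence[FactorSpec]) -> "DesignMatrix":
        df = pd.read_csv(path)
        factors = list(factors)
        coded = df[[f.code for f in factors]].to_numpy(dtype=int)
        is_center = df["is_center"].to_numpy(dtype=bool)
        return cls(
            factors=factors,
            coded=coded,
            is_center=is_center,
            run_order=df["run_order"].to_numpy(dtype=int) - 1,
            n_base_runs=int((~is_center).sum()),
        )

    def validate(self) -> None:
        """Check balance and pairwise orthogonality over non-center runs."""
        base = self.coded[~self.is_center]
        if not np.isin(base, (-1, 1)).all():
            raise DesignError("non-center runs must be coded +/-1")
        if self.coded[self.is_center].any():
            raise DesignError("center runs must have all-zero coded levels")
        if (base.sum(axis=0) != 0).any():
            raise DesignError("unbalanced coded column (unequal -1/+1 counts)")
        gram = base.T @ base
        if not np.array_equal(gram, len(base) * np.eye(self.n_factors, dtype=int)):
            raise DesignError("coded columns are not pairwise orthogonal")


def build_pb_design(
    factors: Sequence[FactorSpec],
    n_base_runs: int,
    n_center_runs: int = 0,
    seed: int | None = None,
) -> DesignMatrix:
    """Construct a PB design with ``n_base_runs + n_center_runs`` rows.

    Run order is shuffled deterministically by ``seed`` (``None`` keeps the
    standard order).  Raises :class:`DesignError` for unsupported run counts
    or when the factor count exceeds the design capacity ``n_base_runs - 1``.
    """
    factors = list(factors)
    if n_base_runs not in SUPPORTED_BASE_RUNS:
        raise DesignError(
            f"unsupported base-run count {n_base_runs}; supported sizes are "
            f"{SUPPORTED_BASE_RUNS}"
        )
    if len(factors) > n_base_runs - 1:
        raise DesignError(
            f"a {n_base_runs}-run design supports at most {n_base_runs - 1} "
            f"factors, got {len(factors)}"
        )
    if n_center_runs < 0:
        raise DesignError("n_center_runs must be >= 0")
    codes = [f.code for f in factors]
    if len(set(codes)) != len(codes):
        raise DesignError("duplicate factor codes")

    H = hadamard_matrix(n_base_runs)
    # normalize so the first column is all +1, then drop it
    H = H * H[:, :1]
    base = H[:, 1 : len(factors) + 1]

    coded = np.vstack([base, np.zeros((n_center_runs, len(factors)), dtype=int)])
    is_center = np.r_[
        np.zeros(n_base_runs, dtype=bool), np.ones(n_center_runs, dtype=bool)
    ]
    order = np.arange(coded.shape[0])
    if seed is not None:
        order = np.random.default_rng(seed).permutation(order)
    design = DesignMatrix(
        factors=factors,
        coded=coded[order],
        is_center=is_center[order],
        run_order=order,
        n_base_runs=n_base_runs,
        seed=seed,
    )
    design.validate()
    return design


def critical_margin(alpha: float, residual_df: int) -> float:
    """Two-sided Student-t quantile at level ``alpha`` (Pareto reference line)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if residual_df < 1:
        raise ValueError(f"residual_df must be >= 1, got {residual_df}")
    return float(student_t.ppf(1 - alpha / 2, residual_df))


@dataclass
class ScreeningFit:
    """OLS fit of a screening design: coefficients, t-ratios and margins."""

    factors: list[FactorSpec]
    coefficients: dict[str, float]  # natural units, keyed by factor name
    coded_coefficients: dict[str, float]  # +/-1 scale, keyed by factor code
    standard_errors: dict[str, float]  # coded scale, keyed like coded_coefficients
    standardized_effects: dict[str, float]  # t-ratios, keyed by factor code
    residual_df: int
    s: float
    r_squared: float
    r_squared_adjusted: float
    alpha: float
    critical_margin: float

    def significant(self) -> dict[str, bool]:
        return {
            code: abs(eff) > self.critical_margin
            for code, eff in self.standardized_effects.items()
        }

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "coded_coefficients": self.coded_coefficients,
            "standard_errors": self.standard_errors,
            "standardized_effects": self.standardized_effects,
            "residual_df": self.residual_df,
            "s": self.s,
            "r_squared": self.r_squared,
            "r_squared_adjusted": self.r_squared_adjusted,
            "alpha": self.alpha,
            "critical_margin": self.critical_margin,
            "significant": self.significant(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on their predecessors (for error messages)."""
    aliased = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        resid = X[:, j] - prev @ np.linalg.lstsq(prev, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            aliased.append(names[j])
    return aliased


def fit_screening(
    design: DesignMatrix,
    responses: Sequence[float],
    alpha: float = 0.05,
    fit_center_term: bool = True,
) -> ScreeningFit:
    """Estimate factor effects by OLS on coded levels.

    The model is intercept + coded main effects, plus a 0/1 center-run
    indicator when ``fit_center_term`` and the design contains center runs
    (the curvature term).  Standardized effects are coefficient / SE t-ratios,
    the convention used by Minitab-style Pareto charts.
    """
    design.validate()
    y = np.asarray(responses, dtype=float)
    if y.shape[0] != design.n_runs:
        raise ValueError(
            f"got {y.shape[0]} responses for a {design.n_runs}-run design"
        )
    use_center = fit_center_term and design.has_center
    names = ["intercept"] + design.codes + (["center_point"] if use_center else [])
    X = np.column_stack(
        [np.ones(design.n_runs), design.coded.astype(float)]
        + ([design.is_center.astype(float)] if use_center else [])
    )
    residual_df = design.n_runs - X.shape[1]
    if residual_df < 1:
        raise ValueError(
            f"saturated model: {design.n_runs} runs cannot estimate "
            f"{X.shape[1]} parameters with residual df >= 1"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design; aliased columns: {_aliased_columns(X, names)}"
        )

    res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    coded_coefficients = {n: float(res.params[n]) for n in names}
    standard_errors = {n: float(res.bse[n]) for n in names}
    with np.errstate(divide="ignore", invalid="ignore"):
        standardized = {
            f.code: float(np.nan_to_num(res.params[f.code] / res.bse[f.code],
                                        nan=0.0, posinf=np.inf, neginf=-np.inf))
            for f in design.factors
        }

    # natural-unit coefficients: b_nat = b_coded / half_range; the natural
    # intercept absorbs the centering offsets
    coefficients: dict[str, float] = {}
    intercept = coded_coefficients["intercept"]
    for f in design.factors:
        b_nat = coded_coefficients[f.code] / f.half_range
        coefficients[f.name] = b_nat
        intercept -= b_nat * f.midpoint
    coefficients["intercept"] = intercept
    if use_center:
        coefficients["center_point"] = coded_coefficients["center_point"]

    return ScreeningFit(
        factors=list(design.factors),
        coefficients=coefficients,
        coded_coefficients=coded_coefficients,
        standard_errors=standard_errors,
        standardized_effects=standardized,
        residual_df=int(res.df_resid),
        s=float(np.sqrt(res.scale)),
        r_squared=float(res.rsquared),
        r_squared_adjusted=float(res.rsquared_adj),
        alpha=alpha,
        critical_margin=critical_margin(alpha, residual_df),
    )


def evaluate_regression(
    fit_or_coefficients: ScreeningFit | Mapping[str, float],
    settings: Mapping[str, float],
) -> float:
    """Evaluate a screening regression at natural factor settings.

    ``fit_or_coefficients`` is either a :class:`ScreeningFit` or a plain
    mapping with an ``"intercept"`` key, per-factor coefficients, and an
    optional ``"center_point"`` term whose 0/1 indicator may be supplied in
    ``settings``.  Pure arithmetic; no clipping.
    """
    if isinstance(fit_or_coefficients, ScreeningFit):
        coeffs = fit_or_coefficients.coefficients
    else:
        coeffs = dict(fit_or_coefficients)
    value = float(coeffs.get("intercept", 0.0))
    missing = [
        k for k in coeffs
        if k not in ("intercept", "center_point") and k not in settings
    ]
    if missing:
        raise KeyError(f"settings missing factors: {sorted(missing)}")
    for key, b in coeffs.items():
        if key in ("intercept",):
            continue
        if key == "center_point":
            value += b * float(settings.get("center_point", 0.0))
        else:
            value += b * float(settings[key])
    return value


def effect_summary(fit: ScreeningFit) -> pd.DataFrame:
    """Factors ranked by |standardized effect|, with Pareto-plot data.

    Ties are broken by factor code so the ordering is stable.
    """
    rows = []
    for f in fit.factors:
        eff = fit.standardized_effects[f.code]
        rows.append(
            {
                "factor": f.name,
                "code": f.code,
                "coded_coefficient": fit.coded_coefficients[f.code],
                "standardized_effect": eff,
                "abs_effect": abs(eff),
                "sign": int(np.sign(eff)),
                "significant": abs(eff) > fit.critical_margin,
                "margin": fit.critical_margin,
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["abs_effect", "code"], ascending=[False, True])
        .reset_index(drop=True)
    )


def factors_from_csv(path) -> list[FactorSpec]:
    """Read factor specs from CSV columns name,code,low,center,high."""
    df = pd.read_csv(path)
    return [
        FactorSpec(r["name"], r["code"], r["low"], r["center"], r["high"])
        for _, r in df.iterrows()
    ]


def factors_to_csv(factors: Sequence[FactorSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "name": f.name,
                "code": f.code,
                "low": f.low_level,
                "center": f.center_level,
                "high": f.high_level,
            }
            for f in factors
        ]
    ).to_csv(path, index=False)
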