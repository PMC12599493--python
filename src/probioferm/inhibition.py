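"""Product-inhibition growth kinetics for lactic acid bacteria.

Two alternative models describe how the specific growth rate mu (h^-1) of a
lactate-producing strain declines as lactic acid x (g/L) accumulates:

* sigmoidal:  mu(x) = mu_max / (1 + exp(lam * (x - x0)))
  -- mu_max is the asymptotic rate at vanishing inhibition, x0 the
  inflection concentration where mu = mu_max / 2, lam (L/g) the steepness.
* power law:  mu(x) = mu_max * (1 - (x / c)^n) for x < c, else 0
  -- c is the hard tolerance ceiling (growth fully blocked), n the shape.

The module also estimates mu from OD600 time series (log-linear slope), fits
both inhibition models to mu-versus-lactate data by nonlinear least squares,
calibrates the linear final-pH-versus-lactate tolerance line, and solves the
line for the concentration at which a target pH is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "SigmoidParams",
    "PowerLawParams",
    "PHLine",
    "InhibitionDataset",
    "FitReport",
    "mu_sigmoidal",
    "mu_powerlaw",
    "estimate_growth_rate",
    "fit_inhibition",
    "fit_ph_line",
    "tolerance_concentration",
    "compare_models",
]

_EXP_CLIP = 700.0  # exp overflow guard; beyond this the limit value is exact


@dataclass(frozen=True)
class SigmoidParams:
    mu_max: float  # h^-1
    lam: float  # L/g
    x0: float  # g/L

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.lam <= 0 or self.x0 < 0:
            raise ValueError(f"invalid sigmoid parameters {self}")

    def mu(self, x):
        return mu_sigmoidal(x, self)

    def tolerance(self, fraction: float = 0.01) -> float:
        """Concentration where mu falls below ``fraction`` of mu_max.

        The sigmoid never reaches zero, so tolerance is defined operationally
        at a configurable residual-growth fraction (default 1%).
        """
        return self.x0 + np.log((1 - fraction) / fraction) / self.lam


@dataclass(frozen=True)
class PowerLawParams:
    mu_max: float  # h^-1
    c: float  # g/L, tolerance ceiling
    n: float  # dimensionless shape

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.c <= 0 or self.n <= 0:
            raise ValueError(f"invalid power-law parameters {self}")

    def mu(self, x):
        return mu_powerlaw(x, self)

    def tolerance(self, fraction: float = 0.01) -> float:
        return self.c


@dataclass(frozen=True)
class PHLine:
    """Final broth pH after 24 h versus initially added lactate, pH = slope*x + intercept."""

    slope: float  # pH units per g/L
    intercept: float  # pH units

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class InhibitionDataset:
    """Lactate challenge data: mu (h^-1) or final pH per added concentration."""

    lactate_concs: np.ndarray
    values: np.ndarray
    kind: str = "mu"  # "mu" or "ph"
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lactate_concs = np.asarray(self.lactate_concs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lactate_concs.shape != self.values.shape:
            raise ValueError("lactate_concs and values must have equal length")
        if (self.lactate_concs < 0).any():
            raise ValueError("lactate concentrations must be non-negative")

    def __len__(self) -> int:
        return self.lactate_concs.size


def mu_sigmoidal(x, p: SigmoidParams):
    """Sigmoidal inhibition curve; overflow-guarded, never NaN."""
    x = np.asarray(x, dtype=float)
    z = np.clip(p.lam * (x - p.x0), -_EXP_CLIP, _EXP_CLIP)
    out = p.mu_max / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def mu_powerlaw(x, p: PowerLawParams):
    """Power-law inhibition curve with hard ceiling at x = c."""
    x = np.asarray(x, dtype=float)
    frac = np.clip(x / p.c, 0.0, None)
    out = np.where(x < p.c, p.mu_max * (1.0 - frac**p.n), 0.0)
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


class GrowthRate(NamedTuple):
    mu: float  # h^-1
    se: float
    window: tuple[int, int]  # [start, stop) indices of the fitted span
    r_squared: float


def estimate_growth_rate(
    times: Sequence[float],
    od: Sequence[float],
    window: tuple[float, float] | None = None,
) -> GrowthRate:
    """Specific growth rate as the slope of ln(OD600) versus time.

    With ``window=(t_lo, t_hi)`` the fit uses that time interval; otherwise
    the window is chosen automatically as the contiguous span of >= 4 points
    maximizing r-squared (ties go to the longest, then earliest, span).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    if t.size < 3:
        raise ValueError(f"need >= 3 points to estimate a growth rate, got {t.size}")
    if (y <= 0).any():
        raise ValueError("non-positive OD in the fitting window")
    lny = np.log(y)

    def _fit(i: int, j: int) -> tuple[float, float, float]:
        ts, ys = t[i:j], lny[i:j]
        if np.ptp(ys) == 0.0:  # flat: exact zero-slope fit
            return 0.0, 0.0, 1.0
        res = linregress(ts, ys)
        return float(res.slope), float(res.stderr), float(res.rvalue**2)

    if window is not None or t.size <= 4:
        mu, se, r2 = _fit(0, t.size)
        return GrowthRate(mu, se, (0, t.size), r2)

    best = None
    min_len = min(4, t.size)
    for i in range(t.size - min_len + 1):
        for j in range(i + min_len, t.size + 1):
            mu, se, r2 = _fit(i, j)
            key = (round(r2, 12), j - i, -i)
            if best is None or key > best[0]:
                best = (key, GrowthRate(mu, se, (i, j), r2))
    return best[1]


@dataclass
class FitReport:
    """Result of a nonlinear inhibition-model fit."""

    model: str  # "sigmoidal" or "powerlaw"
    params: SigmoidParams | PowerLawParams
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    init: tuple[float, ...] = ()
    dataset: InhibitionDataset | None = None

    def to_dict(self) -> dict:
        p = self.params
        if isinstance(p, SigmoidParams):
            pd_ = {"mu_max_per_h": p.mu_max, "lambda_L_per_g": p.lam, "x0_g_per_L": p.x0}
        else:
            pd_ = {"mu_max_per_h": p.mu_max, "c_g_per_L": p.c, "n": p.n}
        return {
            "model": self.model,
            "params": pd_,
            "r_squared": self.r_squared,
            "residuals": list(map(float, self.residuals)),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "init": list(self.init),
        }


def _sigmoid_vec(x, p):
    z = np.clip(p[1] * (x - p[2]), -_EXP_CLIP, _EXP_CLIP)
    return p[0] / (1.0 + np.exp(z))


def _powerlaw_vec(x, p):
    frac = np.clip(x / p[1], 0.0, None)
    return np.maximum(np.where(x < p[1], p[0] * (1.0 - frac ** p[2]), 0.0), 0.0)


def _default_init(x: np.ndarray, mu: np.ndarray, model: str) -> tuple[float, ...]:
    """Heuristic starting point: peak-scaled mu_max, half-max location, log-slope."""
    mu_max0 = 1.1 * mu.max()
    if model == "sigmoidal":
        x0_0 = float(x[np.argmin(np.abs(mu - mu.max() / 2))])
        third = np.abs(mu - mu.max() / 3)
        x_third = float(x[np.argmin(third)])
        lam0 = np.log(2) / (x_third - x0_0) if x_third > x0_0 else 0.05
        return (mu_max0, max(lam0, 1e-4), max(x0_0, 0.0))
    low = x[mu <= 0.05 * mu.max()]
    c0 = float(low.min()) if low.size else 1.2 * float(x.max())
    return (mu_max0, c0, 1.0)


def _profile_scan_inits(x: np.ndarray, mu: np.ndarray, model: str):
    """Starting points from a 1-D scan over mu_max with the remaining
    parameters solved by a conditionally-linear fit.

    For fixed mu_max the sigmoid linearizes as ln(mu_max/mu - 1) = lam*(x - x0)
    and the power law as ln(1 - mu/mu_max) = n*ln(x) - n*ln(c); both reduce to
    a straight-line fit, making the scan cheap and deterministic.
    """
    pos = mu > 0
    xs, ms = x[pos], mu[pos]
    for m in np.geomspace(ms.max() * 1.01, ms.max() * 6.0, 25):
        if model == "sigmoidal":
            z = np.log(np.maximum(m / ms - 1.0, 1e-12))
            res = linregress(xs, z)
            lam = max(float(res.slope), 1e-6)
            x0 = min(max(-float(res.intercept) / lam, 0.0), 10.0 * xs.max() + 1.0)
            yield (m, lam, x0)
        else:
            xp = xs > 0
            if xp.sum() < 2:
                continue
            z = np.log(np.maximum(1.0 - ms[xp] / m, 1e-12))
            res = linregress(np.log(xs[xp]), z)
            n = max(float(res.slope), 1e-6)
            c = float(np.exp(-res.intercept / n))
            if not np.isfinite(c) or c <= xs.max():
                c = 1.2 * float(xs.max())
            yield (m, c, n)


def fit_inhibition(
    data: InhibitionDataset,
    model: str = "sigmoidal",
    init: tuple[float, ...] | None = None,
) -> FitReport:
    """Fit an inhibition model to mu-versus-lactate data by least squares.

    Unweighted residuals on mu.  With ``init=None`` the default heuristic
    start is tried together with deterministic profile-scan starts and the
    lowest-SSE solution is kept; an explicit ``init`` is used alone, so
    refitting from a previous optimum is idempotent.  Never raises on
    non-convergence: ``converged=False`` with best-so-far parameters.
    """
    if model not in ("sigmoidal", "powerlaw"):
        raise ValueError(f"unknown model {model!r}")
    x = data.lactate_concs
    mu = data.values
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if (mu < 0).any():
        raise ValueError("mu values must be non-negative")
    if np.ptp(mu) == 0.0:
        raise ValueError("flat data: all mu values equal, model unidentifiable")

    fun = _sigmoid_vec if model == "sigmoidal" else _powerlaw_vec
    if model == "sigmoidal":
        lb, ub = [1e-9, 1e-9, 0.0], [np.inf, np.inf, np.inf]
    else:
        # ceiling must exceed the largest concentration with observed growth
        x_grow = x[mu > 0].max() if (mu > 0).any() else x.max()
        lb, ub = [1e-9, x_grow + 1e-9, 1e-9], [np.inf, np.inf, np.inf]

    def residual(p):
        return fun(x, p) - mu

    starts = [init] if init is not None else (
        [_default_init(x, mu, model)] + list(_profile_scan_inits(x, mu, model))
    )
    best = None
    used_init = None
    n_iter = 0
    converged = False
    for p0 in starts:
        p0 = np.clip(np.asarray(p0, dtype=float), lb, ub)
        try:
            res = least_squares(
                residual, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:
            continue
        n_iter += res.nfev
        if best is None or res.cost < best.cost - 1e-15:
            best = res
            used_init = tuple(p0)
            converged = bool(res.success)
    if best is None:
        raise RuntimeError("no feasible starting point for the fit")

    p = best.x
    params = (
        SigmoidParams(p[0], p[1], p[2])
        if model == "sigmoidal"
        else PowerLawParams(p[0], p[1], p[2])
    )
    pred = fun(x, p)
    ss_res = float(np.sum((mu - pred) ** 2))
    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    return FitReport(
        model=model,
        params=params,
        r_squared=1.0 - ss_res / ss_tot,
        residuals=mu - pred,
        converged=converged,
        n_iter=n_iter,
        init=used_init,
        dataset=data,
    )


def fit_ph_line(data: InhibitionDataset) -> PHLine:
    """Ordinary least-squares line final_pH = slope * lactate + intercept."""
    x, y = data.lactate_concs, data.values
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct concentrations to fit a line")
    if np.ptp(y) == 0.0:
        return PHLine(0.0, float(y[0]))
    res = linregress(x, y)
    return PHLine(float(res.slope), float(res.intercept))


def tolerance_concentration(line: PHLine, ph_target: float = 7.0) -> float:
    """Lactate concentration at which the final-pH line reaches ``ph_target``.

    This is the tolerance read-out of the 24 h challenge assay: the added
    lactate level at which the culture no longer acidifies the broth below
    the target.
    """
    if line.slope == 0:
        raise ZeroDivisionError("zero slope: the pH line never crosses the target")
    return (ph_target - line.intercept) / line.slope


def compare_models(fit_sig: FitReport, fit_pow: FitReport) -> dict:
    """Side-by-side comparison of the two inhibition fits on one dataset.

    Reports r-squared, small-sample AICc (from SSE with k = 4 counting the
    noise variance), the predicted uninhibited rate mu(0), and each model's
    tolerance concentration (1%-of-mu_max crossing for the sigmoid; the
    ceiling c for the power law).
    """
    ds, dp = fit_sig.dataset, fit_pow.dataset
    if ds is None or dp is None or len(ds) != len(dp) or not np.allclose(
        ds.lactate_concs, dp.lactate_concs
    ) or not np.allclose(ds.values, dp.values):
        raise ValueError("fits must come from the same dataset")
    n = len(ds)
    out = {}
    for label, fit in (("sigmoidal", fit_sig), ("powerlaw", fit_pow)):
        ss = float(np.sum(fit.residuals**2))
        k = 4  # 3 curve parameters + noise variance
        aicc = n * np.log(max(ss, 1e-300) / n) + 2 * k
        if n - k - 1 > 0:
            aicc += 2 * k * (k + 1) / (n - k - 1)
        out[label] = {
            "r_squared": fit.r_squared,
            "aicc": float(aicc),
            "mu_at_zero": float(fit.params.mu(0.0)),
            "tolerance_g_per_L": float(fit.params.tolerance()),
        }
    out["delta_aicc"] = out["sigmoidal"]["aicc"] - out["powerlaw"]["aicc"]
    return out
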