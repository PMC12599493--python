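"""Seeded synthetic-data generators mirroring each pipeline stage's inputs.

Every generator is a pure function of its configuration and seed: the same
seed reproduces byte-identical output, and zero noise makes each generator
the exact inverse of its fitting stage (round-trip property).  Default noise
magnitudes -- screening sd 5% of the response range, 1% relative sd on mu,
0.05 pH units -- are free parameters documented in the methods note; the
source study reports replication but no error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from . import fixtures
from .fedbatch import FeedPolicy, FermentationState, KineticConfig, Trajectory, simulate
from .inhibition import InhibitionDataset, PHLine, PowerLawParams, SigmoidParams
from .screening import DesignMatrix, evaluate_regression
from .wound import ClosureCurve

__all__ = [
    "GeneratorConfig",
    "gen_screening_responses",
    "gen_inhibition_dataset",
    "gen_ph_dataset",
    "gen_fermentation_timecourse",
    "gen_scratch_curves",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise model for observation-level perturbations."""

    seed: int = 0
    noise_model: str = "gaussian"  # "gaussian" (additive) or "lognormal" (multiplicative)
    sd: float = 0.0
    scenario: str = ""

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0.0:
            return np.asarray(values, dtype=float).copy()
        if self.noise_model == "gaussian":
            out = values + rng.normal(0.0, self.sd, np.shape(values))
        elif self.noise_model == "lognormal":
            out = values * np.exp(rng.normal(0.0, self.sd, np.shape(values)))
        else:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        return np.maximum(out, 0.0)  # measurement floor


def gen_screening_responses(
    design: DesignMatrix,
    true_coefficients: Mapping[str, float],
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Responses from a linear effects model on natural levels plus N(0, sd).

    ``true_coefficients`` is keyed like a printed regression: an
    ``"intercept"``, one entry per factor name, and an optional
    ``"center_point"`` curvature term applied to center runs.
    """
    missing = [f.name for f in design.factors if f.name not in true_coefficients]
    if missing:
        raise KeyError(f"true_coefficients missing factors: {missing}")
    natural = design.natural_levels()
    clean = np.empty(design.n_runs)
    for i in range(design.n_runs):
        settings = {f.name: natural.loc[i, f.code] for f in design.factors}
        settings["center_point"] = float(design.is_center[i])
        clean[i] = evaluate_regression(true_coefficients, settings)
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, noise_sd, design.n_runs)


def default_biomass_scenario(
    n_base_runs: int = 36, n_center_runs: int = 1, noise_sd: float | None = None,
    seed: int = 0,
):
    """The 37-run biomass screening scenario with the printed regression as
    ground truth; noise defaults to 5% of the clean response range."""
    from .screening import build_pb_design

    design = build_pb_design(
        fixtures.BIOMASS_FACTORS, n_base_runs, n_center_runs, seed=seed
    )
    clean = gen_screening_responses(design, fixtures.EQ1_BIOMASS_COEFFICIENTS, 0.0, seed)
    if noise_sd is None:
        noise_sd = 0.05 * float(np.ptp(clean))
    y = gen_screening_responses(
        design, fixtures.EQ1_BIOMASS_COEFFICIENTS, noise_sd, seed
    )
    return design, y


def gen_inhibition_dataset(
    params: SigmoidParams | PowerLawParams,
    grid: Sequence[float] | None = None,
    noise_sd_rel: float = 0.01,
    seed: int = 0,
) -> InhibitionDataset:
    """mu-versus-lactate data: model(x) * (1 + eps), eps ~ N(0, rel sd), floored at 0.

    The default grid is the 11-point lactate challenge 0-150 g/L in steps
    of 15.
    """
    x = np.asarray(fixtures.LACTATE_GRID if grid is None else grid, dtype=float)
    if (x < 0).any():
        raise ValueError("grid concentrations must be non-negative")
    mu = params.mu(x)
    rng = np.random.default_rng(seed)
    noisy = mu * (1.0 + rng.normal(0.0, noise_sd_rel, x.size)) if noise_sd_rel else mu
    return InhibitionDataset(x, np.maximum(noisy, 0.0), kind="mu")


def gen_ph_dataset(
    line: PHLine | None = None,
    grid: Sequence[float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> InhibitionDataset:
    """Final-pH data around the tolerance line, clipped to the assay range [3, 9]."""
    line = fixtures.PH_LINE if line is None else line
    x = np.asarray(fixtures.LACTATE_GRID if grid is None else grid, dtype=float)
    rng = np.random.default_rng(seed)
    ph = line.predict(x)
    if noise_sd:
        ph = ph + rng.normal(0.0, noise_sd, x.size)
    return InhibitionDataset(x, np.clip(ph, 3.0, 9.0), kind="ph")


def gen_fermentation_timecourse(
    kin: KineticConfig,
    policy: FeedPolicy | None = None,
    init: FermentationState | None = None,
    t_end: float = 30.0,
    sampling_dt: float = 1.0,
    noise: GeneratorConfig = GeneratorConfig(),
) -> Trajectory:
    """Simulate, subsample at ``sampling_dt`` and perturb each observable.

    Noise is applied independently to X, S, P and E (not to t or V, which
    are instrument-controlled), floored at zero.
    """
    traj = simulate(
        init or fixtures.BIOREACTOR_INIT, kin, policy, t_end=t_end,
        dt_max=min(sampling_dt, 0.25),
    )
    f = traj.frame
    sample_times = np.arange(f.t_h.iloc[0], f.t_h.iloc[-1] + 1e-9, sampling_dt)
    obs = f.set_index("t_h").reindex(sample_times, method="nearest").reset_index()
    obs = obs.rename(columns={"index": "t_h"})
    rng = np.random.default_rng(noise.seed)
    for col in ("X_gDCW_per_L", "S_g_per_L", "P_g_per_L", "E_g_per_L"):
        obs[col] = noise.perturb(obs[col].to_numpy(), rng)
    return Trajectory(obs)


def _logistic_closure(t: np.ndarray, plateau: float, t50: float, tau: float) -> np.ndarray:
    c = plateau / (1.0 + np.exp(-(t - t50) / tau))
    return c - c[0] if t[0] == 0 else c  # anchor closure(0) = 0


def _solve_t50(t_cross: float, threshold: float, plateau: float, tau: float) -> float:
    """t50 such that the zero-anchored logistic crosses ``threshold`` at ``t_cross``."""

    def gap(t50: float) -> float:
        c0 = plateau / (1.0 + np.exp(t50 / tau))
        ct = plateau / (1.0 + np.exp(-(t_cross - t50) / tau))
        return (ct - c0) - threshold

    # gap -> -threshold at both extremes with a single interior maximum; take
    # the larger root (curve still rising at t_cross), bracketed from the peak
    scan = np.linspace(-50.0, 200.0, 501)
    vals = np.array([gap(s) for s in scan])
    peak = int(np.argmax(vals))
    if vals[peak] <= 0:
        raise ValueError(
            f"threshold {threshold}% unreachable at t = {t_cross} h with "
            f"plateau {plateau}% and tau {tau} h"
        )
    return brentq(gap, scan[peak], 250.0, xtol=1e-10)


def gen_scratch_curves(
    group_params: Mapping[str, tuple[float, float]] | None = None,
    n_fields: int = 5,
    noise: GeneratorConfig = GeneratorConfig(sd=0.8),
    t_grid: Sequence[float] | None = None,
    plateau_sd: float = 2.0,
    tau_fraction: float = 0.3,
    a0: float = 100.0,
) -> dict[str, list[ClosureCurve]]:
    """Logistic wound-closure curves per field with seeded jitter.

    ``group_params`` maps group name to (20%-crossing time in h, plateau
    closure %); defaults to the published control / EPS-treated group means
    (8.8 h / 5.3 h) with plateaus matching the reported residual areas.
    ``noise.sd`` jitters each field's timescale (h); ``plateau_sd`` jitters
    its plateau.  Curves are sampled on a 0-40 h grid and returned as wound
    areas in arbitrary units with area(0) = ``a0``.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if group_params is None:
        group_params = {
            "CTR": (
                fixtures.WOUND_CLOSURE_TIMES["CTR"][20][0],
                fixtures.WOUND_PLATEAU["CTR"],
            ),
            "EPS": (
                fixtures.WOUND_CLOSURE_TIMES["EPS"][20][0],
                fixtures.WOUND_PLATEAU["EPS"],
            ),
        }
    t = np.asarray(
        np.arange(0.0, fixtures.WOUND_WATCH_WINDOW_H + 1e-9, 0.5)
        if t_grid is None
        else t_grid,
        dtype=float,
    )
    rng = np.random.default_rng(noise.seed)
    out: dict[str, list[ClosureCurve]] = {}
    for group, (t20, plateau) in group_params.items():
        tau = tau_fraction * t20
        t50 = _solve_t50(t20, 20.0, plateau, tau)
        curves = []
        for i in range(n_fields):
            shift = rng.normal(0.0, noise.sd) if noise.sd else 0.0
            pl = float(np.clip(plateau + (rng.normal(0.0, plateau_sd) if plateau_sd else 0.0), 25.0, 100.0))
            closure = np.clip(_logistic_closure(t, pl, t50 + shift, tau), 0.0, 100.0)
            areas = a0 * (1.0 - closure / 100.0)
            curves.append(ClosureCurve(field_id=f"{group}_{i+1}", times=t, areas=areas))
        out[group] = curves
    return out
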