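"""Stirred-tank batch / fed-batch fermentation model with product inhibition.

State variables: broth volume V (L), biomass X (g DCW/L), glucose S (g/L),
lactate P (g/L) and exopolysaccharide E (g/L).  Mass balances for a fed
stirred tank with feed flow F (L/h) at glucose concentration S_f (g/L) and
dilution D = F/V:

    mu    = mu_inh(P) * S / (K_S + S)          (Monod x product inhibition)
    q_S   = mu / Y_XS + m_S * f(P)             (growth + inhibited maintenance)
    dX/dt = mu * X - D * X
    dS/dt = D * (S_f - S) - q_S * X
    dP/dt = Y_PS * q_S * X - D * P             (yield-coupled lactate)
    dE/dt = (alpha_E * mu + beta_E * f(P)) * X - D * E   (Luedeking-Piret)
    dV/dt = F

where f(P) = mu_inh(P)/mu_max scales maintenance and non-growth EPS
synthesis by the same product-inhibition factor, so all activity ceases at
the tolerance ceiling.  Lactate is yield-coupled to total substrate
consumption because the process yield is defined and measured as product
formed per substrate consumed; Y_PS may exceed 1 g/g (nitrogen-source
co-catabolism).  pH is assumed perfectly controlled at 7 and gas transfer is
absent (anaerobic-style LAB cultivation), so neither appears in the state.

Feeding follows a trigger-based exponential profile: once S first falls
below ``trigger_S`` the volumetric glucose delivery r(t) (g per liter of
current broth per hour) ramps exponentially from ``rate_start`` to
``rate_end`` and stops when the designed glucose total has been delivered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .inhibition import PowerLawParams, SigmoidParams

__all__ = [
    "KineticConfig",
    "FermentationState",
    "FeedPolicy",
    "Trajectory",
    "derivatives",
    "simulate",
    "design_feed",
    "viability_estimate",
]


@dataclass(frozen=True)
class KineticConfig:
    """Strain- and medium-specific rate and yield constants."""

    inhibition: SigmoidParams | PowerLawParams
    K_S: float = 0.1  # g/L; substrate-limited only near depletion
    Y_XS: float = 0.215  # g DCW / g glucose
    Y_PS: float = 1.11  # g lactate / g glucose consumed (may exceed 1)
    m_S: float = 0.0  # g glucose / (g DCW h) maintenance
    alpha_E: float = 0.5  # g EPS / g DCW, growth-associated
    beta_E: float = 0.0  # g EPS / (g DCW h), non-growth-associated
    k_viab: float = 1.59e12  # CFU / g DCW

    def __post_init__(self) -> None:
        for name in ("K_S", "Y_XS", "Y_PS", "m_S", "alpha_E", "beta_E", "k_viab"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Y_XS == 0:
            raise ValueError("Y_XS must be positive")

    @property
    def mu_max(self) -> float:
        return self.inhibition.mu_max

    def to_dict(self) -> dict:
        inh = self.inhibition
        if isinstance(inh, SigmoidParams):
            inh_d = {
                "model": "sigmoidal",
                "mu_max_per_h": float(inh.mu_max),
                "lambda_L_per_g": float(inh.lam),
                "x0_g_per_L": float(inh.x0),
            }
        else:
            inh_d = {
                "model": "powerlaw",
                "mu_max_per_h": float(inh.mu_max),
                "c_g_per_L": float(inh.c),
                "n": float(inh.n),
            }
        return {
            "inhibition": inh_d,
            "K_S_g_per_L": float(self.K_S),
            "Y_XS_g_per_g": float(self.Y_XS),
            "Y_PS_g_per_g": float(self.Y_PS),
            "m_S_g_per_g_h": float(self.m_S),
            "alpha_E_g_per_g": float(self.alpha_E),
            "beta_E_g_per_g_h": float(self.beta_E),
            "k_viab_CFU_per_g": float(self.k_viab),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticConfig":
        inh = d["inhibition"]
        if inh["model"] == "sigmoidal":
            p = SigmoidParams(inh["mu_max_per_h"], inh["lambda_L_per_g"], inh["x0_g_per_L"])
        elif inh["model"] == "powerlaw":
            p = PowerLawParams(inh["mu_max_per_h"], inh["c_g_per_L"], inh["n"])
        else:
            raise ValueError(f"unknown inhibition model {inh['model']!r}")
        return cls(
            inhibition=p,
            K_S=d.get("K_S_g_per_L", 0.1),
            Y_XS=d.get("Y_XS_g_per_g", 0.215),
            Y_PS=d.get("Y_PS_g_per_g", 1.11),
            m_S=d.get("m_S_g_per_g_h", 0.0),
            alpha_E=d.get("alpha_E_g_per_g", 0.5),
            beta_E=d.get("beta_E_g_per_g_h", 0.0),
            k_viab=d.get("k_viab_CFU_per_g", 1.59e12),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KineticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class FermentationState:
    t: float  # h
    V: float  # L
    X: float  # g DCW/L
    S: float  # g/L
    P: float  # g/L
    E: float  # g/L

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError("V must be positive")
        for name in ("X", "S", "P", "E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FeedPolicy:
    """Trigger-based exponential glucose feed.

    ``rate_start``/``rate_end`` are volumetric glucose delivery rates in
    g/(L h) referenced to the *current* broth volume; ``ramp`` (h^-1) is the
    exponential time constant of the rate increase.  ``total_glucose_g`` is
    the designed feed total at which delivery stops; ``flow_L_per_h``
    overrides the rate profile with a constant liquid flow (used e.g. for
    dilution studies with feed_conc = 0, where a g/L/h rate is undefined).
    """

    trigger_S: float = 1.0  # g/L
    feed_conc: float = 550.0  # g glucose / L feed
    rate_start: float = 8.0  # g/(L h)
    rate_end: float = 10.0  # g/(L h)
    ramp: float = 0.05  # h^-1
    P_target: float | None = None  # g/L
    V_max: float | None = None  # L
    total_glucose_g: float | None = None
    flow_L_per_h: float | None = None

    def __post_init__(self) -> None:
        if self.flow_L_per_h is None:
            if not 0 < self.rate_start <= self.rate_end:
                raise ValueError("need 0 < rate_start <= rate_end")
            if self.feed_conc <= 0:
                raise ValueError("feed_conc must be positive without a flow override")
        if self.ramp < 0:
            raise ValueError("ramp must be non-negative")

    def delivery_rate(self, t_since_start: float) -> float:
        """Volumetric glucose delivery r(t) in g/(L h) during feeding."""
        return min(self.rate_start * np.exp(self.ramp * t_since_start), self.rate_end)

    def to_dict(self) -> dict:
        opt = lambda v: None if v is None else float(v)
        return {
            "trigger_S_g_per_L": float(self.trigger_S),
            "feed_conc_g_per_L": float(self.feed_conc),
            "rate_start_g_per_L_h": float(self.rate_start),
            "rate_end_g_per_L_h": float(self.rate_end),
            "ramp_per_h": float(self.ramp),
            "P_target_g_per_L": opt(self.P_target),
            "V_max_L": opt(self.V_max),
            "total_glucose_g": opt(self.total_glucose_g),
            "flow_L_per_h": opt(self.flow_L_per_h),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedPolicy":
        return cls(
            trigger_S=d.get("trigger_S_g_per_L", 1.0),
            feed_conc=d.get("feed_conc_g_per_L", 550.0),
            rate_start=d.get("rate_start_g_per_L_h", 8.0),
            rate_end=d.get("rate_end_g_per_L_h", 10.0),
            ramp=d.get("ramp_per_h", 0.05),
            P_target=d.get("P_target_g_per_L"),
            V_max=d.get("V_max_L"),
            total_glucose_g=d.get("total_glucose_g"),
            flow_L_per_h=d.get("flow_L_per_h"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeedPolicy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Trajectory:
    """Time-ordered states plus instantaneous feed rate and cumulative glucose."""

    frame: pd.DataFrame  # columns t_h, V_L, X_gDCW_per_L, S_g_per_L, P_g_per_L,
    #                      E_g_per_L, feed_L_per_h, glucose_fed_g

    @property
    def terminal(self) -> FermentationState:
        r = self.frame.iloc[-1]
        return FermentationState(
            t=r.t_h, V=r.V_L, X=r.X_gDCW_per_L,
            S=max(r.S_g_per_L, 0.0), P=r.P_g_per_L, E=r.E_g_per_L,
        )

    @property
    def glucose_fed_total(self) -> float:
        return float(self.frame.glucose_fed_g.iloc[-1])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls(pd.read_csv(path))


def _rates(y: np.ndarray, kin: KineticConfig, feed_rate: float, feed_conc: float):
    """Shared RHS arithmetic; y = [V, X, S, P, E, G_fed]."""
    V, X, S, P = y[0], y[1], max(y[2], 0.0), max(y[3], 0.0)
    f_inh = kin.inhibition.mu(P) / kin.mu_max  # product-inhibition factor in [0, 1]
    monod = S / (kin.K_S + S) if S > 0 else 0.0
    mu = kin.mu_max * f_inh * monod
    substrate_available = S > 0 or (feed_rate > 0 and feed_conc > 0)
    q_S = mu / kin.Y_XS + (kin.m_S * f_inh if substrate_available else 0.0)
    D = feed_rate / V
    dV = feed_rate
    dX = mu * X - D * X
    dS = D * (feed_conc - S) - q_S * X
    dP = kin.Y_PS * q_S * X - D * P
    dE = (kin.alpha_E * mu + (kin.beta_E * f_inh if substrate_available else 0.0)) * X - D * y[4]
    dG = feed_rate * feed_conc
    return np.array([dV, dX, dS, dP, dE, dG])


def derivatives(
    state: FermentationState,
    kin: KineticConfig,
    feed_rate: float = 0.0,
    feed_conc: float = 0.0,
) -> dict[str, float]:
    """Instantaneous state derivatives (pure function of the state)."""
    y = np.array([state.V, state.X, state.S, state.P, state.E, 0.0])
    dV, dX, dS, dP, dE, _ = _rates(y, kin, feed_rate, feed_conc)
    return {"dV": dV, "dX": dX, "dS": dS, "dP": dP, "dE": dE}


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_state: FermentationState | None = None):
        super().__init__(message)
        self.last_state = last_state


def _feed_flow(t: float, y: np.ndarray, policy: FeedPolicy, t_feed0: float) -> float:
    if policy.flow_L_per_h is not None:
        return policy.flow_L_per_h
    r = policy.delivery_rate(t - t_feed0)  # g/(L h) on current volume
    return r * y[0] / policy.feed_conc


def simulate(
    init: FermentationState,
    kin: KineticConfig,
    policy: FeedPolicy | None = None,
    t_end: float = 30.0,
    dt_max: float = 0.25,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the fermentation from ``init`` to ``t_end`` hours.

    ``policy=None`` runs a plain batch.  With a feed policy the run has three
    phases -- batch until S first crosses ``trigger_S``, feeding until the
    designed glucose total (or V_max) is reached, then batch again -- each
    integrated with event detection and sampled at most ``dt_max`` apart.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y = np.array([init.V, init.X, init.S, init.P, init.E, 0.0])
    t = init.t
    rows: list[tuple] = []

    def record(ts, ys, flows):
        for tt, yy, ff in zip(ts, ys.T, flows):
            rows.append((tt, *yy[:5], ff, yy[5]))

    def run_phase(t0, t1, flow_fn: Callable[[float, np.ndarray], float], y0, events):
        rhs = lambda tt, yy: _rates(
            yy, kin, flow_fn(tt, yy), policy.feed_conc if policy else 0.0
        )
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="LSODA", max_step=dt_max,
            rtol=rtol, atol=atol, events=events, dense_output=True,
        )
        if not sol.success or not np.isfinite(sol.y[:, -1]).all():
            last = FermentationState(
                t=sol.t[-1], V=sol.y[0, -1], X=max(sol.y[1, -1], 0),
                S=max(sol.y[2, -1], 0), P=max(sol.y[3, -1], 0), E=max(sol.y[4, -1], 0),
            ) if np.isfinite(sol.y[:, -1]).all() else None
            raise IntegrationError(f"integration failed: {sol.message}", last)
        tf = sol.t[-1]
        ts = np.arange(t0, tf, dt_max)
        ts = np.append(ts, tf) if (ts.size == 0 or ts[-1] < tf) else ts
        ys = sol.sol(ts)
        ys[2] = np.maximum(ys[2], 0.0)  # clamp S
        flows = [flow_fn(tt, ys[:, i]) for i, tt in enumerate(ts)]
        return tf, ys[:, -1].copy(), ts, ys, flows

    no_flow = lambda tt, yy: 0.0

    if policy is None:
        tf, y, ts, ys, flows = run_phase(t, t_end, no_flow, y, None)
        record(ts, ys, flows)
        return _as_trajectory(rows)

    # phase 1: batch until S first falls below the trigger
    if y[2] > policy.trigger_S:
        trig = lambda tt, yy: yy[2] - policy.trigger_S
        trig.terminal, trig.direction = True, -1
        tf, y, ts, ys, flows = run_phase(t, t_end, no_flow, y, [trig])
        record(ts, ys, flows)
        t = tf

    # phase 2: exponential feeding until the designed total is delivered
    total = policy.total_glucose_g
    if t < t_end and (total is None or total > 0):
        t_feed0 = t
        flow = lambda tt, yy: _feed_flow(tt, yy, policy, t_feed0)
        events = []
        if total is not None:
            done = lambda tt, yy: yy[5] - total
            done.terminal, done.direction = True, 1
            events.append(done)
        if policy.V_max is not None:
            vmax = lambda tt, yy: yy[0] - policy.V_max
            vmax.terminal, vmax.direction = True, 1
            events.append(vmax)
        tf, y, ts, ys, flows = run_phase(t, t_end, flow, y, events or None)
        record(ts[1:] if rows else ts, ys[:, 1:] if rows else ys, flows[1:] if rows else flows)
        if policy.V_max is not None and y[0] >= policy.V_max - 1e-9 and (
            total is None or y[5] < total * (1 - 1e-9)
        ):
            warnings.warn(
                "feed truncated: V_max reached before the designed glucose total",
                stacklevel=2,
            )
        t = tf

    # phase 3: batch out to t_end
    if t < t_end - 1e-12:
        tf, y, ts, ys, flows = run_phase(t, t_end, no_flow, y, None)
        record(ts[1:], ys[:, 1:], flows[1:])

    return _as_trajectory(rows)


def _as_trajectory(rows: list[tuple]) -> Trajectory:
    frame = pd.DataFrame(
        rows,
        columns=[
            "t_h", "V_L", "X_gDCW_per_L", "S_g_per_L", "P_g_per_L",
            "E_g_per_L", "feed_L_per_h", "glucose_fed_g",
        ],
    )
    frame = frame.drop_duplicates(subset="t_h", keep="last").reset_index(drop=True)
    return Trajectory(frame)


def design_feed(
    P_target: float,
    kin: KineticConfig,
    init: FermentationState,
    feed_conc: float = 550.0,
    rate_band: tuple[float, float] = (8.0, 10.0),
    trigger_S: float = 1.0,
    V_max: float | None = None,
) -> FeedPolicy:
    """Size an exponential feed so the run terminates at ``P_target`` g/L lactate.

    The glucose total M solves the closed mass balance

        P_target * (V0 + M / feed_conc) = P0 * V0 + Y_PS * (S0 * V0 + M)

    by fixed-point iteration to 0.1% closure (the dilution by the feed volume
    couples both sides).  The rate profile ramps exponentially across
    ``rate_band`` over the estimated feeding window.
    """
    if isinstance(kin.inhibition, PowerLawParams) and P_target >= kin.inhibition.c:
        raise ValueError(
            f"P_target {P_target} g/L is at or above the strain tolerance "
            f"ceiling c = {kin.inhibition.c} g/L; the design is infeasible"
        )
    if P_target < init.P:
        raise ValueError("P_target must not be below the current lactate level")
    if kin.Y_PS <= 0:
        raise ValueError("Y_PS must be positive to design a feed")

    V0, S0, P0 = init.V, init.S, init.P
    M = 0.0
    for _ in range(200):
        V_end = V0 + M / feed_conc
        M_new = max((P_target * V_end - P0 * V0 - kin.Y_PS * S0 * V0) / kin.Y_PS, 0.0)
        if M_new == 0.0 or abs(M_new - M) <= 1e-3 * M_new:
            M = M_new
            break
        M = M_new

    rate_start, rate_end = rate_band
    # ramp constant: reach rate_end about when the designed total is delivered
    mean_rate = 0.5 * (rate_start + rate_end) * V0  # g/h
    T_est = M / mean_rate if M > 0 else 1.0
    ramp = np.log(rate_end / rate_start) / T_est if rate_end > rate_start and T_est > 0 else 0.0
    return FeedPolicy(
        trigger_S=trigger_S,
        feed_conc=feed_conc,
        rate_start=rate_start,
        rate_end=rate_end,
        ramp=ramp,
        P_target=P_target,
        V_max=V_max,
        total_glucose_g=M,
    )


def viability_estimate(traj: Trajectory, kin: KineticConfig) -> pd.Series:
    """Viable-count proxy CFU/mL = k_viab * X / 1000 along the trajectory."""
    if kin.k_viab <= 0:
        raise ValueError("k_viab must be positive")
    cfu = kin.k_viab * traj.frame["X_gDCW_per_L"] / 1000.0
    cfu.name = "CFU_per_mL"
    cfu.index = traj.frame["t_h"]
    return cfu
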