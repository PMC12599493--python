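"""Published constants and documented derived fixtures for the D4 bioprocess.

Two provenance classes are kept apart throughout:

* PUBLISHED -- values printed in the source study (factor level tables, the
  two screening regression equations, the final-pH line, the process summary
  tables, the wound-closure times).
* DERIVED -- quantities the study implies but never prints, reconstructed
  here once and documented (the sigmoid steepness lam, the power-law shape,
  substrate consumptions back-computed from yields, process durations
  back-computed from productivities, calibrated simulator yields).
"""

from __future__ import annotations

import numpy as np

from .fedbatch import FermentationState, KineticConfig
from .inhibition import PHLine, PowerLawParams, SigmoidParams
from .kpi import ProcessRecord
from .screening import FactorSpec

# ---------------------------------------------------------------------------
# PUBLISHED: two-level factor tables for the two screening rounds (g/L).
# The MgSO4 high level is printed as 0.125 (< its center 0.25), an obvious
# typo; 0.5 restores the doubling pattern shared by the ascorbic-acid row.
# ---------------------------------------------------------------------------
BIOMASS_FACTORS: list[FactorSpec] = [
    FactorSpec("glucose", "A", 0, 10, 20),
    FactorSpec("sucrose", "B", 0, 10, 20),
    FactorSpec("maltose", "C", 0, 10, 20),
    FactorSpec("galactose", "D", 0, 10, 20),
    FactorSpec("soy peptone", "E", 0, 10, 20),
    FactorSpec("guar peptone", "F", 0, 10, 20),
    FactorSpec("yeast extract", "G", 0, 7.5, 15),
    FactorSpec("ascorbic acid", "H", 0, 0.25, 0.5),
    FactorSpec("MgSO4", "I", 0, 0.25, 0.5),
    FactorSpec("MnSO4", "J", 0, 0.0025, 0.005),
    FactorSpec("FeSO4", "K", 0, 0.0025, 0.005),
    FactorSpec("di-sodium glycerophosphate", "L", 0, 9.5, 19),
    FactorSpec("NaH2PO4", "M", 0, 20.475, 40.950),
    FactorSpec("Na2HPO4", "N", 0, 21.074, 42.148),
]

EPS_FACTORS: list[FactorSpec] = [
    FactorSpec("soy peptone", "X1", 0, 5, 10),
    FactorSpec("yeast extract", "X2", 0, 5, 10),
    FactorSpec("Na2HPO4", "X3", 0, 9.5, 19),
    FactorSpec("MnSO4", "X4", 0, 0.0025, 0.005),
    FactorSpec("ascorbic acid", "X5", 0, 0.25, 0.5),
]

# PUBLISHED: biomass screening regression (natural units; response units
# unstated in the source and treated as opaque).
EQ1_BIOMASS_COEFFICIENTS: dict[str, float] = {
    "intercept": -0.287,
    "glucose": 0.00321,
    "sucrose": 0.00206,
    "maltose": 0.00635,
    "galactose": 0.00168,
    "soy peptone": 0.02935,
    "guar peptone": 0.01109,
    "yeast extract": 0.02179,
    "ascorbic acid": -0.213,
    "MgSO4": -0.230,
    "MnSO4": 46.2,
    "FeSO4": 24.1,
    "di-sodium glycerophosphate": -0.01012,
    "NaH2PO4": 0.02100,
    "Na2HPO4": -0.00160,
    "center_point": 0.433,
}

# PUBLISHED: EPS screening regression (response in mg/L).
EQ2_EPS_COEFFICIENTS: dict[str, float] = {
    "intercept": 222.6,
    "soy peptone": 12.52,
    "yeast extract": 35.15,
    "Na2HPO4": -1.72,
    "MnSO4": -4282.0,
    "ascorbic acid": -178.0,
}

# PUBLISHED: biomass screening model accuracy (37 runs, alpha 0.05).
BIOMASS_MODEL_S = 0.338029
BIOMASS_MODEL_R_SQ = 0.8407
BIOMASS_MODEL_R_SQ_ADJ = 0.7270

# PUBLISHED: final-pH-versus-lactate tolerance line (pH = 0.0219 x + 4.3153).
PH_LINE = PHLine(slope=0.0219, intercept=4.3153)
PH_TARGET = 7.0  # controlled bioreactor pH; the line reaches it near 122 g/L

# PUBLISHED: lactate challenge grid, g/L.
LACTATE_GRID = np.arange(0.0, 151.0, 15.0)  # 0, 15, ..., 150 (11 levels)

# Sigmoidal inhibition fixture.  mu_max 2.14 h^-1 and x0 12.10 g/L are
# PUBLISHED; lam is DERIVED as ln 2 / (60 - 12.10) so that mu(60 g/L) =
# mu_max / 3, the three-fold reduction the study reports at 60 g/L.
SIGMOID_FIXTURE = SigmoidParams(mu_max=2.14, lam=float(np.log(2) / 47.9), x0=12.10)

# Power-law inhibition fixture.  The ceiling c = 120 g/L is PUBLISHED
# ("growth blocked at 120 g/L"); the shape n = 2 is a DERIVED free choice.
POWERLAW_FIXTURE = PowerLawParams(mu_max=2.14, c=120.0, n=2.0)

# ---------------------------------------------------------------------------
# PUBLISHED: bottle-scale comparison (reference M17 vs optimized medium).
# substrate_consumed is DERIVED from the printed yield (lactate / yield);
# duration (24 h bottles) is the stated incubation time.
# ---------------------------------------------------------------------------
BOTTLE_RECORDS: list[ProcessRecord] = [
    ProcessRecord(
        label="bottle_m17", medium="M17", mode="bottle",
        od600=1.60, dcw=0.50, eps=0.14, lactate=2.50,
        substrate_consumed=2.50 / 0.5, duration=24.0,
    ),
    ProcessRecord(
        label="bottle_optimized", medium="optimized", mode="bottle",
        od600=7.90, dcw=2.40, eps=1.81, lactate=16.70,
        substrate_consumed=16.70 / 0.83, duration=24.0,
    ),
]

# ---------------------------------------------------------------------------
# PUBLISHED: bioreactor process summary.  substrate_consumed is DERIVED from
# the printed yield and duration from the printed productivity (consistency
# fixtures; the source states neither directly).
# ---------------------------------------------------------------------------
BIOREACTOR_RECORDS: list[ProcessRecord] = [
    ProcessRecord(
        label="batch_m17", medium="M17", mode="batch",
        od600=3.0, dcw=1.4, eps=0.6, viability=0.6e9, lactate=5.25,
        substrate_consumed=5.25 / 1.05, duration=5.25 / 0.24,
    ),
    ProcessRecord(
        label="batch_optimized", medium="optimized", mode="batch",
        od600=11.5, dcw=4.3, eps=2.2, viability=5.6e9, lactate=22.2,
        substrate_consumed=22.2 / 1.11, duration=22.2 / 1.0,
    ),
    ProcessRecord(
        label="fedbatch_optimized", medium="optimized", mode="fedbatch",
        od600=48.0, dcw=10.7, eps=3.7, viability=1.7e10, lactate=121.2,
        substrate_consumed=121.2 / 1.21, duration=121.2 / 5.5,
    ),
]

# PUBLISHED: wound-closure crossing times, h (mean +/- sd over fields).
WOUND_CLOSURE_TIMES = {
    "CTR": {20: (8.8, 0.6), 60: (14.5, 0.9), 80: (37.7, 5.0)},
    "EPS": {20: (5.3, 1.0), 60: (8.6, 2.0), 80: (14.4, 4.0)},
}
WOUND_WATCH_WINDOW_H = 40.0
WOUND_MIN_FIELDS = 5
# PUBLISHED: residual scratched area at the end of the watch -> plateaus.
WOUND_PLATEAU = {"CTR": 65.0, "EPS": 95.0}

# ---------------------------------------------------------------------------
# DERIVED: simulator calibrations.  Yields are the printed process yields;
# Y_XS and alpha_E are back-computed from the corresponding summary row
# (batch optimized: X 4.3 / S 20; fed-batch: X 10.7 / ~100 g/L consumed).
# ---------------------------------------------------------------------------
KINETICS_BATCH_OPTIMIZED = KineticConfig(
    inhibition=SIGMOID_FIXTURE,
    K_S=0.1,
    Y_XS=0.215,
    Y_PS=1.11,
    m_S=0.0,
    alpha_E=0.5,
    beta_E=0.0,
    k_viab=1.59e12,
)

KINETICS_FEDBATCH = KineticConfig(
    inhibition=SIGMOID_FIXTURE,
    K_S=0.1,
    Y_XS=0.107,
    Y_PS=1.21,
    m_S=0.0,
    alpha_E=0.35,
    beta_E=0.0,
    k_viab=1.59e12,
)

# Bioreactor starting point: 2 L working volume, 20 g/L glucose charge,
# inoculated to OD600 0.1 (~0.037 g DCW/L at the strain's 0.37 g/OD factor).
BIOREACTOR_INIT = FermentationState(t=0.0, V=2.0, X=0.04, S=20.0, P=0.0, E=0.0)

FEED_CONC_G_PER_L = 550.0  # stated 500-600 g/L concentrated medium, midpoint
FEED_RATE_BAND = (8.0, 10.0)  # stated exponential profile, g/(L h)
FEED_TRIGGER_G_PER_L = 1.0  # stated trigger band 1 +/- 0.5 g/L, midpoint
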