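"""Synthetic DTNB plate-assay generator.

Emulates the continuous kinetic assay and the 30-min endpoint substrate
screen so the whole analysis chain (optics -> rates -> kinetics -> stats)
runs without any instrument data.  Progress curves integrate the sequential
rate law with 1:1 substrate depletion (each product molecule consumes one
Ac-CoA and one histidine), optionally damped by an uncompetitive-style
co-substrate inhibition factor 1/(1 + [Ac-CoA]/Ki_si); product concentration
is then mapped to A412 through the Beer-Lambert forward model with a
per-well pathlength and Gaussian absorbance noise.  No-enzyme control wells
are flat at the blank.

Defaults mirror the study conditions: 20 nM enzyme, His 0-4500 µM and
Ac-CoA 5-500 µM grids for kinetics, 300 µM Ac-CoA with 500 nM enzyme for
the endpoint screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import TernaryModel, ternary_rate
from .optics import OpticalCalibration, concentration_to_absorbance

__all__ = [
    "SimScenario",
    "ProgressCurve",
    "DEFAULT_HIS_GRID",
    "DEFAULT_HIS_GRID_HIGH",
    "DEFAULT_ACCOA_GRID",
    "simulate_progress_curves",
    "simulate_rate_grid",
    "simulate_endpoint_screen",
]

# Histidine grids used in the kinetic series (µM): the standard set, and the
# extended set used with the higher Ac-CoA concentrations.
DEFAULT_HIS_GRID = (0.0, 20.0, 50.0, 120.0, 300.0, 720.0, 1800.0, 4500.0)
DEFAULT_HIS_GRID_HIGH = (0.0, 50.0, 120.0, 300.0, 720.0, 1800.0, 4500.0, 10000.0)

# Fixed Ac-CoA levels (µM): the study states only the 5-500 µM range, so a
# log-spread stand-in grid covering it is used.
DEFAULT_ACCOA_GRID = (5.0, 10.0, 25.0, 50.0, 125.0, 500.0)

# Table-layout constants of the wild-type enzyme used as default ground
# truth: kcat 36.5 1/s at 20 nM enzyme, Km_AcCoA 19.8 µM, Km_His 215 µM.
# Ki_His is not a reported constant; 200 µM is a plausible default of the
# same order as Km_His, and the recovered constants do not depend on it.
DEFAULT_ENZYME_UM = 0.02
DEFAULT_MODEL = TernaryModel.from_kcat(
    kcat=36.5, enzyme_uM=DEFAULT_ENZYME_UM, km_accoa=19.8, km_his=215.0,
    ki_his=200.0,
)


@dataclass
class SimScenario:
    """Everything that determines one simulated plate.

    ``noise_sd`` is Gaussian absorbance noise (AU) added to every A412 read
    (instrument-realistic: noise lives in absorbance, not concentration).
    ``substrate_inhibition_ki`` (µM) enables the high-Ac-CoA rate decline;
    None disables it.  ``seed`` fully determines the output.
    """

    model: TernaryModel = DEFAULT_MODEL
    enzyme_uM: float = DEFAULT_ENZYME_UM
    # enzyme concentration at which model.vmax is defined; the simulated
    # rate is scaled by enzyme_uM / model_enzyme_uM (kcat is intensive)
    model_enzyme_uM: float = DEFAULT_ENZYME_UM
    his_grid: tuple = DEFAULT_HIS_GRID
    accoa_grid: tuple = DEFAULT_ACCOA_GRID
    # continuous read: 4 min at 3 s per cycle keeps even the fastest
    # (low-Ac-CoA, saturating-His) wells well sampled before depletion
    duration_s: float = 240.0
    sample_interval_s: float = 3.0
    noise_sd: float = 0.0
    pathlength_mean_cm: float = 0.55
    pathlength_sd_cm: float = 0.0
    substrate_inhibition_ki: float | None = None
    n_replicates: int = 1
    n_controls: int = 2
    seed: int = 0
    calibration: OpticalCalibration = field(
        default_factory=lambda: OpticalCalibration(blank_a412=0.04)
    )
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.his_grid) or any(c < 0 for c in self.accoa_grid):
            raise ValueError("concentrations must be >= 0")
        if self.noise_sd < 0 or self.enzyme_uM < 0:
            raise ValueError("noise_sd and enzyme_uM must be >= 0")
        if self.duration_s <= 0 or self.sample_interval_s <= 0:
            raise ValueError("duration and sample interval must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ProgressCurve:
    """Product (CoA/TNB) concentration vs time for one well."""

    well: str
    times_s: np.ndarray
    product_uM: np.ndarray
    his0_uM: float
    accoa0_uM: float
    is_control: bool = False
    series: str = "1"


def _inhibition_factor(accoa, ki_si):
    if ki_si is None:
        return 1.0
    return 1.0 / (1.0 + accoa / ki_si)


def _depletion_rate(model, enzyme_scale, his0, accoa0, ki_si):
    """RHS of d[P]/dt with both substrates depleted 1:1 by the product."""

    def rhs(_t, p):
        s = max(his0 - p[0], 0.0)
        a = max(accoa0 - p[0], 0.0)
        v = ternary_rate(model, s, a) * _inhibition_factor(a, ki_si)
        return [v * enzyme_scale]

    return rhs

def integrate_progress(
    model: TernaryModel,
    his0: float,
    accoa0: float,
    times_s: np.ndarray,
    enzyme_scale: float = 1.0,
    substrate_inhibition_ki: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate product formation under the depleting sequential law.

    ``enzyme_scale`` multiplies the rate law, letting one TernaryModel
    (whose Vmax refers to a reference enzyme concentration) be reused at a
    different enzyme level.  LSODA with the given tolerances; integrator
    failure raises rather than truncating.
    """
    if enzyme_scale == 0.0 or his0 == 0.0 or accoa0 == 0.0:
        return np.zeros_like(np.asarray(times_s, dtype=float))
    sol = solve_ivp(
        _depletion_rate(model, enzyme_scale, his0, accoa0,
                        substrate_inhibition_ki),
        (0.0, float(times_s[-1])),
        [0.0],
        t_eval=np.asarray(times_s, dtype=float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"progress-curve integration failed: {sol.message}")
    return np.minimum(sol.y[0], min(his0, accoa0))


def simulate_progress_curves(scenario: SimScenario):
    """Simulate one kinetic plate: list of curves plus the raw plate table.

    Returns ``(curves, plate)``: :class:`ProgressCurve` objects carrying the
    noise-free product concentrations (the ground truth for tests) and a
    long-format DataFrame with columns well, role, substrate, his_uM,
    accoa_uM, time_s, a412, a900, a975 holding the noisy absorbance reads.
    """
    rng = scenario.rng()
    times = np.arange(
        0.0, scenario.duration_s + 0.5 * scenario.sample_interval_s,
        scenario.sample_interval_s,
    )
    cal = scenario.calibration
    enzyme_scale = scenario.enzyme_uM / scenario.model_enzyme_uM
    curves, rows = [], []
    widx = 0

    def emit(his0, accoa0, product, is_control, series="1"):
        nonlocal widx
        well = f"W{widx:03d}"
        widx += 1
        path = scenario.pathlength_mean_cm
        if scenario.pathlength_sd_cm > 0:
            path = max(rng.normal(path, scenario.pathlength_sd_cm), 0.05)
        a412 = concentration_to_absorbance(product, path, cal)
        if scenario.noise_sd > 0:
            a412 = a412 + rng.normal(0.0, scenario.noise_sd, size=len(times))
        a900 = 0.04
        a975 = a900 + path * cal.pathlength_divisor
        curves.append(ProgressCurve(
            well=well, times_s=times.copy(), product_uM=np.asarray(product),
            his0_uM=his0, accoa0_uM=accoa0, is_control=is_control,
            series=series,
        ))
        role = "control" if is_control else "reaction"
        for t, a in zip(times, np.atleast_1d(a412)):
            rows.append((well, role, "histidine", his0, accoa0, t,
                         float(a), a900, a975, series))

    for accoa0 in scenario.accoa_grid:
        for his0 in scenario.his_grid:
            product = integrate_progress(
                scenario.model, his0, accoa0, times,
                enzyme_scale=enzyme_scale,
                substrate_inhibition_ki=scenario.substrate_inhibition_ki,
                rtol=scenario.rtol, atol=scenario.atol,
            )
            for _ in range(scenario.n_replicates):
                emit(his0, accoa0, product, is_control=False)
    for _ in range(scenario.n_controls):
        emit(max(scenario.his_grid), max(scenario.accoa_grid),
             np.zeros_like(times), is_control=True)

    plate = pd.DataFrame(
        rows,
        columns=["well", "role", "substrate", "his_uM", "accoa_uM", "time_s",
                 "a412", "a900", "a975", "series"],
    )
    return curves, plate


def simulate_rate_grid(scenario: SimScenario) -> pd.DataFrame:
    """Evaluate v0 analytically at t = 0 for every grid cell.

    Shortcut past progress-curve integration for tests of the downstream
    fitting chain.  Noise (``scenario.noise_sd`` interpreted here as a
    *relative* rate error) is i.i.d. Gaussian; the noise-free output equals
    the rate law exactly.
    """
    rng = scenario.rng()
    enzyme_scale = scenario.enzyme_uM / scenario.model_enzyme_uM
    rows = []
    for accoa in scenario.accoa_grid:
        for his in scenario.his_grid:
            v = ternary_rate(scenario.model, his, accoa) * enzyme_scale
            v *= _inhibition_factor(accoa, scenario.substrate_inhibition_ki)
            if scenario.noise_sd > 0:
                v *= 1.0 + rng.normal(0.0, scenario.noise_sd)
            rows.append((his, accoa, v, "1"))
    return pd.DataFrame(rows, columns=["his_uM", "accoa_uM", "v0_uM_s", "series"])


# Endpoint screen conditions: 300 µM Ac-CoA, 500 nM enzyme, 30 min at 37 C.
SCREEN_ACCOA_UM = 300.0
SCREEN_ENZYME_UM = 0.5
SCREEN_DURATION_S = 1800.0


def simulate_endpoint_screen(
    panel: dict,
    noise_sd: float = 0.003,
    pathlength_mean_cm: float = 0.55,
    pathlength_sd_cm: float = 0.01,
    accoa0_uM: float = SCREEN_ACCOA_UM,
    duration_s: float = SCREEN_DURATION_S,
    n_replicates: int = 4,
    n_controls: int = 2,
    seed: int = 0,
    calibration: OpticalCalibration | None = None,
) -> pd.DataFrame:
    """Simulate the 30-min endpoint substrate screen.

    ``panel`` maps substrate name -> pseudo-first-order activity k (s^-1):
    endpoint product is A0 * (1 - exp(-k * t)), which caps at the Ac-CoA
    pool for highly active substrates and stays at 0 for inactive ones.
    Each substrate gets ``n_replicates`` reaction wells and ``n_controls``
    no-enzyme control wells (flat at the blank), matching the screen layout.

    Returns a plate table with one endpoint row per well (time_s =
    ``duration_s``), columns as in :func:`simulate_progress_curves`.
    """
    if not panel:
        raise ValueError("substrate panel is empty")
    rng = np.random.default_rng(seed)
    cal = calibration or OpticalCalibration.for_assay("endpoint", blank_a412=0.04)
    rows = []
    widx = 0
    for substrate, k in panel.items():
        if k < 0:
            raise ValueError(f"negative activity for {substrate}")
        endpoint = accoa0_uM * (1.0 - np.exp(-k * duration_s))
        for role, n, conc in (("reaction", n_replicates, endpoint),
                              ("control", n_controls, 0.0)):
            for _ in range(n):
                well = f"S{widx:03d}"
                widx += 1
                path = max(rng.normal(pathlength_mean_cm, pathlength_sd_cm), 0.05)
                a412 = concentration_to_absorbance(conc, path, cal)
                if noise_sd > 0:
                    a412 += rng.normal(0.0, noise_sd)
                a900 = 0.04
                a975 = a900 + path * cal.pathlength_divisor
                rows.append((well, role, substrate, 0.0, accoa0_uM,
                             duration_s, float(a412), a900, a975, "screen"))
    return pd.DataFrame(
        rows,
        columns=["well", "role", "substrate", "his_uM", "accoa_uM", "time_s",
                 "a412", "a900", "a975", "series"],
    )
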