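"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of a reconstituted
scramblase experiment: Gaussian vesicle radii (as measured by DLS),
Poisson placement of functional scramblase units by protein mass with a
refractory vesicle fraction, single-exponential dithionite reduction of
the accessible NBD pool, endpoint non-idealities (protein-free endpoint
~43% instead of the ideal 50%, saturating endpoint ~76% instead of 100%),
and pyranine proton-pumping traces under pulsed illumination.

Every stochastic operation takes an explicit integer seed; there is no
global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    EVENT_DITHIONITE,
    AssayTrace,
    ReconstitutionPoint,
    VesiclePopulation,
)
from .errors import InvalidParameterError
from .geometry import DEFAULT_AREA_PER_LIPID
from .occupancy import (
    DEFAULT_RECONSTITUTABLE_FRACTION,
    OccupancyModelParams,
    expected_scramblases,
    mass_to_alpha,
    prob_occupied_gaussian,
)

#: Default dithionite reduction rate constant (s^-1); half-life 15.2 s.
DEFAULT_K_RED = math.log(2) / 15.2


@dataclass(frozen=True)
class DithioniteAssayParams:
    """Parameters of the simulated dithionite scramblase assay.

    k_red : reduction rate constant of accessible NBD (s^-1)
    outer_fraction_ideal : ideal accessible NBD fraction without scramblase
    F0_target : endpoint % reduction for scramblase-free vesicles
    Fmax_target : endpoint % reduction for scramblase-occupied vesicles
    noise_sd : Gaussian noise s.d., % of the pre-addition signal
    baseline_drift : fractional signal loss per second (photobleaching)
    """

    k_red: float = DEFAULT_K_RED
    outer_fraction_ideal: float = 0.5
    F0_target: float = 43.0
    Fmax_target: float = 76.2
    noise_sd: float = 0.5
    baseline_drift: float = 0.0

    def __post_init__(self) -> None:
        if not self.k_red > 0:
            raise InvalidParameterError("k_red must be positive")
        if not 0 < self.outer_fraction_ideal < 1:
            raise InvalidParameterError("outer_fraction_ideal must be in (0, 1)")
        if not 0 <= self.F0_target <= self.Fmax_target <= 100:
            raise InvalidParameterError("need 0 <= F0_target <= Fmax_target <= 100")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_radii(n: int, r_bar: float, sigma: float, seed) -> np.ndarray:
    """Draw ``n`` vesicle radii from Normal(r_bar, sigma), resampling any
    non-positive draws (the DLS distribution has negligible mass there)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not r_bar > 0:
        raise InvalidParameterError("r_bar must be positive")
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    rng = _rng(seed)
    radii = rng.normal(r_bar, sigma, size=n)
    bad = radii <= 0
    while np.any(bad):
        radii[bad] = rng.normal(r_bar, sigma, size=int(bad.sum()))
        bad = radii <= 0
    return radii


def assign_scramblases(
    radii,
    ppr: float,
    M: float,
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
    f_reconstitutable: float = DEFAULT_RECONSTITUTABLE_FRACTION,
    seed=0,
) -> VesiclePopulation:
    """Place functional scramblase units of molar mass ``M`` onto vesicles.

    Each vesicle is refractory with probability ``1 - f_reconstitutable``
    (count 0); otherwise its count is Poisson with mean
    lambda(r) = (alpha/2) * PPR* * r^2, where alpha = 16*pi/(A*M) and
    PPR* = ppr / f. Lipid counts use the equal-leaflet convention
    8*pi*r^2/A, matching the occupancy-model derivation.
    """
    radii = np.asarray(radii, dtype=float)
    if ppr < 0:
        raise InvalidParameterError("ppr must be >= 0")
    alpha = mass_to_alpha(M, area_per_lipid)  # validates M, A
    if not 0 < f_reconstitutable <= 1:
        raise InvalidParameterError("f_reconstitutable must be in (0, 1]")
    rng = _rng(seed)
    refractory = rng.random(len(radii)) >= f_reconstitutable
    lam = expected_scramblases(radii, ppr / f_reconstitutable, alpha) if ppr > 0 else (
        np.zeros(len(radii))
    )
    counts = rng.poisson(lam)
    counts[refractory] = 0
    lipids = np.maximum(
        1, np.rint(8.0 * math.pi * radii**2 / area_per_lipid).astype(int)
    )
    return VesiclePopulation(
        radii=radii,
        scramblase_counts=counts,
        refractory_flags=refractory,
        lipid_counts=lipids,
    )


def simulate_dithionite_trace(
    pop: VesiclePopulation,
    params: DithioniteAssayParams,
    t_grid,
    t_add: float,
    seed=0,
) -> AssayTrace:
    """Simulate an NBD fluorescence trace for a dithionite scramblase assay.

    The trace is normalized to 100% before dithionite addition. After
    addition, each vesicle's reducible NBD pool decays as
    exp(-k_red * (t - t_add)); a vesicle with no scramblase exposes
    ``F0_target``% of its NBD (outer leaflet only, with the measured
    non-ideality), a vesicle with at least one scramblase exposes
    ``Fmax_target``% (full pool, scrambled faster than it is reduced).
    The protected (inner-leaflet) pool of scramblase-free vesicles never
    decreases. Vesicles contribute in proportion to their lipid counts.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise InvalidParameterError("t_grid must be a 1-D grid of >= 2 times")
    if not (t_grid[0] <= t_add <= t_grid[-1]):
        raise InvalidParameterError("t_add must lie within t_grid")
    rng = _rng(seed)
    w = pop.lipid_counts / pop.lipid_counts.sum()
    occupied = pop.scramblase_counts >= 1
    # Per-vesicle reducible fraction: endpoint targets applied per class.
    q = np.where(occupied, params.Fmax_target / 100.0, params.F0_target / 100.0)
    dt = np.clip(t_grid[None, :] - t_add, 0.0, None)
    per_vesicle = (1.0 - q[:, None]) + q[:, None] * np.exp(-params.k_red * dt)
    signal = 100.0 * (w[:, None] * per_vesicle).sum(axis=0)
    if params.baseline_drift:
        signal = signal * (1.0 - params.baseline_drift * (t_grid - t_grid[0]))
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=len(t_grid))
    return AssayTrace(
        time=t_grid,
        fluorescence=np.clip(signal, 0.0, None),
        events={EVENT_DITHIONITE: float(t_add)},
    )


def generate_ppr_series(
    ppr_values,
    M_true: float,
    r_bar: float,
    sigma: float,
    f: float = DEFAULT_RECONSTITUTABLE_FRACTION,
    F0: float = 43.0,
    Fmax: float = 76.2,
    noise_sd: float = 0.02,
    seed=0,
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
) -> list[ReconstitutionPoint]:
    """Generate a scramblase titration: (PPR, % reduction, P) triples.

    The occupancy probability P is computed from the Gaussian-radius model
    at PPR* = ppr / f with alpha = 16*pi/(A*M_true), perturbed by additive
    Gaussian noise (s.d. ``noise_sd``, clipped to [0, 1] with the clipping
    flagged), then mapped to a percent-reduction endpoint via
    F = F0 + P * (Fmax - F0).
    """
    ppr_values = np.asarray(ppr_values, dtype=float)
    if np.any(ppr_values < 0):
        raise InvalidParameterError("ppr values must be >= 0")
    if not F0 < Fmax:
        raise InvalidParameterError("need F0 < Fmax")
    params = OccupancyModelParams(
        alpha=mass_to_alpha(M_true, area_per_lipid),
        r_bar=r_bar,
        sigma=sigma,
        f_reconstitutable=f,
        area_per_lipid=area_per_lipid,
    )
    rng = _rng(seed)
    points: list[ReconstitutionPoint] = []
    for ppr in ppr_values:
        ppr_star = ppr / f
        p = prob_occupied_gaussian(ppr_star, params)
        if noise_sd > 0:
            p = p + rng.normal(0.0, noise_sd)
        clipped = not 0.0 <= p <= 1.0
        p = float(np.clip(p, 0.0, 1.0))
        points.append(
            ReconstitutionPoint(
                ppr=float(ppr),
                ppr_star=float(ppr_star),
                F=F0 + p * (Fmax - F0),
                P=p,
                clipped=clipped,
            )
        )
    return points


def simulate_dls(
    n: int, r_bar: float, sigma: float, seed=0, bin_width: float = 10.0
):
    """Simulate a DLS size measurement: radius samples plus a binned histogram.

    Returns ``(samples, bin_edges, counts)``; counts sum to ``n``.
    """
    if not bin_width > 0:
        raise InvalidParameterError("bin_width must be positive")
    samples = sample_radii(n, r_bar, sigma, seed)
    lo = bin_width * math.floor(samples.min() / bin_width)
    hi = bin_width * math.ceil(samples.max() / bin_width)
    if hi <= lo:  # all samples identical (sigma = 0)
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(samples, bins=edges)
    return samples, edges, counts


# ---------------------------------------------------------------------------
# Pyranine proton-pumping assay
# ---------------------------------------------------------------------------

#: Linear pyranine fluorescence-vs-pH map used by the simulator (a.u.).
SIM_CALIBRATION_SLOPE = 100.0
SIM_CALIBRATION_INTERCEPT = -400.0
SIM_CALIBRATION_RANGE = (5.0, 9.0)


def default_light_schedule(t_total: float = 1200.0, on: float = 20.0, off: float = 20.0):
    """Pulsed illumination: ``on`` s lit / ``off`` s dark cycles over ``t_total`` s."""
    schedule = []
    t = 0.0
    while t < t_total:
        schedule.append((t, min(t + on, t_total)))
        t += on + off
    return schedule


@dataclass(frozen=True)
class PumpAssayParams:
    """Parameters of the simulated light-driven proton-pumping assay.

    Intravesicular pH relaxes toward ``pH_asymptote`` at rate ``k_pump``
    while the light is on and holds during dark intervals (the vesicle
    membrane retains the pumped protons on the assay timescale).
    ``valinomycin=True`` marks the preset where the K+ ionophore dissipates
    the membrane potential, raising both rate and extent of acidification.
    """

    pH_init: float = 7.57
    pH_asymptote: float = 7.57
    k_pump: float = 0.0
    valinomycin: bool = False
    light_schedule: tuple = field(
        default_factory=lambda: tuple(default_light_schedule())
    )
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.pH_init, self.pH_asymptote):
            if not 5.0 <= v <= 9.0:
                raise InvalidParameterError("pH values must lie in [5, 9]")
        if self.k_pump < 0:
            raise InvalidParameterError("k_pump must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


#: Presets calibrated so that pH 20 min after illumination starts matches the
#: measured values: ~7.57 (no protein), ~6.90 (pump), ~6.45 (pump + valinomycin).
PUMP_PRESETS: dict[str, PumpAssayParams] = {
    "no_protein": PumpAssayParams(pH_init=7.57, pH_asymptote=7.57, k_pump=0.0),
    "br": PumpAssayParams(pH_init=7.57, pH_asymptote=6.85, k_pump=4.445e-3),
    "br_valinomycin": PumpAssayParams(
        pH_init=7.57, pH_asymptote=6.40, k_pump=5.254e-3, valinomycin=True
    ),
}


def _lit_time(t_grid: np.ndarray, schedule) -> np.ndarray:
    """Cumulative light-on time before each grid point."""
    lit = np.zeros_like(t_grid)
    for on, off in schedule:
        lit += np.clip(t_grid - on, 0.0, off - on)
    return lit


def simulate_pyranine_trace(
    params: PumpAssayParams,
    calibration=None,
    t_grid=None,
    seed=0,
):
    """Simulate a pyranine fluorescence trace under pulsed illumination.

    ``calibration`` is any object with ``slope``/``intercept`` (a.u. per pH
    unit) and optionally ``valid_range``; defaults to the simulator's linear
    map. Returns ``(AssayTrace, pH_series)`` where the trace fluorescence is
    the calibration's forward map of pH plus Gaussian noise. pH values
    outside the calibrated range raise a warning-level flag on the trace.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 1200.0 + 1.0, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    slope = getattr(calibration, "slope", SIM_CALIBRATION_SLOPE)
    intercept = getattr(calibration, "intercept", SIM_CALIBRATION_INTERCEPT)
    valid_range = getattr(calibration, "valid_range", SIM_CALIBRATION_RANGE)
    rng = _rng(seed)
    lit = _lit_time(t_grid, params.light_schedule)
    ph = params.pH_asymptote + (params.pH_init - params.pH_asymptote) * np.exp(
        -params.k_pump * lit
    )
    fluor = slope * ph + intercept
    if params.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, params.noise_sd, size=len(t_grid))
    events: dict[str, float] = {}
    for i, (on, off) in enumerate(params.light_schedule):
        if t_grid[0] <= on <= t_grid[-1]:
            events[f"light_on_{i}"] = float(on)
        if t_grid[0] <= off <= t_grid[-1]:
            events[f"light_off_{i}"] = float(off)
    flags = []
    lo, hi = valid_range
    if np.any(ph < lo) or np.any(ph > hi):
        flags.append("pH_outside_calibration")
    trace = AssayTrace(time=t_grid, fluorescence=fluor, events=events, flags=flags)
    return trace, ph
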