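"""Scalar readouts from fluorescence traces.

Percent reduction and reduction kinetics of the dithionite scramblase
assay, the scrambling-rate lower bound derived from them, pyranine
fluorescence-to-pH calibration for the proton-pumping assay, and
absorbance-based purity of the protein preparation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datatypes import EVENT_DITHIONITE, AssayTrace
from .errors import FitConvergenceError, InvalidParameterError

#: Extinction coefficients of bacteriorhodopsin (M^-1 cm^-1).
EPSILON_560 = 54_000.0
EPSILON_280 = 66_000.0

#: A560/A280 of a pure preparation (reference convention; the ratio of the
#: extinction coefficients, 54/66 ~ 0.818, is available as an alternative).
PURE_RATIO_DEFAULT = 0.5
PURE_RATIO_EPSILON = EPSILON_560 / EPSILON_280

DEFAULT_BASELINE_WINDOW = (-30.0, 0.0)  # relative to dithionite addition (s)
DEFAULT_PLATEAU_WINDOW = (300.0, 400.0)


@dataclass
class ReductionResult:
    """Summary of a dithionite reduction trace.

    percent_reduction : % of pre-addition fluorescence lost at the plateau
    k_red, t_half : single-exponential rate constant (s^-1) and half-life (s),
        present only when kinetics were fitted; t_half = ln2 / k_red
    plateau_window : (start, end) of the plateau window used (s)
    fit_residual_rms : RMS residual of the exponential fit, % units
    flags : quality flags ("not_converged" when the plateau still drifts)
    """

    percent_reduction: float
    k_red: float | None = None
    t_half: float | None = None
    plateau_window: tuple[float, float] | None = None
    fit_residual_rms: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SpectrumSummary:
    """Absorbance-peak summary of a purified preparation."""

    A280: float
    A560: float
    purity: float
    concentration: float  # mol/L, 1 cm path
    epsilon_560: float = EPSILON_560
    epsilon_280: float = EPSILON_280


def _window_mean(trace: AssayTrace, lo: float, hi: float, what: str) -> np.ndarray:
    mask = (trace.time >= lo) & (trace.time <= hi)
    if not mask.any():
        raise InvalidParameterError(f"{what} window [{lo}, {hi}] contains no samples")
    return trace.fluorescence[mask]


def percent_reduction(
    trace: AssayTrace,
    baseline_window: tuple[float, float] | None = None,
    plateau_window: tuple[float, float] | None = None,
    slope_threshold: float = 0.02,
) -> ReductionResult:
    """Percent fluorescence reduction between baseline and plateau windows.

    Windows are absolute times (s); they default to the 30 s before
    dithionite addition and 300-400 s after it. A plateau still drifting
    faster than ``slope_threshold`` (% per second) raises a
    ``"not_converged"`` flag. The result is invariant under multiplicative
    rescaling of the whole trace.
    """
    if EVENT_DITHIONITE not in trace.events:
        raise InvalidParameterError(
            f"trace has no {EVENT_DITHIONITE!r} event marker"
        )
    t_add = trace.events[EVENT_DITHIONITE]
    if baseline_window is None:
        baseline_window = (t_add + DEFAULT_BASELINE_WINDOW[0], t_add)
    if plateau_window is None:
        plateau_window = (
            t_add + DEFAULT_PLATEAU_WINDOW[0],
            t_add + DEFAULT_PLATEAU_WINDOW[1],
        )
    if not baseline_window[1] <= t_add:
        raise InvalidParameterError("baseline window must precede dithionite addition")
    if not plateau_window[0] >= t_add:
        raise InvalidParameterError("plateau window must follow dithionite addition")
    baseline = _window_mean(trace, *baseline_window, "baseline")
    mask = (trace.time >= plateau_window[0]) & (trace.time <= plateau_window[1])
    if not mask.any():
        raise InvalidParameterError("plateau window contains no samples")
    plateau_t = trace.time[mask]
    plateau_f = trace.fluorescence[mask]
    b = float(baseline.mean())
    if b <= 0:
        raise InvalidParameterError("baseline fluorescence must be positive")
    pct = 100.0 * (1.0 - float(plateau_f.mean()) / b)
    flags: list[str] = []
    if len(plateau_t) >= 2 and np.ptp(plateau_t) > 0:
        slope = np.polyfit(plateau_t, 100.0 * plateau_f / b, 1)[0]
        if abs(slope) > slope_threshold:
            flags.append("not_converged")
    return ReductionResult(
        percent_reduction=float(np.clip(pct, 0.0, 100.0)),
        plateau_window=tuple(plateau_window),
        flags=flags,
    )


class ExponentialDecay(BaseEstimator):
    """Single-exponential decay with floor, ``F(t) = plateau + dF*exp(-k*(t-t0))``.

    Fitted by nonlinear least squares on the post-addition part of a trace.

    Parameters
    ----------
    t0 : time origin of the decay (s); typically the dithionite addition time.

    Attributes
    ----------
    k_ : rate constant (s^-1)
    t_half_ : half-life ln2 / k_ (s)
    plateau_, amplitude_ : fitted floor and decaying amplitude (trace units)
    residual_rms_ : RMS of fit residuals (trace units)
    """

    def __init__(self, t0: float = 0.0):
        self.t0 = t0

    def fit(self, t, F):
        t = np.asarray(t, dtype=float)
        F = np.asarray(F, dtype=float)
        mask = t >= self.t0
        t, F = t[mask], F[mask]
        if len(t) < 10:
            raise InvalidParameterError(
                "need at least 10 samples after the decay origin"
            )
        plateau0 = float(F[-max(1, len(F) // 10):].mean())
        amp0 = max(float(F[0] - plateau0), 1e-9)
        # Half-crossing time gives the initial rate guess.
        below = np.nonzero(F <= plateau0 + amp0 / 2)[0]
        t_half0 = (t[below[0]] - self.t0) if len(below) else (t[-1] - t[0]) / 3
        k0 = math.log(2) / max(t_half0, (t[1] - t[0]))
        p0 = (plateau0, amp0, k0)
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, plateau, amp, k: plateau + amp * np.exp(-k * (tt - self.t0)),
                t,
                F,
                p0=p0,
                bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=10_000,
            )
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"exponential decay fit did not converge: {exc}",
                diagnostics={"p0": p0, "n_samples": len(t)},
            ) from exc
        self.plateau_, self.amplitude_, self.k_ = map(float, popt)
        self.t_half_ = math.log(2) / self.k_
        resid = F - (self.plateau_ + self.amplitude_ * np.exp(-self.k_ * (t - self.t0)))
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        return self

    def predict(self, t):
        check_is_fitted(self, "k_")
        t = np.asarray(t, dtype=float)
        return self.plateau_ + self.amplitude_ * np.exp(-self.k_ * (t - self.t0))


def fit_decay(trace: AssayTrace, t_add: float | None = None) -> ReductionResult:
    """Fit the post-addition reduction kinetics of a dithionite trace.

    Returns a :class:`ReductionResult` carrying the rate constant, half-life
    (ln2/k), RMS residual, and the plateau-based percent reduction implied
    by the fit.
    """
    if t_add is None:
        if EVENT_DITHIONITE not in trace.events:
            raise InvalidParameterError(
                "t_add not given and trace has no dithionite event"
            )
        t_add = trace.events[EVENT_DITHIONITE]
    model = ExponentialDecay(t0=float(t_add)).fit(trace.time, trace.fluorescence)
    initial = model.plateau_ + model.amplitude_
    pct = 100.0 * model.amplitude_ / initial if initial > 0 else 0.0
    return ReductionResult(
        percent_reduction=float(np.clip(pct, 0.0, 100.0)),
        k_red=model.k_,
        t_half=model.t_half_,
        fit_residual_rms=model.residual_rms_,
    )


def scrambling_rate_lower_bound(t_half: float, n_lipids_per_vesicle: float) -> float:
    """Lower bound on the scrambling rate (lipids/s per functional unit).

    Scrambling outpaces dithionite reduction, so the observed reduction
    half-life bounds the scrambling rate from below:
    rate >= (ln2 / t_half) * lipids per vesicle.
    """
    if not t_half > 0:
        raise InvalidParameterError("t_half must be positive")
    if not n_lipids_per_vesicle >= 1:
        raise InvalidParameterError("need at least one lipid per vesicle")
    return (math.log(2) / t_half) * n_lipids_per_vesicle


class PyranineCalibration(BaseEstimator):
    """Linear pyranine fluorescence-vs-pH calibration (ordinary least squares).

    Pyranine fluorescence is linear in intravesicular pH over the assay
    range, so a fitted line converts fluorescence traces to pH time courses.

    Attributes
    ----------
    slope_ : fluorescence a.u. per pH unit
    intercept_ : a.u.
    r_squared_ : coefficient of determination of the line
    valid_range_ : (min pH, max pH) spanned by the calibration points
    """

    def fit(self, pH, F):
        pH = np.asarray(pH, dtype=float)
        F = np.asarray(F, dtype=float)
        if len(pH) < 3 or len(pH) != len(F):
            raise InvalidParameterError("need >= 3 (pH, fluorescence) points")
        if np.ptp(pH) < 0.5:
            raise InvalidParameterError(
                "calibration points must span at least 0.5 pH units"
            )
        res = stats.linregress(pH, F)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.slope_se_ = float(res.stderr)
        self.valid_range_ = (float(pH.min()), float(pH.max()))
        return self

    def predict(self, pH):
        """Forward map: expected fluorescence at the given pH."""
        check_is_fitted(self, "slope_")
        return self.slope_ * np.asarray(pH, dtype=float) + self.intercept_

    def to_pH(self, F):
        """Inverse map: pH from fluorescence."""
        check_is_fitted(self, "slope_")
        return (np.asarray(F, dtype=float) - self.intercept_) / self.slope_

    # simulate_pyranine_trace accepts any object exposing these names
    @property
    def slope(self) -> float:
        return self.slope_

    @property
    def intercept(self) -> float:
        return self.intercept_

    @property
    def valid_range(self) -> tuple[float, float]:
        return self.valid_range_


def fit_pyranine_calibration(points) -> PyranineCalibration:
    """Fit the calibration line from ``(pH, fluorescence)`` pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("points must be (n, 2): columns pH, fluorescence")
    return PyranineCalibration().fit(pts[:, 0], pts[:, 1])


def trace_to_pH(
    trace: AssayTrace,
    cal: PyranineCalibration,
    t_report: float = 1200.0,
):
    """Convert a pyranine trace to a pH time course.

    Returns ``(pH_series, pH_at_report, flags)``; the reported value is the
    nearest sample to ``t_report`` (default 20 min). Fluorescence outside
    the calibrated range is converted anyway but flagged.
    """
    if not trace.time[0] <= t_report <= trace.time[-1]:
        raise InvalidParameterError(
            f"t_report={t_report} lies outside the trace [{trace.time[0]}, {trace.time[-1]}]"
        )
    ph = cal.to_pH(trace.fluorescence)
    flags: list[str] = []
    lo, hi = cal.valid_range_
    f_range = sorted((cal.predict(lo), cal.predict(hi)))
    if np.any(trace.fluorescence < f_range[0]) or np.any(
        trace.fluorescence > f_range[1]
    ):
        flags.append("fluorescence_outside_calibration")
    idx = int(np.argmin(np.abs(trace.time - t_report)))
    return ph, float(ph[idx]), flags


def estimate_purity(
    A560: float, A280: float, pure_ratio: float = PURE_RATIO_DEFAULT
) -> SpectrumSummary:
    """Purity and concentration of a preparation from its absorbance peaks.

    ``purity = min(1, (A560/A280) / pure_ratio)`` against the pure-sample
    peak-height ratio; concentration from A560 and the 560-nm extinction
    coefficient (1 cm path).
    """
    if not A280 > 0:
        raise InvalidParameterError("A280 must be positive")
    if A560 < 0:
        raise InvalidParameterError("A560 must be >= 0")
    if not pure_ratio > 0:
        raise InvalidParameterError("pure_ratio must be positive")
    purity = min(1.0, (A560 / A280) / pure_ratio)
    return SpectrumSummary(
        A280=A280,
        A560=A560,
        purity=purity,
        concentration=A560 / EPSILON_560,
    )
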