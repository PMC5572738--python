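"""The inverse problem: from titration endpoints to the functional mass.

Percent-reduction endpoints F are transformed to occupancy probabilities
P = (F - F0)/(Fmax - F0), the Gaussian-radius Poisson occupancy model is
fitted for its single constant alpha by nonlinear least squares, and the
molar mass of the functional scramblase unit follows as
M = 16*pi / (A * alpha). The vesicle size distribution feeding the model
is fitted separately from DLS radius samples or histograms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datatypes import ReconstitutionPoint
from .errors import FitConvergenceError, InvalidParameterError
from .geometry import DEFAULT_AREA_PER_LIPID
from .occupancy import (
    DEFAULT_RECONSTITUTABLE_FRACTION,
    FIT_RADIUS_PRESET,
    FunctionalMass,
    OccupancyModelParams,
    alpha_to_mass,
    prob_occupied_fixed_radius,
    prob_occupied_gaussian,
)

ALPHA_BOUNDS = (1e-8, 1.0)


@dataclass
class GaussianSizeFit:
    """Gaussian fit of a vesicle radius distribution (nm)."""

    r_bar: float
    sigma: float
    r_bar_se: float
    sigma_se: float
    n_samples: int
    degenerate: bool = False


@dataclass
class FitResult:
    """Result of the occupancy-model fit.

    alpha_hat, alpha_se : fit constant and its standard error (mol g^-1 nm^-2)
    mass, mass_se : derived functional molar mass and its standard error (g/mol)
    model_variant : "gaussian" (radius-distribution average) or "fixed_radius"
    residuals : per-point residuals P_obs - P_model
    alpha_se_bootstrap : optional bootstrap alternative to the Jacobian SE
    """

    alpha_hat: float
    alpha_se: float
    mass: float
    mass_se: float
    model_variant: str
    residuals: np.ndarray
    covariance: float = 0.0  # var(alpha_hat)
    alpha_se_bootstrap: float | None = None
    n_points: int = 0
    params: OccupancyModelParams | None = None
    clipped_points: int = 0


def compute_P(F, F0: float, Fmax: float, return_clipped: bool = False):
    """Occupancy probability from percent-reduction endpoints (affine map).

    ``P = (F - F0) / (Fmax - F0)``, clipped to [0, 1]. With
    ``return_clipped=True`` also returns a boolean mask of clipped values.
    The transform is invariant under common positive rescaling of
    (F, F0, Fmax).
    """
    if not Fmax > F0:
        raise InvalidParameterError(f"need Fmax > F0, got F0={F0}, Fmax={Fmax}")
    F = np.asarray(F, dtype=float)
    raw = (F - F0) / (Fmax - F0)
    clipped = (raw < 0) | (raw > 1)
    p = np.clip(raw, 0.0, 1.0)
    if p.ndim == 0:
        p, clipped = float(p), bool(clipped)
    if return_clipped:
        return p, clipped
    return p


class GaussianRadiusFit(BaseEstimator):
    """Gaussian fit of DLS vesicle radii.

    ``fit(samples)`` uses the maximum-likelihood estimates (sample mean and
    SD) with standard errors sigma/sqrt(n) and sigma/sqrt(2n);
    ``fit_histogram(edges, counts)`` fits a scaled Gaussian to binned counts
    by weighted least squares (Poisson weights).

    Attributes
    ----------
    r_bar_, sigma_ : fitted mean and s.d. (nm)
    r_bar_se_, sigma_se_ : standard errors (nm)
    n_ : number of samples (or total counts)
    degenerate_ : True when all samples coincide (sigma 0)
    """

    def fit(self, samples, y=None):
        samples = np.asarray(samples, dtype=float).ravel()
        n = len(samples)
        if n < 10:
            raise InvalidParameterError("need at least 10 radius samples")
        self.r_bar_ = float(samples.mean())
        self.sigma_ = float(samples.std(ddof=0))
        self.n_ = n
        self.degenerate_ = self.sigma_ == 0.0
        self.r_bar_se_ = self.sigma_ / math.sqrt(n)
        self.sigma_se_ = self.sigma_ / math.sqrt(2 * n)
        return self

    def fit_histogram(self, edges, counts):
        edges = np.asarray(edges, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if len(edges) != len(counts) + 1:
            raise InvalidParameterError("edges must bracket counts (len+1)")
        occupied = counts > 0
        if occupied.sum() < 5:
            raise InvalidParameterError("need at least 5 non-empty bins")
        centers = 0.5 * (edges[:-1] + edges[1:])
        n = counts.sum()
        mu0 = float(np.average(centers, weights=counts))
        sd0 = float(np.sqrt(np.average((centers - mu0) ** 2, weights=counts)))
        amp0 = counts.max()

        def model(x, amp, mu, sd):
            return amp * np.exp(-((x - mu) ** 2) / (2 * sd**2))

        try:
            popt, pcov = optimize.curve_fit(
                model,
                centers,
                counts,
                p0=(amp0, mu0, max(sd0, 1e-6)),
                sigma=np.sqrt(np.maximum(counts, 1.0)),
                absolute_sigma=False,
                maxfev=10_000,
            )
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"Gaussian histogram fit did not converge: {exc}",
                diagnostics={"p0": (amp0, mu0, sd0)},
            ) from exc
        self.r_bar_ = float(popt[1])
        self.sigma_ = float(abs(popt[2]))
        perr = np.sqrt(np.diag(pcov))
        self.r_bar_se_ = float(perr[1])
        self.sigma_se_ = float(perr[2])
        self.n_ = int(n)
        self.degenerate_ = False
        return self

    def result(self) -> GaussianSizeFit:
        check_is_fitted(self, "r_bar_")
        return GaussianSizeFit(
            r_bar=self.r_bar_,
            sigma=self.sigma_,
            r_bar_se=self.r_bar_se_,
            sigma_se=self.sigma_se_,
            n_samples=self.n_,
            degenerate=self.degenerate_,
        )


def fit_gaussian_radii(samples=None, histogram=None) -> GaussianSizeFit:
    """Fit a Gaussian size distribution from raw radii or a histogram.

    ``histogram`` is a ``(bin_edges, counts)`` pair. Exactly one of the two
    inputs must be given.
    """
    if (samples is None) == (histogram is None):
        raise InvalidParameterError("give exactly one of samples or histogram")
    est = GaussianRadiusFit()
    if samples is not None:
        est.fit(samples)
    else:
        est.fit_histogram(*histogram)
    res = est.result()
    if res.degenerate:
        warnings.warn("all radius samples identical: degenerate Gaussian fit")
    return res


class OccupancyModel(BaseEstimator):
    """Vesicle-occupancy regression P(>=1 scramblase) versus PPR*.

    Single-parameter nonlinear least squares for the fit constant alpha of
    the Poisson occupancy model, with the vesicle radius distribution
    (r_bar, sigma) treated as a fixed, externally measured input.

    Parameters
    ----------
    r_bar, sigma : Gaussian radius distribution of the vesicles (nm)
    f_reconstitutable : fraction of vesicles competent for reconstitution
        (used when converting PPR to PPR*, and stored with the fit)
    area_per_lipid : nm^2, used to convert alpha to the functional mass
    variant : "gaussian" (average over the radius distribution) or
        "fixed_radius" (all vesicles at r_bar)
    n_bootstrap : if > 0, also estimate the alpha SE by resampling points
    random_state : seed for the bootstrap

    Attributes
    ----------
    alpha_ : fitted constant (mol g^-1 nm^-2)
    alpha_se_ : Jacobian-based standard error scaled by residual variance
    mass_, mass_se_ : functional molar mass and its delta-method SE (g/mol)
    residuals_ : P_obs - P_model per point
    alpha_se_bootstrap_ : bootstrap SE (only when n_bootstrap > 0)
    """

    def __init__(
        self,
        r_bar: float = FIT_RADIUS_PRESET["r_bar"],
        sigma: float = FIT_RADIUS_PRESET["sigma"],
        f_reconstitutable: float = DEFAULT_RECONSTITUTABLE_FRACTION,
        area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
        variant: str = "gaussian",
        n_bootstrap: int = 0,
        random_state: int = 0,
    ):
        self.r_bar = r_bar
        self.sigma = sigma
        self.f_reconstitutable = f_reconstitutable
        self.area_per_lipid = area_per_lipid
        self.variant = variant
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def _model(self, ppr_star, alpha):
        if self.variant == "fixed_radius":
            return prob_occupied_fixed_radius(self.r_bar, ppr_star, alpha)
        params = OccupancyModelParams(
            alpha=alpha,
            r_bar=self.r_bar,
            sigma=self.sigma,
            f_reconstitutable=self.f_reconstitutable,
            area_per_lipid=self.area_per_lipid,
        )
        return prob_occupied_gaussian(ppr_star, params)

    def _alpha0(self, ppr_star, P):
        """Fixed-radius inversion at the smallest informative point."""
        pos = (ppr_star > 0) & (P > 0) & (P < 1)
        if not pos.any():
            return 1e-4
        i = int(np.argmin(ppr_star[pos]))
        x, p = ppr_star[pos][i], P[pos][i]
        a0 = -2.0 * math.log1p(-p) / (x * self.r_bar**2)
        return float(np.clip(a0, *ALPHA_BOUNDS))

    def fit(self, ppr_star, P, sample_weight=None):
        if self.variant not in ("gaussian", "fixed_radius"):
            raise InvalidParameterError(f"unknown model variant {self.variant!r}")
        ppr_star = np.asarray(ppr_star, dtype=float).ravel()
        P = np.asarray(P, dtype=float).ravel()
        if len(ppr_star) != len(P):
            raise InvalidParameterError("ppr_star and P must have equal length")
        if len(np.unique(ppr_star)) < 3:
            raise InvalidParameterError("need >= 3 points with distinct PPR*")
        if np.all(P == 0):
            raise InvalidParameterError("all P are zero: nothing to fit")
        if P.max() <= 0.2:
            raise InvalidParameterError(
                "identifiability guard: need at least one point with P > 0.2"
            )
        a0 = self._alpha0(ppr_star, P)
        sigma_w = None
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
            sigma_w = 1.0 / np.sqrt(sample_weight)
        try:
            popt, pcov = optimize.curve_fit(
                lambda x, a: self._model(x, a),
                ppr_star,
                P,
                p0=(a0,),
                sigma=sigma_w,
                bounds=([ALPHA_BOUNDS[0]], [ALPHA_BOUNDS[1]]),
                maxfev=10_000,
            )
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"occupancy-model fit did not converge: {exc}",
                diagnostics={"alpha0": a0, "n_points": len(P)},
            ) from exc
        self.alpha_ = float(popt[0])
        var = float(pcov[0, 0])
        self.alpha_se_ = math.sqrt(var) if np.isfinite(var) else float("nan")
        self.covariance_ = var
        self.residuals_ = P - self._model(ppr_star, self.alpha_)
        mass = alpha_to_mass(self.alpha_, self.area_per_lipid, self.alpha_se_)
        self.mass_ = mass.M
        self.mass_se_ = mass.M_uncertainty
        self.alpha_se_bootstrap_ = None
        if self.n_bootstrap > 0:
            self.alpha_se_bootstrap_ = self._bootstrap_se(ppr_star, P)
        return self

    def _bootstrap_se(self, ppr_star, P) -> float:
        rng = np.random.default_rng(self.random_state)
        n = len(P)
        alphas = []
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(ppr_star[idx])) < 3 or P[idx].max() <= 0.2:
                continue
            try:
                popt, _ = optimize.curve_fit(
                    lambda x, a: self._model(x, a),
                    ppr_star[idx],
                    P[idx],
                    p0=(self.alpha_,),
                    bounds=([ALPHA_BOUNDS[0]], [ALPHA_BOUNDS[1]]),
                    maxfev=10_000,
                )
            except RuntimeError:
                continue
            alphas.append(popt[0])
        if len(alphas) < 2:
            return float("nan")
        return float(np.std(alphas, ddof=1))

    def predict(self, ppr_star):
        check_is_fitted(self, "alpha_")
        ppr_star = np.asarray(ppr_star, dtype=float)
        return self._model(ppr_star, self.alpha_)

    def result(self) -> FitResult:
        check_is_fitted(self, "alpha_")
        return FitResult(
            alpha_hat=self.alpha_,
            alpha_se=self.alpha_se_,
            mass=self.mass_,
            mass_se=self.mass_se_,
            model_variant=self.variant,
            residuals=self.residuals_,
            covariance=self.covariance_,
            alpha_se_bootstrap=self.alpha_se_bootstrap_,
            n_points=len(self.residuals_),
            params=OccupancyModelParams(
                alpha=self.alpha_,
                r_bar=self.r_bar,
                sigma=self.sigma,
                f_reconstitutable=self.f_reconstitutable,
                area_per_lipid=self.area_per_lipid,
            ),
        )


def fit_occupancy_model(
    points: list[ReconstitutionPoint],
    r_bar: float = FIT_RADIUS_PRESET["r_bar"],
    sigma: float = FIT_RADIUS_PRESET["sigma"],
    f: float = DEFAULT_RECONSTITUTABLE_FRACTION,
    variant: str = "gaussian",
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
    n_bootstrap: int = 0,
    random_state: int = 0,
) -> FitResult:
    """Fit the occupancy model to titration points (clipped points included,
    but counted on the result)."""
    if not points:
        raise InvalidParameterError("no titration points")
    ppr_star = np.array([p.ppr_star for p in points])
    P = np.array([p.P for p in points])
    est = OccupancyModel(
        r_bar=r_bar,
        sigma=sigma,
        f_reconstitutable=f,
        area_per_lipid=area_per_lipid,
        variant=variant,
        n_bootstrap=n_bootstrap,
        random_state=random_state,
    ).fit(ppr_star, P)
    res = est.result()
    res.clipped_points = sum(p.clipped for p in points)
    return res


def derive_mass(fit: FitResult, area_per_lipid: float = DEFAULT_AREA_PER_LIPID) -> FunctionalMass:
    """Functional molar mass from a fitted alpha: M = 16*pi / (A * alpha),
    with the delta-method SE (exact for the inverse map)."""
    if not fit.alpha_hat > 0:
        raise InvalidParameterError("fit has non-positive alpha")
    return alpha_to_mass(fit.alpha_hat, area_per_lipid, fit.alpha_se)
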