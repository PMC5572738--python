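# Methods

## The occupancy model

A reconstitution distributes protein over preformed vesicles. If insertion
events are independent and the protein mass captured by a vesicle is
proportional to its lipid content (~r^2 for a thin shell), the number of
functional scramblase units in a vesicle of radius r is Poisson with mean

    lambda(r) = (alpha / 2) * PPR* * r^2 .

The factor alpha absorbs the geometry: with 8*pi*r^2/A lipids per vesicle
(two leaflets of equal area, A nm^2 per lipid) and a functional unit of
molar mass M, a vesicle at corrected protein load PPR* (g protein per mol
lipid, shared over the reconstitutable pool only) expects
PPR* * (8*pi*r^2/A) / M units, so alpha = 16*pi / (A*M). This is the only
place the molar mass enters, which is what makes the titration a scale:
fit alpha, invert for M. The uncertainty propagates exactly under the
inverse map, M_se/M = alpha_se/alpha.

Averaging P(r) = 1 - exp(-lambda(r)) over a Gaussian radius distribution
N(r_bar, sigma) has the closed form implemented in
`occupancy.prob_occupied_gaussian`:

    P = 1 - (1 + s)^(-1/2) * exp(-(r_bar^2 PPR* alpha / 2) / (1 + s)),
    s = sigma^2 * alpha * PPR* .

Two analytical notes:

- **Sign of the exponent.** Completing the square in the Gaussian integral
  yields a *negative* exponent; a positive exponent would give P > 1 for
  any PPR* > 0. The implementation uses the negative form, which is the
  exact untruncated-Gaussian average of the fixed-radius model (verified
  against numerical quadrature to ~1e-9 in the tests).
- **Truncation.** Radii are physically positive; the simulators resample
  non-positive Gaussian draws, while the closed form integrates over the
  whole real line. For the measured sigma/r_bar ~ 0.31-0.33 the mass below
  zero is ~1e-3 of a percent and the discrepancy is far below measurement
  noise. The tests bound it empirically: < 5e-4 absolute for
  sigma <= 0.3 r_bar, < 5e-3 up to sigma = 0.4 r_bar. The closed form
  should not be pushed past sigma ~ 0.4 r_bar.

### Units

alpha is stored in mol g^-1 nm^-2: sigma^2 (nm^2) * alpha * PPR*
(g/mol) must be dimensionless, and r_bar^2 * PPR* * alpha likewise.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| area per lipid A | 0.70 | nm^2 | typical for fluid POPC/POPG bilayers; reproduces both the ~3.5e5 lipids/vesicle count and a trimer-scale mass from the reference fit constant |
| bilayer thickness d | 4.0 | nm | inner-leaflet radius offset for lipid counting; the mass conversion uses the equal-leaflet convention (d = 0), matching the model derivation |
| r_bar, sigma (fit preset) | 100.8, 32.8 | nm | the pair that parameterizes the occupancy fit |
| r_bar, sigma (DLS preset) | 100.6, 31.5 | nm | the pair measured by DLS; both presets are exposed because the two measurements differ slightly |
| f_reconstitutable | 0.524 | — | fraction of vesicles competent for insertion; fixed, not co-fitted |
| k_red | ln 2 / 15.2 | s^-1 | anchored to the measured reduction half-life |
| F0, Fmax | 43.0, 76.2 | % | measured protein-free and saturating endpoints |

r_bar and sigma are treated as fixed, externally measured inputs to the
occupancy fit (DLS first, then fit), not co-estimated; co-fitting three
parameters to a single saturating curve is badly conditioned.

## Fitting choices

- **Occupancy fit.** Single-parameter nonlinear least squares
  (`scipy.optimize.curve_fit`, trust-region-reflective with
  alpha in (1e-8, 1)), unweighted on P by default with optional per-point
  weights. Initialization inverts the fixed-radius model at the smallest
  informative point, alpha_0 = -2 ln(1-P) / (PPR* r_bar^2). The standard
  error is Jacobian-based with residual-variance scaling; a nonparametric
  bootstrap over points (default off, 1000 reps suggested) is available as
  a cross-check and agrees within a factor of ~2 on well-conditioned data.
  Identifiability guards: >= 3 distinct PPR* values and at least one point
  with P > 0.2 (an all-toe dataset cannot separate alpha from noise).
  Points clipped into [0, 1] by the endpoint transform are kept in the fit
  but counted on the result — excluding them would bias the plateau.
- **Endpoint transform.** P = (F - F0)/(Fmax - F0), clipped to [0, 1] with
  a flag. F0 and Fmax are inputs, not fitted.
- **Decay model.** Single exponential with floor,
  F(t) = plateau + dF * exp(-k (t - t0)); minimal model consistent with a
  reagent-limited first-order reduction. The half-life is ln 2 / k, and
  the scrambling bound uses the first-order convention
  rate = (ln 2 / t_half) * lipids per vesicle.
- **Gaussian size fit.** For raw radius samples, the maximum-likelihood
  estimates (sample mean and SD) with standard errors sigma/sqrt(n) and
  sigma/sqrt(2n); for histograms, weighted least squares of a scaled
  Gaussian with Poisson (sqrt-count) weights. An all-equal sample yields
  sigma = 0 with a degenerate-fit flag rather than an error.
- **Purity.** purity = min(1, (A560/A280) / pure_ratio). The pure-sample
  reference ratio defaults to 0.5, the peak-height convention under which
  A560/A280 = 0.6/1.22 reads 98%; the extinction-coefficient ratio
  54/66 ~ 0.82 is exposed as `PURE_RATIO_EPSILON` for users who prefer a
  spectroscopic reference. The two conventions disagree and cannot both be
  derived from the stated coefficients; the peak-height convention is the
  default because it matches the reported purity.
- **pH readout.** Pyranine fluorescence is linear in intravesicular pH over
  the assay range, so the calibration is an OLS line and the trace
  conversion its inverse; the 20-min value is a nearest-sample lookup
  (traces are sampled at ~1 s, so interpolation would change nothing).

## What the simulators emulate — and what they do not

- **Radii** are Gaussian with resampling of non-positive draws.
- **Occupancy** follows the model exactly: a vesicle is refractory with
  probability 1 - f; otherwise its count is Poisson(lambda(r)) at PPR*.
  Large-population occupied fractions converge to the closed form (tested
  within 3 binomial standard errors).
- **Dithionite traces** are lipid-weighted sums of per-vesicle signals.
  The reducible fraction is F0_target/100 for scramblase-free vesicles and
  Fmax_target/100 for occupied ones, decaying with a single rate k_red;
  the remainder of each vesicle's signal is inert, so the inner-leaflet
  pool of scramblase-free vesicles is conserved for all time — the assay's
  central topological assumption. The endpoint non-idealities (43% < 50%,
  76.2% < 100%) are applied *per vesicle class* as phenomenological
  targets: no mechanism is modelled (candidate explanations, such as early
  detergent removal, are not distinguishable from endpoint data), and with
  f = 0.524 a population-level calibration could not reach 76.2% at all
  (0.524 * 100% + 0.476 * 43% = 72.9%). Scrambling inside an occupied
  vesicle is treated as infinitely fast relative to reduction, so all
  occupied vesicles share one rate; slow scramblases would break this.
- **Titration series** are drawn from the closed-form P with additive
  Gaussian noise on P (default sd 0.02, clipped to [0, 1] and flagged),
  then mapped to endpoints by the inverse of the P transform. Noise on P
  rather than on raw fluorescence is a simplification; it matches how the
  fit residuals are defined.
- **Pump traces**: intravesicular pH relaxes exponentially toward an
  asymptote at rate k_pump while the light is on and holds in the dark
  (no proton leak on the assay timescale), under a 20 s on / 20 s off
  schedule for 20 min. The three presets (no protein; pump; pump +
  valinomycin, where the ionophore removes the opposing membrane
  potential) were calibrated once so their 20-min pH matches the measured
  values 7.57 / 6.90 / 6.45. Proton electrochemistry is parametric, not
  mechanistic.
- **Noise** is additive Gaussian on the normalized signal (default 0.5% of
  the initial signal for traces); photobleaching/drift defaults to 0 and
  is exposed for robustness tests. No sampling-rate jitter, no baseline
  steps, no stirring artefacts.

Passing tests therefore demonstrate correctness of the *analysis* under
the model's own assumptions (exact round trips, statistical calibration,
invariant conservation); they do not validate the model against real
traces, which contain non-idealities the generators deliberately omit.

## Problem sizes

Statistical tests use the population sizes at which their expected
fluctuations make the checks sharp: 1e4 radii for size-distribution
recovery (SEs ~0.3 nm), 1e5 vesicles for occupancy-fraction convergence
(binomial SE ~1.5e-3), 100 seeded replicates of 20-point titrations for
fit-constant recovery (SE of the mean ~0.3%), 50-60 replicates for
mass-recovery coverage. The acceptance script uses the same sizes.

## Known limitations

- The closed form ignores radius truncation (quantified above) and assumes
  a single homogeneous functional species; mixtures of oligomeric states
  are out of scope.
- F0 and Fmax are inputs; their measurement uncertainty is not propagated
  into alpha.
- The refractory fraction f is fixed, not identifiable from a single
  titration; an incorrect f rescales PPR* and hence alpha linearly.
- The decay fit assumes the reduction is single-exponential; biphasic
  traces (e.g. leaky vesicles) will converge but report a misleading rate,
  flagged only indirectly through the residual RMS.
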