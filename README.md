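# scramfit

Quantitative analysis of reconstituted phospholipid-scramblase assays.

When a candidate scramblase is reconstituted into large unilamellar
vesicles carrying a trace of a fluorescent NBD-labelled lipid, adding the
membrane-impermeant reductant dithionite destroys only the fluorophores it
can reach: the outer leaflet (~50% of the signal) in protein-free vesicles,
the entire pool in vesicles that carry at least one functional scramblase.
Titrating the protein-to-phospholipid ratio (PPR, g protein / mol lipid)
and reading the endpoint fluorescence reduction therefore measures the
*fraction of vesicles that received a functional unit* — and, through
Poisson statistics, weighs that unit. `scramfit` implements this analysis
end to end, together with seeded simulators for every input it consumes,
single-exponential reduction kinetics (which bound the scrambling rate from
below), and the pyranine fluorescence-to-pH conversion used to verify
light-driven proton pumping in the same preparations.

## The model

Endpoint reductions F are mapped to occupancy probabilities with the
affine transform

    P(>=1 scramblase) = (F - F0) / (Fmax - F0)

where F0 (~43%) is the protein-free endpoint and Fmax (~76%) the endpoint
at saturating protein. The number of functional units landing in a vesicle
of radius r is Poisson with mean lambda(r) = (alpha/2) PPR* r^2, where
PPR* = PPR / f corrects for the fraction 1 - f of vesicles refractory to
reconstitution (f = 0.524 by default). Averaging 1 - exp(-lambda(r)) over
the Gaussian radius distribution N(r_bar, sigma) measured by dynamic light
scattering gives the closed form

    P = 1 - (1 + sigma^2 alpha PPR*)^(-1/2)
          * exp( - (r_bar^2 PPR* alpha / 2) / (1 + sigma^2 alpha PPR*) )

with a single free constant alpha (mol g^-1 nm^-2). A nonlinear
least-squares fit of this curve to the titration yields alpha, and the
molar mass of the functional unit follows from the vesicle geometry:

    M = 16 pi / (A alpha)

with A the area per phospholipid (0.70 nm^2 for POPC/POPG). Because
scrambling outpaces dithionite reduction, the reduction half-life t_half
bounds the per-unit scrambling rate from below:
rate >= (ln 2 / t_half) * (lipids per vesicle).

## Worked example

```python
import numpy as np
import scramfit as sf

# 1. vesicle size from synthetic DLS
samples, edges, counts = sf.simulate_dls(10_000, r_bar=100.6, sigma=31.5, seed=11)
size = sf.fit_gaussian_radii(samples=samples)

# 2. a simulated titration of the scramblase assay
ppr = np.linspace(0.05, 2.0, 20) * 0.524
points = sf.generate_ppr_series(ppr, M_true=80_800.0, r_bar=100.8, sigma=32.8,
                                noise_sd=0.02, seed=12)
fit = sf.fit_occupancy_model(points, r_bar=100.8, sigma=32.8)

# 3. scrambling-rate lower bound from reduction kinetics
n_lipids = sf.lipids_per_vesicle(sf.VesicleGeometry(100.6))
rate = sf.scrambling_rate_lower_bound(15.2, n_lipids)
```

prints (formatted):

```
DLS fit: r_bar = 101.1 +/- 0.32 nm, sigma = 31.5 +/- 0.22 nm
occupancy fit: alpha = 9.163e-04 +/- 2.63e-05 mol/g/nm^2
functional mass: M = 78,369 +/- 2,246 g/mol
lipids per vesicle: 3.49e+05; scrambling rate > 15,924 lipids/s
```

The titration was generated from a "true" functional mass of 80,800 g/mol
(a bacteriorhodopsin trimer) with 2% noise on P; the fit recovers it within
its reported uncertainty. A ~3.5e5-lipid vesicle whose accessible pool is
reduced with a 15.2 s half-life implies a scrambling rate above ~1.6e4
lipids per second per functional unit.

The same pipeline is scriptable from the shell: `scramfit simulate`
generates seeded fixtures (dithionite traces, DLS samples, pump traces,
titrations), `scramfit analyze` extracts scalar readouts, `scramfit fit`
solves the inverse problems, and `scramfit pipeline titration.csv dls.csv`
runs DLS fit → P transform → occupancy fit → mass in one step, writing a
JSON report and a reproducibility manifest.

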