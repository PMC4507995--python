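# ocufit

Fluorescence lifetime analysis for ophthalmic time-resolved autofluorescence
data (FLIO) and, more generally, TCSPC-based FLIM.

Fluorescence lifetime imaging ophthalmoscopy records, for every pixel of a
fundus image, a histogram of photon arrival times after a pulsed laser
excitation.  The decay of that histogram carries the fluorescence lifetimes
of the endogenous fluorophores of the retina — information that changes with
metabolic state before morphological damage appears.  Extracting it is a
chain of non-trivial steps: clinical scans carry only ~1,000–10,000 photons
per pixel while reliable multi-exponential fitting needs 100,000–400,000;
the crystalline lens contaminates the signal; reflections in the optical
path corrupt parts of the histogram; and lifetimes must finally be compared
across patient groups.  `ocufit` implements this full chain as a tested
Python library with a thin command-line interface, and ships a simulator
that generates synthetic TCSPC cubes with known ground truth.

## Models

The measured pixel histogram I(t) is modelled as the convolution of the
instrument response function (IRF) with a sum of decay components, plus a
constant background *b*:

- **multi-exponential** — I(t) = IRF ∗ Σᵢ αᵢ e^(−t/τᵢ) + b (1–3 components)
- **stretched exponential** — Kohlrausch kernel e^(−(t/τ)^β), β ∈ (0, 1]
- **spectral global analysis** — one model per spectral channel with selected
  lifetimes tied across channels
- **layered** — per-component time shifts tcᵢ accounting for the axially
  layered structure of the eye
- **lens-corrected** — adds α_lens · I_lens(t − tc_lens), a scaled and
  time-shifted separately measured crystalline-lens decay; the geometric
  lens–retina delay is tc = 2·d·n/c (202.3 ps for the schematic eye)
- **incomplete decay** — when τ is not ≪ the 12.5 ns repetition period,
  the model is folded numerically: I(t) + Σ_q I(t + q·t_R)

Fitting minimizes the reduced chi-square χ²ᵣ = Σⱼ (I_M − I_C)²/w / (m − p)
with Neyman (w = I_M) or Pearson (w = I_C) weighting.  Amplitudes, lens
amplitude and background are linear in the model and solved by weighted
non-negative least squares inside every evaluation (variable projection);
lifetimes, shifts and β are found in two stages — differential evolution on
the image-integrated decay, then bound-constrained Nelder-Mead per pixel.
Reflection artifacts are detected on the integrated decay and excluded from
all figures of merit; a sliding-window pass re-fits outlier pixels from
their best-fitting neighbour.

Before fitting, **adaptive binning** grows a circular window around each
pixel shell-by-shell until a photon threshold is met, guaranteeing the
photon count at the highest spatial resolution the data allow (classic
static square binning is available too).  After fitting, maps can be
filtered spatially, summarized over the nine ETDRS macular subfields, and
two groups of subjects can be compared class-by-class with exact Wilcoxon
rank-sum tests under a Bonferroni/Holm multiplicity threshold th = s/nC,
followed by ROC/AUC analysis with a Youden-optimal cut-off.

## Worked example

```python
import numpy as np
from ocufit import (TimeAxis, gaussian_irf, uniform_truth, simulate_cube,
                    adaptive_bin, fit_image)
from ocufit.fitting import FitConfig
from ocufit.models import ModelSpec

time = TimeAxis(n_channels=256, channel_width_ps=48.8, rep_period_ns=12.5)
irf = gaussian_irf(time, fwhm_ps=172.0, t0_ps=1000.0)
truth = uniform_truth((16, 16), time, irf, tau_ps=(500.0, 2500.0),
                      alpha=(0.6, 0.4), n_photons=2000, seed=1)
cube = simulate_cube(truth)
print(f"simulated {cube.total_photons()} photons over 16x16 pixels")

binned = adaptive_bin(cube, threshold=100_000)
print(f"adaptive binning radii: {binned.radius.min():.1f}-{binned.radius.max():.1f} px, "
      f"min photons/pixel {binned.cube.intensity().min()}")

res = fit_image(binned.cube, ModelSpec("multiexp", 2),
                FitConfig(seed=1, de_maxiter=40), irf)
print(f"median tau1 = {np.median(res['tau1']):.0f} ps (truth 500)")
print(f"median tau2 = {np.median(res['tau2']):.0f} ps (truth 2500)")
print(f"median tau_m = {np.median(res['tau_m']):.0f} ps, "
      f"median chi2_r = {np.median(res['chi2']):.2f}")
```

Output:

```
simulated 511863 photons over 16x16 pixels
adaptive binning radii: 4.1-7.3 px, min photons/pixel 100004
median tau1 = 487 ps (truth 500)
median tau2 = 2472 ps (truth 2500)
median tau_m = 1288 ps, median chi2_r = 1.01
```

The raw cube carries ~2,000 photons per pixel — far too few for a
two-exponential fit.  Adaptive binning collects at least 100,000 photons
per pixel (growing to radius 7.3 px in darker corners), after which both
lifetimes are recovered within a few percent and the reduced chi-square
sits at 1, as expected for pure Poisson noise.  `tau_m` is the
amplitude-weighted mean lifetime, the usual clinical overview parameter.

The same pipeline is available from the shell:

```bash
ocufit simulate --config sim.yaml --seed 3 --out cube.h5
ocufit bin --input cube.h5 --mode adaptive --threshold 100000 --out binned.h5
ocufit fit --config fit.yaml --seed 3 --out results/
ocufit roi --map results/tau1.tiff --grid-center 128,128 --pitch-um 34 --out roi.csv
ocufit compare --config study.yaml --param tau1 --class-width 5 --out cmp/
```

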