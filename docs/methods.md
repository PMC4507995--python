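# Methods

This note documents the models, algorithms and design choices behind
`ocufit`, in the spirit of a methods appendix: what is computed, under which
assumptions, with which defaults, and where the genuinely open decisions
were made.

## Data model and discretization

A TCSPC measurement is a cube of non-negative integer photon counts indexed
(row, col, time channel).  The time axis is defined by the channel width Δt
(ps) and the laser repetition period t_R (ns); the default configuration is
1024 channels of 12.2 ps spanning t_R = 12.5 ns (an 80 MHz source).  Time
channel j covers [j·Δt, (j+1)·Δt) and model curves are evaluated at channel
centers.  All lifetimes and shifts are picoseconds internally; conversions
happen only at I/O boundaries.  The native container is a single HDF5 file
(`/ch{k}/counts` plus acquisition attributes); multi-page float TIFF with a
JSON sidecar and a per-pixel CSV toy format are also read.  Loaders validate
invariants and raise typed errors rather than clamping silently.

## Decay models

All models share the structure "IRF-convolved decay sum + background".  The
IRF is normalized to unit sum before convolution so the fitted amplitudes
keep their photon-count meaning, and convolution is the discrete linear
convolution on the channel grid, truncated to the measurement window.
Sub-channel time shifts are applied by linear interpolation; samples shifted
in from before t = 0 are zero except under incomplete-decay folding.

**Stretching.** The stretched kinds use a single stretching exponent β
shared by all components (the per-component generalization is not
identifiable at clinical photon counts); β can be pinned (e.g. β = 1 turns
the lens-corrected model into plain exponentials, the configuration used in
clinical practice).

**Lens correction.** The crystalline-lens decay is a *measured* curve and
therefore already IRF-broadened.  It is added after the convolution of the
retinal part, even though a literal reading of the model formula would
place it inside the convolution — convolving it again would broaden it
twice.  This is a deliberate physical choice and the only place where the
implementation departs from the printed notation.

**Incomplete decay.** Long-lived fluorophores leave residual signal from
preceding pulses.  The model is folded numerically: the curve is evaluated
on an extended grid of (j+1)·m channels and the copies at t + q·t_R
(q = 1..j) are summed, with linear interpolation when t_R is not an integer
number of channels.  Because excitation is periodic this also fills the
pre-excitation channels, which an analytic tail correction would not.
j = 1 suffices for lifetimes up to ~5 ns at t_R = 12.5 ns; the folding is
applied to the convolved decay sum only — the lens term and the background
are physical signals counted once, not model components to be replicated
(folding the constant background j+1 times would simply rescale it).

## Fitting

The figure of merit is the reduced chi-square over the fitted channels.
Weighting is Neyman (w = measured counts, floored at 1 so empty channels do
not divide by zero) or Pearson (w = model counts, floored at 1e-10 and
recomputed when the model changes; implemented as one re-weighting pass per
objective evaluation).

**Variable projection.**  Amplitudes, lens amplitude and background enter
the model linearly and are solved by weighted non-negative least squares
(active-set NNLS on the row-scaled design) inside every evaluation of the
nonlinear objective.  Only lifetimes, time shifts, β and the lens shift are
left to the nonlinear minimizers, which shrinks the search space from ~8 to
2–5 dimensions for typical configurations.

**Two stages.**  A stochastic differential-evolution fit of the
image-integrated decay (the histogram with the best possible SNR) estimates
a global starting point once per image; every pixel is then fitted with
bound-constrained Nelder-Mead from that start.  Bounds are enforced by
clipping (projection).  Defaults: lifetimes in [10, 8000] ps, shifts in
[−600, 600] ps, β in [0.05, 1]; population 15, ≤100 generations for the
stochastic stage; ≤600 simplex iterations per pixel.  Both stages are
deterministic given the seed.  For models without per-component shifts the
fitted components are sorted by ascending lifetime so map labels are
consistent across pixels.

**Fit interval.**  Models without time shifts fit only the decay (channels
from the smoothed histogram peak onward); the layered and lens-corrected
models fit the full signal including the pre-excitation interval and rising
edge.  Optionally the background can be fixed to the mean of the
pre-excitation channels instead of being fitted.

**Neighborhood objective (optional).**  The figure of merit can be extended
to (χ²ᵣ of the center)² + mean of the adjacent pixels' χ²ᵣ evaluated with
the center's parameters, which regularizes spatially.  The asymmetry
(center squared, neighbors not) is kept exactly as defined.

## Artifacts and outliers

**Reflections** re-inject delayed photons and appear as a rising section in
the otherwise monotone decay.  Because their position in time is the same
for all pixels, detection runs once on the image-integrated decay: the
gradient of a 5-channel moving average is scanned after the global peak for
runs of ≥ 2 consecutive positive gradients; start and peak are then refined
on the raw curve (preceding local minimum / local maximum), and the masked
interval is [start, start + 3·(peak − start)) — the artifact's decay is
taken as three times its rise, a rule calibrated for FLIO-scale decays.
Masked channels are excluded from every figure of merit but never alter the
model curve.  The smoothing width and run length are implementation
constants chosen for stability on noisy integrated decays.

**Outliers.**  After the image fit, a sliding window (default 7×7) moves
over the lifetime maps and the χ²ᵣ map; a pixel whose value deviates from
the window median by more than a relative threshold (default 30%) in any
inspected map is re-fitted, initialized from the window's best-χ²ᵣ pixel,
and the re-fit is kept only if the figure of merit strictly improves — so
outlier treatment can never worsen a pixel.  Amplitude maps are not
inspected by default (they scale with local intensity and would flag
legitimate structure).  One iteration is the default; more can be
configured.

## Binning

Static binning sums the (2f+1)×(2f+1) square window around each pixel,
clipped at the image border.  Adaptive binning grows a circular window
shell-by-shell — the candidate radii are the sorted distinct Euclidean
norms of integer lattice offsets (0, 1, √2, 2, √5, …) — and stops at the
first shell where the enclosed photons reach the threshold; excess photons
of that shell are kept.  Disk membership is center-to-center distance ≤ r
(closed disk), which makes the window exactly invariant under 90°
rotations.  Pixels that cannot reach the threshold within the radius cap
are capped and flagged, with a logged warning.  Binned histograms are raw
sums, not averages.

## Simulator

The simulator is the package's ground-truth instrument.  Per pixel it
evaluates the chosen decay model (IRF convolution, optional lens term,
optional folding), scales the decay part to the target photon number, adds
the constant background rate and draws independent Poisson counts per
channel — the counting statistics of TCSPC detection.  Defaults emulate
clinical fundus acquisitions: 1024 × 12.2 ps channels over 12.5 ns, 1,000
photons per raw pixel, a Gaussian IRF of 172 ps FWHM centred 1 ns into the
window, lifetimes 500/2500 ps with amplitude ratio 0.6/0.4, and a synthetic
biexponential lens curve.  Randomness uses numpy's PCG64 generator;
per-subject streams in group studies are spawned from the master seed via
`SeedSequence`, so studies are reproducible bit-for-bit.

Deliberately not modelled: detector afterpulsing and dead time, IRF drift,
spatially correlated noise, eye-movement registration artifacts, and the
inter-pixel correlation that real adaptive binning introduces when windows
overlap heterogeneous tissue.  Passing tests therefore demonstrate
correctness of the estimator chain under ideal counting statistics, not
robustness to every instrumental effect of in-vivo data.

Two-group studies for the statistics layer are generated directly at the
parameter-map level: subject-level Gaussian variability (default SD 25 ps)
plus pixel-level noise (default SD 50 ps) around population lifetimes, with
the group effect added to one component.  This isolates the statistical
pipeline from fit noise and keeps null simulations cheap.

## ROI statistics and group comparison

The ETDRS grid places three concentric circles of 500/1500/3000 μm radius
at the fovea and splits the two rings with the 45° diagonals into superior,
inferior, nasal and temporal quadrants (nine subfields).  Circle boundaries
are closed inward; a pixel exactly on a diagonal joins the
counter-clockwise sector.  For a right eye in standard orientation nasal is
image-left; the mapping flips for the left eye and is configurable, since
image orientation is an acquisition convention.  Subfield statistics
(mean, median, binned mode, SD, variance, confidence interval) are computed
over finite masked pixels; the CI is normal-theory by default with a
percentile bootstrap option.  Histogram classes are left-closed and aligned
to multiples of the class width starting at zero.

Group comparison reduces each subject's ROI values to a normalized
histogram and tests, per class, the subjects' class frequencies between
groups with a two-sided Wilcoxon rank-sum test.  The unit of analysis is
the subject, not the pixel — pooling pixels would pseudo-replicate within-
subject correlation.  The test is exact (full enumeration over rank
assignments, midranks for ties, cached per sample size) for total n ≤ 20
and a tie-corrected normal approximation beyond.  The multiplicity
threshold is th = s/nC with nC the number of classes observed in at least
one subject; this plain Bonferroni bound is the default, with the
(uniformly at least as powerful) Holm step-down available — the two differ
in name more than in practice here, and both are exposed because the
stricter bound is the one defined by the threshold formula while the
step-down matches the procedure's usual name.  ROC analysis over a
significant class tries both classification directions, keeps the better
AUC (trapezoidal, equal to the Mann-Whitney U statistic over n₁n₂ with
ties counted ½) and selects the cut-off maximizing Youden's J.

## Problem sizes and numerical checks

The test suite and the acceptance script run on reduced problem sizes
chosen to exercise every code path at full fidelity: 256-channel axes
(48.8 ps — same span, coarser sampling) for fitting tests, 16×16 images for
recovery and binning-oracle checks, 200 replicates for the null
family-wise-error simulation, and a 1000 × 12.5 ps axis for the
incomplete-decay geometric-series identity, where t_R is an exact number of
channels and the identity holds to machine precision (on the clinical
12.2 ps grid t_R falls between channels and linear interpolation limits the
agreement to ~5·10⁻⁶).  Lifetime recovery uses 10⁵ photons per pixel, the
established regime for reliable two/three-component fits.  Key oracles are
independent of the implementation: brute-force window/disk summation for
binning, enumeration of rank assignments for the exact test, pair counting
for AUC, dense grid search for the non-negative amplitude solve, and
closed-form exponential identities for the models.

## Known limitations

- The Nelder-Mead stage is a local refiner; with heavily overlapping
  lifetimes or < 10⁴ photons it can settle on degenerate splits (the
  outlier pass catches isolated cases, not systematic ones).
- Pearson weighting uses one re-weighting pass per evaluation rather than
  iterating to a fixed point.
- Reflection detection assumes artifacts occur after the main fluorescence
  peak and decay faster than three times their rise; overlapping artifacts
  merge into one interval.
- The exact rank-sum enumeration is limited to total n ≤ 20 (C(20,10) ≈
  1.8·10⁵ assignments, cached); larger studies use the asymptotic test.
- No reader for vendor binary formats; data enter via HDF5, TIFF or CSV.
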