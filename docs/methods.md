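# Methods

This note documents the models, numerical choices, and limitations behind
`ewdrs`. It is the design record for maintainers; the README covers usage.

## Scope and purpose

The package is a model-based characterization platform for fiber-optic
extended-wavelength diffuse reflectance spectroscopy (EWDRS): joint
VIS/NIR (500-1000 nm) and SWIR (1000-1500 nm) acquisition through a
seven-fiber contact probe. It provides (i) a Monte Carlo transport engine
that simulates what the probe measures over layered and heterogeneous
tissue volumes, (ii) the dual-band preprocessing chain used on measured
spectra, (iii) agreement statistics between simulated and measured
spectra, (iv) diagnostic peak ratios, and (v) a sparse multinomial
logistic regression (SMLR) classifier. Because no measured spectra or
tabulated optical properties ship with the package, a synthetic-data
module fabricates the full study: phantom and tissue stand-ins, raw
measurement triplets, and labeled datasets with repeat noise.

## Spectral preprocessing

Raw dual-band measurements are referenced against a shuttered background
`Bg` and a white-standard measurement `Mstd`:

    S_ref(l) = (M_raw(l) - Bg(l)) / (M_std(l) - Bg(l)).

Because the standard is used in contact geometry, referenced intensities
are in arbitrary units and may exceed 1; no upper bound is enforced.
SWIR spectra are smoothed with a Savitzky-Golay filter (order 2, frame
41). Interior points use the standard SG convolution
(`scipy.signal.savgol_coeffs`); the first and last 20 points refit the
same-order polynomial on the truncated window rather than padding, so no
data are fabricated beyond the spectrum ends and polynomials up to the
filter order are reproduced exactly everywhere.

The two spectrometer bands are joined at 1000 nm by the scalar matching
factor `M = I_visnir(1000) / I_swir(1000)` (linear interpolation at
non-grid match points). The SWIR band is multiplied by `M` and the
VIS/NIR band kept unscaled, preserving the VIS/NIR referencing; VIS/NIR
points at or above the match point and SWIR points below it are dropped
so the merged grid is single-valued. The junction discontinuity is zero
by construction (relative tolerance 1e-12).

## Optical properties

Materials carry absorption `mu_a(l)` and reduced scattering `mu_s'(l)`
(mm^-1) on a 1-nm master grid over 500-1500 nm, with scalar anisotropy
g = 0.9 and refractive index n = 1.34 by default. Reduced scattering is
condensed to a first-order exponential decay
`mu_s'(l) = a*exp(-l/b) + c`, fit by nonlinear least squares
(`scipy.optimize.least_squares`, bounds a,c >= 0, b > 0) initialized
from a log-linear regression of `mu_s' - min` on wavelength; constant
input degenerates to the `a -> 0` branch with `c` the sample mean.
Absorption spectra are SG-smoothed (order 2, window 41 — the window
mirrors the preprocessing default since only the order is prescribed)
and clamped at zero. The full scattering coefficient used in transport
is `mu_s = mu_s' / (1 - g)`.

Synthetic absorption is a non-negative linear combination of
unit-maximum Gaussian-mixture basis shapes: lipid (1210-nm main band,
1180-nm shoulder, weak 1390-nm overtone), water (970 nm weak, 1450 nm
dominant with a red tail), a heme-dye stand-in (single 630-nm band), a
blood doublet (575/610 nm plus a 545-nm component), and a spectrally
flat baseline. The baseline (0.02-0.035 mm^-1 in the presets) represents
the residual absorption floor of gelatin matrices and tissue between the
named bands; a literally zero floor would be unphysical and makes
transport in the photon-dense NIR window needlessly pathological. These
shapes are engineered stand-ins carrying the diagnostically relevant
feature wavelengths, not measured extinction spectra.

Preset chromophore weights and decay parameters were fixed once so that
qualitative orderings hold (nerve-mimicking layer lipid-rich with no
blood pigment; muscle-mimicking layer heme-dye at 630 nm with trace
lipid; nerve/skin/connective tissue classes sharing VIS features but
differing in SWIR lipid; `mu_s'(500)` between 2.5 and 3.6 mm^-1 decaying
to about 1 mm^-1 at 1500 nm). No quantitative fidelity to any specimen
is claimed.

## Tissue models

Coordinates: surface plane z = 0, tissue at z >= 0, probe axis along z.
Layered models are laterally infinite stacks with half-open depth
intervals `[top, bottom)` (an interface depth belongs to the lower
layer). The two-layer builder places a 1-3-mm nerve-mimicking layer over
a 40-mm muscle-mimicking layer. Voxel models use a uniform cubic grid
(default edge 0.1 mm, 20 x 20 mm lateral extent) with lateral and bottom
lookups clamped to the nearest edge voxel, extending the boundary
material outward; a builder refuses voxel edges larger than half the
thinnest feature. The nerve-plexus builder buries a 2-mm-thick network -
three parallel 2-mm trunks 3 mm apart crossed by two 1-mm branches -
under a configurable muscle cover (0.2-2 mm studied). Only the 2-mm
network thickness is anatomically pinned; the lateral geometry is a
plausible pelvic-plexus stand-in and fully configurable.

## Monte Carlo transport

Weighted (implicit-capture) photon packets: free paths drawn from the
local `mu_t = mu_a + mu_s`, a fraction `mu_a/mu_t` of the packet weight
deposited at each interaction, Henyey-Greenstein deflections sampled by
inverse CDF, azimuth uniform. Boundaries evaluate unpolarized Fresnel
coefficients with one stochastic reflect/transmit decision; matched
indices transmit deterministically without consuming a random number, so
a two-layer model with identical materials is bit-identical to the
homogeneous model (adjacent layers that are optically identical at the
simulated wavelength are also merged before transport). Layered models
use exact analytic interface crossing with MCML-style banking of unused
optical depth; voxel volumes use face-to-face traversal with the same
physics and no internal Fresnel step (a uniform tissue index across
voxel materials is enforced - the only mismatch is the top surface
against air, n = 1.0).

Launch: position uniform over the 0.3-mm source core; direction uniform
in solid angle within the NA cone (NA 0.39) in air, Fresnel-attenuated
(booked as specular) and refracted into the tissue. Detection: a packet
exiting the top surface inside one of six detector cores (hexagon ring,
centre spacing 0.66 mm = 0.6-mm core plus a nominal 60-um buffer; the
physical probe's spacing is unpublished) with its refracted air-side
direction inside `arcsin(NA)` is tallied to that fiber; sums of squared
detected weights per fiber provide Monte Carlo standard errors. All
escaping diffuse weight is also histogrammed over exit radius (0.1-mm
annuli) for comparison with diffusion theory.

Termination: Russian roulette below weight 1e-4 with survival 0.1.  Two
further guards handle (near-)conservative media, where weights never
decay:

* In a strictly non-absorbing medium with no transmission path
  (semi-infinite stack or clamped voxel volume) every packet escapes
  through the top with probability one, so packets exceeding a 30k-event
  cap are booked directly to diffuse reflectance. Total reflectance is
  then exact; only the unrecorded exit radius of roughly 1% of packets
  is approximated, and those exits lie centimetres from the probe.
* Otherwise an unbiased age roulette engages after 30k scattering events
  (survival 0.995 per event, killed and gained weight booked to the
  roulette ledger). It is a safety valve; ordinary tissue absorptions
  terminate packets by weight roulette long before it triggers.

Every kill/gain is booked, so the ledger `specular + diffuse +
transmitted + absorbed + roulette + lost = 1` closes to machine
precision on every run (asserted to 1e-6 in tests).

Randomness is a counter-based splitmix64 stream: each (seed, wavelength
index, photon index) triple owns an independent substream, making any
result a pure function of its configuration and bit-reproducible. The
kernels are numba-compiled; `fastmath` is enabled, which is
deterministic for a fixed build.

Default sweep settings are 500-1500 nm at 10-nm steps and 1e5 photons
per wavelength. The validation studies probe each statistic at the
wavelengths that define it rather than sweeping full grids: the
two-layer ratio trends use their four defining wavelengths at 6e5
photons and the 630-nm dip its three wavelengths at 1e6 (budgets at
which the near-saturated 2-to-3-mm trend steps are resolved above
Monte Carlo noise); the plexus depth study uses a 40-nm grid at 2e4
photons per wavelength; the classifier study uses 17 diagnostic
wavelengths at 4e3 photons (VIS/NIR) and 16x that in the SWIR. These
sizes are the package's standard study conditions, chosen once as the
smallest at which each directional result is statistically resolved.

## Diffusion oracle

The independent cross-check for the engine is the steady-state
diffusion dipole for a semi-infinite medium: isotropic source at
`z0 = 1/(mu_a + mu_s')`, negative image across an extrapolated boundary
at `zb = 2AD`. The emerging reflectance uses the radiance-based hybrid
`R(rho) = C_phi * phi(rho, 0) + C_j * j_z(rho, 0)` with `A`, `C_phi`,
`C_j` computed from exact Fresnel integrals over the escape hemisphere.
The flux-only (Farrell) form misses the Monte Carlo by up to ~20% at
1-3 transport mean free paths from a mismatched boundary; the hybrid
stays within a few percent there, which is why it is the test oracle.
A warning flags use outside `mu_s'/mu_a >= 10`.

## Agreement analysis and peak ratios

Simulated and measured spectra are area-normalized (trapezoid rule on
the nm grid) before comparison. Repeated measurements define a pointwise
mean and sample SD (n-1); the 95% band is mean +/- 1.96 SD. The
difference spectrum is simulation minus measurement mean; out-of-band
points are reported as contiguous wavelength intervals with no mask
smoothing. Peak ratios interpolate linearly: 575/610 nm (blood) and
1210/1270 nm (lipid) for tissue, and a documented 630/700-nm variant for
phantoms whose heme-mimicking dye absorbs at 630 nm rather than at the
blood doublet. Thickness trends are summarized by the sign of the
Spearman rank correlation plus a strict-monotonicity flag.

## SMLR classifier

Multinomial logistic regression with a Laplacian (L1) prior of scale
lambda on standardized features, intercept unpenalized, last class
pinned at zero. Training is cyclic coordinate-wise bound optimization:
the multinomial Hessian is bounded by `(1/2)(1 - 1/M) X^T X` on its
diagonal, giving closed-form soft-threshold row updates; each surrogate
step is monotone, so no step size is needed.

Feature preparation: spectra are band-normalized before fitting
(`band_normalize`): each spectrometer segment of every row is scaled to
unit mean. Dual-spectrometer acquisitions carry an independent
multiplicative gain per band per measurement (the generator's noise
model makes this explicit), and the matching factor propagates the
VIS/NIR gain onto the merged SWIR segment; per-band row scaling removes
that common-mode factor so the classifier responds to line shape. The
z-score standardization of `train_smlr` then operates on the
band-normalized features. Convergence at max weight
change < 1e-6 or 1e4 sweeps (non-convergence sets a flag and warns
rather than raising). Ties in the posterior argmax break toward the
lowest class index. Defaults: z-score standardization and lambda = 0.1.
Evaluation uses leave-one-out cross-validation with standardization
refit per fold; a fold left with a single class predicts that class and
warns. A binary special case of this optimizer is checked in the tests
against scikit-learn's saga L1 solver, which addresses the same
objective with C = 1/lambda.

A caution on LOOCV permutation nulls: on balanced data with permuted
labels, leave-one-out is biased *below* chance (removing a row makes its
own class the fold minority, and a heavily shrunk model votes with the
majority), so null checks assert the absence of above-chance skill
rather than a two-sided chance band.

## Synthetic-data generator

Measurement triplets are built so the referencing identity is exact by
construction: `Bg` a small constant, `Mstd = Bg + L(l)` with a smooth
lamp-like profile `L`, `M_raw = Bg + L * S_true`. Repeat noise is a
scalar gain jitter per repeat (SD 2%) on the raw measurement plus
additive noise per channel (SD 0.5% of the band median); both values are
invented, since repeat counts but not noise magnitudes are available for
the emulated protocol, and they are documented as non-canonical. Each
(noise seed, repeat index) pair owns an independent substream.

Labeled datasets simulate each repeat (default 5 per class) of a
homogeneous half-space with an independent photon substream, then push
it through the full dual-band measurement/preprocessing chain: the
merged truth is split at 1000 nm (the junction wavelength is inserted by
interpolation when a coarse grid misses it), each band measured as a
triplet, referenced, the SWIR band SG-smoothed, and re-merged via the
matching factor. The SG frame of 41 samples is defined on the ~1.3-nm
instrument grid, i.e. a ~53-nm spectral span; on coarser simulation
grids the window shrinks to that span and smoothing is skipped when so
few samples remain that the fit would flatten real line shapes.

Per-band photon budgets mirror the instrument's acquisition times: the
SWIR spectrometer integrates 16x longer than the VIS/NIR one (800 ms vs
50 ms), so the generator default simulates wavelengths above 1000 nm
with 16x the photon budget (``swir_factor``). Without this, equal
budgets give the SWIR band - whose detected fractions are several times
smaller - counting noise far beyond anything a real acquisition shows,
and classifier studies then underrate the SWIR band for a purely
numerical reason. Independent substreams matter: reusing one Monte Carlo
realization for all repeats of a class freezes its counting noise into
a per-class fingerprint that any classifier can key on, making even
bands with no designed class contrast perfectly separable. With
independent streams, MC variance instead plays the role of
repeat-to-repeat (site-to-site) variability, and band comparisons
reflect real chromophore contrast. Consequently, repeats differ even at
zero instrument noise; photon counts per repeat set the effective
repeat noise (about 3-4% per wavelength at 2e4 photons). The phantom campaign is
two one-layer phantoms plus three two-layer stacks (1/2/3-mm top) at
five repeats each = 25 spectra. The tissue campaign uses six classes
with counts nerve 10, NVB 15, skin/muscle/vessel/connective 15 each:
the emulated study reports 85 spectra with margins of 25 (nerve + NVB)
and 60 (other), which does not determine per-class counts; this split
reproduces both margins.

What passing tests on these synthetic data do and do not show: they
validate the transport physics, the preprocessing algebra, trend
directions, and the classifier machinery end to end; they do not
validate quantitative agreement with any real tissue, because the
chromophore shapes, noise model and class geometry are stand-ins.
Real-data features not emulated include wavelength-dependent instrument
throughput (beyond a smooth lamp shape), InGaAs fixed-pattern noise,
probe-pressure effects, and spatial heterogeneity within a class.

## Known limitations

* Voxel transport assumes one refractive index across materials
  (enforced); layered transport supports per-layer indices.
* The plexus lateral geometry is invented; only its 2-mm thickness and
  the cover-depth set are anchored.
* The diffusion oracle is a near-field-corrected approximation, not
  ground truth; agreement is asserted at 15%.
* SMLR hyperparameters (lambda = 0.1 on z-scored features) are package
  defaults, not reconstructions of any published configuration.
* Age roulette adds variance to the diffuse-reflectance ledger entry in
  media with `mu_a/mu_t` below ~3e-4; detector tallies are unaffected in
  practice because the affected packets are far from the probe.
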