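# Methods

This note documents the models, estimators and numerical choices behind
`condtrack`, what the synthetic-data generator does and does not emulate,
and the known limits of each stage.

## Imaging model emulated by the simulator

The tracking simulator emulates high-speed oblique-illumination
single-molecule microscopy of nuclear protein assemblies: single-plane
movies on an oversampled 53 nm pixel grid at 80 Hz (12.5 ms frame
interval), analysed within a 240 x 184 px (12.7 x 9.8 µm) crop where the
laser illumination is effectively uniform (the optional Gaussian
illumination profile falls to 80% of peak at the crop corner).

Each assembly carries an integer number of fluorophores. A fluorophore has

* brightness `b_i ~ Normal(b, cv * b)` counts per frame, fixed for its
  lifetime; defaults `b = 110`, `cv = 15/110`, matching an mScarlet-I
  calibration of 110 +/- 15 counts/molecule;
* an exponential bleach time with per-frame rate `bleach_rate`
  (memoryless, no blinking); a static immature dark fraction can be set via
  `maturation_fraction`;
* a 2D Gaussian PSF of sigma 0.130 µm (~2.5 px), truncated at 4 sigma and
  integrated per pixel with error functions, so summed counts are conserved
  to better than 1%. The PSF width is a package choice, set so a focus
  spans the 5-px measurement aperture.

Motion is a 2D random walk with per-axis step variance `2 D dt`, reflected
at the crop boundary. The camera applies
`Poisson(signal + background) + Normal(0, read_noise)` at unit gain.

**Fixture noise.** Background and read noise have no published values; the
defaults (background 10 counts/px, read noise 2 counts) were chosen to be
*consistent with what the emulated instrument demonstrably does*: it
resolves single 110-count photobleaching steps in track intensities and
localizes foci to a few tens of nm. Step counting through the 81-pixel
aperture requires the aperture-summed noise (~36 counts at these defaults)
to stay below roughly a third of the single-molecule step. Real tissue
backgrounds are higher in absolute terms; what matters for every estimator
here is the noise *relative to* `b`, which these defaults place in the
regime the analysis assumes.

The 3D phantom renders ellipsoidal condensates as Gaussians whose half-max
isosurface is the stated ellipsoid, on an anisotropic 0.06 x 0.06 x 0.26 µm
(xyz) voxel grid, two channels, with an optional lateral chromatic offset
of channel 2. Truth includes analytic ellipsoid volumes, voxelized masks
and pairwise channel overlap fractions.

What the simulator does **not** emulate: blinking, fluorophore maturation
dynamics, motion blur within an exposure, depth-dependent aberrations,
scattering, autofluorescence structure, or a 3D PSF for the tracking movies
(single plane, as acquired). Passing tests therefore validate estimator
correctness under the stated noise model, not robustness to every artifact
of deep-tissue imaging.

## Detection and photometry

Aperture intensity is `sum(disc of radius 5 px) - n_disc * mean(rest of the
17 x 17 px square)`; adding a constant to a frame leaves it unchanged.
Candidate foci are strict local maxima of a lightly smoothed frame (sigma
1 px). Sifting accepts a candidate when its per-disc-pixel intensity
exceeds `snr_threshold` (default 0.6) times the robust (MAD-based) sd of
its background region; candidates closer than 6 px are all discarded as
ambiguous overlaps, and candidates whose 17-px box leaves the frame are
discarded. The 0.6 default corresponds to ~6 sd of the summed aperture
noise: with thousands of candidate maxima per frame, a laxer threshold
admits a steady stream of pure-noise detections, while 0.6 preserves
multi-molecule foci. The numeric threshold of the original tracking
software is unpublished; this value is a declared package choice. A
consequence is that single fluorophores (aperture SNR ~0.2 at fixture
noise) are *below* the detection limit — consistent with a deliberately
strict sifting regime — so late-stage bleaching is accessed by trace
extension (below), not by tracking.

Localization is an iterative Gaussian-mask centroid (mask sigma = PSF
sigma, up to 15 iterations, stopping at 1e-4 px movement; ~10 iterations
are needed to converge a half-pixel offset). Its precision estimate uses
the standard centroid-precision formula
`var = (s^2 + a^2/12)/N + 8 pi s^4 b^2 / (a^2 N^2)`. At fixture noise a
4-molecule focus localizes with ~15-25 nm scatter, within the typical
40 nm figure for this imaging mode.

## Linking

Per frame-pair optimal assignment (Hungarian) with squared-displacement
cost; a link is feasible within `max_displacement * sqrt(gap)` µm
(default 0.45 µm/frame), gaps up to 1 frame are closed, and tracks need at
least 3 foci so an MSD fit has two lag points. These linking parameters are
package choices (the original software's values are unpublished). Ties are
broken deterministically by the assignment solver, making linking
invariant to the ordering of foci within a frame.

## Brightness calibration and stoichiometry

`S = I0 / b`. `I0` is the intercept, at the track's first observed frame,
of a least-squares line through the first up-to-5 frame intensities
(linear, not exponential: over five frames at the relevant bleach rates
the two are indistinguishable and the line is unbiased at the intercept).

`b` is the modal size of *isolated, late-stage* photobleaching steps:

* noise sd per trace is estimated robustly from the Chung-Kennedy filter
  residual;
* candidate step times are local maxima of a matched filter — the
  difference of raw-trace means over the `window` (default 10) frames
  before and after each point — thresholded at 3 sd of that difference.
  This is the likelihood-optimal detector for an isolated step in white
  noise and, unlike thresholding the filtered derivative, does not miss
  steps whose filtered transition smears over several frames at step
  signal-to-noise near 2-3;
* a step is kept only if (i) both flanking plateaus are at least one
  window clear of any other detected step, (ii) each plateau passes a
  two-half homogeneity check (a hidden merged step shifts the halves
  apart), and (iii) it leaves the intensity at or below
  `late_stage_fraction` (default 0.5) of the trace's initial level —
  "late stage" defined photophysically, when few fluorophores remain and
  steps are sparse, not by position along the trace;
* the step size is the difference of raw-trace means over the *entire*
  flanking plateau segments. Short fixed windows anchored at the detected
  edges inherit a sizeable positive selection bias (the edges sit on noise
  extremes); full-segment means do not;
* `b_modal` is the mode of a Silverman-bandwidth Gaussian KDE over the
  pooled steps on a 0.1-count grid, refined as the mean of steps within
  +/-25% of that mode. The raw KDE argmax has a sampling sd of ~4 counts
  at ~150 steps; the local robust mean keeps the mode's outlier insensitivity
  (double steps, sub-threshold fragments) at ~2.5x lower variance.

The Chung-Kennedy filter itself combines forward/backward running means
(windows include the current sample and shrink at the edges) with weights
proportional to the inverse window variance to a configurable exponent
(default 2); zero-variance windows dominate outright. It is exposed both
as the denoising step and as the noise estimator for step detection.

**Internal calibration closes the loop.** The 5-px aperture captures ~83%
of a focus's photons (PSF tails fall outside the disc and slightly inflate
the background estimate). Because `b` is calibrated from steps measured
through the *same* photometry, the capture factor cancels in `S = I0 / b`.
The end-to-end recovery test demonstrates this: a sparse acquisition of
immobile 2-3-mers (detected on an average of the first five frames, whose
sqrt(5) noise reduction brings dimers above the sifting threshold, with
aperture traces extended past each track's end at its last position)
calibrates `b`, and stoichiometries 4-48 are then recovered with median
error <= 1 molecule up to 16-mers and <= 10% above. Trace extension
assumes slow or immobile particles; for the fast low-stoichiometry
fraction, calibrate on a dedicated sparse sample, as experimentalists do.

## Diffusion

Per-track time-averaged MSD over all ordered pairs at each frame lag, then
a weighted least-squares line `MSD = 4 D tau + c` over the first 4 lags
(weights = pair counts). Short-lag fitting limits correlated-lag bias for
short tracks; the intercept `c ~ 4 sigma_loc^2` absorbs static
localization error. Negative estimates are retained and flagged — clamping
would bias group means upward. With 12-frame tracks and 40 nm noise,
ensemble means over 1000 tracks recover 0.54 and 0.27 µm²/s within ~3%.
Group statistics split at 10 molecules by default.

## Periodicity

Per-nucleus Gaussian KDE with a *fixed* 0.6-molecule bandwidth (the
empirical spread of the brightness calibration; deliberately not
data-estimated), on a 0.05-molecule grid from 0. Densities integrate to
1 +/- 1e-3 because stoichiometries of 2 and above leave negligible kernel
mass below zero. Peaks require prominence >= 5% of the density maximum
(configurable; the original value is unpublished) and are refined by
3-point parabolic interpolation. Nearest-neighbour peak intervals are
pooled across nuclei; the periodicity `P` is the mode of the interval KDE
(same bandwidth), reported also rounded to the nearest integer, with
optional per-replicate aggregation.

Resolution limit: a repeating unit of 3 molecules or more is recovered
reliably at 300+ tracks; a *dimer* unit is not, because neighbouring peaks
then sit ~2.4 effective sd apart under the 0.6 + 0.6 (measurement +
kernel) blur and merge stochastically. This is a property of the stated
bandwidth, not of the implementation.

Nuclear copy numbers subtract an area-scaled unlabelled-control baseline
from integrated nuclear intensities and divide by `b`; negative adjusted
intensities clamp to zero with a flag.

## 3D segmentation and colocalization

Seeds are local maxima of the Laplacian-of-Gaussian response (per-axis
sigma = diameter / (2 sqrt 3) / voxel size; the stack mean is subtracted
first because at sub-voxel sigmas the discrete LoG kernel does not sum
exactly to zero), normalized to [0, 100]; the "probability threshold" is a
cut on this normalized response, which makes segmentation exactly
invariant to intensity rescaling and offsets. Watershed basins grow on the
smoothed inverted intensity over a domain whose floor approaches the
background as split sensitivity decreases; two touching basins merge when
the saddle depth below the weaker peak is less than
`(1 - split_sensitivity/100)` of that peak's height above background —
0% merges every blob in a connected region, 100% never merges. Object
extent is each basin's half-maximum region. The vendor tool that inspired
the parameter names computes its threshold differently (unpublished);
behavioural equivalence is claimed only for this documented contract.

Volume is voxel count x voxel volume; surface area is a marching-cubes
mesh on the binary mask (pad 1, level 0.5), and sphericity is Wadell's
`pi^(1/3) (6V)^(2/3) / A`. The binary mesh carries a ~5-10% staircase
overestimate of area (digitized spheres score ~0.92, comfortably above the
0.6 filter; thin rods score ~0.5); smoothing before meshing would fix the
sphere at the cost of destroying voxel-thin objects, so the raw mesh is
used. Tiny objects (a few voxels) have unreliable mesh areas, but the
0.03 µm³ volume floor removes them before sphericity matters.

Channel alignment estimates the chromatic shift from bead stacks by
cross-correlation with upsampled-DFT sub-voxel refinement (recovers 0.3
voxel shifts to ~0.05), falling back to zero shift with a warning when
the registration error indicates no common structure. Colocalization is
the voxel-wise AND of two label volumes; an object is colocalized iff it
shares at least one voxel, and per-nucleus counts are reported when a
nucleus label volume is supplied.

## Statistics

The Brunner-Munzel test estimates the relative effect
`p = P(X<Y) + 0.5 P(X=Y)` via midranks and studentizes with
Satterthwaite-type degrees of freedom; two-sided p-values come from the t
reference distribution (the standard small-sample recommendation), with a
permutation variant available. Degenerate inputs (both samples constant
and equal) raise. Welch's t test uses the unequal-variance statistic and
Welch-Satterthwaite df. Type-I error at alpha = 0.05 is nominal (within
[0.03, 0.07] over 5000 null replications at n = 20).

## Reproducibility and scale

All randomness flows from explicit seeds; the movie simulator separates
latent truth from camera noise so the same truth can be re-noised. CSV
outputs embed a hash of the analysis-relevant configuration. Problem sizes
throughout the test suite and acceptance script — 200-frame calibration
movies with 60 emitters, 1000-track diffusion ensembles, 500-track
periodicity samples, 96^2 x 28 phantoms — are desk-scale choices large
enough that the estimators operate in their asymptotic regime while a full
run completes in about a minute on one core.
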