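# condtrack

Single-particle tracking and condensate analysis for nuclear protein
assemblies imaged by high-speed oblique-illumination (Slimfield-style)
fluorescence microscopy and Airyscan-like 3D confocal microscopy — with a
ground-truthed synthetic-data generator so that every stage of the pipeline
can be verified quantitatively without any raw microscopy data.

## Who this is for

Groups quantifying how a fluorescently tagged protein assembles in vivo:
how many molecules a tracked particle contains (its **stoichiometry**),
whether those stoichiometries repeat in multiples of a core oligomer (the
**periodicity**), how mobility depends on assembly size (**diffusion
coefficients** from a random-walk model), and whether two proteins occupy
the same 3D condensates (**intersection colocalization**). The package was
built around the analysis of plant nuclear condensates formed by the
*Arabidopsis* RNA-binding protein FCA and its partner FLL2, but every stage
is generic.

## The analysis in brief

**Tracking side** (2D time-lapse movies, 53 nm pixels, 80 Hz):

1. `simulate_movie` — Brownian assemblies with per-fluorophore exponential
   photobleaching, Gaussian PSF rendering, Poisson + read camera noise, and
   full ground truth.
2. `detect_foci` — candidate foci by strict signal-to-noise "sifting";
   aperture photometry sums a 5-px-radius disc and subtracts the mean of
   the rest of a 17-px square; iterative Gaussian-mask centroid gives
   sub-pixel positions (typically tens of nm).
3. `link_tracks` — optimal (Hungarian) frame-to-frame assignment with a
   displacement budget and gap closing.
4. `calibrate_brightness` — the characteristic single-molecule brightness
   `b` as the modal size of isolated photobleaching steps in
   Chung-Kennedy-denoised track intensities (matched-filter step
   detection).
5. `stoichiometry` — `S = I0 / b`, where `I0` extrapolates the first five
   frame intensities back to the track start to undo early bleaching.
6. `kde_stoichiometry` / `find_stoichiometry_peaks` / `periodicity` — a
   fixed 0.6-molecule-bandwidth kernel density per nucleus; the modal
   nearest-neighbour peak spacing `P` is the repeating oligomer unit.
7. `msd` / `fit_diffusion` — per-track time-averaged mean-square
   displacement fitted with `MSD = 4 D tau + c` over the first lags, the
   intercept absorbing localization error.

**Condensate side** (two-channel 3D stacks, 0.06 x 0.06 x 0.26 µm voxels):

`blob_segment` (scale-matched Laplacian-of-Gaussian seeds + watershed with
a split-sensitivity merge rule), `filter_objects` (minimum volume 0.03 µm³
and mesh Wadell sphericity 0.6), `object_metrics`, `align_channels`
(sub-voxel chromatic correction from bead stacks) and `colocalize`
(voxel-wise intersection; an object is colocalized iff it shares a voxel
with the other channel).

Statistics: `brunner_munzel` (nonparametric relative effect
`P(X<Y) + 0.5 P(X=Y)`, studentized with Satterthwaite df, optional
permutation variant) and `welch_t`.

## Worked example

```python
import numpy as np
from condtrack import (MovieCalibration, EmitterModel, NoiseModel,
                       simulate_movie, detect_foci, link_tracks,
                       BrightnessCalibration, stoichiometry,
                       msd, fit_diffusion)

cal = MovieCalibration(frame_count=60, roi=(240, 184))   # 12.7 x 9.8 um
movie, truth = simulate_movie(
    cal, [{"stoichiometry": 8, "d": 0.05} for _ in range(10)],
    EmitterModel(bleach_rate=0.01), NoiseModel(), seed=3)

foci = {i: detect_foci(frame, frame_index=i) for i, frame in enumerate(movie)}
tracks = link_tracks(foci)
calib = BrightnessCalibration(b_modal=110.0, b_sd=15.0, n_steps_used=200)

t = max(tracks, key=len)
s = stoichiometry(t, calib)
d = fit_diffusion(msd(t))
print(f"{len(tracks)} tracks; longest has {len(t)} foci, "
      f"S = {s.stoichiometry:.1f} molecules, D = {d.D:.2f} um^2/s")
```

Output (deterministic for this seed):

```
11 tracks; longest has 59 foci, S = 6.9 molecules, D = 0.04 um^2/s
```

Ten 8-mers were simulated; the longest track reports ~6.9 apparent
molecules because the fixed external `b` of 110 counts does not include the
~17% of each focus's photons that fall outside the 5-px measurement
aperture — calibrating `b` *in-movie* from photobleaching steps (as
`calibrate_brightness` does) makes those losses cancel. The single-track
diffusion estimate of 0.04 µm²/s scatters around the simulated 0.05 µm²/s;
ensemble means over many tracks recover it to within a few percent.

A `condtrack` command-line interface drives the same stages from a YAML
configuration (`condtrack simulate|detect|track|stoich|mobility|
periodicity|blob3d|coloc|stats`), writing CSV/TIFF artifacts and a log.

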