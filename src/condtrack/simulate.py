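"""Ground-truthed synthetic imaging data for the tracking and segmentation pipelines.

This module emulates the imaging regime of oblique-illumination (Slimfield-style)
single-molecule microscopy of nuclear protein assemblies, plus Airyscan-like
two-channel 3D confocal stacks of condensates:

* Brownian particles whose stoichiometries are integer multiples of a core
  oligomer size, rendered as 2D Gaussian foci on a 53 nm pixel grid at 80 Hz.
* Per-fluorophore exponential photobleaching with a fixed characteristic
  single-molecule brightness ``b`` (counts per molecule per frame).
* Poisson shot noise plus Gaussian read noise; flat or Gaussian illumination.
* Ellipsoidal condensates in two co-imaged channels with a controllable
  lateral chromatic offset.

Every simulation returns its latent ground truth so downstream estimators
(detection, linking, stoichiometry, diffusion, segmentation, colocalization)
can be verified without any external data.

Coordinate conventions
----------------------
2D movies: frames are ``(height, width)`` arrays; continuous positions are
``(x, y)`` in µm with the centre of pixel ``(row, col)`` at
``((col + 0.5) * pixel_size, (row + 0.5) * pixel_size)``.

3D stacks: arrays are ``(z, y, x)``; µm coordinates and voxel sizes in this
module are ordered ``(z, y, x)`` to match.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "MovieCalibration",
    "EmitterModel",
    "NoiseModel",
    "AssemblyTruth",
    "PhantomObject",
    "Phantom3DConfig",
    "simulate_movie",
    "simulate_trajectory",
    "simulate_track_positions",
    "simulate_bleach_trace",
    "simulate_confocal_stack",
]


class ParameterError(ValueError):
    """A non-physical simulation parameter (negative rate, size, ...)."""


@dataclass(frozen=True)
class MovieCalibration:
    """Spatial and temporal calibration of a single-plane time-lapse movie.

    Defaults correspond to an oversampled 53 nm pixel grid imaged at 80 Hz
    (12.5 ms frame interval) cropped to 240 x 184 px (12.7 x 9.8 µm), the
    uniform-illumination analysis region used throughout this package.
    """

    pixel_size: float = 0.053        # µm per pixel
    frame_interval: float = 0.0125   # s
    frame_count: int = 100
    roi: tuple[int, int] = (240, 184)  # (width, height) in px

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if self.frame_count < 1:
            raise ParameterError("frame_count must be >= 1")
        if min(self.roi) < 16:
            raise ParameterError("roi dimensions must be >= 16 px")

    @property
    def width_um(self) -> float:
        return self.roi[0] * self.pixel_size

    @property
    def height_um(self) -> float:
        return self.roi[1] * self.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (height, width) of one frame."""
        return (self.roi[1], self.roi[0])


@dataclass(frozen=True)
class EmitterModel:
    """Photophysics of one fluorophore.

    ``brightness_b`` is the characteristic single-molecule brightness: the
    integrated camera counts one mature fluorophore contributes per frame.
    The default 110 counts with a ~13.6% coefficient of variation matches the
    mScarlet-I calibration (110 +/- 15 counts) that the analysis modules are
    designed to recover. ``bleach_rate`` is per frame; ``maturation_fraction``
    is the fraction of fluorophores that are fluorescent at all (a static
    dark fraction, no blinking).
    """

    brightness_b: float = 110.0
    brightness_cv: float = 15.0 / 110.0
    bleach_rate: float = 0.0          # 1 / frames
    psf_sigma: float = 0.130          # µm
    maturation_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.brightness_b <= 0:
            raise ParameterError("brightness_b must be > 0")
        if self.brightness_cv < 0:
            raise ParameterError("brightness_cv must be >= 0")
        if self.bleach_rate < 0:
            raise ParameterError("bleach_rate must be >= 0")
        if self.psf_sigma <= 0:
            raise ParameterError("psf_sigma must be > 0")
        if not 0.0 <= self.maturation_fraction <= 1.0:
            raise ParameterError("maturation_fraction must be in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Camera and illumination model.

    Counts are ``Poisson(signal + background) + Normal(0, read_noise_sd)``
    at unit gain when ``shot_noise`` is on, otherwise the noiseless
    expectation plus read noise. ``illumination_profile`` is ``"flat"`` or
    ``"gaussian"``; the Gaussian profile has peak 1 at the ROI centre and
    falls to ``illumination_min_fraction`` at the ROI corner, emulating an
    effectively uniform illumination region (80% +/- 9% of peak).
    """

    background_level: float = 10.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    illumination_profile: str = "flat"
    illumination_min_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ParameterError("background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ParameterError("read_noise_sd must be >= 0")
        if self.illumination_profile not in ("flat", "gaussian"):
            raise ParameterError("illumination_profile must be 'flat' or 'gaussian'")
        if not 0.0 < self.illumination_min_fraction <= 1.0:
            raise ParameterError("illumination_min_fraction must be in (0, 1]")


@dataclass
class AssemblyTruth:
    """Latent ground truth for one simulated assembly.

    ``bleach_frames[i]`` is the first frame index at which fluorophore ``i``
    is dark: ``inf`` if it never bleaches, ``nan`` if it was never mature
    (static dark fraction). ``brightnesses[i]`` is its per-frame brightness.
    """

    id: int
    true_stoichiometry: int
    true_D: float
    trajectory: np.ndarray          # (frame_count, 2) positions (x, y) µm
    bleach_frames: np.ndarray       # (true_stoichiometry,)
    brightnesses: np.ndarray        # (true_stoichiometry,)
    out_of_bounds: bool = False

    def emitting_count(self, frame: int) -> int:
        """Number of fluorophores still emitting in ``frame``."""
        bf = self.bleach_frames
        return int(np.sum(bf[~np.isnan(bf)] > frame))

    def expected_signal(self, frame: int) -> float:
        """Expected integrated signal (counts) in ``frame``, before illumination."""
        bf = self.bleach_frames
        alive = ~np.isnan(bf) & (bf > frame)
        return float(self.brightnesses[alive].sum())


def _illumination_factor(x: np.ndarray, y: np.ndarray,
                         calibration: MovieCalibration, noise: NoiseModel) -> np.ndarray:
    if noise.illumination_profile == "flat":
        return np.ones_like(np.asarray(x, dtype=float))
    cx, cy = calibration.width_um / 2.0, calibration.height_um / 2.0
    r_corner2 = cx ** 2 + cy ** 2
    if noise.illumination_min_fraction == 1.0:
        return np.ones_like(np.asarray(x, dtype=float))
    sigma2 = r_corner2 / (-2.0 * math.log(noise.illumination_min_fraction))
    r2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
    return np.exp(-r2 / (2.0 * sigma2))


def _reflect(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] (reflecting boundary)."""
    span = hi - lo
    q = np.mod(p - lo, 2.0 * span)
    q = np.where(q > span, 2.0 * span - q, q)
    return q + lo


def simulate_trajectory(start: np.ndarray, D: float, n_frames: int,
                        calibration: MovieCalibration,
                        rng: np.random.Generator) -> np.ndarray:
    """2D Brownian trajectory with reflecting ROI boundaries.

    Per-axis steps are Normal(0, sqrt(2 D dt)); positions in µm (x, y).
    """
    if D < 0:
        raise ParameterError("diffusion coefficient must be >= 0")
    step_sd = math.sqrt(2.0 * D * calibration.frame_interval)
    steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2)) if n_frames > 1 else np.zeros((0, 2))
    pos = np.vstack([start[None, :], start[None, :] + np.cumsum(steps, axis=0)]) if n_frames > 1 \
        else start[None, :].copy()
    pos[:, 0] = _reflect(pos[:, 0], 0.0, calibration.width_um)
    pos[:, 1] = _reflect(pos[:, 1], 0.0, calibration.height_um)
    return pos


def simulate_track_positions(D: float, n_frames: int, frame_interval: float,
                             localization_sd: float, rng: np.random.Generator,
                             start: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Free (unbounded) Brownian track observed with static localization noise.

    Convenience generator for diffusion-estimator benchmarks: true positions
    follow a 2D random walk with coefficient ``D`` (µm²/s) and each observed
    position carries independent Gaussian localization error of sd
    ``localization_sd`` (µm) per axis.
    """
    if D < 0 or localization_sd < 0:
        raise ParameterError("D and localization_sd must be >= 0")
    step_sd = math.sqrt(2.0 * D * frame_interval)
    steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2))
    true = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)]) + np.asarray(start)
    return true + rng.normal(0.0, localization_sd, size=true.shape)


def _render_gaussian(frame: np.ndarray, x_um: float, y_um: float, total: float,
                     sigma_um: float, pixel_size: float, trunc_sigmas: float = 4.0) -> None:
    """Add a pixel-integrated 2D Gaussian of integrated mass ``total`` in place."""
    if total <= 0:
        return
    sig_px = sigma_um / pixel_size
    cx = x_um / pixel_size   # continuous pixel-edge coordinate
    cy = y_um / pixel_size
    h, w = frame.shape
    r = trunc_sigmas * sig_px
    c0 = max(int(math.floor(cx - r)), 0)
    c1 = min(int(math.ceil(cx + r)) + 1, w)
    r0 = max(int(math.floor(cy - r)), 0)
    r1 = min(int(math.ceil(cy + r)) + 1, h)
    if c0 >= c1 or r0 >= r1:
        return
    edges_x = np.arange(c0, c1 + 1, dtype=float)
    edges_y = np.arange(r0, r1 + 1, dtype=float)
    s = sig_px * math.sqrt(2.0)
    fx = 0.5 * np.diff(erf((edges_x - cx) / s))
    fy = 0.5 * np.diff(erf((edges_y - cy) / s))
    frame[r0:r1, c0:c1] += total * np.outer(fy, fx)


def simulate_movie(calibration: MovieCalibration,
                   assemblies: list[tuple[int, float]] | list[dict],
                   emitter: EmitterModel | None = None,
                   noise: NoiseModel | None = None,
                   seed: int = 0,
                   noise_seed: int | None = None,
                   ) -> tuple[np.ndarray, list[AssemblyTruth]]:
    """Simulate a single-plane time-lapse movie of diffusing assemblies.

    Parameters
    ----------
    assemblies:
        Each entry is either ``(stoichiometry, D)`` or a dict with keys
        ``stoichiometry``, ``d`` and optionally ``start`` (``(x, y)`` µm).
        Stoichiometry is the number of labelled molecules in the assembly;
        D is its diffusion coefficient in µm²/s.
    seed:
        Seeds all latent randomness (trajectories, bleach times, per-molecule
        brightness, start positions).
    noise_seed:
        Optional separate seed for camera noise only; with a fixed ``seed``
        and varying ``noise_seed`` the ground truth is bit-identical while
        the photon noise differs.

    Returns
    -------
    (movie, truths):
        ``movie`` is a float ``(frame_count, height, width)`` array of camera
        counts; ``truths`` one :class:`AssemblyTruth` per assembly.
    """
    emitter = emitter or EmitterModel()
    noise = noise or NoiseModel()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2)
    latent_rng = np.random.default_rng(child[0])
    noise_rng = np.random.default_rng(child[1] if noise_seed is None else noise_seed)

    n_frames = calibration.frame_count
    h, w = calibration.shape
    signal = np.zeros((n_frames, h, w), dtype=float)

    truths: list[AssemblyTruth] = []
    for aid, spec in enumerate(assemblies):
        if isinstance(spec, dict):
            s = int(spec["stoichiometry"])
            d = float(spec.get("d", spec.get("D", 0.0)))
            start = spec.get("start")
        else:
            s, d = int(spec[0]), float(spec[1])
            start = None
        if s < 1:
            raise ParameterError("stoichiometry must be >= 1")
        if start is None:
            start = np.array([latent_rng.uniform(0, calibration.width_um),
                              latent_rng.uniform(0, calibration.height_um)])
        else:
            start = np.asarray(start, dtype=float)
        traj = simulate_trajectory(start, d, n_frames, calibration, latent_rng)

        mature = latent_rng.random(s) < emitter.maturation_fraction
        bleach = np.full(s, np.nan)
        if emitter.bleach_rate > 0:
            tau = latent_rng.exponential(1.0 / emitter.bleach_rate, size=s)
            bleach[mature] = np.ceil(tau[mature])
        else:
            bleach[mature] = np.inf
        bright = emitter.brightness_b * (
            1.0 + emitter.brightness_cv * latent_rng.standard_normal(s))
        bright = np.clip(bright, 0.0, None)
        truths.append(AssemblyTruth(id=aid, true_stoichiometry=s, true_D=d,
                                    trajectory=traj, bleach_frames=bleach,
                                    brightnesses=bright))

    for t in range(n_frames):
        fr = signal[t]
        for truth in truths:
            total = truth.expected_signal(t)
            if total <= 0:
                continue
            x, y = truth.trajectory[t]
            illum = float(_illumination_factor(np.array(x), np.array(y), calibration, noise))
            _render_gaussian(fr, x, y, total * illum, emitter.psf_sigma,
                             calibration.pixel_size)

    expected = signal + noise.background_level
    if noise.shot_noise:
        movie = noise_rng.poisson(expected).astype(float)
    else:
        movie = expected.copy()
    if noise.read_noise_sd > 0:
        movie += noise_rng.normal(0.0, noise.read_noise_sd, size=movie.shape)
    return movie, truths


def simulate_bleach_trace(n_fluor: int,
                          emitter: EmitterModel | None = None,
                          noise_sd: float = 0.0,
                          seed: int = 0,
                          n_frames: int | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one integrated-intensity photobleach trace.

    Each of ``n_fluor`` fluorophores has brightness drawn once from
    ``Normal(b, cv * b)`` and an exponential bleach time with rate
    ``emitter.bleach_rate`` per frame; the trace at frame ``t`` is the sum of
    brightnesses of fluorophores whose bleach time exceeds ``t``, plus
    Gaussian noise of sd ``noise_sd``. The final plateau is zero-mean
    background.

    Returns ``(trace, step_frames)`` where ``step_frames`` are the true frame
    indices at which each fluorophore goes dark (sorted).
    """
    if n_fluor < 1:
        raise ParameterError("n_fluor must be >= 1")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    emitter = emitter or EmitterModel(bleach_rate=0.05)
    if emitter.bleach_rate <= 0:
        raise ParameterError("bleach trace simulation requires bleach_rate > 0")
    rng = np.random.default_rng(seed)
    tau = rng.exponential(1.0 / emitter.bleach_rate, size=n_fluor)
    steps = np.ceil(tau).astype(int)
    bright = emitter.brightness_b * (1.0 + emitter.brightness_cv * rng.standard_normal(n_fluor))
    bright = np.clip(bright, 0.0, None)
    if n_frames is None:
        n_frames = int(steps.max()) + 20
    t = np.arange(n_frames)
    alive = steps[None, :] > t[:, None]        # emits in frame t iff ceil(tau) > t
    trace = (alive * bright[None, :]).sum(axis=1)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
    return trace, np.sort(steps)


# --------------------------------------------------------------------------
# 3D two-channel phantoms
# --------------------------------------------------------------------------

@dataclass
class PhantomObject:
    """One ellipsoidal condensate: centre/radii in µm, ``(z, y, x)`` order."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float] | float
    peak: float = 1000.0

    def radii_zyx(self) -> np.ndarray:
        r = self.radii
        if np.isscalar(r):
            r = (float(r),) * 3
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ParameterError("all radii must be > 0")
        return r

    @property
    def analytic_volume(self) -> float:
        """Ellipsoid volume 4/3 pi rz ry rx (µm³)."""
        rz, ry, rx = self.radii_zyx()
        return 4.0 / 3.0 * math.pi * rz * ry * rx


@dataclass
class Phantom3DConfig:
    """Two-channel 3D confocal-like phantom.

    ``voxel_size`` is ``(z, y, x)`` in µm; the default corresponds to an
    Airyscan acquisition with 0.06 x 0.06 x 0.26 µm (xyz) voxels.
    ``channel_shift`` is a lateral ``(y, x)`` chromatic offset in µm applied
    to every channel-2 object.
    """

    shape: tuple[int, int, int] = (28, 96, 96)          # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.26, 0.06, 0.06)
    channels: tuple[list[PhantomObject], list[PhantomObject]] = field(
        default_factory=lambda: ([], []))
    channel_shift: tuple[float, float] = (0.0, 0.0)      # (dy, dx) µm
    background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel sizes must be > 0")
        if self.background < 0 or self.noise_sd < 0:
            raise ParameterError("background and noise_sd must be >= 0")


@dataclass
class ObjectTruth:
    """Ground truth for one rendered phantom object."""

    id: int
    channel: int
    center: np.ndarray            # (z, y, x) µm, after any channel shift
    radii: np.ndarray             # (z, y, x) µm
    analytic_volume: float        # µm³, closed-form ellipsoid
    voxel_count: int
    clipped: bool


_HALF_MAX = math.sqrt(2.0 * math.log(2.0))   # Gaussian sigma -> half-max radius


def simulate_confocal_stack(config: Phantom3DConfig
                            ) -> tuple[np.ndarray, dict]:
    """Render a two-channel 3D stack of ellipsoidal condensates.

    Objects are rendered as 3D Gaussians whose half-maximum isosurface is the
    stated ellipsoid (sigma = radius / sqrt(2 ln 2) per axis); channel 2 is
    laterally shifted by ``channel_shift``. Returns ``(stack, truth)`` with
    ``stack`` of shape ``(2, z, y, x)`` and a truth dict containing:

    - ``"labels"``: per-channel integer label volumes of the true ellipsoid
      masks (label ``i+1`` = object ``i`` of that channel; later objects
      overwrite earlier ones where ellipsoids overlap),
    - ``"objects"``: per-channel lists of :class:`ObjectTruth`,
    - ``"overlap"``: matrix ``overlap[i, j]`` = fraction of channel-1 object
      ``i``'s true voxels shared with channel-2 object ``j``.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape
    vz, vy, vx = config.voxel_size
    zc = (np.arange(nz) + 0.5) * vz
    yc = (np.arange(ny) + 0.5) * vy
    xc = (np.arange(nx) + 0.5) * vx
    extent = np.array([nz * vz, ny * vy, nx * vx])

    stack = np.zeros((2, nz, ny, nx), dtype=float)
    labels = [np.zeros((nz, ny, nx), dtype=np.int32) for _ in range(2)]
    objects: list[list[ObjectTruth]] = [[], []]
    masks: list[list[np.ndarray]] = [[], []]
    any_rendered = False

    for ch in (0, 1):
        shift = np.array([0.0, *config.channel_shift]) if ch == 1 else np.zeros(3)
        for oid, obj in enumerate(config.channels[ch]):
            c = np.asarray(obj.center, dtype=float) + shift
            r = obj.radii_zyx()
            clipped = bool(np.any(c - r < 0) or np.any(c + r > extent))
            sig = r / _HALF_MAX
            gz = np.exp(-0.5 * ((zc - c[0]) / sig[0]) ** 2)
            gy = np.exp(-0.5 * ((yc - c[1]) / sig[1]) ** 2)
            gx = np.exp(-0.5 * ((xc - c[2]) / sig[2]) ** 2)
            stack[ch] += obj.peak * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
            ez = ((zc - c[0]) / r[0]) ** 2
            ey = ((yc - c[1]) / r[1]) ** 2
            ex = ((xc - c[2]) / r[2]) ** 2
            mask = (ez[:, None, None] + ey[None, :, None] + ex[None, None, :]) <= 1.0
            n_vox = int(mask.sum())
            if n_vox:
                any_rendered = True
                labels[ch][mask] = oid + 1
            masks[ch].append(mask)
            objects[ch].append(ObjectTruth(
                id=oid, channel=ch, center=c, radii=r,
                analytic_volume=obj.analytic_volume,
                voxel_count=n_vox, clipped=clipped or n_vox == 0))

    if (config.channels[0] or config.channels[1]) and not any_rendered:
        warnings.warn("stack too small to contain any object", stacklevel=2)

    overlap = np.zeros((len(objects[0]), len(objects[1])))
    for i, ma in enumerate(masks[0]):
        na = ma.sum()
        if na == 0:
            continue
        for j, mb in enumerate(masks[1]):
            overlap[i, j] = float(np.logical_and(ma, mb).sum()) / float(na)

    stack += config.background
    if config.noise_sd > 0:
        stack += rng.normal(0.0, config.noise_sd, size=stack.shape)

    truth = {"labels": labels, "objects": objects, "overlap": overlap}
    return stack, truth
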