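"""Brightness calibration and stoichiometry from photobleaching.

The number of labelled molecules in a tracked particle (its stoichiometry S)
is estimated as the particle's initial intensity divided by the
characteristic single-molecule brightness b. b is calibrated in-movie as the
modal size of downward steps in Chung-Kennedy-filtered track intensities
during late-stage photobleaching; the initial intensity is the intercept of
a least-squares line through the track's first (up to) five frame
intensities, which compensates photobleaching during detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .link import Track

__all__ = ["StoichConfig", "BrightnessCalibration", "TrackStoichiometry",
           "CalibrationError", "bleach_correct", "chung_kennedy",
           "detect_bleach_steps", "calibrate_brightness", "stoichiometry",
           "kde_mode"]


class CalibrationError(RuntimeError):
    """Raised when too few photobleach steps are available for calibration."""


@dataclass(frozen=True)
class StoichConfig:
    """How initial track intensity is extrapolated.

    A least-squares line is fitted through the first ``n_initial_frames``
    intensity samples and evaluated at the track's first observed frame.
    """

    n_initial_frames: int = 5

    def __post_init__(self) -> None:
        if self.n_initial_frames < 2:
            raise ValueError("n_initial_frames must be >= 2")


@dataclass(frozen=True)
class BrightnessCalibration:
    """Characteristic single-molecule brightness (counts/molecule/frame)."""

    b_modal: float
    b_sd: float
    n_steps_used: int

    def __post_init__(self) -> None:
        if self.b_modal <= 0:
            raise ValueError("b_modal must be > 0")


@dataclass
class TrackStoichiometry:
    track_id: int
    stoichiometry: float
    initial_intensity: float
    nucleus_id: int | None = None
    accepted: bool = True
    reason: str = ""


def bleach_correct(movie: np.ndarray) -> tuple[np.ndarray, dict]:
    """Temporal bleach correction of a whole movie.

    The whole-field frame mean is fitted with ``A exp(-k t) + C``; each frame
    is divided by the fitted decay normalized to its value in frame 0. On fit
    failure, or when no decay is found (k <= 0 or A <= 0), the movie is
    returned unchanged with a warning and ``params["corrected"] = False``.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.shape[0] < 10:
        raise ValueError("bleach correction requires >= 10 frames")
    means = movie.mean(axis=(1, 2))
    t = np.arange(len(means), dtype=float)

    def model(tt, a, k, c):
        return a * np.exp(-k * tt) + c

    p0 = (max(means[0] - means[-1], 1e-6), 3.0 / len(means), means[-1])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, t, means, p0=p0,
                                bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]),
                                maxfev=10000)
        a, k, c = popt
        # require a non-negligible fitted decay amplitude, otherwise the
        # "decay" is just noise around a constant level
        ok = a > 0 and k > 0 and a / max(a + c, 1e-12) > 1e-3
    except (RuntimeError, ValueError):
        ok = False
    if not ok:
        warnings.warn("no photobleaching decay detected; identity correction",
                      stacklevel=2)
        return movie.copy(), {"amplitude": 0.0, "rate": 0.0,
                              "offset": float(means.mean()), "corrected": False}
    decay = model(t, a, k, c) / model(0.0, a, k, c)
    return movie / decay[:, None, None], {"amplitude": float(a), "rate": float(k),
                                          "offset": float(c), "corrected": True}


def chung_kennedy(trace: np.ndarray, window: int = 5, exponent: float = 2.0
                  ) -> np.ndarray:
    """Edge-preserving forward/backward adaptive mean filter.

    For each sample, a forward running mean over the window ending at the
    sample and a backward running mean over the window starting at it are
    combined with weights proportional to the inverse window variance raised
    to ``exponent``. A window that straddles an intensity step has a large
    variance and so contributes little, which preserves the step; windows
    shrink at the trace edges. Zero-variance windows dominate outright (both
    zero: the two means are averaged).
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if window < 2:
        raise ValueError("window must be >= 2")
    if n <= window:
        raise ValueError("trace must be longer than the window")
    # cumulative sums for O(n) window means/variances
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    c2 = np.concatenate([[0.0], np.cumsum(trace ** 2)])
    idx = np.arange(n)
    f_lo = np.maximum(idx - window + 1, 0)
    f_hi = idx + 1
    b_lo = idx
    b_hi = np.minimum(idx + window, n)

    def win_stats(lo, hi):
        cnt = (hi - lo).astype(float)
        s1 = c1[hi] - c1[lo]
        s2 = c2[hi] - c2[lo]
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean ** 2, 0.0)
        return mean, var

    mf, vf = win_stats(f_lo, f_hi)
    mb, vb = win_stats(b_lo, b_hi)

    out = np.empty(n)
    tol = 1e-12 * max(1.0, float(np.max(np.abs(trace))) ** 2)
    zf = vf <= tol
    zb = vb <= tol
    both = zf & zb
    out[both] = 0.5 * (mf[both] + mb[both])
    only_f = zf & ~zb
    out[only_f] = mf[only_f]
    only_b = zb & ~zf
    out[only_b] = mb[only_b]
    rest = ~(zf | zb)
    wf = vf[rest] ** -exponent
    wb = vb[rest] ** -exponent
    out[rest] = (wf * mf[rest] + wb * mb[rest]) / (wf + wb)
    return out


def detect_bleach_steps(trace: np.ndarray, window: int = 10,
                        exponent: float = 2.0,
                        late_stage_fraction: float = 0.5,
                        step_sigmas: float = 3.0,
                        min_plateau: int | None = None) -> np.ndarray:
    """Sizes of isolated downward photobleaching steps in a trace.

    The local noise sd is estimated robustly from the residual of the
    Chung-Kennedy filtered trace. Candidate step times are then found with a
    matched filter for a downward step: the difference of raw-trace means
    over the ``window`` frames before and after each point, thresholded at
    ``step_sigmas`` times its noise sd (``noise_sd * sqrt(2/window)``); the
    argmax of each contiguous super-threshold region is one step time.
    Increases (blinking-on) are ignored.

    Two selection rules keep only trustworthy single steps:

    * isolation — both flanking plateaus must be at least ``min_plateau``
      frames (default: the filter window) clear of any other step; the step
      size is then the difference of raw-trace means over the entire
      flanking plateau segments, which is unbiased even at step
      signal-to-noise near the detection limit;
    * late stage, defined photophysically rather than by trace position — a
      step counts only when it leaves the intensity at or below
      ``late_stage_fraction`` of the trace's initial level, i.e. once most
      fluorophores have bleached and steps are sparse.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n <= 2 * window:
        return np.array([])
    if min_plateau is None:
        min_plateau = window
    filt = chung_kennedy(trace, window, exponent)
    resid = trace - filt
    noise_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    sd_diff = max(noise_sd, 1e-12) * np.sqrt(2.0 / window)

    # matched filter for a downward step: difference of raw-trace means over
    # the window before and after each candidate transition point t
    # (the step t: trace[t-1] bright, trace[t] dark)
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    t_idx = np.arange(window, n - window + 1)
    before_mean = (c1[t_idx] - c1[t_idx - window]) / window
    after_mean = (c1[t_idx + window] - c1[t_idx]) / window
    stat = before_mean - after_mean
    thr = step_sigmas * sd_diff
    # each true step raises the statistic over a ~2-window-wide triangular
    # region; take the argmax of every contiguous super-threshold region as
    # a step time
    above = stat >= max(thr, 1e-9)
    step_times: list[int] = []
    i = 0
    while i < len(stat):
        if above[i]:
            j = i
            while j + 1 < len(stat) and above[j + 1]:
                j += 1
            k = i + int(np.argmax(stat[i:j + 1]))
            step_times.append(int(t_idx[k]))
            i = j + 1
        else:
            i += 1

    def homogeneous(segment: np.ndarray) -> bool:
        # a hidden (undetected or merged) step inside a plateau shifts the
        # two half-means apart; reject such contaminated plateaus
        half = segment.size // 2
        if half < 2:
            return True
        gap = abs(float(segment[:half].mean() - segment[-half:].mean()))
        return gap <= 3.0 * max(noise_sd, 1e-12) * np.sqrt(2.0 / half)

    initial_level = float(np.percentile(filt, 99))
    steps = []
    for k, t in enumerate(step_times):
        prev_t = step_times[k - 1] if k > 0 else -(min_plateau + 1)
        next_t = step_times[k + 1] if k + 1 < len(step_times) else n + min_plateau + 1
        # isolation: clean plateaus of at least min_plateau frames each side
        if t - prev_t < min_plateau + 1 or next_t - t < min_plateau + 1:
            continue
        before = trace[max(prev_t + 1, 0):t]
        after = trace[t:min(next_t, n)]
        if not homogeneous(before) or not homogeneous(after):
            continue
        size = float(before.mean() - after.mean())
        if size < thr:
            continue
        if after.mean() <= late_stage_fraction * initial_level:
            steps.append(size)
    return np.asarray(steps)


def kde_mode(values: np.ndarray, grid_step: float = 0.1,
             bandwidth: float | None = None) -> float:
    """Mode of a Gaussian KDE over ``values`` on a uniform grid.

    ``bandwidth=None`` uses Silverman's rule; degenerate inputs (single value
    or zero spread) return the common value directly.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("kde_mode of empty input")
    if values.size == 1 or np.ptp(values) == 0:
        return float(values[0])
    if bandwidth is None:
        sd = float(np.std(values, ddof=1))
        iqr = float(np.subtract(*np.percentile(values, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * values.size ** (-0.2)
    bandwidth = max(bandwidth, grid_step)
    lo = values.min() - 3 * bandwidth
    hi = values.max() + 3 * bandwidth
    grid = np.arange(lo, hi + grid_step, grid_step)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / bandwidth) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def calibrate_brightness(traces, late_stage_fraction: float = 0.5,
                         window: int = 10, exponent: float = 2.0,
                         min_steps: int = 10,
                         refine_fraction: float = 0.25) -> BrightnessCalibration:
    """Calibrate the single-molecule brightness from photobleach steps.

    ``traces`` is an iterable of 1D intensity traces (or :class:`Track`
    objects, whose intensities are used). Downward steps detected in the
    final ``late_stage_fraction`` of each Chung-Kennedy-filtered trace are
    pooled; the modal step is located as the mode of their kernel density
    (Silverman bandwidth, 0.1-count grid) and then refined as the mean of
    the steps within ``+/- refine_fraction`` of that mode — a local robust
    mean that is insensitive to double-step and sub-threshold outliers while
    much less variable than the raw KDE argmax. Raises
    :class:`CalibrationError` when fewer than ``min_steps`` steps are found.
    """
    all_steps = []
    for tr in traces:
        if isinstance(tr, Track):
            tr = tr.intensities
        tr = np.asarray(tr, dtype=float)
        if tr.size <= window:
            continue
        all_steps.append(detect_bleach_steps(tr, window, exponent,
                                             late_stage_fraction))
    steps = np.concatenate(all_steps) if all_steps else np.array([])
    if steps.size < min_steps:
        raise CalibrationError(
            f"only {steps.size} photobleach steps found (need >= {min_steps})")
    mode = kde_mode(steps)
    core = steps[(steps >= (1.0 - refine_fraction) * mode)
                 & (steps <= (1.0 + refine_fraction) * mode)]
    b_modal = float(core.mean()) if core.size else mode
    return BrightnessCalibration(b_modal=b_modal,
                                 b_sd=float(np.std(steps, ddof=1)),
                                 n_steps_used=int(steps.size))


def extend_bleach_trace(movie: np.ndarray, track: Track,
                        pixel_size: float = 0.053,
                        aperture=None) -> np.ndarray:
    """Track intensities continued at the final position to the movie end.

    Detection loses a particle once it dims toward the single-molecule
    level, which is exactly where the late-stage photobleaching steps live.
    For calibration the aperture intensity is therefore re-measured at the
    track's last known position for every frame after the track ends and
    appended to the tracked intensities. Appropriate for slow or immobile
    particles (high-stoichiometry assemblies are the slow ones).
    """
    from .detect import ApertureConfig, measure_intensity
    aperture = aperture or ApertureConfig()
    intens = list(track.intensities)
    x, y = track.foci[-1].position
    row = int(round(y / pixel_size - 0.5))
    col = int(round(x / pixel_size - 0.5))
    h, w = movie.shape[1:]
    hw = aperture.background_box_halfwidth
    row = min(max(row, hw), h - hw - 1)
    col = min(max(col, hw), w - hw - 1)
    for fr in range(int(track.foci[-1].frame) + 1, movie.shape[0]):
        intens.append(measure_intensity(movie[fr], (row, col), aperture))
    return np.asarray(intens)


def initial_intensity(intensities: np.ndarray,
                      config: StoichConfig | None = None) -> float:
    """Intercept at the first sample of a line through the first frames."""
    config = config or StoichConfig()
    vals = np.asarray(intensities, dtype=float)[:config.n_initial_frames]
    if vals.size < 2:
        raise ValueError("need >= 2 intensity samples")
    x = np.arange(vals.size, dtype=float)
    slope, intercept = np.polyfit(x, vals, 1)
    return float(intercept)


def stoichiometry(track, calibration: BrightnessCalibration,
                  config: StoichConfig | None = None) -> TrackStoichiometry:
    """Convert a track's initial intensity to a molecule count.

    ``track`` is a :class:`Track` or a bare intensity sequence. The initial
    intensity extrapolated to the first observed frame is divided by
    ``calibration.b_modal``; tracks with non-positive initial intensity are
    returned with ``accepted=False`` and a reason code.
    """
    if isinstance(track, Track):
        intens = track.intensities
        tid = track.id
        nid = track.nucleus_id
    else:
        intens = np.asarray(track, dtype=float)
        tid = -1
        nid = None
    i0 = initial_intensity(intens, config)
    if i0 <= 0:
        return TrackStoichiometry(track_id=tid, stoichiometry=np.nan,
                                  initial_intensity=i0, nucleus_id=nid,
                                  accepted=False, reason="nonpositive_initial_intensity")
    return TrackStoichiometry(track_id=tid, stoichiometry=i0 / calibration.b_modal,
                              initial_intensity=i0, nucleus_id=nid)
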