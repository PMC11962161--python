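"""Linking foci into tracks, nucleus masking, and random-overlap estimation.

Frame-to-frame linking solves an optimal assignment (Hungarian algorithm)
with squared-displacement cost; links longer than a per-frame displacement
budget are forbidden, gaps of up to ``max_gap`` frames may be closed with
the budget scaled by sqrt(gap + 1), and unmatched foci start new tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as ndi_label
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .detect import Focus

__all__ = ["LinkingConfig", "Track", "link_tracks", "overlap_probability",
           "apply_nucleus_mask"]

_INFEASIBLE = 1e18


@dataclass(frozen=True)
class LinkingConfig:
    max_displacement: float = 0.45   # µm per frame
    max_gap: int = 1                 # frames a track may skip
    min_track_length: int = 3        # minimum number of foci

    def __post_init__(self) -> None:
        if self.max_displacement <= 0 or self.max_gap < 0 or self.min_track_length < 1:
            raise ValueError("linking parameters must be positive")


@dataclass
class Track:
    """An ordered sequence of foci belonging to one particle."""

    id: int
    foci: list[Focus] = field(default_factory=list)
    nucleus_id: int | None = None

    @property
    def frames(self) -> np.ndarray:
        return np.array([f.frame for f in self.foci], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) µm."""
        return np.array([f.position for f in self.foci], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([f.intensity for f in self.foci], dtype=float)

    def __len__(self) -> int:
        return len(self.foci)


def _as_frame_dict(foci_by_frame) -> dict[int, list[Focus]]:
    if isinstance(foci_by_frame, dict):
        return {int(k): list(v) for k, v in foci_by_frame.items()}
    out: dict[int, list[Focus]] = {}
    for i, fl in enumerate(foci_by_frame):
        out[i] = list(fl)
    return out


def link_tracks(foci_by_frame, config: LinkingConfig | None = None) -> list[Track]:
    """Link per-frame foci into tracks by optimal per-frame-pair assignment.

    ``foci_by_frame`` is a dict ``{frame: [Focus, ...]}`` or a list indexed
    by frame. Within each new frame, active track heads compete for foci with
    cost equal to squared displacement; a link is feasible when the
    displacement is at most ``max_displacement * sqrt(gap_frames)`` where
    ``gap_frames`` is the frame difference. Tracks unmatched for more than
    ``max_gap`` consecutive frames are closed. Tracks shorter than
    ``min_track_length`` foci are dropped.
    """
    config = config or LinkingConfig()
    frames = _as_frame_dict(foci_by_frame)
    active: list[Track] = []
    finished: list[Track] = []
    next_id = 0
    for fr in sorted(frames):
        foci = frames[fr]
        still_active: list[Track] = []
        closeable: list[Track] = []
        for t in active:
            if fr - t.foci[-1].frame <= config.max_gap + 1:
                still_active.append(t)
            else:
                closeable.append(t)
        finished.extend(closeable)
        active = still_active

        assigned = [False] * len(foci)
        if active and foci:
            cost = np.full((len(active), len(foci)), _INFEASIBLE)
            for i, t in enumerate(active):
                last = t.foci[-1]
                gap_frames = fr - last.frame
                budget = config.max_displacement * np.sqrt(gap_frames)
                lp = np.asarray(last.position)
                for j, f in enumerate(foci):
                    d2 = float(np.sum((np.asarray(f.position) - lp) ** 2))
                    if d2 <= budget ** 2:
                        cost[i, j] = d2
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < _INFEASIBLE:
                    active[i].foci.append(foci[j])
                    assigned[j] = True
        for j, f in enumerate(foci):
            if not assigned[j]:
                active.append(Track(id=next_id, foci=[f]))
                next_id += 1
    finished.extend(active)
    kept = [t for t in finished if len(t) >= config.min_track_length]
    kept.sort(key=lambda t: t.id)
    for new_id, t in enumerate(kept):
        t.id = new_id
    return kept


def overlap_probability(foci_by_frame, overlap_radius: float) -> float:
    """Fraction of foci whose nearest same-frame neighbour is within radius.

    The boundary is closed: a pair at exactly ``overlap_radius`` separation
    counts as overlapping. Foci alone in their frame count as
    non-overlapping. Raises on empty input.
    """
    frames = _as_frame_dict(foci_by_frame)
    n_total = 0
    n_overlap = 0
    for fr, foci in frames.items():
        n_total += len(foci)
        if len(foci) < 2:
            continue
        pts = np.array([f.position for f in foci], dtype=float)
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=2)
        n_overlap += int(np.sum(dist[:, 1] <= overlap_radius + 1e-12))
    if n_total == 0:
        raise ValueError("overlap_probability requires at least one focus")
    return n_overlap / n_total


def _position_to_pixel(position: tuple[float, float], pixel_size: float
                       ) -> tuple[int, int]:
    x, y = position
    return int(round(y / pixel_size - 0.5)), int(round(x / pixel_size - 0.5))


def apply_nucleus_mask(items, mask: np.ndarray, pixel_size: float = 0.053):
    """Restrict foci or tracks to a nucleus mask and attach nucleus ids.

    ``mask`` is a 2D array over the ROI: boolean (connected components are
    labelled automatically) or an integer label image (0 = outside). A focus
    is kept when its position falls on a non-zero mask pixel; a track is kept
    when the majority of its foci do, and its ``nucleus_id`` is the most
    common label among them.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        labels, _ = ndi_label(mask)
    else:
        labels = mask.astype(int)
    if not labels.any():
        warnings.warn("empty nucleus mask: all items removed", stacklevel=2)
        return []
    h, w = labels.shape

    def _label_at(pos) -> int:
        row, col = _position_to_pixel(pos, pixel_size)
        if 0 <= row < h and 0 <= col < w:
            return int(labels[row, col])
        return 0

    out = []
    for item in items:
        if isinstance(item, Track):
            labs = np.array([_label_at(f.position) for f in item.foci])
            inside = labs > 0
            if inside.sum() * 2 >= len(labs):
                vals, counts = np.unique(labs[inside], return_counts=True)
                item.nucleus_id = int(vals[np.argmax(counts)])
                out.append(item)
        else:
            if _label_at(item.position) > 0:
                out.append(item)
    return out
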