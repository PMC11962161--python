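"""Mean-square displacement and diffusion-coefficient estimation.

Each track's time-averaged MSD (all ordered pairs at each frame lag) is
fitted over its first few lags with a weighted least-squares line
``msd = 4 D tau + c`` under a 2D random-walk model; the intercept ``c``
absorbs the static localization error (``c ~ 4 sigma_loc^2``). Group
statistics relate mobility to stoichiometry above/below a molecule-count
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .link import Track

__all__ = ["MSDCurve", "DiffusionEstimate", "msd", "fit_diffusion",
           "mobility_by_stoichiometry"]


@dataclass
class MSDCurve:
    lag_times: np.ndarray    # s, strictly increasing
    values: np.ndarray       # µm²
    counts: np.ndarray       # displacement pairs per lag


@dataclass
class DiffusionEstimate:
    D: float                 # µm²/s; may be slightly negative from noise
    intercept: float         # µm², localization-error term (~ 4 sigma_loc²)
    n_lags_used: int
    negative: bool = False


def msd(track, frame_interval: float = 0.0125) -> MSDCurve:
    """Time-averaged MSD of one track over all ordered pairs per frame lag.

    ``track`` is a :class:`Track` or an ``(n, 2)`` position array (µm); for a
    Track, actual frame numbers are used so gap-closed tracks contribute only
    pairs at exact frame separations.
    """
    if isinstance(track, Track):
        pos = track.positions
        frames = track.frames
    else:
        pos = np.asarray(track, dtype=float)
        frames = np.arange(len(pos))
    n = len(pos)
    if n < 2:
        raise ValueError("msd requires >= 2 positions")
    max_lag = int(frames[-1] - frames[0])
    lags, vals, counts = [], [], []
    frame_index = {int(f): i for i, f in enumerate(frames)}
    for k in range(1, max_lag + 1):
        sq = [float(np.sum((pos[frame_index[f + k]] - pos[i]) ** 2))
              for i, f in enumerate(frames) if (f + k) in frame_index]
        if sq:
            lags.append(k * frame_interval)
            vals.append(float(np.mean(sq)))
            counts.append(len(sq))
    return MSDCurve(lag_times=np.asarray(lags), values=np.asarray(vals),
                    counts=np.asarray(counts, dtype=int))


def fit_diffusion(curve: MSDCurve, n_lags: int = 4) -> DiffusionEstimate:
    """Weighted least-squares fit ``msd = 4 D tau + c`` over the first lags.

    Weights are the pair counts per lag. Negative estimates are retained but
    flagged (clamping would bias ensemble means upward). Raises when fewer
    than two lags are available.
    """
    m = min(n_lags, len(curve.lag_times))
    if m < 2:
        raise ValueError("fit_diffusion requires >= 2 usable lags")
    tau = curve.lag_times[:m]
    y = curve.values[:m]
    w = np.sqrt(curve.counts[:m].astype(float))
    slope, intercept = np.polyfit(tau, y, 1, w=w)
    d = float(slope) / 4.0
    return DiffusionEstimate(D=d, intercept=float(intercept), n_lags_used=m,
                             negative=d < 0)


def mobility_by_stoichiometry(table: pd.DataFrame, threshold: float = 10.0,
                              s_col: str = "stoichiometry", d_col: str = "D"
                              ) -> pd.DataFrame:
    """Mean/sd/n of the diffusion coefficient below and at/above a
    stoichiometry threshold (default 10 molecules).

    Returns one row per non-empty group (``"S<10"`` / ``"S>=10"`` style
    labels); an empty group is simply absent.
    """
    if table.empty:
        raise ValueError("empty stoichiometry/diffusion table")
    rows = []
    groups = {
        f"S<{threshold:g}": table[table[s_col] < threshold],
        f"S>={threshold:g}": table[table[s_col] >= threshold],
    }
    for name, sub in groups.items():
        d = sub[d_col].dropna()
        if len(d) == 0:
            continue
        rows.append({"group": name, "mean_D": float(d.mean()),
                     "sd_D": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
                     "n": int(len(d))})
    return pd.DataFrame(rows)
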