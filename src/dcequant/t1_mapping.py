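"""Variable-TR saturation-recovery T1 mapping.

Fits S(TR) = s0 (1 - exp(-TR/T1)) per voxel by bounded nonlinear least
squares.  A two-parameter model is used deliberately: the acquisition is
saturation-recovery-like and no inversion-efficiency term is estimable
from a multi-TR RARE series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

T1_BOUNDS = (0.01, 20.0)  # seconds


@dataclass
class T1Map:
    """Per-voxel T1 estimates with fit diagnostics."""

    t1: np.ndarray        # seconds
    s0: np.ndarray        # signal units
    fit_rss: np.ndarray
    valid_mask: np.ndarray


def robust_noise_floor(series: np.ndarray, patch: int = 4) -> float:
    """Noise scale from a corner patch of the shortest-TR volume.

    1.4826 * median absolute deviation around the patch median; falls
    back to the patch median if the MAD is zero.
    """
    vol = series[..., 0]
    sl = tuple(slice(0, min(patch, n)) for n in vol.shape)
    corner = vol[sl].ravel()
    mad = np.median(np.abs(corner - np.median(corner)))
    return float(1.4826 * mad) if mad > 0 else float(np.median(corner))


def _fit_voxel(signal: np.ndarray, trs: np.ndarray):
    s_max = signal[-1]
    if s_max <= 0 or not np.any(signal > 0):
        return np.nan, np.nan, np.nan, False
    half_idx = int(np.argmax(signal >= 0.5 * s_max))
    t1_init = float(np.clip(trs[half_idx] / np.log(2.0),
                            T1_BOUNDS[0] * 1.5, T1_BOUNDS[1] * 0.5))
    s0_init = s_max / (1.0 - np.exp(-trs[-1] / t1_init))

    def resid(p):
        return p[0] * (1.0 - np.exp(-trs / p[1])) - signal

    try:
        res = optimize.least_squares(
            resid, (s0_init, t1_init),
            bounds=((0.0, T1_BOUNDS[0]), (np.inf, T1_BOUNDS[1])),
            method="trf")
    except Exception:
        return np.nan, np.nan, np.nan, False
    s0, t1 = res.x
    rss = float(2.0 * res.cost)
    at_bound = (t1 <= T1_BOUNDS[0] * (1 + 1e-6)
                or t1 >= T1_BOUNDS[1] * (1 - 1e-6))
    ok = res.status > 0 and not at_bound
    return float(t1), float(s0), rss, ok


def fit_t1(series: np.ndarray, trs, mask: np.ndarray | None = None,
           background_factor: float = 5.0) -> T1Map:
    """Voxel-wise T1 fit of a multi-TR series.

    Parameters
    ----------
    series : ndarray, shape (..., n_TRs)
        Signal, last axis ordered as ``trs``.
    trs : sequence of float
        Repetition times in seconds, at least 3, strictly increasing.
    mask : boolean ndarray, optional
        Voxels to fit.  When omitted, background is excluded by an
        intensity threshold of ``background_factor`` times the robust
        noise floor estimated from a corner patch of the longest-TR
        volume.
    """
    series = np.asarray(series, dtype=float)
    trs = np.asarray(trs, dtype=float)
    if trs.size < 3 or np.unique(trs).size < 3:
        raise ValueError("need at least 3 distinct TRs")
    if np.any(series < 0):
        raise ValueError("signals must be non-negative")
    shape = series.shape[:-1]
    if mask is None:
        floor = robust_noise_floor(series[..., ::-1])
        mask = series[..., -1] > background_factor * max(floor, 0.0)
    mask = np.asarray(mask, dtype=bool)

    t1 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for vox in np.argwhere(mask):
        key = tuple(vox)
        t1_v, s0_v, rss_v, ok = _fit_voxel(series[key], trs)
        t1[key], s0[key], rss[key] = t1_v, s0_v, rss_v
        valid[key] = ok
    return T1Map(t1=t1, s0=s0, fit_rss=rss, valid_mask=valid)
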