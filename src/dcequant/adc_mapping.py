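"""Apparent diffusion coefficient mapping from multi-b-value DWI.

Per diffusion direction, ln S is regressed on b (ordinary least squares);
the slope is -ADC and the intercept extrapolates ln S0 — no b = 0 image
is required.  The reported ADC is the arithmetic mean of the
per-direction estimates (trace ADC).  A weighted variant (weights
proportional to S^2) is available to temper the Rician noise floor's
influence at high b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dce_kinetics import ParametricMap


@dataclass
class DWISeries:
    """Diffusion-weighted signals, shape (..., n_directions, n_b)."""

    signals: np.ndarray
    b_values: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.b_values.size < 2:
            raise ValueError("need at least 2 b-values")
        if self.signals.shape[-1] != self.b_values.size:
            raise ValueError("last axis must match b_values")


def fit_adc(series: DWISeries, weighted: bool = False) -> ParametricMap:
    """Log-linear ADC fit, averaged over directions (mm^2/s).

    Voxels containing any non-positive signal are flagged invalid.
    Voxels whose signal is constant across b in every direction get
    ADC = 0 and are flagged invalid (no diffusion information).
    """
    s = series.signals
    b = series.b_values
    if np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    positive = np.all(s > 0, axis=(-2, -1))
    s_safe = np.where(s > 0, s, 1.0)
    y = np.log(s_safe)                       # (..., ndir, nb)
    if weighted:
        w = s_safe ** 2
    else:
        w = np.ones_like(s_safe)
    # weighted simple regression of y on b, vectorised over voxels/directions
    sw = w.sum(axis=-1)
    bw = (w * b).sum(axis=-1) / sw
    yw = (w * y).sum(axis=-1) / sw
    cov = (w * (b - bw[..., None]) * (y - yw[..., None])).sum(axis=-1)
    var = (w * (b - bw[..., None]) ** 2).sum(axis=-1)
    slope = cov / var                        # (..., ndir)
    adc_dir = -slope
    adc = adc_dir.mean(axis=-1)
    flat = np.all(np.ptp(s, axis=-1) == 0, axis=-1)
    adc = np.where(flat, 0.0, adc)
    valid = positive & ~flat
    return ParametricMap(values=adc, mask=valid, units="mm^2/s",
                         parameter_name="adc")
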