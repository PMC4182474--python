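"""Extended Tofts pharmacokinetic modelling for DCE-MRI.

The tissue is modelled as two compartments exchanging a low-molecular-weight
gadolinium tracer with the blood plasma: an intravascular plasma space of
fractional volume ``vp`` and an extravascular extracellular space (EES) of
fractional volume ``ve``.  Tracer flux from plasma into the EES is governed
by the volume transfer constant ``ktrans`` (1/min), and efflux by
``kep = ktrans / ve``.  The tissue concentration is

    C_t(t) = vp * C_p(t) + ktrans * int_0^t C_p(tau) exp(-kep (t - tau)) dtau

where ``C_p`` is the arterial input function (AIF).  With a biexponential
AIF the convolution has a closed form (sum of exponential differences),
which is what the voxel-wise fit evaluates; a fine-grid numerical
convolution is kept alongside as an independent cross-check path.

Units: ``ktrans`` and the AIF decay rates are in 1/min internally; sample
times are supplied in seconds and converted at a single point.
Concentrations are in mM; AUC is in mM*s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.integrate import cumulative_trapezoid

#: Longitudinal relaxivity of gadodiamide-class agents at high field,
#: L mmol^-1 s^-1.  An assumption, not a measured value; configurable
#: everywhere it is used.
DEFAULT_R1_RELAXIVITY = 3.9

_SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class AIFModel:
    """Biexponential plasma concentration curve for a bolus at ``t0``.

    C_p(t) = dose * (a1 exp(-m1 (t-t0)/60) + a2 exp(-m2 (t-t0)/60)) for
    t >= t0 (t in seconds, decay rates in 1/min), and 0 before the bolus.

    The shipped defaults describe a rat plasma curve for a
    gadodiamide-like agent (fast distribution phase, slow renal
    clearance).  They are literature-derived working values, not measured
    in any particular animal: replace them with your own AIF as needed.

    Parameters
    ----------
    a1, a2 : float
        Amplitudes in (mmol/L) per (mmol/kg) injected dose, i.e. kg/L.
    m1, m2 : float
        Decay rates, 1/min.
    t0 : float
        Bolus arrival time, seconds from the start of the dynamic series.
    dose : float
        Injected dose, mmol/kg body weight.
    """

    a1: float = 5.8
    a2: float = 0.7
    m1: float = 4.2
    m2: float = 0.016
    t0: float = 0.0
    dose: float = 0.2

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("AIF amplitudes must be non-negative")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("AIF decay rates must be positive")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")

    def total_exposure(self) -> float:
        """Integral of C_p over [t0, inf) in mM*min (closed form)."""
        return self.dose * (self.a1 / self.m1 + self.a2 / self.m2)


def aif_concentration(t, aif: AIFModel) -> np.ndarray:
    """Plasma concentration (mM) at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    tau = (t - aif.t0) / _SECONDS_PER_MINUTE
    tau_pos = np.where(tau >= 0, tau, 0.0)
    cp = aif.dose * (aif.a1 * np.exp(-aif.m1 * tau_pos)
                     + aif.a2 * np.exp(-aif.m2 * tau_pos))
    return np.where(tau >= 0, cp, 0.0)


@dataclass
class ToftsParams:
    """Per-voxel extended Tofts parameters with fit diagnostics."""

    ktrans: float  # 1/min
    ve: float      # fraction
    vp: float      # fraction
    rss: float = 0.0
    converged: bool = True
    auc1min: float | None = None  # mM*s, filled by map_voxelwise

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be non-negative")
        if not (0.0 <= self.ve <= 1.0) or not (0.0 <= self.vp <= 1.0):
            raise ValueError("ve and vp must lie in [0, 1]")


@dataclass
class ConcentrationSeries:
    """Tissue tracer concentration over time for one or many voxels.

    ``conc`` has shape ``(..., n_times)``; leading axes index voxels.
    ``clipped`` flags frames whose signal exceeded the invertible range of
    the signal equation, ``excluded`` flags voxels dropped from analysis
    (non-positive baseline or missing T1).
    """

    times: np.ndarray          # seconds from series start
    conc: np.ndarray           # mM
    baseline_frames: int
    clipped: np.ndarray | None = None
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape[-1] != self.times.shape[-1]:
            raise ValueError("conc and times disagree on frame count")


@dataclass
class ParametricMap:
    """3D map of one quantitative parameter with its validity mask."""

    values: np.ndarray
    mask: np.ndarray
    units: str
    parameter_name: str

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def summary(self) -> dict:
        v = self.masked_values()
        if v.size == 0:
            return {"n": 0}
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"n": int(v.size), "mean": float(v.mean()),
                "median": float(med), "iqr": float(q3 - q1)}


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def tofts_forward(ktrans: float, ve: float, vp: float, aif: AIFModel,
                  times_s) -> np.ndarray:
    """Closed-form extended Tofts tissue concentration (mM).

    Valid for the biexponential AIF; each plasma exponential convolved
    with the efflux kernel gives a difference of exponentials.
    """
    if ktrans < 0:
        raise ValueError("ktrans must be non-negative")
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve must be positive when ktrans > 0 "
                         "(efflux rate undefined)")
    times = np.asarray(times_s, dtype=float)
    cp = aif_concentration(times, aif)
    if ktrans == 0:
        return vp * cp
    tau = (times - aif.t0) / _SECONDS_PER_MINUTE
    active = tau >= 0
    tau = np.where(active, tau, 0.0)
    kep = ktrans / ve
    conv = np.zeros_like(tau)
    for a, m in ((aif.a1, aif.m1), (aif.a2, aif.m2)):
        if abs(kep - m) < 1e-10:
            conv += a * tau * np.exp(-m * tau)
        else:
            conv += a * (np.exp(-m * tau) - np.exp(-kep * tau)) / (kep - m)
    return vp * cp + ktrans * aif.dose * np.where(active, conv, 0.0)


def tofts_forward_many(ktrans, ve, vp, aif: AIFModel, times_s) -> np.ndarray:
    """Vectorised closed form over arrays of voxel parameters.

    Returns shape ``(n_voxels, n_times)``.  Voxels with ktrans = 0 are
    allowed any ve (the leakage term vanishes).
    """
    ktrans = np.atleast_1d(np.asarray(ktrans, dtype=float))
    ve = np.atleast_1d(np.asarray(ve, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    if np.any((ktrans > 0) & (ve <= 0)):
        raise ValueError("ve must be positive wherever ktrans > 0")
    times = np.asarray(times_s, dtype=float)
    cp = aif_concentration(times, aif)
    tau = np.maximum((times - aif.t0) / _SECONDS_PER_MINUTE, 0.0)
    active = (times - aif.t0) >= 0
    ve_safe = np.where(ve > 0, ve, 1.0)
    kep = (ktrans / ve_safe)[:, None]
    e_kep = np.exp(-kep * tau[None, :])
    conv = np.zeros((ktrans.size, times.size))
    for a, m in ((aif.a1, aif.m1), (aif.a2, aif.m2)):
        denom = kep - m
        safe = np.abs(denom) > 1e-10
        e_m = np.exp(-m * tau)[None, :]
        conv += np.where(safe, a * (e_m - e_kep) / np.where(safe, denom, 1.0),
                         a * tau[None, :] * e_m)
    ct = vp[:, None] * cp[None, :] \
        + ktrans[:, None] * aif.dose * conv * active[None, :]
    return ct


def tofts_forward_numeric(ktrans: float, ve: float, vp: float, aif: AIFModel,
                          times_s, dt: float = 0.01) -> np.ndarray:
    """Fine-grid trapezoidal convolution; independent of the closed form.

    Integrates C_p(tau) exp(-kep (t - tau)) on a uniform grid of step
    ``dt`` seconds starting exactly at the bolus (C_p vanishes before
    ``t0``, so the discontinuity sits on a grid node).
    """
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve must be positive when ktrans > 0")
    times = np.asarray(times_s, dtype=float)
    cp_at_times = aif_concentration(times, aif)
    if ktrans == 0:
        return vp * cp_at_times
    t_end = float(times.max())
    if t_end <= aif.t0:
        return vp * cp_at_times
    n = int(np.ceil((t_end - aif.t0) / dt))
    grid = aif.t0 + np.arange(n + 1) * dt
    cp_grid = aif_concentration(grid, aif)
    kep_s = (ktrans / ve) / _SECONDS_PER_MINUTE
    rel = grid - aif.t0
    if kep_s * rel[-1] < 600.0:
        weighted = cp_grid * np.exp(kep_s * rel)
        integral = cumulative_trapezoid(weighted, grid, initial=0.0)
        conv = np.exp(-kep_s * rel) * integral
    else:  # stable stepwise recursion for extreme kep * t products
        conv = np.zeros_like(grid)
        decay = np.exp(-kep_s * dt)
        for k in range(n):
            conv[k + 1] = conv[k] * decay + 0.5 * dt * (
                cp_grid[k] * decay + cp_grid[k + 1])
    leak = (ktrans / _SECONDS_PER_MINUTE) * np.interp(
        times, grid, conv, left=0.0)
    return vp * cp_at_times + leak


# ---------------------------------------------------------------------------
# Signal <-> concentration
# ---------------------------------------------------------------------------

def saturation_recovery_signal(s0, t1, tr: float, conc=0.0,
                               r1: float = DEFAULT_R1_RELAXIVITY):
    """S = s0 (1 - exp(-TR R1)), R1 = 1/T1 + r1 C.  Shared forward model."""
    r1_total = 1.0 / np.asarray(t1, dtype=float) + r1 * np.asarray(conc)
    return np.asarray(s0) * (1.0 - np.exp(-tr * r1_total))


def signal_to_concentration(dyn: np.ndarray, t1_pre: np.ndarray, seq,
                            r1: float = DEFAULT_R1_RELAXIVITY,
                            valid: np.ndarray | None = None,
                            ) -> ConcentrationSeries:
    """Invert the saturation-recovery signal equation frame by frame.

    Parameters
    ----------
    dyn : ndarray, shape (..., n_frames)
        Dynamic signal; leading axes are voxels.
    t1_pre : ndarray, shape (...)
        Pre-contrast T1 (seconds) on the same voxel grid.
    seq : SequenceSpec
        Supplies ``tr_dynamic``, ``n_baseline``, ``frame_interval``.
    valid : boolean ndarray, optional
        Voxels with a usable T1 fit; invalid voxels are excluded.

    The equilibrium magnetisation is calibrated per voxel from the mean
    of the ``n_baseline`` pre-contrast frames and the voxel's own T1.
    Frames whose signal reaches or exceeds the saturation asymptote are
    clipped to the maximum invertible concentration and flagged.
    """
    dyn = np.asarray(dyn, dtype=float)
    t1_pre = np.asarray(t1_pre, dtype=float)
    nb = seq.n_baseline
    if nb < 2:
        raise ValueError("need at least 2 baseline frames")
    tr = seq.tr_dynamic
    s_pre = dyn[..., :nb].mean(axis=-1)
    excluded = (s_pre <= 0) | ~np.isfinite(t1_pre) | (t1_pre <= 0)
    if valid is not None:
        excluded |= ~valid
    t1_safe = np.where(excluded, 1.0, t1_pre)
    s_pre_safe = np.where(excluded, 1.0, s_pre)
    s0 = s_pre_safe / (1.0 - np.exp(-tr / t1_safe))
    frac = 1.0 - dyn / s0[..., None]
    clipped = frac <= 1e-9
    frac = np.clip(frac, 1e-9, None)
    r1_t = -np.log(frac) / tr
    conc = (r1_t - 1.0 / t1_safe[..., None]) / r1
    conc[excluded] = np.nan
    times = np.arange(dyn.shape[-1]) * seq.frame_interval
    return ConcentrationSeries(times=times, conc=conc, baseline_frames=nb,
                               clipped=clipped, excluded=excluded)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

#: Multi-start initial points (ktrans 1/min, ve, vp): a low-uptake, a
#: mid-range, and a fast-washout start.  Fixed list -> deterministic fit.
FIT_STARTS = ((0.05, 0.2, 0.02), (0.3, 0.4, 0.05), (1.0, 0.15, 0.005))
FIT_LOWER = (0.0, 1e-3, 0.0)
FIT_UPPER = (5.0, 1.0, 1.0)


def fit_tofts(conc, times_s, aif: AIFModel,
              fix_vp: float | None = None) -> ToftsParams:
    """Bounded nonlinear least squares of the extended Tofts model.

    Three fixed starting points are tried and the best residual sum of
    squares wins, making the fit deterministic.  ``fix_vp`` pins the
    plasma volume fraction instead of fitting it.
    """
    conc = np.asarray(conc, dtype=float)
    times = np.asarray(times_s, dtype=float)
    post = times >= aif.t0
    if post.sum() < 10:
        raise ValueError("need at least 10 post-bolus frames")
    if np.max(np.abs(conc)) < 1e-12:
        return ToftsParams(ktrans=0.0, ve=FIT_LOWER[1], vp=0.0, rss=0.0,
                           converged=False)

    if fix_vp is None:
        def resid(p):
            return tofts_forward(p[0], p[1], p[2], aif, times) - conc
        lower, upper = FIT_LOWER, FIT_UPPER
        starts = FIT_STARTS
        scale = (0.1, 0.1, 0.01)
    else:
        def resid(p):
            return tofts_forward(p[0], p[1], fix_vp, aif, times) - conc
        lower, upper = FIT_LOWER[:2], FIT_UPPER[:2]
        starts = tuple(s[:2] for s in FIT_STARTS)
        scale = (0.1, 0.1)

    best = None
    any_ok = False
    for x0 in starts:
        try:
            res = optimize.least_squares(resid, x0, bounds=(lower, upper),
                                         x_scale=scale, method="trf")
        except Exception:
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res.x, res.status > 0)
        any_ok = any_ok or res.status > 0
    if best is None:
        return ToftsParams(ktrans=0.0, ve=FIT_LOWER[1], vp=0.0,
                           rss=float(np.sum(conc ** 2)), converged=False)
    rss, x, ok = best
    if fix_vp is None:
        ktrans, ve, vp = x
    else:
        (ktrans, ve), vp = x, fix_vp
    return ToftsParams(ktrans=float(ktrans), ve=float(ve), vp=float(vp),
                       rss=rss, converged=bool(ok))


def auc_1min(conc, times_s, n_baseline: int, window: float = 60.0) -> float:
    """Trapezoidal area under the concentration curve (mM*s).

    Integrates from bolus arrival (the first frame after the baseline
    block) to arrival + ``window`` seconds, linearly interpolating the
    curve at the window end.
    """
    conc = np.asarray(conc, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if n_baseline >= times.size:
        raise ValueError("no post-baseline frames")
    t_arr = times[n_baseline]
    t_stop = t_arr + window
    if times[-1] < t_stop:
        raise ValueError(
            f"need {window:g} s of post-arrival data, have "
            f"{times[-1] - t_arr:g} s")
    inside = (times >= t_arr) & (times <= t_stop)
    t_win = times[inside]
    c_win = conc[inside]
    if t_win[-1] < t_stop:
        c_end = np.interp(t_stop, times, conc)
        t_win = np.append(t_win, t_stop)
        c_win = np.append(c_win, c_end)
    return float(np.trapezoid(c_win, t_win))


def map_voxelwise(dyn: np.ndarray, t1map, mask: np.ndarray, aif: AIFModel,
                  seq, r1: float = DEFAULT_R1_RELAXIVITY,
                  fix_vp: float | None = None) -> dict:
    """Fit the kinetic model in every masked voxel of a 4D series.

    Returns a dict of :class:`ParametricMap` (``ktrans``, ``ve``, ``vp``,
    ``auc1min``) plus a ``convergence_rate`` summary.  ``t1map`` may be a
    :class:`~dcequant.t1_mapping.T1Map` or a plain T1 array.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if hasattr(t1map, "t1"):
        t1 = t1map.t1
        valid = t1map.valid_mask
    else:
        t1 = np.asarray(t1map, dtype=float)
        valid = np.isfinite(t1) & (t1 > 0)
    series = signal_to_concentration(dyn[mask], t1[mask], seq, r1=r1,
                                     valid=valid[mask])
    shape = mask.shape
    out = {name: np.full(shape, np.nan) for name in
           ("ktrans", "ve", "vp", "auc1min")}
    fit_ok = np.zeros(mask.sum(), dtype=bool)
    idx = np.argwhere(mask)
    n_conv = 0
    for i, vox in enumerate(idx):
        if series.excluded is not None and series.excluded[i]:
            continue
        c = series.conc[i]
        p = fit_tofts(c, series.times, aif, fix_vp=fix_vp)
        p.auc1min = auc_1min(c, series.times, seq.n_baseline)
        key = tuple(vox)
        out["ktrans"][key] = p.ktrans
        out["ve"][key] = p.ve
        out["vp"][key] = p.vp
        out["auc1min"][key] = p.auc1min
        fit_ok[i] = p.converged
        n_conv += p.converged
    valid_map = np.zeros(shape, dtype=bool)
    valid_map[tuple(idx[fit_ok].T)] = True
    units = {"ktrans": "1/min", "ve": "fraction", "vp": "fraction",
             "auc1min": "mM*s"}
    maps = {name: ParametricMap(values=out[name], mask=valid_map,
                                units=units[name], parameter_name=name)
            for name in out}
    maps["convergence_rate"] = n_conv / mask.sum()
    return maps
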