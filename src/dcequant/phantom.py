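"""Digital phantoms for quantitative tumour MRI.

Generates synthetic saturation-recovery T1-mapping series, dynamic
contrast-enhanced (DCE) series, and multi-b-value diffusion-weighted
series on small 3D grids with a spherical "tumour" in a homogeneous
background, plus summary-level two-cohort animal studies.  Every
generator is seeded and fully reproducible; ground truth travels with
the data so fitting routines can be validated by parameter recovery.

The acquisition defaults mirror a 7 T small-animal protocol: a 206-frame
dynamic series at 4.8 s temporal resolution with 20 pre-contrast
baseline frames and TR = 200 ms, a seven-TR RARE T1 map, and
diffusion weighting at b = 300/500/800/1200 s/mm^2 along three
orthogonal directions, with a 0.2 mmol/kg gadodiamide bolus.

Noise is Rician (magnitude of complex Gaussian), the physically correct
model for magnitude MRI; a Gaussian option exists for debugging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dce_kinetics import (AIFModel, DEFAULT_R1_RELAXIVITY,
                           saturation_recovery_signal, tofts_forward_many)

GROUPS = ("control", "mAb", "NK", "NK+mAb")


@dataclass(frozen=True)
class SequenceSpec:
    """Acquisition timing for the dynamic, T1-mapping and DWI scans."""

    n_frames: int = 206
    frame_interval: float = 4.8          # s
    n_baseline: int = 20
    tr_dynamic: float = 0.200            # s
    t1map_trs: tuple = (0.125, 0.250, 0.500, 1.200, 2.500, 5.500, 10.000)
    b_values: tuple = (300.0, 500.0, 800.0, 1200.0)   # s/mm^2
    n_directions: int = 3
    dose: float = 0.2                    # mmol/kg

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not self.n_baseline < self.n_frames:
            raise ValueError("n_baseline must be smaller than n_frames")
        b = np.asarray(self.b_values, dtype=float)
        if b.size and (np.any(b <= 0) or np.any(np.diff(b) <= 0)):
            raise ValueError("b_values must be positive, strictly increasing")
        trs = np.asarray(self.t1map_trs, dtype=float)
        if np.any(np.diff(trs) <= 0):
            raise ValueError("t1map_trs must be strictly increasing")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def injection_time(self) -> float:
        """Bolus time: immediately after the last baseline frame."""
        return self.n_baseline * self.frame_interval


def default_aif(seq: SequenceSpec, **overrides) -> AIFModel:
    """AIF with onset at the sequence's injection time."""
    kw = dict(t0=seq.injection_time, dose=seq.dose)
    kw.update(overrides)
    return AIFModel(**kw)


@dataclass
class PhantomTruth:
    """Voxel-wise ground truth for one synthetic animal."""

    ktrans_map: np.ndarray   # 1/min
    ve_map: np.ndarray       # fraction
    vp_map: np.ndarray       # fraction
    t1_map: np.ndarray       # s
    adc_map: np.ndarray      # mm^2/s
    s0_map: np.ndarray       # arbitrary signal units
    tumour_mask: np.ndarray  # bool
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        ve, vp, kt = self.ve_map, self.vp_map, self.ktrans_map
        if np.any(ve < 0) or np.any(ve > 1) or np.any(vp < 0) or np.any(vp > 1):
            raise ValueError("ve and vp must lie in [0, 1]")
        if np.any(kt < 0):
            raise ValueError("ktrans must be non-negative")
        if np.any((ve + vp)[self.tumour_mask] > 1 + 1e-12):
            raise ValueError("ve + vp must not exceed 1 inside the tumour")
        if np.any(self.t1_map <= 0) or np.any(self.adc_map <= 0):
            raise ValueError("t1 and adc must be positive")
        if np.any((kt > 0) & (ve == 0)):
            raise ValueError("ve = 0 with ktrans > 0: efflux rate undefined")


def make_phantom_truth(shape=(32, 32, 4), tumour_radius: float = 6.0,
                       tumour_ktrans: float = 0.15, tumour_ve: float = 0.30,
                       tumour_vp: float = 0.03, tumour_t1: float = 1.8,
                       tumour_adc: float = 1.1e-3, bg_ktrans: float = 0.01,
                       bg_ve: float = 0.10, bg_vp: float = 0.01,
                       bg_t1: float = 1.5, bg_adc: float = 0.7e-3,
                       s0: float = 1000.0, seed: int = 0,
                       noise_sigma: float = 0.0) -> PhantomTruth:
    """Spherical tumour in homogeneous brain-like background.

    Tissue defaults (tumour T1 1.8 s at 7 T, tumour ADC above normal
    brain, modest leakage in background) are stated assumptions of the
    phantom, not measured values.
    """
    grid = np.indices(shape).astype(float)
    centre = [(n - 1) / 2 for n in shape]
    # in-plane voxels ~0.27 mm, slices 1.5 mm: radius in in-plane voxels
    r2 = ((grid[0] - centre[0]) ** 2 + (grid[1] - centre[1]) ** 2
          + ((grid[2] - centre[2]) * 2.0) ** 2)
    mask = r2 <= tumour_radius ** 2
    pick = lambda tum, bg: np.where(mask, tum, bg)
    return PhantomTruth(
        ktrans_map=pick(tumour_ktrans, bg_ktrans),
        ve_map=pick(tumour_ve, bg_ve),
        vp_map=pick(tumour_vp, bg_vp),
        t1_map=pick(tumour_t1, bg_t1),
        adc_map=pick(tumour_adc, bg_adc),
        s0_map=np.full(shape, s0),
        tumour_mask=mask, seed=seed, noise_sigma=noise_sigma)


def add_rician(clean: np.ndarray, sigma: float,
               rng: np.random.Generator, model: str = "rician") -> np.ndarray:
    """Magnitude-MRI noise: |(S + n1) + i n2| with n ~ N(0, sigma)."""
    if sigma == 0:
        return np.asarray(clean, dtype=float).copy()
    clean = np.asarray(clean, dtype=float)
    if model == "rician":
        re = clean + rng.normal(0.0, sigma, clean.shape)
        im = rng.normal(0.0, sigma, clean.shape)
        return np.hypot(re, im)
    if model == "gaussian":
        return clean + rng.normal(0.0, sigma, clean.shape)
    raise ValueError(f"unknown noise model {model!r}")


def generate_dce_phantom(truth: PhantomTruth, seq: SequenceSpec,
                         aif: AIFModel | None = None,
                         r1: float = DEFAULT_R1_RELAXIVITY,
                         noise_model: str = "rician"):
    """Forward-simulate the dynamic series.

    Returns ``(signal, conc)``: the noisy 4D signal (..., n_frames) and
    the noise-free tissue concentration.  The first ``n_baseline``
    frames precede the bolus and carry no tracer.
    """
    if aif is None:
        aif = default_aif(seq)
    shape = truth.ktrans_map.shape
    flat = lambda a: np.asarray(a, dtype=float).ravel()
    conc = tofts_forward_many(flat(truth.ktrans_map), flat(truth.ve_map),
                              flat(truth.vp_map), aif, seq.frame_times)
    conc = conc.reshape(shape + (seq.n_frames,))
    signal = saturation_recovery_signal(
        truth.s0_map[..., None], truth.t1_map[..., None], seq.tr_dynamic,
        conc=conc, r1=r1)
    rng = np.random.default_rng(truth.seed)
    return add_rician(signal, truth.noise_sigma, rng, noise_model), conc


def generate_t1_series(truth: PhantomTruth, seq: SequenceSpec,
                       noise_model: str = "rician") -> np.ndarray:
    """Saturation-recovery series, shape (..., n_TRs)."""
    trs = np.asarray(seq.t1map_trs, dtype=float)
    clean = saturation_recovery_signal(truth.s0_map[..., None],
                                       truth.t1_map[..., None],
                                       trs[None, None, None, :])
    # distinct stream from the DCE noise: offset the seed deterministically
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 1)))
    return add_rician(clean, truth.noise_sigma, rng, noise_model)


def generate_dwi_phantom(truth: PhantomTruth, seq: SequenceSpec,
                         noise_model: str = "rician") -> np.ndarray:
    """Monoexponential diffusion decay, shape (..., n_dir, n_b).

    The truth is isotropic: every direction decays with the same ADC.
    """
    b = np.asarray(seq.b_values, dtype=float)
    if b.size == 0:
        raise ValueError("b_values is empty")
    if np.any(truth.adc_map <= 0):
        raise ValueError("adc must be positive")
    decay = np.exp(-b[None, None, None, None, :]
                   * truth.adc_map[..., None, None])
    clean = truth.s0_map[..., None, None] * decay
    clean = np.broadcast_to(
        clean, truth.adc_map.shape + (seq.n_directions, b.size)).copy()
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 2)))
    return add_rician(clean, truth.noise_sigma, rng, noise_model)


# ---------------------------------------------------------------------------
# Summary-level cohort studies
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of one synthetic treatment cohort.

    Per animal and timepoint, the tumour-median interstitial volume
    fraction ve is drawn as group mean + animal random effect + residual;
    ADC carries a group-specific linear dependence on ve so that a
    negative ADC-ve association in the NK-cell groups is reproducible by
    construction.  Defaults encode the study conditions the phantom
    emulates: four arms, two post-treatment timepoints, an elevated ve
    under combination therapy (+0.15 over control) and a depressed ve
    under NK monotherapy (-0.10), between-animal SD 0.05.
    """

    groups: tuple = GROUPS
    n_per_group: int = 5
    timepoints: tuple = ("day7", "day17")
    group_ve_means: dict = field(default_factory=lambda: {
        "control": 0.30, "mAb": 0.30, "NK": 0.20, "NK+mAb": 0.45})
    between_animal_sd: float = 0.05
    within_animal_sd: float = 0.03
    adc_ve_slope: dict = field(default_factory=lambda: {
        "control": 0.0, "mAb": 0.0, "NK": -1.0e-3, "NK+mAb": -1.0e-3})
    adc_base: float = 1.0e-3        # mm^2/s at the group-mean ve
    adc_sd: float = 5.0e-5
    ktrans_mean: float = 0.15       # 1/min, no treatment effect by default
    ktrans_sd: float = 0.03
    vp_mean: float = 0.03
    vp_sd: float = 0.008
    volume_start: float = 2000.0    # voxels at day 0
    growth_rate: dict = field(default_factory=lambda: {
        "control": 0.12, "mAb": 0.11, "NK": 0.115, "NK+mAb": 0.08})  # 1/day
    volume_cv: float = 0.3
    cohort: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.groups:
            if not 0.0 < self.group_ve_means[g] < 1.0:
                raise ValueError("group ve means must lie in (0, 1)")
        if self.between_animal_sd < 0 or self.within_animal_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")


_TIMEPOINT_DAYS = {"day7": 7.0, "day17": 17.0}


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Long-format per-animal, per-timepoint parameter table.

    One row per animal x timepoint with columns animal_id, cohort,
    group, timepoint, ve, ktrans, vp, adc, auc1min, tumour_voxels,
    qc_pass.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    n_trunc = n_draws = 0
    for g in spec.groups:
        mu = spec.group_ve_means[g]
        slope = spec.adc_ve_slope[g]
        rate = spec.growth_rate[g]
        for i in range(spec.n_per_group):
            animal = f"c{spec.cohort}_{g}_{i:02d}"
            b = rng.normal(0.0, spec.between_animal_sd)
            kt_animal = max(rng.normal(spec.ktrans_mean, spec.ktrans_sd), 1e-3)
            vp_animal = float(np.clip(
                rng.normal(spec.vp_mean, spec.vp_sd), 1e-4, 0.5))
            v0 = spec.volume_start * rng.lognormal(0.0, spec.volume_cv)
            for tp in spec.timepoints:
                ve = mu + b + rng.normal(0.0, spec.within_animal_sd)
                n_draws += 1
                if not 1e-3 < ve < 1 - 1e-3:
                    n_trunc += 1
                    ve = float(np.clip(ve, 1e-3, 1 - 1e-3))
                adc = (spec.adc_base + slope * (ve - mu)
                       + rng.normal(0.0, spec.adc_sd))
                adc = max(adc, 1e-5)
                days = _TIMEPOINT_DAYS.get(tp, 7.0)
                vol = v0 * np.exp(rate * days) * rng.lognormal(0.0, 0.1)
                # AUC scales with uptake: crude proportionality plus noise
                auc = kt_animal * 60.0 * (1.0 + rng.normal(0.0, 0.1))
                rows.append(dict(animal_id=animal, cohort=spec.cohort,
                                 group=g, timepoint=tp, ve=ve,
                                 ktrans=kt_animal, vp=vp_animal, adc=adc,
                                 auc1min=auc, tumour_voxels=int(round(vol)),
                                 qc_pass=True))
    if n_trunc > 0.10 * n_draws:
        warnings.warn("more than 10% of ve draws hit the (0,1) bounds: "
                      "effect sizes implausible", stacklevel=2)
    return pd.DataFrame(rows)
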