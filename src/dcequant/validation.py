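"""Validation experiments: parameter recovery and statistical calibration.

Self-contained, seeded experiments that exercise the whole analysis
chain against phantoms with known ground truth:

* agreement of the closed-form Tofts convolution with a fine-grid
  numerical oracle;
* exact recovery of generating parameters from noise-free phantoms;
* recovery error under Rician noise at the acquisition grids the
  package simulates (SNR quoted as mean acquired signal over sigma; for
  the dynamic series, pre-contrast baseline signal over sigma);
* type-I error and confidence-interval coverage of the cluster-robust
  Scheffe machinery on simulated null cohorts;
* power to recover the built-in treatment-effect direction.

Each function returns plain floats so results can be logged or
serialised directly.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import adc_mapping, cohort_stats, t1_mapping
from .dce_kinetics import (fit_tofts, saturation_recovery_signal,
                           signal_to_concentration, tofts_forward,
                           tofts_forward_many, tofts_forward_numeric)
from .phantom import (CohortSpec, GROUPS, SequenceSpec, add_rician,
                      default_aif, generate_cohort)

KTRANS_GRID = (0.05, 0.2, 0.5)
VE_GRID = (0.1, 0.3, 0.6)
VP_GRID = (0.01, 0.03, 0.08)


def oracle_agreement(dt: float = 0.01) -> dict:
    """Max |closed form - fine-grid convolution| (mM) over a 3x3x3
    parameter grid on the full dynamic sampling grid."""
    seq = SequenceSpec()
    aif = default_aif(seq)
    t = seq.frame_times
    worst = 0.0
    for kt, ve, vp in itertools.product(KTRANS_GRID, VE_GRID, VP_GRID):
        closed = tofts_forward(kt, ve, vp, aif, t)
        numeric = tofts_forward_numeric(kt, ve, vp, aif, t, dt=dt)
        worst = max(worst, float(np.max(np.abs(closed - numeric))))
    return {"max_abs_error_mM": worst,
            "n": len(KTRANS_GRID) * len(VE_GRID) * len(VP_GRID)}


def noise_free_recovery() -> dict:
    """Max relative recovery error of each fitter on noise-free data."""
    seq = SequenceSpec()
    aif = default_aif(seq)
    # kinetic fit
    truth = (0.12, 0.35, 0.04)
    conc = tofts_forward(*truth, aif, seq.frame_times)
    p = fit_tofts(conc, seq.frame_times, aif)
    tofts_err = max(abs(p.ktrans - truth[0]) / truth[0],
                    abs(p.ve - truth[1]) / truth[1],
                    abs(p.vp - truth[2]) / truth[2])
    # T1 fit at the seven TRs
    trs = np.asarray(seq.t1map_trs)
    t1_true, s0 = 1.8, 500.0
    sig = (s0 * (1 - np.exp(-trs / t1_true))).reshape(1, 1, 1, -1)
    t1_fit = t1_mapping.fit_t1(sig, trs, mask=np.ones((1, 1, 1), bool))
    t1_err = abs(t1_fit.t1[0, 0, 0] - t1_true) / t1_true
    # ADC at the four b-values x three directions
    b = np.asarray(seq.b_values)
    adc_true = 1.0e-3
    dwi = np.broadcast_to(1000.0 * np.exp(-b * adc_true), (1, 3, 4)).copy()
    pm = adc_mapping.fit_adc(adc_mapping.DWISeries(dwi, b))
    adc_err = abs(pm.values[0] - adc_true) / adc_true
    return {"tofts_max_rel_err": float(tofts_err),
            "t1_rel_err": float(t1_err), "adc_rel_err": float(adc_err)}


def noisy_recovery(seed: int = 0, n_tofts: int = 500, snr_dce: float = 20.0,
                   n_adc: int = 1000, snr_adc: float = 20.0,
                   n_t1: int = 1000, snr_t1: float = 50.0) -> dict:
    """Median relative recovery errors under Rician noise (percent)."""
    seq = SequenceSpec()
    aif = default_aif(seq)
    rng = np.random.default_rng(seed)

    kt = rng.uniform(0.05, 0.5, n_tofts)
    ve = rng.uniform(0.1, 0.6, n_tofts)
    vp = rng.uniform(0.01, 0.08, n_tofts)
    t1_tissue, s0 = 1.8, 1000.0
    conc = tofts_forward_many(kt, ve, vp, aif, seq.frame_times)
    sig = saturation_recovery_signal(s0, t1_tissue, seq.tr_dynamic, conc)
    s_pre = float(sig[0, 0])
    noisy = add_rician(sig, s_pre / snr_dce, rng)
    series = signal_to_concentration(noisy, np.full(n_tofts, t1_tissue), seq)
    ve_err, kt_err = [], []
    for i in range(n_tofts):
        p = fit_tofts(series.conc[i], series.times, aif)
        ve_err.append(abs(p.ve - ve[i]) / ve[i])
        kt_err.append(abs(p.ktrans - kt[i]) / kt[i])

    b = np.asarray(seq.b_values)
    adc_true = 1.0e-3
    clean = np.broadcast_to(s0 * np.exp(-b * adc_true),
                            (n_adc, seq.n_directions, b.size)).copy()
    dwi = add_rician(clean, clean.mean() / snr_adc, rng)
    pm = adc_mapping.fit_adc(adc_mapping.DWISeries(dwi, b))
    adc_err = np.abs(pm.values - adc_true) / adc_true

    trs = np.asarray(seq.t1map_trs)
    t1_true = rng.uniform(0.8, 2.5, n_t1)
    clean_t1 = s0 * (1 - np.exp(-trs[None, :] / t1_true[:, None]))
    noisy_t1 = add_rician(clean_t1, clean_t1.mean() / snr_t1,
                          rng).reshape(n_t1, 1, 1, -1)
    fit = t1_mapping.fit_t1(noisy_t1, trs, mask=np.ones((n_t1, 1, 1), bool))
    t1_err = np.abs(fit.t1[:, 0, 0] - t1_true) / t1_true

    return {"ve_median_rel_err_pct": 100.0 * float(np.median(ve_err)),
            "ktrans_median_rel_err_pct": 100.0 * float(np.median(kt_err)),
            "adc_median_rel_err_pct": 100.0 * float(np.median(adc_err)),
            "t1_median_rel_err_pct": 100.0 * float(np.median(t1_err)),
            "n_tofts": n_tofts, "n_adc": n_adc, "n_t1": n_t1}


def null_calibration(seed: int = 0, n_rep: int = 5000) -> dict:
    """Scheffe family-wise error and 95% CI coverage on null cohorts.

    Every replicate draws a cohort with equal group ve means (animal
    random effects, two timepoints per animal), fits the clustered
    linear model, and tests all pairwise contrasts with Scheffe's
    adjustment; coverage is scored on the NK+mAb-vs-NK contrast whose
    true value is zero.
    """
    null_means = {g: 0.30 for g in GROUPS}
    base = int(seed) % (2 ** 31 - 1)
    rej = cover = 0
    for i in range(n_rep):
        spec = CohortSpec(seed=(base + i) % (2 ** 31 - 1),
                          group_ve_means=dict(null_means))
        tab = generate_cohort(spec)
        model = cohort_stats.fit_clustered_lm(tab, "ve")
        contrasts = cohort_stats.scheffe_contrasts(model)
        rej += any(c.p_adjusted < 0.05 for c in contrasts)
        _, _, lo, hi = cohort_stats.contrast_ci(model, ("NK+mAb", "NK"))
        cover += lo <= 0.0 <= hi
    return {"fwer": rej / n_rep, "coverage_pct": 100.0 * cover / n_rep,
            "n": n_rep}


def effect_direction_power(seed: int = 0, n_rep: int = 200) -> dict:
    """Fraction of replicate default-effect studies with a positive,
    Scheffe-significant NK+mAb-vs-NK ve contrast."""
    base = int(seed) % (2 ** 31 - 1)
    hits = 0
    for i in range(n_rep):
        tab = generate_cohort(CohortSpec(seed=(base + i) % (2 ** 31 - 1)))
        model = cohort_stats.fit_clustered_lm(tab, "ve")
        c = cohort_stats.scheffe_contrasts(model,
                                           pairs=[("NK+mAb", "NK")])[0]
        hits += (c.estimate > 0) and (c.p_adjusted < 0.05)
    return {"power_pct": 100.0 * hits / n_rep, "n": n_rep}
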