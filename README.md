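# dcequant

Quantitative MRI analysis of tumour treatment response in small-animal
studies: voxel-wise **extended Tofts** pharmacokinetic mapping from
dynamic contrast-enhanced (DCE) MRI, variable-TR **T1 mapping**,
**ADC mapping** from multi-b-value diffusion imaging, end-stage
**histology indices**, and **cluster-robust cohort statistics** — plus
seeded digital phantoms with known ground truth so every stage of the
chain can be validated by parameter recovery.

The scientific setting is early response assessment of experimental
brain-tumour therapies (e.g. intralesional cellular immunotherapy in
rat glioma models), where tumour size changes too late to be useful and
physiological parameters must carry the signal.  The headline biomarker
is the extravascular extracellular volume fraction `v_e`: effective
cell killing enlarges the interstitium and raises `v_e`, while an
ineffective cell infusion packs the tissue and lowers it.

## The model

Tissue tracer concentration follows the extended Tofts two-compartment
model driven by a biexponential arterial input function C_p:

    C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^{-(K^trans/v_e)(t−τ)} dτ
    C_p(t) = D (a₁ e^{−m₁(t−t₀)} + a₂ e^{−m₂(t−t₀)}),  t ≥ t₀

Per tumour voxel the package converts signal to concentration through
the saturation-recovery signal equation (using that animal's own fitted
T1 map), fits (K^trans, v_e, v_p) by bounded deterministic least
squares, and integrates the model-free AUC_1min.  ADC comes from a
log-linear fit over b = 300–1200 s/mm² averaged over three directions.
Group inference uses linear models with a cluster-robust sandwich
covariance per animal and Scheffé-adjusted pairwise contrasts
(Bell–McCaffrey CR2 with Satterthwaite degrees of freedom by default;
the Stata-style CR1 / df = G−1 convention is selectable).  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate one noisy animal phantom, fit its maps, then analyse a
simulated two-timepoint cohort:

```python
import dcequant as dq
from dcequant import phantom, cohort_stats

seq = dq.SequenceSpec()                 # 206 frames @ 4.8 s, 7 TRs, 4 b-values
aif = dq.default_aif(seq)               # bolus after the 20 baseline frames

truth = phantom.make_phantom_truth(shape=(16, 16, 3), tumour_radius=3.0,
                                   seed=7, noise_sigma=2.0)
dyn, _ = phantom.generate_dce_phantom(truth, seq, aif)
t1map = dq.fit_t1(phantom.generate_t1_series(truth, seq), seq.t1map_trs,
                  mask=truth.tumour_mask)
maps = dq.map_voxelwise(dyn, t1map, truth.tumour_mask, aif, seq)
print("ve", maps["ve"].summary())

tab = phantom.generate_cohort(phantom.CohortSpec(cohort=2, seed=11))
model = cohort_stats.fit_clustered_lm(tab, "ve")
for c in cohort_stats.scheffe_contrasts(model, pairs=[("NK+mAb", "NK"),
                                                      ("NK", "control")]):
    print(f"{c.contrast}: estimate={c.estimate:+.3f}, t={c.t:.2f}, "
          f"p_adj={c.p_adjusted:.4f}, CI [{c.ci_lower:.3f}, {c.ci_upper:.3f}]")
```

Output:

```
ve {'n': 64, 'mean': 0.29892589263606056, 'median': 0.29869316879319757, 'iqr': 0.010246465339469935}
NK+mAb vs NK: estimate=+0.260, t=7.70, p_adj=0.0002, CI [0.147, 0.372]
NK vs control: estimate=-0.087, t=-2.31, p_adj=0.2145, CI [-0.214, 0.039]
```

The 64 tumour voxels, generated with true v_e = 0.30, fit back to a
median v_e of 0.2987 — recovery error well inside the noise budget.  In
the cohort analysis the combination-therapy arm's v_e sits 0.26 above
the NK-monotherapy arm (a Scheffé-significant, positive contrast,
matching the generator's built-in effect: cell death opens the
interstitium), while the NK-vs-control contrast is negative but not
significant at this sample size.

A CLI wraps the same functionality:

```sh
dcequant simulate cohort --seed 4 --out out/
dcequant cohort-stats --table out/cohort.csv --response ve --cohort 1 --out out/stats
dcequant run --seed 1 --out out/study      # full phantom study, maps + tables
```

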