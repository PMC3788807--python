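# aslkin

Kinetic modelling of multi-inflow-time pulsed arterial spin labeling
(ASL) perfusion MRI, aimed at tissue with a substantial non-exchanging
vascular signal — brain tumours in particular, where tortuous and
dilated feeding vessels make the difference signal *biphasic* and bias
conventional perfusion estimates.

ASL labels arterial blood water magnetically and measures the
control-minus-label difference signal dM at a series of inflow times
(TIs).  The classical single-stage general kinetic model for pulsed ASL
writes

    dM(t) = 2 M0b · f · [ c ⊛ (r · m) ](t)

with delivery `c(t) = α e^(−t/T1b)` for `BAT ≤ t < BAT + τ` (else 0),
residue `r(u) = e^(−f u/λ)` and relaxation `m(u) = e^(−u/T1t)`, where
`f` is perfusion (CBF/6000, ml/g/s), `BAT` the bolus arrival time, `τ`
the bolus duration, `λ` the blood–tissue partition coefficient, and
T1b/T1t the blood/tissue longitudinal relaxation times.  It assumes the
label exchanges with tissue instantly on arrival — false wherever a
voxel contains arteries or arterioles whose blood perfuses tissue
elsewhere.

The **two-stage model** splits the voxel signal into a non-exchanging
*pre-capillary* component (signal fraction `f_pc`; boxcar residue of
duration `pcTT`, the pre-capillary transit time; relaxation with T1b)
and an exchanging *capillary* component (fraction `1 − f_pc`;
single-compartment residue; relaxation with T1t) arriving independently
at the capillary bolus arrival time `BAT_c`:

    dM(t) = f_pc · dM_pc(t; BAT, pcTT) + (1 − f_pc) · dM_cap(t; BAT_c)

Both models are fitted per voxel by multi-start Nelder–Mead least
squares and compared with the Bayesian information criterion
`BIC = N ln(RSS/N) + k ln N` (k = 2 vs 5); the central volume theorem
then yields a pre-capillary blood volume `pcCBV = CBF · pcTT / 60`
(ml/100 g), a promising marker of abnormal vascularity.

The package provides:

* closed-form signal models (`aslkin.kinetics`), cross-checked against
  numerical convolution;
* statsmodels-style model objects (`SingleStageModel`, `TwoStageModel`,
  `InversionRecoveryModel`) whose `fit()` returns results with
  parameter estimates, RSS, BIC, `summary()` and `plot()`;
* a biphasic-curve simulator and 4-D digital phantom
  (`aslkin.simulation`);
* a NIfTI volume pipeline — noise filtering, voxelwise T1t/M0t
  calibration from inversion-recovery data, dual-model fitting,
  parameter maps (`aslkin.pipeline`);
* ROI analysis with the high-pcCBV (90th percentile) tumour ROI and a
  per-subject CSV report (`aslkin.roi_analysis`);
* a CLI: `aslkin fit-voxel | fit-volume | simulate | roi-report`.

## Worked example

Simulate a gray-matter voxel whose signal is half pre-capillary and
half capillary (both sources generated with CBF = 50 ml/100 g/min), and
fit both models:

```python
from aslkin import (SimulationSpec, generate_fpc_series,
                    SingleStageModel, TwoStageModel, select_model)

curve = generate_fpc_series(SimulationSpec())[0.5]
single = SingleStageModel.from_curve(curve, m0b=1.0, t1t=1.1).fit()
two = TwoStageModel.from_curve(curve, m0b=1.0, t1t=1.1).fit()
print(two.summary())
print(f"single-stage CBF: {single.params['CBF']:.1f} ml/100 g/min (BIC {single.bic:.1f})")
print(f"preferred model:  {select_model(single, two)}")
```

```
Two-stage kinetic model
=======================
n TIs: 12    k: 5    converged: True
rss: 4.92789e-08    BIC: -219.3036
----------------------------------
  BAT          0.0754 s
  CBF         59.2905 ml/100 g/min
  pcTT         0.4586 s
  f_pc         0.3600 
  BAT_c        0.8145 s

single-stage CBF: 25.4 ml/100 g/min (BIC -171.5)
preferred model:  two
```

The biphasic curve defeats the single-stage model: its best fit is a
wide, flat curve with CBF pulled down to 25 ml/100 g/min, half the
generating value, and the BIC rejects it.  The two-stage model captures
both peaks and keeps CBF near the truth (the ~+18% excess over 50 is
the expected consequence of the simulation relaxing both sources with
the tissue T1 while the fitted pre-capillary stage uses the blood T1;
see `docs/methods.md`).

Volume-level use mirrors this via the CLI:

```sh
aslkin simulate --phantom spec.yaml --out phantom/
aslkin fit-volume --dm phantom/dm.nii.gz --ir phantom/ir.nii.gz \
    --brain-mask phantom/brain_mask.nii.gz --config phantom/config.yaml --out maps/
aslkin roi-report --maps maps/ --lesion phantom/lesion_mask.nii.gz --out report.csv
```

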