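# t1mt — why every T1-mapping method measures a different T1

Longitudinal relaxation of brain white matter at 3 T is reported anywhere
between ~0.6 and ~1.1 s, depending on which T1-mapping method produced the
number. `t1mt` implements the analysis that attributes this inter-method
variability to magnetization transfer (MT): simulate each pulse sequence with
a two-pool MT model, apply each method's *own* published mono-exponential
fitting procedure to the simulated signal, and ask whether a **single** set
of tissue parameters explains the spread of the resulting method-specific
T1 values.

It is aimed at quantitative-MRI researchers who want to

* simulate T1-mapping families (inversion recovery, saturation recovery,
  Look-Locker, variable flip angle, MP-RAGE, MP2RAGE) under mono-exponential,
  Graham-spectral and generalized Bloch spin models,
* reproduce the nested global least-squares fit of MT parameters to a roster
  of per-method T1 observations, with AIC/BIC model comparison, and
* replicate the analysis voxelwise on (synthetic) quantitative-MT parameter
  maps.

## The model

White matter is modelled as a free water pool (fraction `1 − m0s`,
relaxation times `T1f`, `T2f`) exchanging longitudinal magnetization at rate
`Rx` with a semi-solid macromolecular pool (fraction `m0s`, `T1s`,
`T2s ≈ 12.5 µs`, super-Lorentzian lineshape). Without RF the longitudinal
system relaxes biexponentially,

    d/dt [zf]   [−(1/T1f + Rx·m0s)      Rx·(1−m0s)       ] [zf]   [(1−m0s)/T1f]
         [zs] = [ Rx·m0s          −(1/T1s + Rx·(1−m0s)) ] [zs] + [ m0s/T1s   ]

During RF pulses the semi-solid pool is treated either as an exponential
saturation at Graham's spectral rate
`Rrf = (π/τ)∫|S(f)|² g(f) df` (pulse power spectrum × lineshape), or with
the generalized Bloch model, in which pulses *rotate* the semi-solid
magnetization and its transverse component relaxes non-exponentially with
the lineshape's Green's function `G(t)`:

    ∂t zs = −Re[ω(t) ∫₀ᵗ G(t−s) ω̄(s) zs(s) ds] + exchange + relaxation .

Each simulated method is then inverted with its own mono-exponential recipe
(IR with inversion efficiency, DESPOT1, Look-Locker T1* correction, MP2RAGE
dictionary, ...), and the outer fit minimizes
`Σ_m (T1_m^observed − T1_m^predicted(m0s, T1f, T1s))²` with `T2f`, `T2s` and
`Rx` held fixed for stability.

## Worked example

One tissue, three pulse sequences, three different "T1"s:

```python
>>> from t1mt.spin_models import WM_3T_FIT, make_mono_model
>>> from t1mt.meta_analysis import predict_t1_roster
>>> names = ["invivo_ir", "invivo_mp2rage", "invivo_vfa"]
>>> t1, _ = predict_t1_roster(WM_3T_FIT, names, "generalized_bloch")
>>> [round(float(v), 3) for v in t1]
[0.817, 0.88, 1.004]
>>> t1, _ = predict_t1_roster(make_mono_model(1.0), names, "mono")
>>> [round(float(v), 3) for v in t1]
[1.0, 1.0, 1.0]
```

With the fitted white-matter MT parameter set (`WM_3T_FIT`: m0s = 0.21,
T1f = 2.06 s, T1s = 0.26 s) the saturation-prepared inversion-recovery
protocol reads 0.82 s, the MP2RAGE 0.88 s and the variable-flip-angle
protocol 1.00 s — a 20% spread from identical tissue. Under mono-exponential
physics (second call) all three methods agree to 0.1%, so the spread is
created by MT, not by the fitting procedures. Across the full 25-method
roster the same parameter set spans 0.72–1.09 s (inter-method coefficient of
variation 8%), squarely inside the range reported for white matter.

The estimator-style interface fits MT parameters to an observed roster:

```python
>>> from t1mt.meta_analysis import GlobalMTFit
>>> from t1mt.synthetic_data import RosterSpec, generate_roster
>>> obs = generate_roster(RosterSpec(seed=7))          # synthetic "literature"
>>> est = GlobalMTFit().fit([o.method_id for o in obs],
...                         [o.observed_t1 for o in obs])
>>> round(est.params_.m0s, 3), round(est.params_.t1f, 2), round(est.params_.t1s, 3)
(0.201, 1.89, 0.262)
```

The same pipeline is available from the shell (`t1mt --help`): `simulate`,
`fit-global`, `synthesize-maps`, `synthesize-images`, `fit-maps`, `recover`
and `report` (observed-vs-predicted scatter and ROI bar figures).

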