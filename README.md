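# lrtcmr — free-running low-rank tensor cardiac MRI on a digital phantom

Staging irreversible tissue injury after a reperfused myocardial
infarction needs several cardiac MRI contrasts — cine for function, late
gadolinium enhancement for infarct size, early/late enhancement for
microvascular obstruction (MVO), and T2\*-weighted imaging for
intramyocardial hemorrhage (IMH). Conventional protocols acquire these
one at a time with ECG gating and breath-holds and can take an hour.
A free-running alternative acquires a single continuous, ungated,
free-breathing 3-D scan (~14 min) and reconstructs everything at once by
modelling the data as a six-dimensional low-rank tensor — one spatial
dimension and five temporal ones (cardiac phase, respiratory phase,
inversion time τ, echo time, gadolinium dynamics):

```
x(r; c, p, τ, e, g) = Σ_l  U_x[r, l] · Φ[l, (c, p, τ, e, g)]
```

with the temporal basis Φ estimated from frequently repeated k-space
centre "training" lines (completed by Tucker low-rank tensor completion
at ranks (8, 3, 5, 3, 4)) and the spatial factor `U_x` solved by
preconditioned conjugate gradient on the subspace-constrained
least-squares data-consistency problem. Cardiac and respiratory phases
come from the data itself (self-navigation), with no ECG and no
breath-holds.

This package implements that entire chain **on a synthetic dynamic
phantom** where ground truth is exact: a deformable left ventricle with
an infarct wedge, MVO core and IMH band, realistic motion and gadolinium
kinetics; the free-running acquisition schedule (TR 13.2 ms, six echoes,
5° flip, 192 segments per 2534.4 ms inversion block, Gaussian-density
Cartesian sampling, training line every 6 readouts); multi-coil k-space
simulation; self-navigated binning (24 cardiac × 4 respiratory phases ×
√time gadolinium bins); the LRT reconstruction; T1/T2\* mapping
(IR-FLASH variable-projection fit with exact flip-angle correction;
weighted mono-exponential T2\*); semi-automatic injury quantification;
and the method-comparison statistics of a two-arm study (Bland–Altman
bias/limits of agreement/reproducibility coefficient, regression with
95% CIs and R², paired t, sector-level ROC/AUC) against an idealized
gated comparator arm. It is aimed at people developing or teaching
free-running/motion-resolved reconstruction who want a controlled,
fully-inspectable testbed.

## Worked example

Build a phantom and the acquisition schedule, and report the ground
truth and sampling statistics:

```
$ lrtcmr simulate --grid 64,64,4 --seed 0 --out out/demo
events=65151 sampling_fraction=0.1160 -> out/demo
```

65151 readouts are the 14 min 20 s scan at TR 13.2 ms; the sampling
fraction is the filled share of the (ky, kz, cardiac, respiratory,
gadolinium) sampling tensor — at the protocol's native 192×14 matrix it
is ≈ 1.3%, i.e. the acquisition undersamples the complete tensor by
almost two orders of magnitude, which is what the low-rank model
absorbs. `out/demo/true_metrics.json` holds the phantom truth:

```
{"lvef_pct": 31.82, "edv_ml": 37.59, "esv_ml": 25.63,
 "mi_pct_lv": 15.83, "transmurality_pct": 72.0,
 "mvo_pct_lv": 5.0, "imh_pct_lv": 4.17}
```

— an ejection fraction of 31.8%, an infarct occupying 15.8% of the
myocardium at 72% transmural depth, with a 5 %LV no-reflow core and a
4.2 %LV hemorrhage, the scale of an acute reperfused infarction.

The full two-arm study (12 subjects, both arms, statistics):

```
$ lrtcmr cohort --n-subjects 12 --seed 0 --out out/study
```

writes tidy per-subject metrics, the agreement table (bias, limits of
agreement, reproducibility coefficient, slope/R², paired-t p) and the
sector-level detection scores. On the default run the two arms agree on
early MVO with a reproducibility coefficient of ≈ 1.3 %LV (R² 0.92,
slope 1.02) and on IMH with ≈ 1.6 %LV; sector-level detection AUCs are
0.98 (infarct), 0.87 (MVO) and 0.96 (hemorrhage). A single subject runs
in about half a minute; the cohort in about seven.

Library use mirrors the CLI: `build_phantom` / `build_schedule` /
`simulate_free_running` / `extract_nav` / `assign_bins` /
`estimate_subspaces` / `solve_spatial` / `ReconImage6D` compose the
reconstruction; `tissue_metrics` and `stats` quantify and compare.

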