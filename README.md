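# ephysdev

Analysis pipeline for the postnatal development of the electrical phenotype
of substantia nigra pars compacta (SNc) dopaminergic neurons, with a
calibrated synthetic-cohort generator standing in for raw recordings.

During the first four postnatal weeks these neurons switch from intrinsic
bursting to irregular firing and finally to the mature regular pacemaking,
while their passive and action-potential properties reorganize in two
distinct transitions.  `ephysdev` implements the complete quantitative
workflow needed to characterize that trajectory from current-clamp data:

1. **Feature extraction** — 16 electrophysiological parameters per neuron:
   ISI_avg (s) and CV_ISI (%) from ≥ 40 s of spontaneous firing; τ_m, R_in,
   C_m from mono-exponential fits of small hyperpolarizing pulses
   (τ_m = R_in·C_m); sag amplitude and post-inhibitory rebound delay; the
   averaged-AP waveform metrics (threshold at 5 % of peak dV/dt, amplitude,
   half-width, 10–90 % rise and decay slopes, AHP amplitude); and the f–I
   gains GS/GE with the spike-frequency-adaptation index SFA = GS/GE.
2. **Firing-pattern classification** — regular (CV_ISI < 20 %), irregular
   (20–80 %), bursting (> 80 %), with per-stage proportions.
3. **Stage statistics** — one-way ANOVA with protected post-hoc Tukey HSD
   per parameter over the 15 postnatal stage bins (P2–P3 … P28–P29),
   assembled into the "statistical stacking table" of all 105 stage pairs ×
   16 parameters with 4-level significance codes.
4. **Multivariate trajectory** — on the 8 spontaneous-activity parameters:
   mean-normalization, Ward agglomerative clustering with an automatic
   dissimilarity cut (centroids, central objects, class mean ages),
   covariance-(n) PCA with supplementary projection, the per-stage (F1, F2)
   trajectory, variability ellipses A = π·SD(PC1)·SD(PC2), and the
   SD(PC1)-vs-age correlation.
5. **Perturbation emulation** — apamin-like AHP block, low-dose-TTX sodium
   scaling and dynamic-clamp leak conductances
   (g = 1000/R_target − 1000/R_in nS, E_rev = −65 mV), with the induced
   phenotype shifts projected into the reference PCA space.

Because no recordings are deposited with the study this package
operationalizes, a **synthetic-cohort generator** (`ephysdev.synth`)
produces seeded, fully ground-truthed recordings whose per-stage parameter
distributions are calibrated to the published stage statistics
(`src/ephysdev/data/table1_calibration.csv`).  Generator and extractor are
bound by a round-trip contract — noiseless synthetic recordings must return
their ground truth within stated tolerances — which is the package's primary
correctness surface.  See `docs/methods.md` for the generative models and
numerical conventions.

## Worked example

```python
from ephysdev import (generate_cohort, extract_features, classify_firing,
                      sample_feature_cohort, normalize_features, ahc_ward,
                      auto_cut, pca_covariance)

# render a small cohort of synthetic neurons (voltage traces + protocols)
recs, truth = generate_cohort(plan=[("P2-P3", 5), ("P7", 5), ("P21-P23", 5)],
                              seed=42)
fv = extract_features(recs[-1])
print(fv.isi_avg, fv.cv_isi, classify_firing(fv.cv_isi))
```

For the last neuron (a P22 cell) this prints, feature by feature:

```
n0014 (P21-P23, P22):
  ISI_avg  0.42 s   CV_ISI 3.5 %  -> regular
  R_in 329 MOhm  C_m 389 pF  tau_m 128.1 ms
  AP: thr -41.7 mV  amp 61.5 mV  HW 1.60 ms  AHP 29.4 mV
  gain GS 6.5  GE 5.4  SFA 1.19
```

i.e. a mature pacemaker: low CV_ISI, fast large AP, deep AHP, little
adaptation.  Clustering a cohort of the three canonical stages on the 8
spontaneous-activity parameters recovers the three developmental classes:

```python
df = sample_feature_cohort(plan=[("P2-P3", 30), ("P7", 30), ("P21-P23", 30)],
                           seed=0)
m = normalize_features(df)
classes = auto_cut(ahc_ward(m), m)
model = pca_covariance(m)
```

```
classes: 3
  class 1: n=29  mean age P2.5 +- 0.5    (bursting)
  class 2: n=32  mean age P7.3 +- 3.0    (irregular)
  class 3: n=29  mean age P21.9 +- 0.7   (regular)
PC1+PC2 variance: 83.1 %
```

## Command line

```bash
ephysdev --seed 1 --out run1 all            # generate -> ... -> perturb
ephysdev --config cfg.yaml --out run2 extract
```

Subcommands `generate`, `extract`, `classify`, `stack`, `cluster`, `pca`,
`perturb`, `all`; the config file (JSON or YAML) carries stage plans, trace
durations, noise level and perturbation settings.  Identical config + seed
give byte-identical outputs.

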