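# rbefit

Dose–response analysis of radiation-induced apoptosis in the developing
brain of medaka (*Oryzias latipes*) embryos: curve fitting to
rosette-count data, relative biological effectiveness (RBE) estimation by
iso-effect dose inversion, and threshold-dose determination by ANOVA with
Bonferroni post-hoc tests.

## The problem

High-LET radiation (here iron-ions at 200 keV/μm) damages the developing
central nervous system far more effectively per Gy than low-LET X-rays.
In the underlying experiment, medaka embryos were irradiated at doses of
0–1.5 Gy and the apoptotic response of the optic tectum (OT) was
quantified as the number of AO-stained rosette-shaped apoptotic clusters
per OT, one count per embryo. This package provides the statistical
machinery for such data, for radiobiologists and biostatisticians:

* **Curve fitting with lack-of-fit diagnostics.** Candidate families
  y = cx, y = αx + βx², y = βx², and the shifted power y = (x + a)ᵖ + b
  (p odd; through-origin constraint b = −aᵖ) are fit by group-size-weighted
  least squares on the dose-group means and screened with the classical
  pure-error lack-of-fit F test on the replicated design:
  F = MS_lack / MS_pure on (k − n_params, N − k) df.
* **RBE by iso-effect inversion.** RBE(y) = D_reference(y) / D_test(y),
  the ratio of the reference (X-ray) to the test (iron-ion) dose producing
  the same effect level y; the shifted-power family inverts in closed form
  x = (y − b)^{1/p} − a (real odd root). A percentile bootstrap
  (embryo-level resampling within dose groups, refit per replicate) gives
  an uncertainty interval.
* **Threshold dose.** One-way ANOVA computed from group summaries
  (mean, SD, n) — algebraically identical to the raw per-embryo ANOVA —
  followed by pooled-MSE dose-vs-control t tests with Bonferroni
  correction; the threshold interval is (highest non-significant dose,
  lowest significant dose).
* **Synthetic experiments.** Negative-binomial count generator
  (variance μ + μ²/k, Poisson as k → ∞) driven by any fitted curve, for
  power/recovery studies without any external data.

The published group summaries and the two published regression curves are
bundled as `medaka_reference()`, so every analysis is reproducible from
the package alone.

## Worked example

```python
from rbefit import medaka_reference, rbe_profile, threshold_report

ref = medaka_reference()
for est in rbe_profile(ref.iron_curve, ref.xray_curve, [15.0, 45.0]):
    print(f"y={est.effect_level:g}: iron {est.dose_test:.4f} Gy, "
          f"X-ray {est.dose_reference:.4f} Gy, RBE={est.rbe:.4f}")

report = threshold_report(ref.iron, control_dose=0.0, level=0.01)
print(f"F={report.anova.F:.2f}, threshold "
      f"({report.threshold_low:g}, {report.threshold_high:g}) Gy")
```

prints

```
y=15: iron 0.7862 Gy, X-ray 3.3256 Gy, RBE=4.2302
y=45: iron 1.1984 Gy, X-ray 4.4376 Gy, RBE=3.7028
F=234.27, threshold (0.2, 0.5) Gy
```

Only 0.79 Gy of iron-ions produce the 15 clusters/OT that require 3.33 Gy
of X-rays — iron-ions are ~4.2× more effective per Gy at that effect
level (~3.7× at 45 clusters/OT, the ratio falling because the iron curve
is steeper). The ANOVA across the five iron-ion dose groups is decisive,
0.2 Gy is indistinguishable from control while 0.5 Gy is already highly
significant (Bonferroni-adjusted p ≈ 2×10⁻⁴), so the neurocytotoxic
threshold lies between 0.2 and 0.5 Gy.

The scripts in `examples/` walk through each capability: RBE reproduction,
threshold analysis, model selection under the lack-of-fit test, and a
simulate-and-bootstrap study. A thin CLI mirrors the pipeline:

```sh
rbefit rbe "shifted_power:a=0.95,p=5,b=-0.774" \
           "shifted_power:a=-0.9,p=3,b=0.729" --effect 15 --effect 45
rbefit threshold iron.csv --level 0.01
rbefit fit iron.csv --out fit.json
rbefit simulate config.json --out synthetic.csv
```

Datasets are plain CSV, either raw (`dose_gy,count`, one row per embryo)
or summary (`dose_gy,mean,sd,n`).

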