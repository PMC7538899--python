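# octlayers

Retinal sublayer thickness analysis for longitudinal OCT cohorts in
ABCA4-associated Stargardt disease (STGD1).

Stargardt disease is the most common inherited macular dystrophy, and
objective imaging biomarkers of its slow progression are needed for
clinical trials. Given macular OCT volumes segmented into 11 boundary
surfaces, this package quantifies the thickness of each retinal sublayer
(NFL, GCL, IPL, INL, OPL, ONL, EZ, OS, RPE, plus combined inner/outer
retina) within the three ETDRS subfields (1-mm center disc, 1–3 mm inner
ring, 3–6 mm outer ring), and provides the statistical machinery to

1. **assess measurement agreement** between automated segmentation and
   grader-corrected values with repeated-measures Bland–Altman limits of
   agreement — the bias μ and limits μ ± 1.96·√(σ²ₐ + σ²ᵦ + σ²ₑ) come
   from linear mixed models with random intercepts per patient and per
   eye within patient, and confidence intervals from a stratified
   patient-level cluster bootstrap;
2. **compare baseline thickness and rate of change** between STGD1
   patients and controls with the mixed model
   `thickness ~ years + group + years:group`, random `~ 1 + years` per
   patient and per eye (REML, unstructured 2×2 covariances), fit
   independently for each of 33 layer × subfield combinations with
   Bonferroni control (p < 0.05/33 ≈ 0.0015);
3. **simulate cohorts with known ground truth** that carry the same
   hierarchical structure, for calibration and parameter-recovery
   testing.

The REML engine is implemented in-repo (profiled likelihood with
analytic gradients, containment degrees of freedom); statsmodels and R
nlme are used only as independent cross-checks in the test suite.

## Worked example

```python
import octlayers as ol

# simulate a study-sized cohort (40 control / 63 STGD1 patients) with
# the reference ONL-center effect sizes
params = ol.CohortParams(
    fixed_effects={("ONL", "center"): ol.LayerEffects(
        control_mean=116.9, group_diff=-92.9, control_slope=0.0,
        slope_diff=-2.0)},
    seed=11,
)
table, truth = ol.simulate_cohort(params)

# average the two graders, fit the longitudinal model
records = ol.grader_average(table).query("source == 'grader_avg'")
model = ol.NestedMixedModel(
    fixed_terms=("intercept", "years", "group", "years:group"),
    random_structure="nested_intercept_slope",
).fit(records)
w = model.wald("group")
print(f"baseline difference: {w.estimate:.1f} um (SE {w.se:.1f}), "
      f"p = {w.p:.2e}, df = {w.df}")

# limits of agreement for the uncorrected segmentation
diff = ol.bland_altman_table(table)["uncorrected"]
loa = ol.bootstrap_loa(diff, "ONL", "center", n_boot=499, seed=1)
print(f"bias {loa.bias:.2f} um, LoA [{loa.loa_lower:.2f}, {loa.loa_upper:.2f}]")
```

prints

```
baseline difference: -89.4 um (SE 1.6), p = 3.04e-77, df = 101
bias 4.18 um, LoA [-1.82, 10.18]
```

i.e. the fitted group deficit recovers the generating −92.9 µm ONL
thinning within sampling error, and the agreement analysis recovers the
+4 µm systematic overestimate injected for the uncorrected ONL
segmentation.

A command-line pipeline wraps the same functions:

```sh
octlayers simulate --config docs/example_config.yaml --seed 7 --out-dir run/
octlayers agreement run/cohort.csv --comparison uncorrected --n-boot 1999
octlayers longitudinal run/cohort.csv --out-dir run/report
```

`longitudinal` writes `report_baseline.csv` / `report_rates.csv` with
one row per layer × subfield: group means ± SE with 95% CIs, the
baseline difference and rate difference with p-values, and the
Bonferroni significance flags.

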