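# mirecur

Serum microRNA profiling is an attractive, minimally invasive way to judge
whether a biliary tract cancer (BTC) patient who has undergone radical
surgery is likely to relapse. `mirecur` implements, as a tested and
reusable Python pipeline, the full analysis such a study requires:

1. **Array normalization** — per-array presence calls against a trimmed
   mean of negative-control probes, background subtraction, cross-array
   quantile normalization, and rescaling so that each array's mean over a
   set of stably expressed internal-control miRNAs hits a preset value.
2. **Candidate selection funnel** — starting from every miRNA on the
   panel: (i) detected in at least half the pre-operative samples;
   (ii) paired pre/post-surgery t test, split into *pre-high* and
   *pre-low* pools; (iii) median-split log-rank test on recurrence-free
   survival (RFS); (iv) a three-time-point trajectory rule (fall after
   surgery, re-rise at recurrence, concentrated in relapsers; mirrored for
   pre-low candidates).
3. **Recurrence-predictive index** — Fisher's linear discriminant over
   every subset of the candidates. The index is the affine score
   *s(x) = Σ cᵢ·xᵢ + b* along the discriminant direction
   *w ∝ S_w⁻¹(μ_rec − μ_non)*; a patient with *s ≥ τ* (the midpoint of the
   projected class means) is predicted to relapse. Panels are ranked by
   training accuracy, AUC, then size; sensitivity/specificity and
   Mann-Whitney AUC are reported per panel, alongside dichotomized CEA and
   CA19-9 baselines.
4. **Survival analysis** — Kaplan-Meier curves and log-rank tests for the
   index-defined groups on RFS and overall survival, plus univariate Cox
   models and a multivariate model over all covariates with univariate
   hazard ratio ≥ 2.

Because per-patient microarray studies of this kind are small and their
raw data often incompletely deposited, the package ships a first-class
**synthetic-cohort generator**: 22 patients × 3 time points by default,
a 2565-miRNA panel with 47 internal controls and 100 negative-control
probes, planted up- and down-regulated recurrence markers with exported
ground truth, per-array scale factors and additive background, and
exponential, censored RFS/OS times. Every downstream stage is exercised
and validated against this generator.

## Worked example

```python
import mirecur as m

cfg = m.SimulationConfig(seed=1)                      # the default design
panel, cohort, samples, raw, truth = m.simulate(cfg)
norm = m.normalize_chain(raw, panel)                  # background -> QN -> IC -> log2
report = m.run_funnel(norm, samples, cohort)
print(report.counts())
```

prints

```
{'input': 2565, 'detected': 1207, 'paired_significant': 65,
 'pre_high': 26, 'pre_low': 39, 'rfs_significant_pre_high': 4,
 'rfs_significant_pre_low': 6, 'final_up': 4, 'final_down': 3, 'final': 7}
```

i.e. of 2565 miRNAs, 1207 were detected in most pre-operative samples, 65
changed significantly across surgery, 10 of those also split RFS at their
pre-operative median, and 7 survived the trajectory rule — including all
six planted markers with the correct direction labels (4 up, 2 down, one
false positive). Fitting the index on the final candidates:

```python
cands = sorted(report.final_up | report.final_down)
pre = {s.patient_id: s.sample_id for s in samples if s.time_point == m.TimePoint.PRE}
X = norm.values.loc[cands, [pre[p] for p in cohort["patient_id"]]].T
X.index = cohort["patient_id"]
search = m.exhaustive_search(X, cohort["group"].to_numpy(), cands, 3)
print(search.best().metrics)
# {'accuracy': 1.0, 'sensitivity': 1.0, 'specificity': 1.0, 'auc': 1.0}
```

With the default planted effect (1.5 log2 units) the best panel separates
the simulated groups perfectly; the log-rank test on the index split gives
p ≈ 4.1e-06. The two published index formulas (members, coefficients,
intercepts 1.09 / 3.14, cut-offs 0.671 / 0.646) are available via
`m.published_indices()` and can be applied to new expression vectors with
`m.apply_index`.

The same workflow is available from the shell:

```sh
mirecur simulate --out-dir sim/ --seed 1
mirecur normalize --signals sim/signals_raw.tsv --panel sim/panel.tsv --out sim/norm.tsv
mirecur select --signals sim/norm.tsv --samples sim/samples.csv --cohort sim/cohort.csv --out sim/funnel.json
mirecur fit-index --signals sim/norm.tsv --samples sim/samples.csv --cohort sim/cohort.csv \
    --candidates sim/funnel.json --out sim/models
mirecur run-all --out-dir run/ --seed 1     # everything at once
```

Deposited GEO series-matrix files can be ingested with
`m.read_geo_series_matrix`; time-point annotations are mapped through the
editable vocabulary `mirecur.io.GEO_TIMEPOINT_VOCABULARY`.

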