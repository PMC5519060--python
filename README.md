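# swiddenscape

Reconstruction of shifting-cultivation land-use history from irregular
optical-satellite time series, with the downstream landscape statistics and a
synthetic riverine-landscape simulator for validation.

## The problem

In riverine Amazonia, agriculture is dominated by shifting cultivation:
fields are opened from forest by slash-and-burn (a *clear-cut*), cropped for
about two years (the *swidden* phase), then left to regrow as secondary
forest (the *fallow* phase) until the next cut.  The land-use intensity of a
landscape is written into each field's chronology — how many swidden-fallow
cycles it went through, how long its fallows lasted, and how those quantities
vary with access (distance to residences), village size, and calendar time.

Those chronologies can be read from three decades of Landsat observations.
The pipeline implemented here:

1. **NDMI series assembly** — land cover is tracked with the Normalized
   Difference Moisture Index, NDMI = (NIR − SWIR)/(NIR + SWIR), which drops
   abruptly at a clear-cut and recovers during regrowth.  Cloud-masked
   observations are carried as invalid flags, never dropped.
2. **Trajectory segmentation** — neighbouring pixels with similar NDMI
   trajectories (RMS distance after interpolation onto a common time grid)
   are grouped into segments ("fields"), the unit of all later analysis.
3. **Breakpoint detection** — each segment's series is fit with a piecewise
   linear + annual harmonic model.  Break count k and positions minimize

   `BIC(k) = n·ln(RSS/n) + p_k·ln(n)`, `p_k = (k+1)·p_seg + k`

   over all placements with at least `h_min` valid observations per temporal
   segment, solved *exactly* by dynamic programming over candidate splits.
4. **Break classification** — a random forest over each break's magnitude,
   slopes and preceding duration separates clear-cuts from
   abandonment/stabilization breaks, with out-of-bag (OOB) validation; a
   six-class random-forest classification of the start-of-record reference
   scene identifies which fields were still old-growth forest then.
5. **History metrics** — per field: cycle count, fallow periods (inter-cut
   interval minus the 2-yr cropping period), current fallow age; per year:
   cultivated and deforested area and their OLS trends; cumulative
   age/intensity curves.
6. **Statistics** — a from-scratch random-intercept linear mixed model
   (profiled ML/REML, AIC selection, containment degrees of freedom) relates
   fallow age and cycle counts to distance-to-residences and village-size
   class with communities as the random factor; recurrent-event
   Kaplan-Meier curves with right censoring and a log-rank test compare
   fallow survival between two calendar periods.

Because no satellite archive is needed, everything runs on a synthetic
landscape generator (`swiddenscape.synthetic`) that emulates the study
system: 16-day acquisitions over 1984.5–2015.6 with 50 % missingness, abrupt
NDMI drops with exponential-saturating recovery, annual seasonality, and
lognormal fallow lengths whose log-mean is linear in distance, village-size
class, and a calendar-period indicator.

## Worked example

```python
from swiddenscape import benchmark_config, run_pipeline

report = run_pipeline(benchmark_config())   # 300 fields, 31 communities, seed 42
print(report["benchmark"])
print(report["survival"]["logrank"])
```

On the standard benchmark landscape this prints (about 100 s on one core):

```
{'n_fields': 300, 'nrmse_cycles': 0.0198, 'recall': 0.9992, 'precision': 0.9992,
 'n_fallow_pairs': 934, 'nrmse_fallow': 0.0053, 'mae_fallow_yr': 0.0162}
{'chi2': 80.28, 'df': 1, 'p_value': 3.3e-19}
```

Reading: over 300 fields the pipeline recovered per-field cycle counts with
a normalized RMSE of 0.020 and fallow lengths to 0.016 yr mean absolute
error (99.9 % of true cuts matched within a year), and the log-rank test
detects the generator's shorter second-period fallows decisively.  The mixed
models in `report["lmm"]` recover the generating sign structure: fallow age
rises with distance to residences, cycle counts fall with distance and rise
with village size.

The same run is available from the shell:

```bash
swiddenscape run-all --seed 42 --out run/       # full report + artifacts
swiddenscape benchmark --seed 42                # accuracy metrics only
swiddenscape scene-oob --seed 42                # reference-scene OOB error
```

## Layout

- `src/swiddenscape/synthetic.py` — landscape generator (ground truth)
- `src/swiddenscape/raster.py` — NDMI, series containers, masks, TIFF I/O
- `src/swiddenscape/segmentation.py` — trajectory distance, region growing
- `src/swiddenscape/breaks.py` — BIC/DP piecewise fits, break features
- `src/swiddenscape/classify.py` — break & reference-scene random forests
- `src/swiddenscape/history.py` — cycles, fallows, annual areas, trends
- `src/swiddenscape/mixedlm.py`, `stats.py` — sampling, covariates, LMM
- `src/swiddenscape/survival.py` — records, Kaplan-Meier, log-rank
- `src/swiddenscape/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model details, parameter choices, limitations
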