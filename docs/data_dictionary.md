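# Data dictionary

Columns of the files written by `run_pipeline(..., outdir=...)` and
`swiddenscape generate`.

## histories.csv — one row per active field (segment with ≥ 1 clear-cut)

| column | type | meaning |
|---|---|---|
| field_id | int | segment id (dense from 1 in the segment map) |
| area_ha | float | pixel count × 0.09 ha (30 m pixels) |
| cover_1984 | int | cover class at the reference date (1 = old-growth, 2 = agricultural) |
| n_cycles | int | clear-cut breaks in the analysis window |
| current_age | float, yr | census date − last clear-cut |
| cropping | bool | census within the 2-yr cropping phase of the last cut |
| clearcut_dates | str | ';'-joined decimal years, ascending |

## annual_series.csv — one row per calendar year

| column | type | meaning |
|---|---|---|
| year | int | calendar year (floor of break decimal year) |
| cultivated_ha | float | area of fields with ≥ 1 break that year (once per field) |
| deforested_ha | float | area of fields whose FIRST break is that year and that were old-growth at the reference date |
| pct_deforested | float | 100 × deforested / cultivated; empty when cultivated = 0 |

## records.csv — one row per survival interval

| column | type | meaning |
|---|---|---|
| field_id | int | segment id |
| duration | float, yr | at-risk time (fallow age for inter-cut spells) |
| event | bool | True = cut observed; False = right-censored at window end |
| period | str | P1/P2 by the calendar date the at-risk clock starts |
| kind | str | "initial" (old-growth spell from window start) or "fallow" |

## segments.txt

Space-separated integer grid (rows × cols) of segment ids; 0 = excluded
(old-growth at the final date).

## ndmi_stack.* (also from `swiddenscape generate`)

- `ndmi_stack.tif` — float32 TIFF, bands = acquisitions (T × H × W)
- `ndmi_stack.valid.tif` — uint8 TIFF validity mask, same shape
- `ndmi_stack.dates.csv` — index, decimal_year, iso_date per band
- `ndmi_stack.transform.json` — x/y origin (m) and pixel size (m)

## truth_fields.csv (`swiddenscape generate`)

| column | meaning |
|---|---|
| field_id | generator field id |
| community | id of nearest community |
| distance_km | Euclidean distance to that community's centre |
| village_class | isolated / small / medium / large (household bins 1–3/4–10/11–29/≥30) |
| cover_1984 | true cover class at the reference date |
| area_ha | field area |
| clearcut_dates | ';'-joined true cut dates within the record |

## communities.geojson

Point features in the geographic frame (km); properties: id, households,
village_class.

## report.json — selected keys

- `counts` — per-stage record counts (segments, breaks, clear-cuts, active
  fields, sampled fields, total cycles)
- `benchmark` — nrmse_cycles, nrmse_fallow, mae_fallow_yr, recall,
  precision, n_fallow_pairs (detected vs generator truth, ±1 yr matching)
- `trends` — slope, adj_r2, p_value, df per annual series
- `cumulative` — ages/cycle counts at 50 % and 80 % of active area
- `lmm` — per response: terms, beta, se, df, t, p, variance components, AIC
- `survival` — record counts, log-rank chi2/df/p, KM survival at integer
  ages per period, per-period completed-fallow mean/sd and share ≥ 10 yr
- `break_classifier_oob` — OOB error of the break classifier (if trained)
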