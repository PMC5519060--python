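"""End-to-end orchestration: generate -> segment -> detect -> classify ->
derive histories -> landscape statistics, with one root seed and a
machine-readable run report.

All randomness derives from a single SeedSequence, spawned per stage, so an
identical (config, seed) pair yields an identical report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .breaks import all_break_records, detectable_window, fit_piecewise
from .classify import (CLEAR_CUT, classify_break, classify_reference_image,
                       label_breaks_from_truth, train_break_classifier)
from .evaluate import evaluate_against_truth
from .history import (annual_area_series, build_field_history,
                      cumulative_distributions, trend_regression)
from .raster import mask_final_old_growth
from .segmentation import segment_landscape, segment_mean_series
from .stats import distance_to_residences, fit_lmm, sample_fields, sampled_table, select_model
from .survival import (P1, P2, build_survival_records, fallow_age_summary,
                       km_estimate, logrank_test)
from .synthetic import (GeneratorConfig, OLD_GROWTH, generate_landscape,
                        render_reference_scene, simulate_stack)


@dataclass
class PipelineParams:
    """Detection and analysis settings layered on top of the generator config."""

    threshold_tau: float = 0.1
    connectivity: int = 4
    grid_step_yr: float = 0.25
    h_min: int | None = None          # None: one year of expected valid observations
    max_breaks: int = 8
    seasonal: bool = True
    match_tolerance_yr: float = 1.0
    split_year: float = 2001.0
    window: tuple | None = None       # None: (span start + 3 yr, census)
    n_sample_points: int = 5000
    min_spacing_m: float = 70.0
    rf_trees: int = 500


def benchmark_config() -> GeneratorConfig:
    """The standard synthetic benchmark landscape (the generator defaults)."""
    return GeneratorConfig()


def _default_h_min(cfg: GeneratorConfig) -> int:
    per_yr = 365.25 / cfg.acquisition_interval_days * (1.0 - cfg.missingness_prob)
    return max(int(round(per_yr)), 5)


def _majority(arr: np.ndarray) -> int:
    vals, counts = np.unique(arr, return_counts=True)
    return int(vals[np.argmax(counts)])


def run_pipeline(config: GeneratorConfig, params: PipelineParams | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the full synthetic-mode pipeline and return the run report.

    The report carries per-stage counts, benchmark metrics against the
    generator truth, trend regressions, the mixed-model tables, Kaplan-Meier
    summaries and the log-rank test.
    """
    params = params or PipelineParams()
    cfg = config
    cfg.validate()
    if cfg.n_fields < 1:
        raise ValueError("config must request at least one field")
    seq = np.random.SeedSequence(cfg.seed)
    r_stack, r_sample, r_clf = [np.random.default_rng(s) for s in seq.spawn(3)]
    clf_seed = int(r_clf.integers(0, 2**31 - 1))

    truth = generate_landscape(cfg)
    stack = simulate_stack(truth, r_stack)
    h_min = params.h_min if params.h_min is not None else _default_h_min(cfg)
    window = params.window or (cfg.time_span[0] + 3.0, cfg.census_year)

    include = mask_final_old_growth(truth.final_cover(), OLD_GROWTH)
    segmap = segment_landscape(stack, include, params.threshold_tau,
                               params.connectivity, params.grid_step_yr)

    field_map = truth.field_label_map()
    gh, gw = truth.grid_shape
    ext_x, ext_y = cfg.landscape_extent_km

    def grid_to_km(row: float, col: float) -> tuple[float, float]:
        return ((col + 0.5) / gw * ext_x, (row + 0.5) / gh * ext_y)

    # --- break detection per segment ------------------------------------
    seg_breaks: dict[int, list] = {}
    seg_field: dict[int, int] = {}
    n_undetectable = 0
    for sid in range(1, segmap.n_segments + 1):
        px = segmap.pixels_of(sid)
        series = segment_mean_series(px, stack)
        fit = fit_piecewise(series, h_min=h_min, max_breaks=params.max_breaks,
                            seasonal=params.seasonal)
        if fit.undetectable:
            n_undetectable += 1
        recs = [r for r in all_break_records(fit) if window[0] <= r.time <= window[1]]
        seg_breaks[sid] = recs
        seg_field[sid] = _majority(field_map[px[:, 0], px[:, 1]])

    # --- truth-labelled classifier training ------------------------------
    feats, labels = [], []
    for sid, recs in seg_breaks.items():
        if not recs:
            continue
        fid = seg_field[sid]
        true_cuts = truth.fields[fid - 1].clearcut_dates if fid else np.empty(0)
        lab = label_breaks_from_truth(np.array([r.time for r in recs]), true_cuts,
                                      params.match_tolerance_yr)
        for r, l in zip(recs, lab):
            feats.append(r.features())
            labels.append(l)
    model = None
    if len(labels) >= 20 and len(set(labels)) >= 2:
        model = train_break_classifier(np.asarray(feats), labels, seed=clf_seed,
                                       n_trees=params.rf_trees)
    for recs in seg_breaks.values():
        for r in recs:
            r.label = classify_break(model, r)

    # --- field histories (segment level) ---------------------------------
    histories = []
    for sid, recs in seg_breaks.items():
        cuts = sorted(r.time for r in recs if r.label == CLEAR_CUT)
        # a cut cannot recur within the cropping phase
        dedup: list[float] = []
        for c in cuts:
            if not dedup or c - dedup[-1] > cfg.cropping_period_yr:
                dedup.append(c)
        if not dedup:
            continue
        fid = seg_field[sid]
        cover = truth.fields[fid - 1].cover_1984 if fid else OLD_GROWTH
        histories.append(build_field_history(
            dedup, cover, cfg.census_year, cfg.cropping_period_yr,
            field_id=sid, area_ha=float(segmap.area_ha[sid - 1])))

    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "h_min": h_min,
        "window": list(window),
        "counts": {
            "fields_truth": len(truth.fields),
            "segments": int(segmap.n_segments),
            "segments_undetectable": n_undetectable,
            "breaks_detected": int(sum(len(v) for v in seg_breaks.values())),
            "breaks_clear_cut": int(sum(1 for v in seg_breaks.values()
                                        for r in v if r.label == CLEAR_CUT)),
            "active_fields": len(histories),
            "total_cycles": int(sum(h.n_cycles for h in histories)),
        },
        "break_classifier_oob": model.oob_error if model else None,
    }

    # --- benchmark metrics against truth (field level) --------------------
    det_by_field: dict[int, list] = {}
    for h in histories:
        fid = seg_field[h.field_id]
        if fid:
            det_by_field.setdefault(fid, []).extend(h.clearcut_dates.tolist())
    truth_by_field = {}
    for f in truth.fields:
        c = f.clearcut_dates
        truth_by_field[f.id] = c[(c >= window[0]) & (c <= window[1])]
    report["benchmark"] = evaluate_against_truth(
        {k: np.sort(v) for k, v in det_by_field.items()}, truth_by_field,
        params.match_tolerance_yr, cfg.cropping_period_yr)

    # --- landscape summaries ----------------------------------------------
    if histories:
        annual = annual_area_series(histories, OLD_GROWTH)
        trends = {}
        for col in ("cultivated_ha", "deforested_ha", "pct_deforested"):
            try:
                trends[col] = trend_regression(annual["year"], annual[col])
            except ValueError:
                trends[col] = None
        report["trends"] = trends
        cdfs = cumulative_distributions(histories)
        report["cumulative"] = {k: cdfs[k] for k in
                                ("age_p50", "age_p80", "cycles_p50", "cycles_p80",
                                 "total_active_area_ha")}
    else:
        annual = None
        report["trends"] = report["cumulative"] = None

    # --- sampling + mixed models -----------------------------------------
    hist_by_seg = {h.field_id: h for h in histories}
    comm_xy = np.asarray([c.location_km for c in truth.communities])
    samples = sample_fields(segmap, r_sample, params.n_sample_points,
                            params.min_spacing_m, cfg.pixel_size_m)
    samples = [s for s in samples if s.field_id in hist_by_seg]
    for s in samples:
        h = hist_by_seg[s.field_id]
        s.current_age = h.current_age
        s.n_cycles = h.n_cycles
        cen = segmap.centroids[s.field_id - 1]
        cen_km = grid_to_km(cen[0], cen[1])
        s.distance_km = distance_to_residences(cen_km, comm_xy)
        ci = int(np.argmin(np.hypot(comm_xy[:, 0] - cen_km[0],
                                    comm_xy[:, 1] - cen_km[1])))
        s.community_id = truth.communities[ci].id
        s.village_class = truth.communities[ci].village_class
    table = sampled_table(samples)
    report["counts"]["sampled_fields"] = len(table)

    report["lmm"] = {}
    term_sets = [
        ["distance_km"],
        ["distance_km", "village_class"],
        ["distance_km", "village_class", "distance_km:village_class"],
    ]
    for resp in ("current_age", "n_cycles"):
        candidates = []
        for terms in term_sets:
            try:
                candidates.append(fit_lmm(table, resp, terms, "community", "ML"))
            except (ValueError, np.linalg.LinAlgError):
                continue  # e.g. a village class unsampled in a small landscape
        try:
            if not candidates:
                raise ValueError("no mixed-model candidate could be fit")
            best = select_model(candidates)
            report["lmm"][resp] = {
                "terms": best.terms,
                "beta": best.beta.tolist(),
                "se": best.se.tolist(),
                "df": best.df.tolist(),
                "t": best.t_values.tolist(),
                "p": best.p_values.tolist(),
                "sigma2_group": best.sigma2_group,
                "sigma2_resid": best.sigma2_resid,
                "aic_reml": best.aic,
            }
        except ValueError as exc:
            report["lmm"][resp] = {"error": str(exc)}

    # --- survival ---------------------------------------------------------
    records = build_survival_records(histories, window, params.split_year,
                                     cfg.cropping_period_yr)
    rec1 = [r for r in records if r.period == P1]
    rec2 = [r for r in records if r.period == P2]
    surv: dict = {"n_records": len(records), "n_P1": len(rec1), "n_P2": len(rec2)}
    if rec1 and rec2:
        km1, km2 = km_estimate(rec1), km_estimate(rec2)
        surv["logrank"] = logrank_test(rec1, rec2)
        ages = np.arange(1.0, 13.0)
        surv["km_at_ages"] = {"ages": ages.tolist(),
                              "P1": np.asarray(km1.sf(ages)).tolist(),
                              "P2": np.asarray(km2.sf(ages)).tolist()}
        surv["median_like"] = {
            "S6_P1": km1.sf(6.0), "S6_P2": km2.sf(6.0)}
        for per, rec in ((P1, rec1), (P2, rec2)):
            try:
                s = fallow_age_summary(rec)
                surv[f"fallow_{per}"] = {"n": s["n"], "mean": s["mean"],
                                         "sd": s["sd"], "frac_ge_10yr": s["frac_ge_long"]}
            except ValueError:
                surv[f"fallow_{per}"] = None
    report["survival"] = surv

    if outdir is not None:
        _write_artifacts(Path(outdir), report, histories, annual, records, segmap, stack)
    return report


def reference_scene_benchmark(config: GeneratorConfig | None = None,
                              seed: int = 42, n_train: int = 5000,
                              date: float = 1984.6, n_trees: int = 500) -> dict:
    """Render the six-class reference scene and report the classifier's
    out-of-bag error (%), with the pairwise error matrix."""
    cfg = config or benchmark_config()
    seq = np.random.SeedSequence(seed)
    r_truth, r_scene, r_pick = [np.random.default_rng(s) for s in seq.spawn(3)]
    truth = generate_landscape(cfg)
    bands, labels = render_reference_scene(truth, date, cfg, r_scene)
    h, w = labels.shape
    # guarantee every class in training: stratified random picks
    idx_all = np.column_stack(np.unravel_index(np.arange(h * w), (h, w)))
    chosen = []
    flat = labels.ravel()
    for cls in range(1, 7):
        members = np.nonzero(flat == cls)[0]
        take = max(1, int(round(n_train * len(members) / flat.size)))
        chosen.append(r_pick.choice(members, size=min(take, len(members)),
                                    replace=False))
    chosen = np.concatenate(chosen)[:n_train]
    train_idx = idx_all[chosen]
    train_labels = flat[chosen]
    class_map, oob, pw = classify_reference_image(
        bands, train_idx, train_labels, seed=int(seed), n_trees=n_trees)
    return {"oob_error_pct": 100.0 * oob, "pairwise_error_max": float(pw.max()),
            "n_train": int(len(train_labels)),
            "map_accuracy": float(np.mean(class_map == labels))}


def _write_artifacts(outdir: Path, report: dict, histories, annual, records,
                     segmap, stack) -> None:
    import pandas as pd

    from .raster import write_stack

    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_safe)
    if histories:
        pd.DataFrame([{
            "field_id": h.field_id, "area_ha": h.area_ha, "cover_1984": h.cover_1984,
            "n_cycles": h.n_cycles, "current_age": h.current_age,
            "cropping": h.cropping_flag,
            "clearcut_dates": ";".join(f"{d:.3f}" for d in h.clearcut_dates),
        } for h in histories]).to_csv(outdir / "histories.csv", index=False)
    if annual is not None:
        annual.to_csv(outdir / "annual_series.csv", index=False)
    if records:
        pd.DataFrame([{"field_id": r.field_id, "duration": r.duration,
                       "event": r.event, "period": r.period, "kind": r.kind}
                      for r in records]).to_csv(outdir / "records.csv", index=False)
    np.savetxt(outdir / "segments.txt", segmap.labels, fmt="%d")
    write_stack(stack, outdir / "ndmi_stack")


def _json_safe(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
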