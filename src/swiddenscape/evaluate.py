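"""Benchmark metrics: detected chronologies against generator truth.

Detected clear-cut dates are matched one-to-one to true dates within a dating
tolerance (greedy, smallest dating error first).  Reported metrics:

* NRMSE of per-field cycle counts (RMSE / mean true count), over fields with
  at least one true cut;
* NRMSE and MAE of fallow-period lengths over matched fallow pairs — a pair
  is formed whenever two consecutive true cuts are both matched, the fallow
  being the inter-cut interval minus the cropping period on both sides;
* break recall and precision at the dating tolerance.
"""

from __future__ import annotations

import numpy as np


def _match(det: np.ndarray, true: np.ndarray, tol: float) -> list[tuple[int, int]]:
    pairs = [(abs(d - t), i, j) for i, d in enumerate(det)
             for j, t in enumerate(true) if abs(d - t) <= tol]
    used_d: set[int] = set()
    used_t: set[int] = set()
    out = []
    for _, i, j in sorted(pairs):
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        out.append((j, i))  # (true index, detected index)
    return sorted(out)


def evaluate_against_truth(detected: dict, truth: dict, tolerance_yr: float = 1.0,
                           cropping_yr: float = 2.0) -> dict:
    """Compare detected and true chronologies, keyed by field id.

    detected, truth : mapping field id -> ascending array of clear-cut dates.
    Fields present in ``truth`` but absent from ``detected`` count as empty
    detections.
    """
    if not set(truth):
        raise ValueError("no overlapping fields between truth and detections")
    cyc_err = []
    true_counts = []
    fallow_true: list[float] = []
    fallow_det: list[float] = []
    n_true = n_det = n_matched = 0
    for fid, tdates in truth.items():
        tdates = np.asarray(tdates, dtype=float)
        ddates = np.asarray(detected.get(fid, ()), dtype=float)
        n_true += len(tdates)
        n_det += len(ddates)
        if len(tdates) == 0:
            continue
        cyc_err.append(len(ddates) - len(tdates))
        true_counts.append(len(tdates))
        pairs = _match(ddates, tdates, tolerance_yr)
        n_matched += len(pairs)
        for (j0, i0), (j1, i1) in zip(pairs[:-1], pairs[1:]):
            if j1 == j0 + 1:  # consecutive true cuts, both matched
                fallow_true.append(max(tdates[j1] - tdates[j0] - cropping_yr, 0.0))
                fallow_det.append(max(ddates[i1] - ddates[i0] - cropping_yr, 0.0))
    if not true_counts:
        raise ValueError("truth contains no cut fields")
    cyc_err = np.asarray(cyc_err, dtype=float)
    mean_cycles = float(np.mean(true_counts))
    out = {
        "n_fields": len(true_counts),
        "nrmse_cycles": float(np.sqrt(np.mean(cyc_err ** 2)) / mean_cycles),
        "recall": n_matched / n_true if n_true else np.nan,
        "precision": n_matched / n_det if n_det else np.nan,
        "n_fallow_pairs": len(fallow_true),
    }
    if fallow_true:
        ft = np.asarray(fallow_true)
        fd = np.asarray(fallow_det)
        out["nrmse_fallow"] = float(np.sqrt(np.mean((fd - ft) ** 2)) / ft.mean())
        out["mae_fallow_yr"] = float(np.mean(np.abs(fd - ft)))
    else:
        out["nrmse_fallow"] = np.nan
        out["mae_fallow_yr"] = np.nan
    return out
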