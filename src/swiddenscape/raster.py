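"""Dated raster series: NDMI computation, per-pixel series assembly, masking, I/O.

The atomic signal of the pipeline is an :class:`AcquisitionSeries` — one
location's dated, gappy vegetation-index observations.  Invalid observations
(clouds, sensor gaps) are retained with a ``valid`` flag rather than dropped,
so downstream detectability margins can count valid observations explicitly.

Grid geometry convention: 0-based (row, col) indices; geographic placement is
carried by an affine-style transform ``(x_origin_m, y_origin_m, pixel_size_m)``
kept alongside arrays, never baked into indices.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class AcquisitionSeries:
    """One pixel's (or segment's) dated NDMI observations.

    times
        Strictly increasing decimal years.
    values
        NDMI per time; only meaningful where ``valid``.
    valid
        Boolean flag per time; False marks cloud/missing observations.
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.valid)):
            raise ValueError("times, values, valid must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        ok = self.values[self.valid]
        if ok.size and np.nanmax(np.abs(ok)) > 1 + 1e-9:
            raise ValueError("valid NDMI values must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_times(self) -> np.ndarray:
        return self.times[self.valid]

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass
class SeriesStack:
    """A co-registered stack of dated observations over a pixel grid.

    values : (T, H, W) float array
    valid  : (T, H, W) bool array
    times  : (T,) strictly increasing decimal years
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    transform: tuple[float, float, float] = (0.0, 0.0, 30.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(np.unique(self.times)) != len(self.times):
            raise ValueError("duplicated acquisition dates in stack")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("acquisition dates must be sorted ascending")
        if self.values.shape != self.valid.shape or self.values.shape[0] != len(self.times):
            raise ValueError("grid mismatch between values, valid and times")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def series_at(self, row: int, col: int) -> AcquisitionSeries:
        return AcquisitionSeries(self.times, self.values[:, row, col], self.valid[:, row, col])


def compute_ndmi(nir: np.ndarray | float, swir: np.ndarray | float) -> np.ndarray | float:
    """Normalized Difference Moisture Index, (NIR - SWIR) / (NIR + SWIR).

    Defined for non-negative reflectances; where ``nir + swir == 0`` the value
    is undefined and returned as NaN so it propagates as a masked observation.
    """
    nir = np.asarray(nir, dtype=float)
    swir = np.asarray(swir, dtype=float)
    if np.any(nir < 0) or np.any(swir < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir + swir
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (nir - swir) / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def assemble_series(stack: SeriesStack) -> np.ndarray:
    """Explode a stack into a (H, W) object array of per-pixel AcquisitionSeries.

    Never invents observations: the sum of valid flags over all series equals
    the number of unmasked pixel-date samples in the stack.
    """
    h, w = stack.shape
    out = np.empty((h, w), dtype=object)
    for r in range(h):
        for c in range(w):
            out[r, c] = stack.series_at(r, c)
    return out


def mask_final_old_growth(final_cover: np.ndarray, old_growth_code: int,
                          known_codes: set[int] | None = None) -> np.ndarray:
    """Inclusion mask excluding pixels classed old-growth at the final date.

    Only areas that went through some land-use change are analysed; pixels
    still old-growth in the most recent scene carry no trajectory information.
    """
    final_cover = np.asarray(final_cover)
    if known_codes is not None:
        bad = set(np.unique(final_cover).tolist()) - set(known_codes)
        if bad:
            raise ValueError(f"unknown cover class codes: {sorted(bad)}")
    return final_cover != old_growth_code


# ---------------------------------------------------------------------------
# I/O: TIFF stack + sidecar CSV of dates (+ JSON transform)

def write_stack(stack: SeriesStack, path: str | Path) -> None:
    """Write a SeriesStack as <path>.tif (values), <path>.valid.tif, <path>.dates.csv."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tif"), stack.values.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(path.with_suffix(".valid.tif"), stack.valid.astype(np.uint8),
                     photometric="minisblack")
    with open(path.with_suffix(".dates.csv"), "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["index", "decimal_year", "iso_date"])
        for i, t in enumerate(stack.times):
            wtr.writerow([i, f"{t:.6f}", _decimal_year_to_iso(t)])
    with open(path.with_suffix(".transform.json"), "w") as fh:
        json.dump({"x_origin_m": stack.transform[0], "y_origin_m": stack.transform[1],
                   "pixel_size_m": stack.transform[2]}, fh)


def read_stack(path: str | Path) -> SeriesStack:
    import tifffile

    path = Path(path)
    values = tifffile.imread(path.with_suffix(".tif")).astype(float)
    valid = tifffile.imread(path.with_suffix(".valid.tif")).astype(bool)
    times = []
    with open(path.with_suffix(".dates.csv")) as fh:
        for row in csv.DictReader(fh):
            times.append(float(row["decimal_year"]))
    tf = (0.0, 0.0, 30.0)
    tpath = path.with_suffix(".transform.json")
    if tpath.exists():
        with open(tpath) as fh:
            d = json.load(fh)
        tf = (d["x_origin_m"], d["y_origin_m"], d["pixel_size_m"])
    return SeriesStack(np.asarray(times), values, valid, tf)


def _decimal_year_to_iso(t: float) -> str:
    year = int(np.floor(t))
    frac = t - year
    day = int(frac * 365.25)
    date = np.datetime64(f"{year:04d}-01-01") + np.timedelta64(day, "D")
    return str(date)
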