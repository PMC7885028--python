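"""Gap-filling, aggregation, and net forest-loss accounting.

Classification codes for fine rasters and per-year series:
``1`` forest, ``0`` nonforest, ``-1`` missing (``MISSING``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from paimpact.synthetic_landscape import Landscape

MISSING = -1
FOREST = 1
NONFOREST = 0


def gap_fill_series(series: Sequence[int] | np.ndarray) -> np.ndarray:
    """Fill MISSING classifications from agreeing temporal neighbors.

    A MISSING entry becomes forest iff both the previous and following
    year are forest, nonforest iff both are nonforest, and otherwise stays
    MISSING.  The pass is single (neighbors are the *original* values, so
    fills never cascade) and the first/last years are never filled.

    Accepts a 1-D series or a 2-D (n_cells, n_years) array; years are the
    last axis.
    """
    arr = np.asarray(series, dtype=int)
    if arr.shape[-1] < 3:
        raise ValueError("need at least 3 ordered years to gap-fill")
    bad = ~np.isin(arr, (FOREST, NONFOREST, MISSING))
    if bad.any():
        raise ValueError("classifications must be in {1, 0, -1}")
    out = arr.copy()
    prev = arr[..., :-2]
    nxt = arr[..., 2:]
    mid = arr[..., 1:-1]
    fill_forest = (mid == MISSING) & (prev == FOREST) & (nxt == FOREST)
    fill_nonforest = (mid == MISSING) & (prev == NONFOREST) & (nxt == NONFOREST)
    target = out[..., 1:-1]
    target[fill_forest] = FOREST
    target[fill_nonforest] = NONFOREST
    return out


def gap_fill_landscape(landscape: Landscape) -> Landscape:
    """Continuous analogue of :func:`gap_fill_series` for forest fractions.

    A missing fraction in an interior year is filled with the mean of its
    two temporal neighbors when both are observed; endpoints are never
    filled.  Single pass over the original values.
    """
    out = landscape.copy()
    years = out.years
    if len(years) < 3:
        return out
    orig = {y: landscape.cells[f"forest_{y}"].to_numpy(float) for y in years}
    for prev_y, y, next_y in zip(years[:-2], years[1:-1], years[2:]):
        mid = orig[y]
        fill = np.isnan(mid) & ~np.isnan(orig[prev_y]) & ~np.isnan(orig[next_y])
        if fill.any():
            filled = mid.copy()
            filled[fill] = 0.5 * (orig[prev_y][fill] + orig[next_y][fill])
            out.cells[f"forest_{y}"] = filled
    return out


def _block_sums(mask: np.ndarray, k: int) -> np.ndarray:
    """Sum a 2-D 0/1 array over k x k blocks, trailing partial blocks kept."""
    nr, nc = mask.shape
    row_idx = np.arange(0, nr, k)
    col_idx = np.arange(0, nc, k)
    tmp = np.add.reduceat(mask, row_idx, axis=0)
    return np.add.reduceat(tmp, col_idx, axis=1)


def aggregate_to_grid(fine: np.ndarray, factor: int) -> np.ndarray:
    """Average a fine classification raster into coarse forest fractions.

    Each coarse cell's fraction is (# forest fine cells) / (# non-missing
    fine cells) within its ``factor x factor`` block; all-missing blocks
    are NaN.  Trailing partial blocks (dimensions not divisible by
    ``factor``) are averaged over the fine cells available.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    fine = np.asarray(fine, dtype=int)
    if fine.size == 0:
        raise ValueError("empty raster")
    forest = _block_sums((fine == FOREST).astype(np.int64), factor)
    observed = _block_sums((fine != MISSING).astype(np.int64), factor)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = forest / observed
    frac[observed == 0] = np.nan
    return frac


@dataclass
class LossTable:
    """Per-cell net forest loss (start fraction minus end fraction).

    ``loss`` is negative for gain; ``usable`` is False when the start or
    end fraction is missing.
    """

    table: pd.DataFrame  # columns: cell_id, loss, usable
    start_year: int
    end_year: int

    @property
    def loss(self) -> pd.Series:
        return self.table.set_index("cell_id")["loss"]

    @property
    def usable(self) -> pd.Series:
        return self.table.set_index("cell_id")["usable"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_loss(landscape: Landscape, start_year: int | None = None, end_year: int | None = None) -> LossTable:
    """Net loss per cell between two observed years of the landscape."""
    years = landscape.years
    start_year = years[0] if start_year is None else int(start_year)
    end_year = years[-1] if end_year is None else int(end_year)
    for y in (start_year, end_year):
        if y not in years:
            raise ValueError(f"year {y} not present in landscape (has {years})")
    f0 = landscape.forest(start_year).to_numpy(float)
    f1 = landscape.forest(end_year).to_numpy(float)
    usable = ~np.isnan(f0) & ~np.isnan(f1)
    loss = np.where(usable, f0 - f1, np.nan)
    table = pd.DataFrame(
        {"cell_id": landscape.cells["cell_id"].to_numpy(), "loss": loss, "usable": usable}
    )
    return LossTable(table, start_year, end_year)


def summarize_loss(
    loss_table: LossTable,
    landscape: Landscape,
    by: str | pd.Series | None = None,
    label: str = "all",
) -> pd.DataFrame:
    """Group means of loss with 95% normal-approximation CIs.

    ``by`` may be a landscape column name (e.g. ``region_id``, ``pa_id``,
    ``iucn_cat``) or a Series aligned to cell_id; None summarizes all
    usable cells under ``label``.  Also reports total start-year forest
    area (km²) per group.  Empty groups are omitted with a warning.
    """
    cells = landscape.cells.set_index("cell_id")
    t = loss_table.table.set_index("cell_id")
    usable = t.index[t["usable"]]
    area = landscape.cell_size**2
    f_start = cells[f"forest_{loss_table.start_year}"]

    if by is None:
        groups = pd.Series(label, index=usable)
    elif isinstance(by, str):
        groups = cells.loc[usable, by]
    else:
        groups = by.reindex(usable)

    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        if isinstance(by, str) and by == "pa_id" and (pd.isna(g)):
            continue
        if isinstance(g, str) and g == "":
            continue
        vals = t.loc[idx, "loss"].to_numpy(float)
        if len(vals) == 0:
            warnings.warn(f"group {g!r} empty; omitted")
            continue
        mean = float(vals.mean())
        half = 0.0 if len(vals) < 2 else float(1.96 * vals.std(ddof=1) / np.sqrt(len(vals)))
        rows.append(
            {
                "group": g,
                "n_cells": len(vals),
                "mean_loss": mean,
                "ci_half_width": half,
                "start_forest_km2": float(f_start.loc[idx].sum() * area),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_cells", "mean_loss", "ci_half_width", "start_forest_km2"])
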