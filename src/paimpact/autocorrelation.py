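"""Distance-binned Moran's I correlograms with permutation envelopes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class UndefinedStatisticError(ValueError):
    """Raised when Moran's I is undefined (zero variance)."""


class EmptyBandError(ValueError):
    """Raised when a distance band contains no pairs."""


def _band_pairs(coords: np.ndarray, d_lo: float, d_hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Unordered index pairs (i, j), i<j, with d_lo < dist <= d_hi."""
    tree = cKDTree(coords)
    # query_pairs uses dist <= r; take the upper band and drop the lower one
    hi = tree.query_pairs(d_hi, output_type="ndarray")
    if d_lo > 0:
        d = np.linalg.norm(coords[hi[:, 0]] - coords[hi[:, 1]], axis=1)
        hi = hi[d > d_lo]
    else:
        d = np.linalg.norm(coords[hi[:, 0]] - coords[hi[:, 1]], axis=1)
        hi = hi[d > 0]  # exclude coincident points (self-like pairs)
    return hi[:, 0], hi[:, 1]


def _morans_from_pairs(z: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> float:
    n = len(z)
    s0 = 2.0 * len(ii)  # symmetric binary weights, both orientations
    cross = 2.0 * float(z[ii] @ z[jj])
    denom = float(z @ z)
    return (n / s0) * cross / denom


def morans_i(values: np.ndarray, coords: np.ndarray, band: tuple[float, float]) -> float:
    """Moran's I with binary distance-band weights (d_lo, d_hi].

    ``I = (n / S0) * sum_{i!=j} w_ij z_i z_j / sum_i z_i^2`` with
    ``z = value - mean`` and ``w_ij = 1`` iff ``d_lo < dist(i, j) <= d_hi``.
    """
    values = np.asarray(values, float)
    coords = np.asarray(coords, float)
    d_lo, d_hi = band
    if len(values) < 2:
        raise UndefinedStatisticError("need at least 2 values")
    z = values - values.mean()
    if np.allclose(z, 0.0):
        raise UndefinedStatisticError("zero variance: Moran's I undefined")
    ii, jj = _band_pairs(coords, d_lo, d_hi)
    if len(ii) == 0:
        raise EmptyBandError(f"no pairs in band ({d_lo}, {d_hi}]")
    return _morans_from_pairs(z, ii, jj)


@dataclass
class Correlogram:
    """Moran's I per contiguous distance bin with a 95% permutation envelope."""

    table: pd.DataFrame  # bin_lo, bin_hi, I, envelope_lo, envelope_hi, n_pairs
    n_cells: int
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and not np.allclose(t["bin_lo"].to_numpy()[1:], t["bin_hi"].to_numpy()[:-1]):
            raise ValueError("bins must be contiguous and ascending")

    @property
    def max_dist(self) -> float:
        return float(self.table["bin_hi"].iloc[-1])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def residual_correlogram(
    residuals: pd.Series,
    coords: pd.DataFrame | np.ndarray,
    max_dist: float = 60.0,
    bin_width: float = 5.0,
    n_sample: int = 10_000,
    n_perm: int = 199,
    seed: int = 0,
) -> Correlogram:
    """Correlogram of residuals on a random subsample of cells.

    ``residuals`` is indexed by cell_id; ``coords`` is an (x, y) frame
    indexed by cell_id (or an array aligned with the residuals).  At most
    ``n_sample`` residuals are used (without replacement); the envelope is
    the 2.5/97.5 percentile of per-bin I over ``n_perm`` random relabelings
    of residual values to locations.  Bins with no pairs get NaN I.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    residuals = residuals.dropna()
    if isinstance(coords, pd.DataFrame):
        xy = coords.loc[residuals.index, ["x", "y"]].to_numpy(float)
    else:
        xy = np.asarray(coords, float)
        if len(xy) != len(residuals):
            raise ValueError("coords must align with residuals")
    rng = np.random.default_rng(seed)
    n_avail = len(residuals)
    if n_sample < n_avail:
        pick = np.sort(rng.choice(n_avail, size=n_sample, replace=False))
        vals = residuals.to_numpy(float)[pick]
        xy = xy[pick]
    else:
        vals = residuals.to_numpy(float)
    n = len(vals)
    z = vals - vals.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise UndefinedStatisticError("zero variance: Moran's I undefined")

    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    edges = edges[edges <= max_dist + 1e-9]
    if edges[-1] < max_dist:
        edges = np.append(edges, max_dist)

    tree = cKDTree(xy)
    all_pairs = tree.query_pairs(float(edges[-1]), output_type="ndarray")
    dists = np.linalg.norm(xy[all_pairs[:, 0]] - xy[all_pairs[:, 1]], axis=1)
    keep = dists > 0
    all_pairs, dists = all_pairs[keep], dists[keep]
    which = np.searchsorted(edges, dists, side="left") - 1
    which = np.clip(which, 0, len(edges) - 2)

    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        ii = all_pairs[sel, 0]
        jj = all_pairs[sel, 1]
        n_pairs = int(sel.sum())
        if n_pairs == 0:
            rows.append((edges[b], edges[b + 1], np.nan, np.nan, np.nan, 0))
            continue
        s0 = 2.0 * n_pairs
        scale = (n / s0) * 2.0 / denom
        i_obs = scale * float(z[ii] @ z[jj])
        zp = z[perms]
        i_perm = scale * np.einsum("pi,pi->p", zp[:, ii], zp[:, jj])
        lo, hi = np.percentile(i_perm, [2.5, 97.5])
        rows.append((edges[b], edges[b + 1], i_obs, lo, hi, n_pairs))
    table = pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "I", "envelope_lo", "envelope_hi", "n_pairs"]
    )
    return Correlogram(table, n, n_perm, seed)


def first_nonsignificant_distance(corr: Correlogram) -> float:
    """Distance (km) up to which residual autocorrelation is significant.

    Scans bins from distance 0: returns the upper edge of the last bin
    whose I lies outside the envelope before the first bin inside it;
    0 if the first bin is already inside; ``max_dist`` (with a warning)
    when every bin is outside.  Empty bins count as inside.
    """
    t = corr.table
    if len(t) == 0:
        raise ValueError("correlogram has no bins")
    last_sig_edge = 0.0
    for _, row in t.iterrows():
        inside = (
            row["n_pairs"] == 0
            or np.isnan(row["I"])
            or (row["envelope_lo"] <= row["I"] <= row["envelope_hi"])
        )
        if inside:
            return float(last_sig_edge)
        last_sig_edge = row["bin_hi"]
    warnings.warn("all bins significant; returning max_dist")
    return float(corr.max_dist)
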