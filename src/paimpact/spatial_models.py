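"""Outcome models on matched data with spatial-autocorrelation corrections.

Four model variants:

1. linear mixed model: loss ~ protection, crossed random intercepts for
   municipality and matched pair (REML);
2. model 1 + mean neighborhood loss within one buffer radius;
3. model 1 + mean neighborhood loss within two buffer radii;
4. spatial error model (simultaneous autoregressive errors) with
   row-standardized distance-band weights, maximum likelihood, fit on a
   random subsample.

Buffer radii are selected iteratively from Moran's I correlograms of the
previous model's residuals (radius = first non-significant distance minus
a step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree
from scipy.stats import norm

from paimpact.autocorrelation import (
    Correlogram,
    first_nonsignificant_distance,
    residual_correlogram,
)
from paimpact.forest_change import LossTable
from paimpact.lmm import fit_crossed_lmm
from paimpact.matching import MatchedPairs
from paimpact.synthetic_landscape import Landscape


@dataclass
class ModelSpec:
    """Which outcome model to fit and with what spatial settings."""

    model_id: int
    buffer_radii: tuple[float, ...] = ()
    sar_max_dist: float = 30.0
    sar_subsample: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError("model_id must be 1..4")
        self.buffer_radii = tuple(float(r) for r in self.buffer_radii)
        if any(r <= 0 for r in self.buffer_radii):
            raise ValueError("buffer radii must be positive")
        need = {1: 0, 2: 1, 3: 2, 4: 0}[self.model_id]
        if len(self.buffer_radii) != need:
            raise ValueError(f"model {self.model_id} needs {need} buffer radii")
        if self.model_id == 3 and not self.buffer_radii[0] > self.buffer_radii[1]:
            raise ValueError("model 3 radii must be strictly decreasing")


@dataclass
class OutcomeModelFit:
    """Fitted protection effect with uncertainty and residuals."""

    model_id: int
    coefficient: float  # effect of protection on loss
    se: float
    pvalue: float
    stars: str
    var_municipality: float
    var_pair: float
    var_residual: float
    residuals: pd.Series  # indexed by cell_id
    converged: bool
    params: pd.Series = field(default_factory=pd.Series)
    extra: dict = field(default_factory=dict)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def buffer_mean_loss(
    loss_table: LossTable,
    coords: pd.DataFrame,
    radius: float,
) -> pd.DataFrame:
    """Mean net loss of all usable cells within ``radius`` of each cell.

    The focal cell itself is excluded.  ``coords`` is an (x, y) frame
    indexed by cell_id covering at least the loss-table cells.  Cells with
    no neighbor inside the radius get NaN (excluded downstream).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    t = loss_table.table
    ids = t["cell_id"].to_numpy()
    xy = coords.loc[ids, ["x", "y"]].to_numpy(float)
    usable = t["usable"].to_numpy(bool)
    loss = t["loss"].to_numpy(float)

    tree = cKDTree(xy[usable])
    u_loss = loss[usable]
    u_pos = np.flatnonzero(usable)
    neighbor_lists = tree.query_ball_point(xy, r=radius)
    means = np.full(len(ids), np.nan)
    counts = np.zeros(len(ids), dtype=int)
    for i, nb in enumerate(neighbor_lists):
        nb = np.asarray(nb, dtype=int)
        if usable[i]:
            nb = nb[u_pos[nb] != i]  # exclude the focal cell
        if len(nb):
            means[i] = u_loss[nb].mean()
            counts[i] = len(nb)
    return pd.DataFrame(
        {"cell_id": ids, "radius": radius, "buffer_loss": means, "n_neighbors": counts}
    )


def assemble_matched_data(
    landscape: Landscape,
    pairs: MatchedPairs,
    loss_table: LossTable,
    buffer_radii: tuple[float, ...] = (),
) -> pd.DataFrame:
    """Long-format modeling frame: one row per matched cell.

    Columns: cell_id, pair_id, protected, municipality_id, x, y, loss and
    one ``buffer_<radius>`` column per requested radius (means over all
    usable landscape cells, not only matched ones).
    """
    cells = landscape.cells.set_index("cell_id")
    loss = loss_table.loss
    rows = []
    for _, pr in pairs.pairs.iterrows():
        for cid, prot in ((pr["treated_id"], 1), (pr["control_id"], 0)):
            rows.append(
                {
                    "cell_id": cid,
                    "pair_id": pr["pair_id"],
                    "protected": prot,
                    "municipality_id": cells.at[cid, "municipality_id"],
                    "x": cells.at[cid, "x"],
                    "y": cells.at[cid, "y"],
                    "loss": loss.loc[cid],
                }
            )
    data = pd.DataFrame(rows)
    for r in buffer_radii:
        data = add_buffer_column(data, landscape, loss_table, r)
    return data


def add_buffer_column(
    data: pd.DataFrame,
    landscape: Landscape,
    loss_table: LossTable,
    radius: float,
) -> pd.DataFrame:
    col = buffer_column_name(radius)
    if col in data.columns:
        return data
    buf = buffer_mean_loss(loss_table, landscape.cells.set_index("cell_id"), radius)
    data = data.merge(
        buf[["cell_id", "buffer_loss"]].rename(columns={"buffer_loss": col}),
        on="cell_id",
        how="left",
    )
    return data


def buffer_column_name(radius: float) -> str:
    return f"buffer_{radius:g}"


def _design(data: pd.DataFrame, buffer_radii: tuple[float, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "protected": data["protected"].astype(float)})
    for r in buffer_radii:
        X[buffer_column_name(r)] = data[buffer_column_name(r)].to_numpy(float)
    return X


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> OutcomeModelFit:
    """Fit one of models 1-4 to an assembled matched-data frame.

    Models 1-3: Gaussian mixed model with crossed municipality and pair
    random intercepts (REML); buffer covariates as fixed effects.  Rows
    with a missing buffer value (no neighbor) are dropped with a warning.
    Model 4: spatial error model on a random subsample (see
    :func:`fit_sar_error`).  The p-value is the large-sample normal
    approximation of coefficient / SE.
    """
    if data["pair_id"].nunique() < 2:
        raise ValueError("need at least 2 matched pairs")
    if spec.model_id == 4:
        return fit_sar_error(data, spec)

    needed = [buffer_column_name(r) for r in spec.buffer_radii]
    keep = data[needed].notna().all(axis=1) if needed else pd.Series(True, index=data.index)
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} rows lacking buffer neighbors")
    d = data.loc[keep]
    X = _design(d, spec.buffer_radii)
    res = fit_crossed_lmm(
        d["loss"].to_numpy(float),
        X,
        {
            "municipality": d["municipality_id"].to_numpy(),
            "pair": d["pair_id"].to_numpy(),
        },
    )
    coef = float(res.params["protected"])
    se = float(res.bse["protected"])
    p = float(2.0 * norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    if not res.converged:
        warnings.warn(f"model {spec.model_id}: REML optimizer did not converge")
    return OutcomeModelFit(
        model_id=spec.model_id,
        coefficient=coef,
        se=se,
        pvalue=p,
        stars=significance_stars(p),
        var_municipality=res.re_variances["municipality"],
        var_pair=res.re_variances["pair"],
        var_residual=res.sigma2,
        residuals=pd.Series(res.resid, index=d["cell_id"].to_numpy()),
        converged=res.converged,
        params=res.params,
    )


def _row_standardized_band_weights(xy: np.ndarray, max_dist: float):
    """Binary distance-band adjacency, row-standardized (W scheme).

    Returns (W dense, degrees); isolated cells have zero rows.
    """
    n = len(xy)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(max_dist, output_type="ndarray")
    A = np.zeros((n, n))
    A[pairs[:, 0], pairs[:, 1]] = 1.0
    A[pairs[:, 1], pairs[:, 0]] = 1.0
    deg = A.sum(axis=1)
    W = A / np.where(deg > 0, deg, 1.0)[:, None]
    return W, deg


def fit_sar_error(data: pd.DataFrame, spec: ModelSpec) -> OutcomeModelFit:
    """ML spatial error model: ``y = Xb + u, u = rho W u + eps``.

    Fixed effects are intercept + protection (the model-1 mean structure);
    the autoregressive component uses row-standardized distance-band
    weights up to ``spec.sar_max_dist``.  Fit on a random subsample of at
    most ``spec.sar_subsample`` rows.  The log-determinant uses the
    eigenvalues of the (symmetrized-similar) weight matrix, so the
    subsample is limited to a few thousand cells.  Reported residuals are
    the spatially filtered innovations ``(I - rho W)(y - Xb)``.
    """
    rng = np.random.default_rng(spec.seed)
    d = data
    if len(d) > spec.sar_subsample:
        pick = np.sort(rng.choice(len(d), size=spec.sar_subsample, replace=False))
        d = d.iloc[pick]
    n = len(d)
    if n > 4000:
        raise ValueError("SAR subsample too large for dense eigenvalue route; lower sar_subsample")
    xy = d[["x", "y"]].to_numpy(float)
    W, deg = _row_standardized_band_weights(xy, spec.sar_max_dist)
    isolated = deg == 0
    if isolated.any():
        warnings.warn(f"dropping {int(isolated.sum())} isolated cells from SAR fit")
        d = d.loc[~isolated]
        xy = xy[~isolated]
        W, deg = _row_standardized_band_weights(xy, spec.sar_max_dist)
        n = len(d)

    y = d["loss"].to_numpy(float)
    X = _design(d, ()).to_numpy(float)

    # W = D^-1 A is similar to the symmetric D^-1/2 A D^-1/2: real spectrum
    dinv_sqrt = 1.0 / np.sqrt(deg)
    sym = W * (np.sqrt(deg)[:, None] * dinv_sqrt[None, :])
    eigs = np.linalg.eigvalsh(sym)
    lo = 1.0 / eigs.min() + 1e-6 if eigs.min() < 0 else -0.999
    hi = 1.0 / eigs.max() - 1e-6

    def neg_ll(rho: float) -> float:
        Ay = y - rho * (W @ y)
        AX = X - rho * (W @ X)
        beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
        e = Ay - AX @ beta
        sigma2 = float(e @ e) / n
        logdet = float(np.log1p(-rho * eigs).sum())
        return 0.5 * n * np.log(sigma2) - logdet

    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded")
    rho = float(res.x)
    Ay = y - rho * (W @ y)
    AX = X - rho * (W @ X)
    beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
    e = Ay - AX @ beta
    sigma2 = float(e @ e) / n
    cov = sigma2 * np.linalg.inv(AX.T @ AX)
    se = float(np.sqrt(cov[1, 1]))
    coef = float(beta[1])
    p = float(2.0 * norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    return OutcomeModelFit(
        model_id=4,
        coefficient=coef,
        se=se,
        pvalue=p,
        stars=significance_stars(p),
        var_municipality=float("nan"),
        var_pair=float("nan"),
        var_residual=sigma2,
        residuals=pd.Series(e, index=d["cell_id"].to_numpy()),
        converged=bool(res.success if hasattr(res, "success") else True),
        params=pd.Series(beta, index=["const", "protected"]),
        extra={"rho": rho, "n_sar": n},
    )


def select_buffer_distances(
    data: pd.DataFrame,
    landscape: Landscape,
    loss_table: LossTable,
    bin_width: float = 5.0,
    step: float = 5.0,
    max_dist: float | None = None,
    n_sample: int = 10_000,
    n_perm: int = 199,
    seed: int = 0,
    correlogram_fn=None,
) -> dict:
    """Iterative buffer-radius selection from residual correlograms.

    Fit model 1 -> correlogram -> d1 -> radius_1 = d1 - step; fit model 2
    with radius_1 -> correlogram -> d2 -> radius_2 = d2 - step.  Emits the
    specs for models 2 and 3 (model 3 radii = (radius_1, radius_2)) and
    sets the SAR max distance to radius_1.  The procedure stops early and
    reports the last viable model whenever a radius would be <= 0.

    ``correlogram_fn(residuals) -> Correlogram`` may be injected (e.g. for
    testing the rule in isolation); the default computes a permutation
    correlogram of the residuals at the matched cells' coordinates.
    """
    coords = landscape.cells.set_index("cell_id")[["x", "y"]]
    if max_dist is None:
        span = coords.to_numpy(float)
        max_dist = float(np.linalg.norm(span.max(axis=0) - span.min(axis=0)) / 2.0)

    def default_corr(residuals: pd.Series) -> Correlogram:
        return residual_correlogram(
            residuals, coords, max_dist=max_dist, bin_width=bin_width,
            n_sample=n_sample, n_perm=n_perm, seed=seed,
        )

    corr_fn = correlogram_fn or default_corr

    out: dict = {"specs": [ModelSpec(1)], "final_model": 1}
    fit1 = fit_model(data, ModelSpec(1))
    corr1 = corr_fn(fit1.residuals)
    d1 = first_nonsignificant_distance(corr1)
    out.update(fit1=fit1, correlogram1=corr1, d1=d1)
    radius_1 = d1 - step
    if radius_1 <= 0:
        return out

    spec2 = ModelSpec(2, (radius_1,))
    out["specs"].append(spec2)
    out["final_model"] = 2
    data2 = add_buffer_column(data, landscape, loss_table, radius_1)
    fit2 = fit_model(data2, spec2)
    corr2 = corr_fn(fit2.residuals)
    d2 = first_nonsignificant_distance(corr2)
    out.update(fit2=fit2, correlogram2=corr2, d2=d2, sar_max_dist=radius_1)
    radius_2 = d2 - step
    if radius_2 <= 0 or radius_2 >= radius_1:
        return out

    out["specs"].append(ModelSpec(3, (radius_1, radius_2)))
    out["final_model"] = 3
    return out


def compare_models(
    data: pd.DataFrame,
    specs: list[ModelSpec],
    landscape: Landscape,
    loss_table: LossTable,
    bin_width: float = 5.0,
    max_dist: float | None = None,
    n_sample: int = 10_000,
    n_perm: int = 199,
    seed: int = 0,
    include_sar: bool = False,
) -> tuple[pd.DataFrame, dict[int, OutcomeModelFit], dict[int, Correlogram]]:
    """Fit several specs and rank them by residual-autocorrelation reach.

    Returns (summary table sorted by first non-significant distance then
    model id, fits by model id, correlograms by model id).  Model 4 is
    skipped unless ``include_sar`` (it is costly and, in practice, not the
    best performer).
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 specs to compare")
    coords = landscape.cells.set_index("cell_id")[["x", "y"]]
    if max_dist is None:
        span = coords.to_numpy(float)
        max_dist = float(np.linalg.norm(span.max(axis=0) - span.min(axis=0)) / 2.0)
    fits: dict[int, OutcomeModelFit] = {}
    corrs: dict[int, Correlogram] = {}
    rows = []
    for spec in specs:
        if spec.model_id == 4 and not include_sar:
            continue
        d = data
        for r in spec.buffer_radii:
            d = add_buffer_column(d, landscape, loss_table, r)
        fit = fit_model(d, spec)
        corr = residual_correlogram(
            fit.residuals, coords, max_dist=max_dist, bin_width=bin_width,
            n_sample=n_sample, n_perm=n_perm, seed=seed,
        )
        dist = first_nonsignificant_distance(corr)
        fits[spec.model_id] = fit
        corrs[spec.model_id] = corr
        rows.append(
            {
                "model_id": spec.model_id,
                "coefficient": fit.coefficient,
                "se": fit.se,
                "pvalue": fit.pvalue,
                "stars": fit.stars,
                "first_nonsignificant_km": dist,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["first_nonsignificant_km", "model_id"], kind="stable"
    ).reset_index(drop=True)
    return table, fits, corrs
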