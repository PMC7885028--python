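"""Propensity-score estimation and greedy 1:1 matching without replacement.

National matching plus the three regional procedures: *subsetting*
(partition national pairs by the treated cell's region), *exact subsetting*
(national propensity fit, controls restricted to the treated cell's region)
and *submatching* (an independent fit-and-match per region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from paimpact.forest_change import LossTable
from paimpact.synthetic_landscape import Landscape

CATEGORICAL_COVARIATES = ("region_id", "municipality_id", "department_id")

PROCEDURES = ("national", "subsetting", "exact_subsetting", "submatching")


@dataclass
class PropensityFit:
    """Fitted logistic model of protection and per-cell scores."""

    covariate_names: list[str]
    coefficients: pd.Series  # includes "const"
    scores: pd.Series  # indexed by cell_id, in (0, 1)
    treated: pd.Series  # bool, indexed by cell_id
    score_sd: float  # SD over the pooled (treated + control) sample
    dropped: list[str] = field(default_factory=list)
    ridged: bool = False


@dataclass
class MatchedPairs:
    """1:1 matched treated/control cells.

    Invariants (checked on construction): each treated and each control id
    appears at most once, and every score distance is within the caliper.
    """

    pairs: pd.DataFrame  # columns: pair_id, treated_id, control_id, distance
    caliper: float  # absolute score units
    n_unmatched_treated: int
    procedure: str = "national"

    def __post_init__(self) -> None:
        p = self.pairs
        if p["treated_id"].duplicated().any():
            raise ValueError("a treated cell appears in more than one pair")
        if p["control_id"].duplicated().any():
            raise ValueError("a control cell was reused")
        if len(p) and (p["distance"] > self.caliper + 1e-12).any():
            raise ValueError("pair distance exceeds the caliper")
        if self.procedure not in PROCEDURES:
            raise ValueError(f"unknown procedure {self.procedure!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def treated_ids(self) -> np.ndarray:
        return self.pairs["treated_id"].to_numpy()

    @property
    def control_ids(self) -> np.ndarray:
        return self.pairs["control_id"].to_numpy()

    @property
    def matched_ids(self) -> np.ndarray:
        return np.concatenate([self.treated_ids, self.control_ids])

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)


def design_matrix(landscape: Landscape, covariates: list[str]) -> pd.DataFrame:
    """Dummy-encoded design for the given covariates (no intercept).

    Continuous covariates are resolved from ``cov_<name>`` columns;
    ``region_id`` / ``municipality_id`` / ``department_id`` expand to
    drop-first dummy columns.
    """
    cells = landscape.cells.set_index("cell_id")
    parts = []
    for name in covariates:
        if name in CATEGORICAL_COVARIATES:
            dummies = pd.get_dummies(cells[name].astype("category"), prefix=name, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            col = f"cov_{name}" if f"cov_{name}" in cells.columns else name
            if col not in cells.columns:
                raise KeyError(f"covariate {name!r} not found in landscape")
            parts.append(cells[[col]].astype(float).rename(columns={col: name}))
    return pd.concat(parts, axis=1)


def eligible_mask(landscape: Landscape, loss_table: LossTable | None = None) -> pd.Series:
    """Cells usable for matching: outcome defined (if a LossTable is given)."""
    idx = landscape.cells.set_index("cell_id").index
    if loss_table is None:
        return pd.Series(True, index=idx)
    return loss_table.usable.reindex(idx).fillna(False).astype(bool)


def fit_propensity(
    landscape: Landscape,
    covariates: list[str],
    eligible: pd.Series | None = None,
) -> PropensityFit:
    """Maximum-likelihood logistic regression of protection on covariates.

    Constant covariates are dropped with a warning; complete separation or
    non-convergence falls back to a ridge-penalized fit (warning).
    """
    cells = landscape.cells.set_index("cell_id")
    if eligible is None:
        eligible = pd.Series(True, index=cells.index)
    eligible = eligible.reindex(cells.index).fillna(False).astype(bool)
    X = design_matrix(landscape, covariates).loc[eligible]
    y = cells.loc[eligible, "protected"].astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one treated and one control among eligible cells")

    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}")
        X = X.drop(columns=dropped)

    Xc = sm.add_constant(X, has_constant="add")
    ridged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        params = res.params
        if not converged or not np.isfinite(params).all() or np.abs(params).max() > 50:
            raise np.linalg.LinAlgError("suspect separation")
        scores = pd.Series(res.predict(Xc), index=Xc.index)
    except Exception:
        warnings.warn("logistic MLE failed (possible separation); using ridge-penalized fit")
        ridged = True
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=2000)
        lr.fit(X.to_numpy(float), y.to_numpy())
        params = pd.Series(
            np.concatenate([[lr.intercept_[0]], lr.coef_[0]]), index=["const", *X.columns]
        )
        scores = pd.Series(lr.predict_proba(X.to_numpy(float))[:, 1], index=X.index)

    scores = scores.clip(1e-12, 1 - 1e-12)
    return PropensityFit(
        covariate_names=list(X.columns),
        coefficients=pd.Series(params, index=params.index),
        scores=scores,
        treated=y.astype(bool),
        score_sd=float(scores.std(ddof=1)),
        dropped=dropped,
        ridged=ridged,
    )


def nearest_neighbor_match(
    fit: PropensityFit,
    caliper_sd: float = 0.25,
    procedure: str = "national",
) -> MatchedPairs:
    """Greedy 1:1 nearest-neighbor matching on the propensity score.

    Treated cells are processed in descending score order (ties: ascending
    cell_id); each takes the unused control with the smallest absolute
    score difference (ties: ascending control cell_id).  A treated cell is
    left unmatched when its nearest unused control is farther than
    ``caliper_sd * score_sd``.  Controls are used at most once.
    """
    caliper = float(caliper_sd) * fit.score_sd
    t_ids = fit.treated.index[fit.treated].to_numpy()
    c_ids = fit.treated.index[~fit.treated].to_numpy()
    if len(t_ids) == 0:
        raise ValueError("no treated cells to match")
    t_scores = fit.scores.loc[t_ids].to_numpy(float)
    if len(c_ids) == 0:
        warnings.warn("no control cells available; all treated left unmatched")
        empty = pd.DataFrame(columns=["pair_id", "treated_id", "control_id", "distance"])
        return MatchedPairs(empty, caliper, len(t_ids), procedure)

    # treated order: score desc, id asc
    t_order = np.lexsort((t_ids, -t_scores))
    # controls sorted by (score, id)
    c_scores = fit.scores.loc[c_ids].to_numpy(float)
    c_order = np.lexsort((c_ids, c_scores))
    cs = c_scores[c_order]
    cid = c_ids[c_order]
    used = np.zeros(len(cs), dtype=bool)

    rows = []
    n_unmatched = 0
    for ti in t_order:
        s = t_scores[ti]
        pos = np.searchsorted(cs, s)
        left = pos - 1
        while left >= 0 and used[left]:
            left -= 1
        right = pos
        while right < len(cs) and used[right]:
            right += 1
        dl = s - cs[left] if left >= 0 else np.inf
        dr = cs[right] - s if right < len(cs) else np.inf
        best = min(dl, dr)
        if best > caliper or not np.isfinite(best):
            n_unmatched += 1
            continue
        # gather every unused control at exactly the best distance and take
        # the smallest cell_id (scores may tie in runs on either side)
        candidates = []
        if left >= 0 and s - cs[left] == best:
            j, val = left, cs[left]
            while j >= 0 and cs[j] == val:
                if not used[j]:
                    candidates.append(j)
                j -= 1
        if right < len(cs) and cs[right] - s == best:
            j, val = right, cs[right]
            while j < len(cs) and cs[j] == val:
                if not used[j]:
                    candidates.append(j)
                j += 1
        j = min(candidates, key=lambda k: cid[k])
        used[j] = True
        rows.append((t_ids[ti], cid[j], best))

    pairs = pd.DataFrame(rows, columns=["treated_id", "control_id", "distance"])
    pairs.insert(0, "pair_id", np.arange(len(pairs)))
    return MatchedPairs(pairs, caliper, n_unmatched, procedure)


def match_national(
    landscape: Landscape,
    covariates: list[str],
    loss_table: LossTable | None = None,
    caliper_sd: float = 0.25,
) -> MatchedPairs:
    """Fit propensity on all eligible cells, then greedy 1:1 matching."""
    fit = fit_propensity(landscape, covariates, eligible_mask(landscape, loss_table))
    return nearest_neighbor_match(fit, caliper_sd, procedure="national")


def _region_of(landscape: Landscape) -> pd.Series:
    return landscape.cells.set_index("cell_id")["region_id"]


def match_regional(
    landscape: Landscape,
    covariates: list[str],
    procedure: str,
    loss_table: LossTable | None = None,
    caliper_sd: float = 0.25,
) -> dict[int, MatchedPairs]:
    """Regional matched pairs under one of the three procedures.

    Returns one MatchedPairs per region (keyed by region id).  Regions
    whose treated cells find no eligible controls yield an empty result
    with a warning.
    """
    if procedure not in ("subsetting", "exact_subsetting", "submatching"):
        raise ValueError(f"unknown regional procedure {procedure!r}")
    region = _region_of(landscape)
    eligible = eligible_mask(landscape, loss_table)
    out: dict[int, MatchedPairs] = {}

    if procedure == "subsetting":
        national = match_national(landscape, covariates, loss_table, caliper_sd)
        for reg in np.sort(region.unique()):
            mask = region.loc[national.pairs["treated_id"]].to_numpy() == reg
            sub = national.pairs.loc[mask].reset_index(drop=True)
            out[reg] = MatchedPairs(sub, national.caliper, 0, "subsetting")
        return out

    if procedure == "exact_subsetting":
        fit = fit_propensity(landscape, covariates, eligible)
        for reg in np.sort(region.unique()):
            in_reg = region.reindex(fit.scores.index) == reg
            sub_treated = fit.treated & in_reg
            if not sub_treated.any():
                out[reg] = MatchedPairs(
                    pd.DataFrame(columns=["pair_id", "treated_id", "control_id", "distance"]),
                    caliper_sd * fit.score_sd,
                    0,
                    "exact_subsetting",
                )
                continue
            sub_fit = PropensityFit(
                covariate_names=fit.covariate_names,
                coefficients=fit.coefficients,
                scores=fit.scores[in_reg],
                treated=fit.treated[in_reg],
                score_sd=fit.score_sd,  # caliper stays on the national scale
            )
            if (~sub_fit.treated).sum() == 0:
                warnings.warn(f"region {reg}: treated cells but no controls")
                out[reg] = MatchedPairs(
                    pd.DataFrame(columns=["pair_id", "treated_id", "control_id", "distance"]),
                    caliper_sd * fit.score_sd,
                    int(sub_fit.treated.sum()),
                    "exact_subsetting",
                )
                continue
            out[reg] = nearest_neighbor_match(sub_fit, caliper_sd, "exact_subsetting")
        return out

    # submatching: independent fit and match per region; region/department
    # dummies are dropped from the per-region design (constant there)
    sub_covs = [c for c in covariates if c not in ("region_id", "department_id")]
    for reg in np.sort(region.unique()):
        in_reg = (region == reg) & eligible
        cells = landscape.cells.set_index("cell_id")
        treated_here = cells.loc[in_reg[in_reg].index, "protected"]
        if treated_here.sum() == 0:
            out[reg] = MatchedPairs(
                pd.DataFrame(columns=["pair_id", "treated_id", "control_id", "distance"]),
                0.0,
                0,
                "submatching",
            )
            continue
        if (~treated_here.astype(bool)).sum() == 0:
            warnings.warn(f"region {reg}: treated cells but no controls")
            out[reg] = MatchedPairs(
                pd.DataFrame(columns=["pair_id", "treated_id", "control_id", "distance"]),
                0.0,
                int(treated_here.sum()),
                "submatching",
            )
            continue
        fit = fit_propensity(landscape, sub_covs, in_reg)
        out[reg] = nearest_neighbor_match(fit, caliper_sd, "submatching")
    return out


def concat_pairs(per_region: dict[int, MatchedPairs], procedure: str) -> MatchedPairs:
    """Pool per-region pairs into one set (pair_ids renumbered)."""
    frames = [mp.pairs for mp in per_region.values() if len(mp.pairs)]
    caliper = max((mp.caliper for mp in per_region.values()), default=0.0)
    unmatched = sum(mp.n_unmatched_treated for mp in per_region.values())
    if not frames:
        empty = pd.DataFrame(columns=["pair_id", "treated_id", "control_id", "distance"])
        return MatchedPairs(empty, caliper, unmatched, procedure)
    pairs = pd.concat(frames, ignore_index=True)
    pairs["pair_id"] = np.arange(len(pairs))
    return MatchedPairs(pairs, caliper, unmatched, procedure)
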