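"""Covariate balance diagnostics: normalized differences before/after matching."""

from __future__ import annotations

import numpy as np
import pandas as pd

from paimpact.forest_change import LossTable
from paimpact.matching import MatchedPairs, design_matrix, eligible_mask
from paimpact.synthetic_landscape import Landscape

#: |normalized difference| (percent) above which a covariate is flagged imbalanced
IMBALANCE_THRESHOLD = 25.0


def normalized_difference(treated: np.ndarray, control: np.ndarray) -> float:
    """Normalized difference in percent.

    ``100 * (mean_t - mean_c) / sqrt((var_t + var_c) / 2)`` with sample
    (n-1) variances.  If both variances are zero the result is 0 for equal
    means and signed infinity otherwise.
    """
    t = np.asarray(treated, float)
    c = np.asarray(control, float)
    if len(t) == 0 or len(c) == 0:
        raise ValueError("both samples must be non-empty")
    var_t = t.var(ddof=1) if len(t) > 1 else 0.0
    var_c = c.var(ddof=1) if len(c) > 1 else 0.0
    diff = t.mean() - c.mean()
    pooled = np.sqrt((var_t + var_c) / 2.0)
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    return float(100.0 * diff / pooled)


def _records(X: pd.DataFrame, t_ids: np.ndarray, c_ids: np.ndarray, phase: str) -> list[dict]:
    rows = []
    for col in X.columns:
        tv = X.loc[t_ids, col].to_numpy(float)
        cv = X.loc[c_ids, col].to_numpy(float)
        nd = normalized_difference(tv, cv)
        rows.append(
            {
                "covariate": col,
                "phase": phase,
                "mean_treated": tv.mean(),
                "mean_control": cv.mean(),
                "sd_treated": tv.std(ddof=1) if len(tv) > 1 else 0.0,
                "sd_control": cv.std(ddof=1) if len(cv) > 1 else 0.0,
                "normalized_difference": nd,
                "imbalanced": bool(abs(nd) > IMBALANCE_THRESHOLD),
            }
        )
    return rows


def balance_table(
    landscape: Landscape,
    pairs: MatchedPairs,
    covariates: list[str],
    loss_table: LossTable | None = None,
    treated_scope: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-covariate balance records before and after matching.

    *Before* compares all eligible treated cells against all eligible
    controls (restricted to ``treated_scope`` cells when given, e.g. one
    region); *after* compares matched treated cells against their matched
    controls.  Categorical covariates are assessed dummy-by-dummy.
    """
    cells = landscape.cells.set_index("cell_id")
    X = design_matrix(landscape, covariates)
    eligible = eligible_mask(landscape, loss_table)
    if treated_scope is not None:
        eligible = eligible & treated_scope.reindex(eligible.index).fillna(False).astype(bool)
    prot = cells["protected"].astype(bool)
    t_all = cells.index[prot & eligible].to_numpy()
    c_all = cells.index[~prot & eligible].to_numpy()

    rows = _records(X, t_all, c_all, "before")
    if pairs.n_pairs > 0:
        rows += _records(X, pairs.treated_ids, pairs.control_ids, "after")
    return pd.DataFrame(rows)


def balanced_fraction(table: pd.DataFrame, phase: str = "after") -> float:
    """Fraction of covariates with |normalized difference| <= threshold."""
    sub = table[table["phase"] == phase]
    if len(sub) == 0:
        return float("nan")
    return float((~sub["imbalanced"]).mean())
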