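"""Effectiveness summaries: loss inside PAs vs matched and unmatched controls."""

from __future__ import annotations

import numpy as np
import pandas as pd

from paimpact.forest_change import LossTable
from paimpact.matching import MatchedPairs
from paimpact.spatial_models import OutcomeModelFit
from paimpact.synthetic_landscape import Landscape


def percent_reduction(loss_pa: float, loss_control: float) -> float:
    """Percent less loss in PAs than in controls: 100 * (c - pa) / c.

    Negative when PAs lose more than their controls.  Undefined for zero
    control loss (raises; callers report an absolute difference instead).
    """
    if loss_control == 0:
        raise ZeroDivisionError("control loss is zero; percent reduction undefined")
    return float(100.0 * (loss_control - loss_pa) / loss_control)


def _group_row(
    label_level: str,
    label: object,
    pa_loss: np.ndarray,
    matched_loss: np.ndarray | None,
    unprot_loss: np.ndarray,
    fit: OutcomeModelFit | None,
) -> dict:
    mean_pa = 100.0 * float(np.mean(pa_loss)) if len(pa_loss) else np.nan
    mean_matched = (
        100.0 * float(np.mean(matched_loss))
        if matched_loss is not None and len(matched_loss)
        else np.nan
    )
    mean_unprot = 100.0 * float(np.mean(unprot_loss)) if len(unprot_loss) else np.nan
    reduction = np.nan
    reduction_is_absolute = False
    if not np.isnan(mean_matched):
        try:
            reduction = percent_reduction(mean_pa, mean_matched)
        except ZeroDivisionError:
            reduction = mean_matched - mean_pa
            reduction_is_absolute = True
    return {
        "level": label_level,
        "group": label,
        "n_pa_cells": len(pa_loss),
        "n_matched_controls": 0 if matched_loss is None else len(matched_loss),
        "mean_loss_pa_pct": mean_pa,
        "mean_loss_matched_pct": mean_matched,
        "mean_loss_unprotected_pct": mean_unprot,
        "percent_reduction": reduction,
        "reduction_is_absolute": reduction_is_absolute,
        "model_coefficient": np.nan if fit is None else fit.coefficient,
        "model_pvalue": np.nan if fit is None else fit.pvalue,
        "model_stars": "" if fit is None else fit.stars,
        "model_id": np.nan if fit is None else fit.model_id,
        "flagged": fit is None,
    }


def build_report(
    landscape: Landscape,
    loss_table: LossTable,
    national_pairs: MatchedPairs,
    regional_pairs: dict[int, MatchedPairs],
    national_fit: OutcomeModelFit | None = None,
    regional_fits: dict[int, OutcomeModelFit] | None = None,
) -> pd.DataFrame:
    """Effectiveness rows at national, region, PA, and IUCN-category levels.

    Loss columns come straight from the loss table (no model dependence);
    the model columns report the supplied fits (intended: model 3 on
    national pairs for the national row and on submatching pairs per
    region).  PA and IUCN rows carry loss summaries only.
    """
    regional_fits = regional_fits or {}
    cells = landscape.cells.set_index("cell_id")
    loss = loss_table.loss
    usable = loss_table.usable
    prot = cells["protected"].astype(bool)

    def losses(ids) -> np.ndarray:
        ids = pd.Index(ids)
        ok = usable.reindex(ids).fillna(False).astype(bool)
        return loss.loc[ids[ok]].to_numpy(float)

    pa_ids_all = cells.index[prot]
    unprot_ids_all = cells.index[~prot]

    rows = [
        _group_row(
            "national",
            "all",
            losses(pa_ids_all),
            losses(national_pairs.control_ids),
            losses(unprot_ids_all),
            national_fit,
        )
    ]

    region = cells["region_id"]
    for reg in np.sort(region.unique()):
        in_reg = region == reg
        mp = regional_pairs.get(reg)
        matched = losses(mp.control_ids) if mp is not None and mp.n_pairs else None
        rows.append(
            _group_row(
                "region",
                reg,
                losses(cells.index[prot & in_reg]),
                matched,
                losses(cells.index[~prot & in_reg]),
                regional_fits.get(reg),
            )
        )

    for pa in np.sort(cells.loc[prot, "pa_id"].dropna().unique()):
        ids = cells.index[cells["pa_id"] == pa]
        rows.append(_group_row("pa", pa, losses(ids), None, np.array([]), None))

    if "iucn_cat" in cells.columns:
        cats = cells.loc[prot, "iucn_cat"]
        for cat in sorted(c for c in cats.unique() if isinstance(c, str) and c):
            ids = cells.index[prot & (cells["iucn_cat"] == cat)]
            rows.append(_group_row("iucn", cat, losses(ids), None, np.array([]), None))

    return pd.DataFrame(rows)


def report_text(report: pd.DataFrame) -> str:
    """Small human-readable rendering of the report frame."""
    lines = ["Protected-area effectiveness summary", "=" * 38]
    for _, r in report.iterrows():
        if r["level"] in ("national", "region"):
            red = r["percent_reduction"]
            red_s = "n/a" if pd.isna(red) else f"{red:.1f}%{' (abs diff)' if r['reduction_is_absolute'] else ''}"
            coef = r["model_coefficient"]
            coef_s = "n/a" if pd.isna(coef) else f"{coef:.4f}{r['model_stars']}"
            lines.append(
                f"{r['level']:>8} {str(r['group']):>6}: PA loss {r['mean_loss_pa_pct']:.2f}% | "
                f"matched {r['mean_loss_matched_pct']:.2f}% | reduction {red_s} | model coef {coef_s}"
            )
    return "\n".join(lines) + "\n"
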