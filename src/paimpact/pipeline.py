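"""End-to-end orchestration: simulate -> gap-fill -> loss -> match ->
balance -> buffer selection -> model fits -> correlograms -> report.

Every stage draws its own seed deterministically from the master seed, so
a rerun with the same config reproduces all CSV outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

import paimpact
from paimpact.balance import balance_table, balanced_fraction
from paimpact.effectiveness import build_report, report_text
from paimpact.forest_change import compute_loss, gap_fill_landscape, summarize_loss
from paimpact.matching import concat_pairs, match_national, match_regional
from paimpact.spatial_models import (
    ModelSpec,
    add_buffer_column,
    assemble_matched_data,
    compare_models,
    fit_model,
    select_buffer_distances,
)
from paimpact.synthetic_landscape import SimulationConfig, generate_landscape

logger = logging.getLogger(__name__)

REGIONAL_PROCEDURES = ("subsetting", "exact_subsetting", "submatching")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    covariates: list[str] = field(
        default_factory=lambda: [
            "elevation",
            "slope",
            "dist_road",
            "pop_density",
            "initial_forest",
            "region_id",
        ]
    )
    procedures: tuple[str, ...] = REGIONAL_PROCEDURES
    caliper_sd: float = 0.25
    bin_width: float = 5.0
    buffer_step: float = 5.0
    max_dist: float | None = None
    n_sample: int = 10_000
    n_perm: int = 199
    out_dir: str = "runs/demo"
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d.pop("out_dir", None)  # location-independent so reruns hash identically
        Path(path).write_text(json.dumps(d, indent=2, default=list))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing artifacts and a manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": paimpact.__version__,
        "master_seed": config.master_seed,
        "stage_seeds": {},
        "files": {},
        "timings_s": {},
    }
    t_all = time.time()

    def _stage(name: str):
        seed = config.stage_seed(name)
        manifest["stage_seeds"][name] = seed
        logger.info("stage %s (seed %d)", name, seed)
        return seed, time.time()

    def _done(name: str, t0: float, *paths: Path) -> None:
        manifest["timings_s"][name] = round(time.time() - t0, 3)
        for p in paths:
            manifest["files"][p.name] = _hash_file(p)

    # simulate
    seed, t0 = _stage("simulate")
    sim_cfg = SimulationConfig(**{**asdict(config.sim), "seed": seed})
    sim_cfg.covariate_specs = config.sim.covariate_specs
    landscape, truth = generate_landscape(sim_cfg)
    sim_cfg.to_json(out / "sim_config.json")
    landscape.to_csv(out / "landscape.csv")
    truth.to_csv(out / "ground_truth.csv")
    _done("simulate", t0, out / "sim_config.json", out / "landscape.csv", out / "ground_truth.csv")

    # gap-fill + loss
    seed, t0 = _stage("loss")
    landscape = gap_fill_landscape(landscape)
    loss_table = compute_loss(landscape)
    loss_table.to_csv(out / "loss.csv")
    summarize_loss(loss_table, landscape, "region_id").to_csv(out / "loss_by_region.csv", index=False)
    _done("loss", t0, out / "loss.csv", out / "loss_by_region.csv")

    # matching
    seed, t0 = _stage("match")
    national = match_national(landscape, config.covariates, loss_table, config.caliper_sd)
    national.to_csv(out / "pairs_national.csv")
    regional = {}
    files = [out / "pairs_national.csv"]
    for proc in config.procedures:
        per_region = match_regional(landscape, config.covariates, proc, loss_table, config.caliper_sd)
        regional[proc] = per_region
        pooled = concat_pairs(per_region, proc)
        path = out / f"pairs_{proc}.csv"
        pooled.to_csv(path)
        files.append(path)
    _done("match", t0, *files)

    # balance
    seed, t0 = _stage("balance")
    files = []
    nat_bal = balance_table(landscape, national, config.covariates, loss_table)
    nat_bal.to_csv(out / "balance_national.csv", index=False)
    files.append(out / "balance_national.csv")
    region_col = landscape.cells.set_index("cell_id")["region_id"]
    frac_rows = [{"procedure": "national", "region": "all",
                  "balanced_fraction": balanced_fraction(nat_bal)}]
    for proc, per_region in regional.items():
        tabs = []
        for reg, mp in per_region.items():
            scope = region_col == reg
            tab = balance_table(landscape, mp, config.covariates, loss_table, treated_scope=scope)
            tab.insert(0, "region", reg)
            tabs.append(tab)
            frac_rows.append({"procedure": proc, "region": reg,
                              "balanced_fraction": balanced_fraction(tab)})
        path = out / f"balance_{proc}.csv"
        pd.concat(tabs, ignore_index=True).to_csv(path, index=False)
        files.append(path)
    pd.DataFrame(frac_rows).to_csv(out / "balanced_fractions.csv", index=False)
    files.append(out / "balanced_fractions.csv")
    _done("balance", t0, *files)

    # buffer selection + model comparison (national pairs)
    seed, t0 = _stage("models")
    data = assemble_matched_data(landscape, national, loss_table)
    sel = select_buffer_distances(
        data, landscape, loss_table,
        bin_width=config.bin_width, step=config.buffer_step, max_dist=config.max_dist,
        n_sample=config.n_sample, n_perm=config.n_perm, seed=seed,
    )
    (out / "buffer_selection.json").write_text(
        json.dumps(
            {
                "d1": sel.get("d1"),
                "d2": sel.get("d2"),
                "final_model": sel["final_model"],
                "specs": [asdict(s) for s in sel["specs"]],
            },
            indent=2,
        )
    )
    files = [out / "buffer_selection.json"]
    if len(sel["specs"]) >= 2:
        table, fits, corrs = compare_models(
            data, sel["specs"], landscape, loss_table,
            bin_width=config.bin_width, max_dist=config.max_dist,
            n_sample=config.n_sample, n_perm=config.n_perm, seed=seed,
        )
        table.to_csv(out / "model_comparison.csv", index=False)
        files.append(out / "model_comparison.csv")
        for mid, fit in fits.items():
            fit.residuals.rename("residual").to_csv(out / f"residuals_model{mid}.csv")
            corrs[mid].to_csv(out / f"correlogram_model{mid}.csv")
            files += [out / f"residuals_model{mid}.csv", out / f"correlogram_model{mid}.csv"]
        best_spec = sel["specs"][-1]
        national_fit = fits[best_spec.model_id]
    else:
        best_spec = sel["specs"][0]
        national_fit = sel["fit1"]
    _done("models", t0, *files)

    # regional fits (submatching pairs, best spec) + report
    seed, t0 = _stage("report")
    regional_fits = {}
    sub = regional.get("submatching", {})
    for reg, mp in sub.items():
        if mp.n_pairs < 2:
            continue
        d = assemble_matched_data(landscape, mp, loss_table, best_spec.buffer_radii)
        try:
            regional_fits[reg] = fit_model(d, best_spec)
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            logger.warning("region %s model fit failed: %s", reg, exc)
    report = build_report(
        landscape, loss_table, national,
        {reg: mp for reg, mp in sub.items()},
        national_fit=national_fit, regional_fits=regional_fits,
    )
    report.to_csv(out / "report.csv", index=False)
    (out / "summary.txt").write_text(report_text(report))
    _done("report", t0, out / "report.csv", out / "summary.txt")

    manifest["total_s"] = round(time.time() - t_all, 3)
    config.to_json(out / "run_config.json")
    manifest["files"]["run_config.json"] = _hash_file(out / "run_config.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "out_dir": str(out),
        "manifest": manifest,
        "report": report,
        "selection": sel,
        "national_pairs": national,
    }
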