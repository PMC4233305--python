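"""Parameter-sweep driver.

Reproduces the study design: three mechanism sweeps (72 + 90 + 216 =
378 full-cycle simulations), re-run under impaired length-dependent
activation (beta1 in {-1.5, -0.75, 0}) and under increased afterload
(p_a in {9, 11.25, 13.5} kPa).  Results are tidy one-row-per-run
tables; mechanically degenerate corner configurations that fail to find
an equilibrium are recorded with ``status="aborted"`` rather than
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .calcium import CalciumTransient
from .gradients import MechanismConfig, all_grids
from .hemodynamics import WindkesselParams, default_windkessel
from .metrics import AB_SIGNIFICANT, ab_timecourse, select_results
from .ventricle import VentricleGeometry, run_cycle

__all__ = [
    "SWEEP_COLUMNS",
    "run_sweep",
    "run_lda_variants",
    "run_afterload_variants",
    "summarize",
]

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = [
    "config_id", "mechanism", "z_a", "z_b",
    "ca_t50_homog", "ca_t50_apex", "ca_t50_base", "t_ref_apex",
    "beta1", "p_a",
    "edv", "esv", "ef", "ab_end_systole", "ab_peak",
    "peak_pressure", "significant", "status",
]


def _row(config: MechanismConfig, result, ballooning) -> dict:
    row = {
        "config_id": config.config_id,
        "mechanism": config.mechanism,
        "z_a": config.gradient.z_a,
        "z_b": config.gradient.z_b,
        "ca_t50_homog": config.ca_t50_homog,
        "ca_t50_apex": config.ca_t50_apex,
        "ca_t50_base": config.ca_t50_base,
        "t_ref_apex": config.t_ref_apex,
        "beta1": config.beta1,
        "p_a": config.p_a,
        "edv": result.edv,
        "esv": result.esv,
        "ef": result.ef,
        "peak_pressure": result.peak_pressure,
        "status": result.status,
    }
    if ballooning is not None:
        row.update(
            ab_end_systole=ballooning.ab_end_systole,
            ab_peak=ballooning.ab_peak,
            significant=ballooning.significant,
        )
    else:
        row.update(ab_end_systole=np.nan, ab_peak=np.nan, significant=False)
    return row


def run_sweep(
    configs: list[MechanismConfig],
    geometry: VentricleGeometry | None = None,
    cell_params=None,
    hemo: WindkesselParams | None = None,
    transients: tuple[CalciumTransient, CalciumTransient] | None = None,
    dt: float = 0.05,
    progress: bool = False,
) -> pd.DataFrame:
    """Run one beat per configuration; one table row per run.

    Output rows are ordered by config id, so the table is byte-stable
    across re-runs (the whole pipeline is deterministic).
    """
    hemo = hemo if hemo is not None else default_windkessel()
    iterator = configs
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(configs, desc="sweep")
        except ImportError:  # pragma: no cover
            pass
    rows = []
    for config in iterator:
        run_hemo = replace(hemo, p_a=config.p_a)
        cell = cell_params
        if cell is not None and cell.beta1 != config.beta1:
            cell = replace(cell, beta1=config.beta1)
        elif cell is None and config.beta1 != -1.5:
            from .contraction import default_contraction_params

            cell = replace(default_contraction_params(), beta1=config.beta1)
        result = run_cycle(
            config, geometry=geometry, cell_params=cell, hemo=run_hemo,
            transients=transients, dt=dt,
        )
        ballooning = ab_timecourse(result) if result.status == "ok" else None
        rows.append(_row(config, result, ballooning))
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    return table.sort_values("config_id", kind="mergesort").reset_index(drop=True)


def run_lda_variants(
    configs: list[MechanismConfig] | None = None,
    beta1_set: tuple[float, ...] = (-1.5, -0.75, 0.0),
    **kwargs,
) -> pd.DataFrame:
    """Repeat every configuration at each length-dependence setting
    (normal, halved, removed)."""
    if configs is None:
        configs = all_grids()
    tables = []
    for beta1 in beta1_set:
        variant = [replace(c, beta1=beta1) for c in configs]
        tables.append(run_sweep(variant, **kwargs))
    return pd.concat(tables, ignore_index=True)


def run_afterload_variants(
    configs: list[MechanismConfig] | None = None,
    p_a_set: tuple[float, ...] = (9.0, 11.25, 13.5),
    **kwargs,
) -> pd.DataFrame:
    """Repeat every configuration at control, +25% and +50% afterload."""
    if configs is None:
        configs = all_grids()
    tables = []
    for p_a in p_a_set:
        variant = [replace(c, p_a=p_a) for c in configs]
        tables.append(run_sweep(variant, **kwargs))
    return pd.concat(tables, ignore_index=True)


def summarize(table: pd.DataFrame, ef_window=(30.0, 60.0)) -> dict:
    """Per-mechanism summary: the max-A:B row inside the EF window and
    counts of significant-ballooning runs."""
    if len(table) == 0:
        raise ValueError("cannot summarize an empty sweep table")
    report: dict = {"n_runs": int(len(table)), "mechanisms": {}}
    ok = table[table["status"] == "ok"]
    report["n_aborted"] = int(len(table) - len(ok))
    for mech, sub in ok.groupby("mechanism"):
        selected = select_results(sub, ef_window)
        entry = {
            "n_ok": int(len(sub)),
            "n_significant": int((sub["ab_end_systole"] >= AB_SIGNIFICANT).sum()),
        }
        if len(selected):
            top = selected.iloc[0]
            entry["best_in_window"] = {
                "config_id": top["config_id"],
                "ef": float(top["ef"]),
                "ab_end_systole": float(top["ab_end_systole"]),
            }
        else:
            entry["best_in_window"] = None
        report["mechanisms"][mech] = entry
    return report
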