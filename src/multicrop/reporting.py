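"""Summary tables: global and per-cell areas, production, yields and water.

Area totals are reported in Mha, production in million tons dry matter
(mio t DM), water volumes in km^3/yr, average yields in t DM/ha
(production / area).  Derived shares (irrigated share of active
cropland, multiple-cropped share of irrigated land, production increase
relative to REF) are percentages; divisions by zero are reported as NaN
(undefined), never as 0.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MulticropError
from .scenarios import SYSTEM_COLS, ScenarioResult

HA_TO_MHA = 1e-6
T_TO_MIOT = 1e-6


def share_pct(part: float, whole: float) -> float:
    """part / whole as a percentage; NaN when the whole is zero."""
    if whole == 0:
        return float("nan")
    return 100.0 * part / whole


def percent_increase(old: float, new: float) -> float:
    """(new - old) / old as a percentage; NaN when old is zero."""
    if old == 0:
        return float("nan")
    return 100.0 * (new - old) / old


def round_pct(value: float) -> float:
    """Nearest-integer percent, the rounding used in headline reporting."""
    return float(np.round(value))


def summarize(results: Sequence[ScenarioResult]) -> dict:
    """Global and per-cell summary tables for >= 1 scenario results.

    Returns {'global': DataFrame indexed by scenario, 'cells': long
    DataFrame}.  The REF scenario, when present, is the baseline for
    production-increase percentages.
    """
    results = list(results)
    if not results:
        raise MulticropError("summarize needs at least one scenario result")
    ref_prod = None
    for r in results:
        if r.name == "REF":
            ref_prod = r.production[list(SYSTEM_COLS)].to_numpy().sum() * T_TO_MIOT

    rows = {}
    cell_frames = []
    for r in results:
        row = {}
        total_area = 0.0
        total_prod = 0.0
        for col in SYSTEM_COLS:
            a = r.areas[col].sum() * HA_TO_MHA
            p = r.production[col].sum() * T_TO_MIOT
            row[f"area_{col}_mha"] = a
            row[f"production_{col}_miot"] = p
            row[f"yield_{col}_t_ha"] = p / a if a > 0 else float("nan")
            total_area += a
            total_prod += p
        row["area_fallow_mha"] = r.areas["fallow"].sum() * HA_TO_MHA
        row["active_area_mha"] = total_area
        row["physical_cropland_mha"] = total_area + row["area_fallow_mha"]
        row["production_total_miot"] = total_prod
        irr_area = row["area_irrigated_single_mha"] + row["area_irrigated_mc_mha"]
        rf_area = row["area_rainfed_single_mha"] + row["area_rainfed_mc_mha"]
        mc_area = row["area_rainfed_mc_mha"] + row["area_irrigated_mc_mha"]
        row["irrigated_area_mha"] = irr_area
        row["mc_area_mha"] = mc_area
        row["irrigated_share_of_active_pct"] = share_pct(irr_area, total_area)
        row["mc_share_of_irrigated_pct"] = share_pct(row["area_irrigated_mc_mha"], irr_area)
        row["mc_share_of_rainfed_pct"] = share_pct(row["area_rainfed_mc_mha"], rf_area)
        row["enabled_mc_area_mha"] = r.enabled_mc_area.sum() * HA_TO_MHA
        row["irrigation_withdrawal_km3"] = r.water["withdrawal_km3"].sum()
        row["irrigation_consumption_km3"] = r.water["consumption_km3"].sum()
        row["groundwater_km3"] = r.water["groundwater_km3"].sum()
        row["nonag_withdrawal_km3"] = r.water["nonag_withdrawal_km3"].sum()
        if ref_prod is not None:
            row["production_increase_vs_ref_pct"] = percent_increase(ref_prod, total_prod)
        else:
            row["production_increase_vs_ref_pct"] = float("nan")
        rows[r.name] = row

        cf = r.areas.copy()
        cf.columns = [f"area_{c}_ha" for c in cf.columns]
        for col in SYSTEM_COLS:
            cf[f"production_{col}_t"] = r.production[col]
        for col in r.water.columns:
            cf[col] = r.water[col]
        cf["enabled_mc_area_ha"] = r.enabled_mc_area
        cf.insert(0, "scenario", r.name)
        cf.index.name = "cell"
        cell_frames.append(cf.reset_index())

    glob = pd.DataFrame.from_dict(rows, orient="index")
    glob.index.name = "scenario"
    cells = pd.concat(cell_frames, ignore_index=True)
    return {"global": glob, "cells": cells}


def write_summary(tables: dict, directory) -> None:
    """Write the summary tables as CSV plus a machine-readable JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tables["global"].to_csv(d / "summary_global.csv", float_format="%.10g")
    tables["cells"].to_csv(d / "summary_cells.csv", index=False, float_format="%.10g")
    payload = {
        scenario: {k: (None if isinstance(v, float) and np.isnan(v) else v)
                   for k, v in row.items()}
        for scenario, row in tables["global"].to_dict(orient="index").items()
    }
    with open(d / "summary_global.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_summary(directory) -> dict:
    d = Path(directory)
    glob = pd.read_csv(d / "summary_global.csv", index_col="scenario")
    cells = pd.read_csv(d / "summary_cells.csv")
    return {"global": glob, "cells": cells}
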