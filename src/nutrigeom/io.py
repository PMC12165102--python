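"""CSV/JSON readers and writers for panels, diet tables and fit reports.

CSV is the single tabular interchange format (UTF-8, header row, ``.``
decimal); fitted models are reported as JSON so runs are diffable.
Dialects:

* diet design:    ``label,protein_pct,carb_pct,fat_pct,energy_density_mj_kg``
* diet response:  ``label,protein_pct,carb_pct,fat_pct,response``
* country panel:  ``country,year,stratum,protein_kcal,carb_kcal,fat_kcal,gdp,rate``
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .diet_design import DietComposition, DietDesign
from .gamm_surface import PANEL_COLUMNS, CountryPanel, PanelSchemaError
from .mixture_models import DietResponseTable

__all__ = [
    "read_panel",
    "write_panel",
    "read_diet_design",
    "write_diet_design",
    "read_diet_response",
    "write_diet_response",
    "write_fit_json",
]

log = logging.getLogger(__name__)

DIET_DESIGN_COLUMNS = ["label", "protein_pct", "carb_pct", "fat_pct", "energy_density_mj_kg"]
DIET_RESPONSE_COLUMNS = ["label", "protein_pct", "carb_pct", "fat_pct", "response"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{path}: missing required column(s): {missing}")


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based + header line
            raise ValueError(
                f"{path}: non-numeric value {df.loc[df.index[bad][0], col]!r} "
                f"in column {col!r} (file row {row})"
            )
        df[col] = converted
    return df


def read_panel(path) -> CountryPanel:
    """Read and validate a country panel CSV.

    Rows violating the panel invariants (non-positive supplies or GDP,
    negative or missing rate) are dropped with a logged reason and row
    number; a missing column is a schema error naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PANEL_COLUMNS, path)
    num_cols = ["year", "protein_kcal", "carb_kcal", "fat_kcal", "gdp", "rate"]
    df = _check_numeric(df, num_cols, path)

    n0 = len(df)
    bad = ~np.isfinite(df[num_cols]).all(axis=1)
    for col in ("protein_kcal", "carb_kcal", "fat_kcal", "gdp"):
        bad |= df[col] <= 0
    bad |= df["rate"] < 0
    if bad.any():
        for idx in df.index[bad]:
            log.warning("%s: dropping invalid row %d (file row %d)", path, idx, idx + 2)
        df = df[~bad]
    panel = CountryPanel(df.reset_index(drop=True))
    log.info("%s: read %d rows (%d dropped)", path, len(panel), n0 - len(panel))
    return panel


def write_panel(panel: CountryPanel, path) -> Path:
    path = Path(path)
    panel.data.to_csv(path, index=False, columns=PANEL_COLUMNS)
    return path


def read_diet_design(path) -> DietDesign:
    """Read a diet-design CSV (percent compositions, normalized on read)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, DIET_DESIGN_COLUMNS, path)
    df = _check_numeric(df, DIET_DESIGN_COLUMNS[1:], path)
    diets = tuple(
        DietComposition.from_percent(
            str(r.label), r.protein_pct, r.carb_pct, r.fat_pct, r.energy_density_mj_kg
        )
        for r in df.itertuples(index=False)
    )
    return DietDesign(diets, diets[0].energy_density)


def write_diet_design(design: DietDesign, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "label": [d.label for d in design],
            "protein_pct": [100 * d.protein_frac for d in design],
            "carb_pct": [100 * d.carb_frac for d in design],
            "fat_pct": [100 * d.fat_frac for d in design],
            "energy_density_mj_kg": [d.energy_density for d in design],
        }
    ).to_csv(path, index=False)
    return path


def read_diet_response(path) -> DietResponseTable:
    """Read a diet-response CSV: one row per animal, compositions in percent."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, DIET_RESPONSE_COLUMNS, path)
    df = _check_numeric(df, DIET_RESPONSE_COLUMNS[1:], path)
    diets = tuple(
        DietComposition.from_percent(str(r.label), r.protein_pct, r.carb_pct, r.fat_pct)
        for r in df.itertuples(index=False)
    )
    return DietResponseTable(diets=diets, responses=df["response"].to_numpy(dtype=float))


def write_diet_response(table: DietResponseTable, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "label": [d.label for d in table.diets],
            "protein_pct": [100 * d.protein_frac for d in table.diets],
            "carb_pct": [100 * d.carb_frac for d in table.diets],
            "fat_pct": [100 * d.fat_frac for d in table.diets],
            "response": table.responses,
        }
    ).to_csv(path, index=False)
    return path


def write_fit_json(report: dict, path) -> Path:
    """Write a fit report (already dict-shaped) as indented JSON."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")
    return path
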