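"""Readers, writers and run configuration for the pipeline CLI.

All tabular I/O is UTF-8 CSV with dot decimal separator; plate-reader
exports using comma decimals are normalized on read.  Time columns are
converted to hours when the header carries a unit suffix (``time_h``,
``time_min``, ``time_s``).  Every run can write a metadata JSON
capturing configuration and seed for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .host_range import HostRangeMatrix, SpotResult
from .killing import GrowthCurve, KillingAssayResult
from .quantify import (
    DEFAULT_COUNTABLE_RANGE,
    DEFAULT_MCFARLAND,
    DilutionSeries,
    PlateCount,
    TiterEstimate,
)
from .stats import ExplantEndpoint

log = logging.getLogger(__name__)

_TIME_FACTORS = {"time_h": 1.0, "time_hours": 1.0, "time_min": 1 / 60.0,
                 "time_minutes": 1 / 60.0, "time_s": 1 / 3600.0,
                 "time_sec": 1 / 3600.0, "time": 1.0}


@dataclass
class RunConfig:
    """User-tunable knobs shared across pipeline stages."""

    seed: int = 0
    alpha: float = 0.05
    countable_range: tuple[int, int] = DEFAULT_COUNTABLE_RANGE
    baseline_mode: str = "raw"
    lod_policy: str = "half_lod"
    mcfarland_table: dict = field(default_factory=lambda: dict(DEFAULT_MCFARLAND))
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    cfg = {k: v for k, v in raw.items() if k in known}
    if "countable_range" in cfg:
        cfg["countable_range"] = tuple(cfg["countable_range"])
    if "mcfarland_table" in cfg:
        cfg["mcfarland_table"] = {float(k): float(v)
                                  for k, v in cfg["mcfarland_table"].items()}
    return RunConfig(**cfg)


def _normalize_decimal(df: pd.DataFrame) -> pd.DataFrame:
    """Convert comma-decimal object columns to floats where possible."""
    for col in df.columns:
        if df[col].dtype == object:
            converted = pd.to_numeric(
                df[col].astype(str).str.replace(",", ".", regex=False),
                errors="coerce",
            )
            if converted.notna().all():
                df[col] = converted
    return df


# ---------------------------------------------------------------- count sheets

def read_count_sheet(path: str | Path) -> list[DilutionSeries]:
    """Read a plate-count CSV into one DilutionSeries per (sample, analyte).

    Columns: sample_id, analyte, dilution_exponent, plated_volume_ml, count.
    """
    df = _normalize_decimal(pd.read_csv(path))
    required = {"sample_id", "analyte", "dilution_exponent", "plated_volume_ml",
                "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count sheet missing columns: {sorted(missing)}")
    series = []
    for (sample, analyte), grp in df.groupby(["sample_id", "analyte"], sort=False):
        plates = tuple(
            PlateCount(str(sample), str(analyte), int(row.dilution_exponent),
                       float(row.plated_volume_ml), int(row.count))
            for row in grp.itertuples()
        )
        series.append(DilutionSeries(str(sample), str(analyte), plates))
    return series


def write_titer_table(estimates: Sequence[TiterEstimate], path: str | Path) -> None:
    rows = [
        {
            "sample_id": e.sample_id,
            "analyte": e.analyte,
            "concentration_per_ml": e.concentration,
            "log10_concentration": e.log10_concentration,
            "limit_of_detection_per_ml": e.limit_of_detection,
            "censored": e.censored,
            "n_countable_dilutions": e.n_countable_dilutions,
        }
        for e in estimates
    ]
    cols = ["sample_id", "analyte", "concentration_per_ml", "log10_concentration",
            "limit_of_detection_per_ml", "censored", "n_countable_dilutions"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------- spot records

def read_spot_results(path: str | Path) -> list[SpotResult]:
    """Read spot/plaque records (phage_id, isolate_id, replicate, outcome,
    plaque_count, dilution_exponent, plated_volume_ml)."""
    df = _normalize_decimal(pd.read_csv(path))
    spots = []
    for row in df.itertuples():
        count = getattr(row, "plaque_count", None)
        count = None if count is None or pd.isna(count) else int(count)
        spots.append(
            SpotResult(
                phage_id=str(row.phage_id),
                isolate_id=str(row.isolate_id),
                replicate=int(row.replicate),
                outcome=str(row.outcome),
                plaque_count=count,
                dilution_exponent=int(row.dilution_exponent),
                plated_volume=float(row.plated_volume_ml),
            )
        )
    return spots


def write_spot_results(spots: Iterable[SpotResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "phage_id": s.phage_id,
                "isolate_id": s.isolate_id,
                "replicate": s.replicate,
                "outcome": s.outcome,
                "plaque_count": s.plaque_count,
                "dilution_exponent": s.dilution_exponent,
                "plated_volume_ml": s.plated_volume,
            }
            for s in spots
        ]
    ).to_csv(path, index=False)


def read_reference_titers(path: str | Path) -> dict[str, float]:
    """CSV with columns phage_id, reference_titer_pfu_per_ml."""
    df = _normalize_decimal(pd.read_csv(path))
    return {
        str(r.phage_id): float(r.reference_titer_pfu_per_ml)
        for r in df.itertuples()
    }


def write_host_range(matrix: HostRangeMatrix, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eop_path = outdir / "eop_matrix.csv"
    grade_path = outdir / "eop_grades.csv"
    matrix.to_eop_frame().to_csv(eop_path, index_label="phage_id")
    matrix.to_grade_frame().to_csv(grade_path, index_label="phage_id")
    return {"eop_matrix": eop_path, "eop_grades": grade_path}


# ---------------------------------------------------------------- plate reader

def read_well_map(path: str | Path) -> pd.DataFrame:
    """Well metadata CSV: well, isolate, phage, moi, replicate, is_control."""
    df = _normalize_decimal(pd.read_csv(path))
    required = {"well", "isolate", "phage", "moi", "replicate", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"well map missing columns: {sorted(missing)}")
    return df


def _time_to_hours(df: pd.DataFrame, time_col: str) -> np.ndarray:
    factor = _TIME_FACTORS.get(time_col.lower())
    if factor is None:
        raise ValueError(f"unrecognized time column {time_col!r}")
    t = df[time_col].to_numpy(dtype=float) * factor
    if not np.all(np.diff(t) > 0):
        raise ValueError("time column is not strictly increasing")
    return t


def read_plate_reader(
    path: str | Path, layout: str, well_map_path: str | Path
) -> list[GrowthCurve]:
    """Read a plate-reader export plus its well map into GrowthCurves.

    ``layout`` is "wide" (first column time, one column per well) or
    "long" (columns well, time_*, od600).  Every well in the data must
    appear in the well map.  Rows with missing OD are flagged (logged)
    and kept as NaN so downstream AUC computation can refuse them.
    """
    wm = read_well_map(well_map_path)
    meta = {str(r.well): r for r in wm.itertuples()}
    df = _normalize_decimal(pd.read_csv(path))

    def _curve(well: str, t: np.ndarray, od: np.ndarray) -> GrowthCurve:
        if well not in meta:
            raise ValueError(f"well {well!r} present in data but absent from well map")
        m = meta[well]
        if np.isnan(od).any():
            log.warning("well %s: %d missing OD readings", well, np.isnan(od).sum())
        is_control = bool(m.is_control)
        od = np.where(np.isnan(od), np.nan, np.clip(od, 0.0, None))
        return GrowthCurve(
            well_id=well,
            isolate_id=str(m.isolate),
            phage_id=None if is_control else str(m.phage),
            moi=None if is_control else float(m.moi),
            replicate=int(m.replicate),
            times=t,
            od600=od,
        )

    curves = []
    if layout == "wide":
        time_col = df.columns[0]
        t = _time_to_hours(df, time_col)
        for well in df.columns[1:]:
            curves.append(_curve(str(well), t, df[well].to_numpy(dtype=float)))
    elif layout == "long":
        time_col = next(
            (c for c in df.columns if c.lower() in _TIME_FACTORS), None
        )
        if time_col is None or "well" not in df.columns or "od600" not in df.columns:
            raise ValueError("long layout needs columns well, time_*, od600")
        for well, grp in df.groupby("well", sort=False):
            grp = grp.sort_values(time_col)
            t = _time_to_hours(grp, time_col)
            curves.append(_curve(str(well), t, grp["od600"].to_numpy(dtype=float)))
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    return curves


def write_growth_curves_long(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od600):
            rows.append(
                {
                    "well": c.well_id,
                    "isolate": c.isolate_id,
                    "phage": "" if c.phage_id is None else c.phage_id,
                    "moi": "" if c.moi is None else c.moi,
                    "replicate": c.replicate,
                    "time_h": t,
                    "od600": od,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_killing_results(
    results: Sequence[KillingAssayResult], path: str | Path
) -> None:
    cols = ["phage_id", "isolate_id", "moi", "auc_treatment", "auc_control",
            "virulence_index", "test_method", "p_value", "significant", "flag"]
    rows = [
        {
            "phage_id": r.phage_id,
            "isolate_id": r.isolate_id,
            "moi": r.moi,
            "auc_treatment": r.auc_treatment,
            "auc_control": r.auc_control,
            "virulence_index": r.virulence_index,
            "test_method": r.comparison.method if r.comparison else "",
            "p_value": r.comparison.p_value if r.comparison else np.nan,
            "significant": r.comparison.significant if r.comparison else "",
            "flag": r.flag or "",
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ------------------------------------------------------------------ endpoints

def read_endpoints(path: str | Path) -> list[ExplantEndpoint]:
    """Endpoint CSV: uterus_id, group, phage_id, cfu_per_ml, pfu_per_ml,
    ldh_6h, ldh_24h (blank cells allowed for pfu/ldh)."""
    df = _normalize_decimal(pd.read_csv(path))

    def _opt(v):
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    out = []
    for r in df.itertuples():
        phage = getattr(r, "phage_id", None)
        phage = None if phage is None or pd.isna(phage) else str(phage)
        out.append(
            ExplantEndpoint(
                uterus_id=str(r.uterus_id),
                group=str(r.group),
                phage_id=phage,
                cfu_per_ml=float(r.cfu_per_ml),
                pfu_per_ml=_opt(getattr(r, "pfu_per_ml", None)),
                ldh_6h=_opt(getattr(r, "ldh_6h", None)),
                ldh_24h=_opt(getattr(r, "ldh_24h", None)),
            )
        )
    return out


def write_run_metadata(config: RunConfig, outdir: str | Path, **extra) -> Path:
    """Provenance JSON: configuration, seed and package versions."""
    import phagekit

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": {**asdict(config),
                   "countable_range": list(config.countable_range)},
        "versions": {"phagekit": phagekit.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        **extra,
    }
    path = outdir / "run_metadata.json"
    path.write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")
    return path
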