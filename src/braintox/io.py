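"""Readers and writers for the long-format cohort schema.

Two companion CSV files describe a cohort:

* scans — header ``mouse_id,strain,dose_gy,scan_week,ce_volume_ul``, one
  row per MRI scan;
* survival — header ``mouse_id,strain,dose_gy,last_week,event``, one row
  per mouse.

Comma-separated, UTF-8, ``.`` decimal, header mandatory; volumes are
serialised with 6 significant digits so that write-then-read is exact for
the decimal strings as written.  Malformed input is rejected with an error
naming the offending CSV line.
"""

from __future__ import annotations

import hashlib
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .cohort import SCAN_COLUMNS, SURVIVAL_COLUMNS, CohortTable
from .fitting import FitResult

__all__ = [
    "read_cohort",
    "write_cohort",
    "fit_result_to_json",
    "read_supplementary_export",
]

logger = logging.getLogger("braintox")

try:
    _VERSION = version("braintox")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    _VERSION = "unknown"


class CohortFormatError(ValueError):
    """A cohort CSV violates the schema; the message names the row."""


def _check_columns(df: pd.DataFrame, expected, path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")


def _fail_rows(df_mask: pd.Series, path, what: str) -> None:
    if df_mask.any():
        # +2: one for the header line, one for 0-based indexing
        lines = [int(i) + 2 for i in df_mask[df_mask].index[:5]]
        raise CohortFormatError(f"{path}: {what} at CSV line(s) {lines}")


def read_cohort(
    scan_path: Union[str, Path], survival_path: Optional[Union[str, Path]] = None
) -> CohortTable:
    """Load a cohort from its scan CSV and optional companion survival CSV."""
    scans = pd.read_csv(scan_path)
    _check_columns(scans, SCAN_COLUMNS, scan_path)
    _fail_rows(scans["ce_volume_ul"] < 0, scan_path, "negative CE volume")
    dup = scans.duplicated(subset=["mouse_id", "scan_week"], keep=False)
    if dup.any():
        key = scans.loc[dup, ["mouse_id", "scan_week"]].iloc[0]
        _fail_rows(dup, scan_path, f"duplicate (mouse_id, scan_week) key "
                                   f"({key.mouse_id!r}, {key.scan_week})")
    dose_levels = scans.groupby("mouse_id")["dose_gy"].nunique()
    if (dose_levels > 1).any():
        bad = dose_levels[dose_levels > 1].index.tolist()
        raise CohortFormatError(f"{scan_path}: dose varies within mouse_id(s) {bad}")

    survival = None
    if survival_path is not None:
        survival = pd.read_csv(survival_path)
        _check_columns(survival, SURVIVAL_COLUMNS, survival_path)
        _fail_rows(~survival["event"].isin([0, 1]), survival_path, "event flag not in {0,1}")
        _fail_rows(survival.duplicated(subset=["mouse_id"], keep=False),
                   survival_path, "duplicate mouse_id")
    return CohortTable.from_frames(scans, survival)


def write_cohort(
    table: CohortTable,
    scan_path: Union[str, Path],
    survival_path: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a cohort to the scan CSV and, optionally, the survival CSV."""
    scans = table.scan_frame()
    scans.to_csv(scan_path, index=False, float_format="%.6g")
    if survival_path is not None:
        table.survival_frame().to_csv(survival_path, index=False, float_format="%.6g")
    digest = hashlib.sha256(scans.to_csv(index=False, float_format="%.6g").encode()).hexdigest()
    logger.info(
        "wrote cohort (%d mice, %d scan rows) to %s [braintox %s, seed=%s, sha256=%s]",
        len(table), len(scans), scan_path, _VERSION, seed, digest[:12],
    )


def fit_result_to_json(result: FitResult) -> str:
    import json

    return json.dumps(result.to_dict(), indent=2)


def read_supplementary_export(
    scan_path: Union[str, Path], survival_path: Optional[Union[str, Path]] = None
) -> CohortTable:
    """Import adapter for the study's contoured-volume/onset export.

    The study's contoured MRI volumes and onset times are distributed as a
    supplementary data export whose exact layout is not fixed here;
    once that file is mapped onto the documented cohort schema (scan CSV,
    optional survival CSV) this single entry point feeds it to the same
    fitting pipeline as simulated cohorts.
    """
    return read_cohort(scan_path, survival_path)
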