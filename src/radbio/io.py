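"""Reading and writing DVH files and cohort manifests.

Two DVH dialects are supported:

* **CSV schema** — columns ``structure,mode,dose_gy,volume``, one file per
  plan, any number of structures stacked.  For cumulative rows ``dose_gy``
  is the bin edge and ``volume`` the fraction receiving >= that dose; for
  differential rows ``dose_gy`` is the bin's *upper* edge (the first row's
  lower edge is 0) and ``volume`` the fractional volume in the bin.
  Absolute structure volumes ride in header comment lines of the form
  ``# structure=<name> volume_cc=<v>``.
* **Eclipse-style plain text** — blocks introduced by a line starting
  ``Structure:``, followed by a table whose header mentions ``Dose`` and
  ``Volume``; units are auto-detected (``cGy`` -> Gy, ``%`` volume ->
  fraction, ``cc``/``cm3`` volume -> fraction with the total retained).

The cohort manifest is a CSV with columns
``patient_id,location,ptv_cc,ref_dvh_path,recalc_dvh_path``; relative DVH
paths are resolved against the manifest's directory.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dvh import DoseVolumeHistogram, DVHValidationError, to_cumulative

__all__ = [
    "read_dvh_csv",
    "write_dvh_csv",
    "read_eclipse_text",
    "read_manifest",
    "write_manifest",
]


def read_dvh_csv(path) -> Dict[str, DoseVolumeHistogram]:
    """Read one plan's DVHs from the CSV schema, keyed by structure."""
    path = Path(path)
    volumes_cc: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.search(r"structure=(\S+)\s+volume_cc=([\d.eE+-]+)", line)
            if m:
                volumes_cc[m.group(1)] = float(m.group(2))
    df = pd.read_csv(path, comment="#")
    required = {"structure", "mode", "dose_gy", "volume"}
    if not required.issubset(df.columns):
        raise DVHValidationError(
            f"{path}: DVH CSV must have columns {sorted(required)}"
        )
    out: Dict[str, DoseVolumeHistogram] = {}
    for sid, grp in df.groupby("structure", sort=False):
        modes = grp["mode"].unique()
        if len(modes) != 1:
            raise DVHValidationError(f"{path}: mixed modes for structure {sid!r}")
        mode = modes[0]
        dose = grp["dose_gy"].to_numpy(dtype=float)
        vol = grp["volume"].to_numpy(dtype=float)
        if mode == "cumulative":
            edges, values = dose, vol
        elif mode == "differential":
            edges = np.concatenate([[0.0], dose])
            values = vol
        else:
            raise DVHValidationError(f"{path}: unknown mode {mode!r}")
        out[sid] = DoseVolumeHistogram(
            sid, edges, values, mode, total_volume_cc=volumes_cc.get(sid)
        )
    if not out:
        raise DVHValidationError(f"{path}: no DVH rows")
    return out


def write_dvh_csv(path, dvhs: Dict[str, DoseVolumeHistogram]) -> None:
    """Write a plan's DVHs in cumulative form (lossless for the pipeline)."""
    path = Path(path)
    lines: List[str] = []
    for sid, dvh in dvhs.items():
        if dvh.total_volume_cc is not None:
            lines.append(f"# structure={sid} volume_cc={dvh.total_volume_cc:.6g}")
    lines.append("structure,mode,dose_gy,volume")
    for sid, dvh in dvhs.items():
        cum = to_cumulative(dvh)
        for d, v in zip(cum.dose_edges, cum.volume):
            lines.append(f"{sid},cumulative,{float(d)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


_NUM_ROW = re.compile(r"^\s*[-+\d.]")


def read_eclipse_text(path) -> Dict[str, DoseVolumeHistogram]:
    """Read an Eclipse-style plain-text cumulative DVH export."""
    path = Path(path)
    out: Dict[str, DoseVolumeHistogram] = {}
    sid: Optional[str] = None
    dose_scale = 1.0
    vol_is_percent = False
    vol_is_absolute = False
    rows: List[Tuple[float, float]] = []
    total_cc: Optional[float] = None

    def flush() -> None:
        nonlocal rows
        if sid is None or not rows:
            rows = []
            return
        dose = np.array([r[0] for r in rows]) * dose_scale
        vol = np.array([r[1] for r in rows])
        if vol_is_percent:
            vol = vol / 100.0
        total = total_cc
        if vol_is_absolute:
            total = float(vol.max())
            vol = vol / total
        if dose[0] > 1e-9:  # extend the recorded curve back to 0 Gy
            dose = np.concatenate([[0.0], dose])
            vol = np.concatenate([[vol[0]], vol])
        vol = np.minimum.accumulate(np.clip(vol, 0.0, None))
        if abs(vol[0] - 1.0) <= 1e-3:
            vol[0] = 1.0
        out[sid] = DoseVolumeHistogram(sid, dose, vol, "cumulative", total)
        rows = []

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line.lower().startswith("structure:"):
            flush()
            sid = line.split(":", 1)[1].strip()
            dose_scale, vol_is_percent, vol_is_absolute, total_cc = 1.0, False, False, None
            continue
        if sid is None:
            continue
        m = re.match(r"volume\s*\[?\s*(cm3|cc)", line, re.IGNORECASE)
        if m:
            try:
                total_cc = float(line.split(":")[-1])
            except ValueError:
                pass
            continue
        if "dose" in line.lower() and "volume" in line.lower():
            dose_scale = 0.01 if "cgy" in line.lower() else 1.0
            vol_part = line.lower()[line.lower().index("volume"):]
            vol_is_percent = "%" in vol_part
            vol_is_absolute = ("cm3" in vol_part or "cc" in vol_part)
            continue
        if _NUM_ROW.match(line):
            parts = line.split()
            try:
                rows.append((float(parts[0]), float(parts[-1])))
            except ValueError:
                continue
    flush()
    if not out:
        raise DVHValidationError(f"{path}: no DVH blocks found")
    return out


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest, resolving DVH paths against its directory."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"patient_id", "location", "ptv_cc", "ref_dvh_path", "recalc_dvh_path"}
    if not required.issubset(df.columns):
        raise DVHValidationError(f"{path}: manifest must have columns {sorted(required)}")
    bad = set(df["location"]) - {"peripheral", "central"}
    if bad:
        raise DVHValidationError(f"{path}: unknown tumor locations {sorted(bad)}")
    for col in ("ref_dvh_path", "recalc_dvh_path"):
        df[col] = [str((path.parent / p)) for p in df[col]]
    return df


def write_manifest(path, rows: List[dict]) -> None:
    path = Path(path)
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "location", "ptv_cc", "ref_dvh_path", "recalc_dvh_path"],
    )
    df.to_csv(path, index=False)
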