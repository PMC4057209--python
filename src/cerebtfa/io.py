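"""Delimited-text readers and writers for recordings, panels and cohorts.

Time series travel as CSV with header ``time_s,map_mmHg,mcav_cm_s``;
blood-gas panels as single-row CSV with header
``paO2_kPa,saO2_frac,paCO2_kPa,hb_mM,caO2_mM``. A generated cohort is
written as one file per cell plus a ``layout.yaml`` study description
and a ``ground_truth.json`` sidecar holding the simulator parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import IngestError
from .oxygen import BloodGasPanel
from .preprocess import HemodynamicRecording
from .simulate import SyntheticCohort

RECORDING_COLUMNS = ("time_s", "map_mmHg", "mcav_cm_s")
PANEL_COLUMNS = ("paO2_kPa", "saO2_frac", "paCO2_kPa", "hb_mM", "caO2_mM")


def write_recording(rec: HemodynamicRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": rec.time, "map_mmHg": rec.map, "mcav_cm_s": rec.mcav}
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_recording(
    path: str | Path,
    subject_id: str = "",
    condition: str = "",
    intervention: str = "",
) -> HemodynamicRecording:
    """Parse a delimited time-series file into a recording.

    The sampling rate is inferred from the time column, which must be a
    uniform gap-free grid; irregular spacing is an ingest error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as a named ingest error
        raise IngestError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path} lacks required columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise IngestError(f"{path} holds fewer than 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise IngestError(f"{path} has a non-uniform time grid (gaps are not imputed)")
    return HemodynamicRecording(
        map=df["map_mmHg"].to_numpy(dtype=float),
        mcav=df["mcav_cm_s"].to_numpy(dtype=float),
        sampling_rate=1.0 / float(dt[0]),
        subject_id=subject_id,
        condition=condition,
        intervention=intervention,
    )


def write_panel(panel: BloodGasPanel, path: str | Path) -> Path:
    path = Path(path)
    row = {
        "paO2_kPa": panel.paO2,
        "saO2_frac": panel.saO2,
        "paCO2_kPa": panel.paCO2,
        "hb_mM": panel.hb,
        "caO2_mM": panel.caO2,
    }
    pd.DataFrame([row]).to_csv(path, index=False, float_format="%.6f")
    return path


def read_panel(path: str | Path) -> BloodGasPanel:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise IngestError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path} lacks required columns {missing}")
    if len(df) != 1:
        raise IngestError(f"{path} must hold exactly one panel row, found {len(df)}")
    r = df.iloc[0]
    # caO2 was rounded on write; recompute from the stored fields.
    return BloodGasPanel(
        paO2=float(r["paO2_kPa"]),
        saO2=float(r["saO2_frac"]),
        paCO2=float(r["paCO2_kPa"]),
        hb=float(r["hb_mM"]),
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a synthetic cohort as files plus layout and ground-truth sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout: dict = {"subjects": {}}
    truth_out: dict = {}
    for (sid, condition, intervention), rec in sorted(cohort.recordings.items()):
        stem = f"{sid}_{condition}_{intervention}"
        rec_path = write_recording(rec, outdir / f"{stem}.csv")
        panel_path = write_panel(cohort.panels[(sid, condition, intervention)], outdir / f"{stem}_gases.csv")
        layout["subjects"].setdefault(sid, {}).setdefault(condition, {})[intervention] = {
            "recording": rec_path.name,
            "blood_gas": panel_path.name,
        }
        truth_out[f"{sid}/{condition}/{intervention}"] = asdict(
            cohort.ground_truth[(sid, condition, intervention)]
        )
    (outdir / "layout.yaml").write_text(yaml.safe_dump(layout, sort_keys=True))
    (outdir / "ground_truth.json").write_text(json.dumps(truth_out, indent=1, sort_keys=True))
    return outdir
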