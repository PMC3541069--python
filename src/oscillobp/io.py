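"""CSV/JSON/YAML serialisation for recordings, envelopes and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import ArteryModel, CuffModel, PressureWaveform, derive_a, derive_b
from .scenarios import Scenario, ValidationReport
from .simulate import Envelope, Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_envelope",
    "read_envelope",
    "write_report",
    "read_report",
    "report_to_csv",
    "load_scenario_config",
]

_REC_COLUMNS = ["time_s", "cuff_pressure_mmHg", "oscillation_mmHg"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    osc = rec.osc if rec.osc is not None else np.full(rec.P.size, np.nan)
    df = pd.DataFrame({"time_s": rec.t, "cuff_pressure_mmHg": rec.P, "oscillation_mmHg": osc})
    df.to_csv(path, index=False, float_format="%.8g")
    meta = dict(rec.meta, sample_rate=rec.sample_rate)
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording CSV; the metadata sidecar is optional."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REC_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path} lacks required columns {missing}")
    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    t = df["time_s"].to_numpy(float)
    if "sample_rate" in meta:
        rate = float(meta.pop("sample_rate"))
    else:
        rate = 1.0 / float(np.median(np.diff(t)))
    osc = None
    if "oscillation_mmHg" in df.columns and df["oscillation_mmHg"].notna().any():
        osc = df["oscillation_mmHg"].to_numpy(float)
    return Recording(
        t=t, P=df["cuff_pressure_mmHg"].to_numpy(float), osc=osc, sample_rate=rate, meta=meta
    )


def write_envelope(env: Envelope, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "beat_index": env.beat_indices,
            "cuff_pressure_mmHg": env.pressures,
            "amplitude_mmHg": env.amplitudes,
        }
    ).to_csv(path, index=False, float_format="%.8g")
    return path


def read_envelope(path: str | Path) -> Envelope:
    df = pd.read_csv(path)
    return Envelope(
        pressures=df["cuff_pressure_mmHg"].to_numpy(float),
        amplitudes=df["amplitude_mmHg"].to_numpy(float),
        beat_indices=df["beat_index"].to_numpy(int),
    )


def write_report(report: ValidationReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1))
    return path


def read_report(path: str | Path) -> ValidationReport:
    return ValidationReport.from_dict(json.loads(Path(path).read_text()))


def report_to_csv(report: ValidationReport, path: str | Path) -> Path:
    """Flat CSV of the validation table: scenario, parameter, actual, algorithm."""
    path = Path(path)
    records = []
    for r in report.rows:
        for param, actual, algo in [
            ("a", r.true_a, r.a_hat),
            ("b", r.true_b, r.b_hat),
            ("SBP", r.true_SBP, r.SBP_hat),
            ("DBP", r.true_DBP, r.DBP_hat),
        ]:
            records.append(
                {"scenario": r.name, "parameter": param, "actual": actual, "algorithm": algo}
            )
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.6g")
    return path


def load_scenario_config(path: str | Path, name: str | None = None) -> Scenario:
    """Build a Scenario from a YAML or JSON configuration file.

    Recognised keys (all optional, defaults are the standard normal model):
    ``sbp, dbp, heart_rate_bpm`` (or ``f`` in Hz, values above 10 are taken
    as beats/min), ``p0, r, v0`` (cuff), ``va0, a, b`` or the derivation
    inputs ``pc, cn, pmid``, plus ``noise_sd, seed, duration, dt, name``.
    Explicit ``a``/``b`` override the derivation inputs.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"scenario config {path} must be a mapping")
    cfg = {str(k).lower(): v for k, v in cfg.items()}

    if "heart_rate_bpm" in cfg:
        f = float(cfg["heart_rate_bpm"]) / 60.0
    elif "f" in cfg:
        f = float(cfg["f"])
        if f > 10.0:  # beats/min, not Hz
            f /= 60.0
    else:
        f = 80.0 / 60.0
    waveform = PressureWaveform(
        SBP=float(cfg.get("sbp", 120.0)), DBP=float(cfg.get("dbp", 80.0)), f=f
    )

    va0 = float(cfg.get("va0", 0.3))
    a = cfg.get("a")
    b = cfg.get("b")
    if a is None:
        a = derive_a(float(cfg["pc"])) if "pc" in cfg else 0.11
    if b is None:
        if "cn" in cfg:
            b = derive_b(float(cfg["cn"]), float(a), va0, float(cfg.get("pmid", 100.0)))
        else:
            b = 0.03
    artery = ArteryModel(a=float(a), b=float(b), Va0=va0)

    cuff = CuffModel(
        V0=float(cfg.get("v0", 300.0)),
        P0=float(cfg.get("p0", 150.0)),
        r=float(cfg.get("r", 3.0)),
    )
    return Scenario(
        name=name or str(cfg.get("name", path.stem)),
        truth=waveform,
        artery=artery,
        cuff=cuff,
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        seed=cfg.get("seed"),
        duration=float(cfg.get("duration", 40.0)),
        dt=float(cfg.get("dt", 5e-4)),
    )
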