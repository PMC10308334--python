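"""Delimited-text readers and writers for pipeline objects.

All files are UTF-8, comma-separated, '.' decimal, Unix newlines
(readers tolerate CRLF).  Formats:

* sensorgram:      ``time_s,response,phase,concentration_M,channel``
* QCM-D trace:     ``time_s,f3_hz,d3_1e6[,f5_hz,d5_1e6,...]`` plus a JSON
                   sidecar with stage annotations ``[{name,start_s,end_s}]``
* calibration:     ``concentration_particles_per_ml,signal``
* blank set:       one signal per line
* sample panel:    ``sample_id,channel,signal,dilution_factor,
                   reference_concentration,reference_sd`` (extra columns
                   such as ``replicate`` are preserved)

Readers are tolerant of extra columns (kept as metadata) and report
malformed rows with line numbers.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import BlankSet
from .kinetics import Sensorgram
from .qcmd import QcmdTrace, StageAnnotation

__all__ = [
    "ParseError",
    "read_timeseries",
    "write_sensorgram",
    "read_sensorgram",
    "write_qcmd_trace",
    "read_qcmd_trace",
    "write_calibration_table",
    "read_calibration_table",
    "write_blankset",
    "read_blankset",
    "write_panel",
    "read_panel",
]


class ParseError(ValueError):
    """Malformed input file; the message names the first offending line."""


_SENSORGRAM_COLUMNS = ["time_s", "response", "phase", "concentration_M", "channel"]
_PHASES = {"baseline", "association", "dissociation"}


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df

def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ParseError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
            f"{col!r} at line {line} (use '.' as the decimal separator)"
        )
    return converted.to_numpy(dtype=float)


def _check_monotone_time(t: np.ndarray, path: Path) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise ParseError(
            f"{path}: time not strictly increasing at line {int(bad[0]) + 3}"
        )


def write_sensorgram(s: Sensorgram, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": s.time,
            "response": s.response,
            "phase": s.phase,
            "concentration_M": s.concentration,
            "channel": s.channel,
        }
    )
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_sensorgram(path: str | Path) -> Sensorgram:
    path = Path(path)
    df = _read_csv(path, _SENSORGRAM_COLUMNS)
    t = _numeric(df, "time_s", path)
    _check_monotone_time(t, path)
    resp = _numeric(df, "response", path)
    conc = _numeric(df, "concentration_M", path)
    phases = df["phase"].astype(str).to_numpy()
    unknown = set(phases) - _PHASES
    if unknown:
        raise ParseError(f"{path}: unknown phase labels {sorted(unknown)}")
    channels = df["channel"].astype(str).unique()
    if len(channels) != 1 or len(np.unique(conc)) != 1:
        raise ParseError(f"{path}: sensorgram files hold one channel and concentration")
    extras = {
        c: df[c].to_numpy() for c in df.columns if c not in _SENSORGRAM_COLUMNS
    }
    return Sensorgram(t, resp, phases, float(conc[0]), str(channels[0]), extras=extras)


def write_qcmd_trace(
    trace: QcmdTrace, path: str | Path, stages_path: str | Path
) -> None:
    data = {"time_s": trace.time}
    for ot in trace.overtones:
        data[f"f{ot}_hz"] = trace.delta_f[ot]
        data[f"d{ot}_1e6"] = trace.delta_d[ot]
    pd.DataFrame(data).to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    ann = [
        {
            "name": st.name,
            "start_s": float(trace.time[st.start]),
            "end_s": float(trace.time[st.end - 1]),
        }
        for st in trace.stages
    ]
    Path(stages_path).write_text(json.dumps(ann, indent=1) + "\n", encoding="utf-8")


def read_qcmd_trace(path: str | Path, stages_path: str | Path) -> QcmdTrace:
    path = Path(path)
    df = _read_csv(path, ["time_s"])
    t = _numeric(df, "time_s", path)
    _check_monotone_time(t, path)
    delta_f: dict[int, np.ndarray] = {}
    delta_d: dict[int, np.ndarray] = {}
    extras = {}
    for col in df.columns:
        m = re.fullmatch(r"f(\d+)_hz", col)
        if m:
            delta_f[int(m.group(1))] = _numeric(df, col, path)
            continue
        m = re.fullmatch(r"d(\d+)_1e6", col)
        if m:
            delta_d[int(m.group(1))] = _numeric(df, col, path)
            continue
        if col != "time_s":
            extras[col] = df[col].to_numpy()
    if not delta_f:
        raise ParseError(f"{path}: no overtone columns (expected e.g. f3_hz,d3_1e6)")
    if set(delta_f) != set(delta_d):
        raise ParseError(f"{path}: mismatched f/d overtone columns")
    ann = json.loads(Path(stages_path).read_text(encoding="utf-8"))
    stages = []
    for a in ann:
        start = int(np.searchsorted(t, float(a["start_s"]), side="left"))
        end = int(np.searchsorted(t, float(a["end_s"]), side="right"))
        stages.append(StageAnnotation(str(a["name"]), start, end))
    return QcmdTrace(time=t, delta_f=delta_f, delta_d=delta_d, stages=stages, extras=extras)


def write_calibration_table(concentrations, signals, path: str | Path) -> None:
    pd.DataFrame(
        {"concentration_particles_per_ml": concentrations, "signal": signals}
    ).to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_calibration_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    df = _read_csv(path, ["concentration_particles_per_ml", "signal"])
    return (
        _numeric(df, "concentration_particles_per_ml", path),
        _numeric(df, "signal", path),
    )


def write_blankset(blanks: BlankSet, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{float(v)!r}\n" for v in blanks.values), encoding="utf-8"
    )


def read_blankset(
    path: str | Path, channel: str = "", signal_kind: str = "qcmd_freq_step"
) -> BlankSet:
    path = Path(path)
    values = []
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            values.append(float(line))
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric blank value at line {i}") from exc
    return BlankSet(np.asarray(values), channel=channel, signal_kind=signal_kind)


_PANEL_COLUMNS = ["sample_id", "channel", "signal", "dilution_factor"]


def write_panel(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_panel(path: str | Path) -> list[dict]:
    path = Path(path)
    df = _read_csv(path, _PANEL_COLUMNS)
    for col in ("signal", "dilution_factor"):
        _numeric(df, col, path)
    return df.to_dict(orient="records")


def read_timeseries(path: str | Path, kind: str, stages_path: str | Path | None = None):
    """Read a time series of the given kind (``"spr"`` or ``"qcmd"``)."""
    if kind == "spr":
        return read_sensorgram(path)
    if kind == "qcmd":
        if stages_path is None:
            stages_path = Path(path).with_suffix(".stages.json")
        return read_qcmd_trace(path, stages_path)
    raise ValueError(f"unknown time-series kind {kind!r}")
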