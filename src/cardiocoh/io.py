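"""Plain-text file formats and the cohort manifest.

* RR file: CSV with header ``beat_time_s,rr_ms`` — one row per interval,
  timestamped at the interval's starting beat.  The final beat time is
  recovered as ``last start + last rr/1000``.
* Respiration file: CSV with header ``time_s,amplitude`` on a uniform grid.
* Manifest: YAML (``schema_version: 1``) listing, per participant, the
  condition label, the seed and the four phase files.  Paths are relative
  to the manifest's directory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import RespSignal, RRSeries
from .synth import Participant

__all__ = ["ManifestEntry", "CohortManifest", "write_rr", "read_rr",
           "write_resp", "read_resp", "write_cohort", "read_manifest"]

MANIFEST_SCHEMA_VERSION = 1
_PHASES = ("video", "guided")


#: 17 significant digits: exact float64 round-trip
_FLOAT_FMT = "%.17g"


def write_rr(rr: RRSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"beat_time_s": rr.beat_times[:-1], "rr_ms": rr.rr_ms}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_rr(path) -> RRSeries:
    df = _read_two_column(path, ("beat_time_s", "rr_ms"))
    times = df["beat_time_s"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)
    beat_times = np.append(times, times[-1] + rr[-1] / 1000.0)
    return RRSeries(beat_times, rr)


def write_resp(resp: RespSignal, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": resp.times, "amplitude": resp.samples}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_resp(path) -> RespSignal:
    df = _read_two_column(path, ("time_s", "amplitude"))
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.abs(dt - dt[0]).max() > 1e-6:
        raise ValueError(f"{path}: time grid is not uniform")
    return RespSignal(fs=1.0 / dt[0], samples=df["amplitude"].to_numpy(float),
                      start_time=float(t[0]))


def _read_two_column(path, columns: tuple[str, str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # surface the offending file and line
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    numeric = df[list(columns)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-numeric or missing value at line {line}")
    return numeric


@dataclass(frozen=True)
class ManifestEntry:
    """One participant's condition, seed and phase files (absolute paths)."""

    participant_id: str
    condition: str
    seed: int
    rr: dict
    resp: dict


@dataclass
class CohortManifest:
    entries: list
    root: Path

    def __post_init__(self) -> None:
        ids = [e.participant_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("participant ids must be unique")
        for e in self.entries:
            for phase in _PHASES:
                if phase not in e.rr or phase not in e.resp:
                    raise ValueError(
                        f"{e.participant_id}: missing {phase} phase files")
                for p in (e.rr[phase], e.resp[phase]):
                    if not Path(p).exists():
                        raise FileNotFoundError(f"{e.participant_id}: {p}")


def write_cohort(participants: list[Participant], out_dir,
                 seed: int | None = None) -> Path:
    """Write every phase file plus ``manifest.yaml``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for p in participants:
        files = {}
        for phase, rr, resp in (("video", p.rr_video, p.resp_video),
                                ("guided", p.rr_guided, p.resp_guided)):
            rr_name = f"{p.participant_id}_rr_{phase}.csv"
            resp_name = f"{p.participant_id}_resp_{phase}.csv"
            write_rr(rr, out_dir / rr_name)
            write_resp(resp, out_dir / resp_name)
            files[phase] = {"rr": rr_name, "resp": resp_name}
        records.append({
            "id": p.participant_id,
            "condition": p.condition,
            "seed": int(p.seed),
            "files": {
                "rr_video": files["video"]["rr"],
                "rr_guided": files["guided"]["rr"],
                "resp_video": files["video"]["resp"],
                "resp_guided": files["guided"]["resp"],
            },
        })
    doc = {"schema_version": MANIFEST_SCHEMA_VERSION, "participants": records}
    if seed is not None:
        doc["seed"] = int(seed)
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return manifest_path


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"{path}: invalid YAML{where} ({exc})") from exc
    if not isinstance(doc, dict) or "participants" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'participants' list")
    version = doc.get("schema_version")
    if version != MANIFEST_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema_version {version!r}")
    root = path.parent
    entries = []
    for rec in doc["participants"]:
        try:
            files = rec["files"]
            entries.append(ManifestEntry(
                participant_id=str(rec["id"]),
                condition=str(rec["condition"]),
                seed=int(rec.get("seed", 0)),
                rr={ph: root / files[f"rr_{ph}"] for ph in _PHASES},
                resp={ph: root / files[f"resp_{ph}"] for ph in _PHASES},
            ))
        except KeyError as exc:
            raise ValueError(f"{path}: participant record missing {exc}") from exc
    return CohortManifest(entries=entries, root=root)
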