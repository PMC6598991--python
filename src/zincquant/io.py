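"""File formats and run provenance.

Plain-text, versioned schemas throughout:

* traces — long-format CSV, one row per time x cell x channel:
  ``time_s, cell_id, channel, roi_mean, bg_mean`` (UTF-8, '.' decimal).
* protocol phases — JSON list of ``{name, t_start_s, t_end_s}``.
* titrations — CSV ``free_zn_nM, response, replicate_id``.
* images — TIFF, one channel per file or page.
* run manifest — JSON with tool version, timestamp, config hash and SHA-256
  digests of inputs/outputs, so any stage can be re-run and verified from
  its serialized inputs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import ProtocolPhase, validate_phases
from .titration import TitrationDataset, TitrationFit
from .traces import CellQuantification, ExperimentSummary, RoiTrace

SCHEMA_VERSION = 1
TRACE_COLUMNS = ["time_s", "cell_id", "channel", "roi_mean", "bg_mean"]

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_phase_json",
    "write_phase_json",
    "read_titration_csv",
    "write_titration_csv",
    "write_fit_report",
    "write_quantification_csv",
    "write_summary_json",
    "RunManifest",
    "write_manifest",
]


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


def write_trace_csv(traces: Sequence[RoiTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for ch, vals in tr.channels.items():
            bg = tr.background[ch]
            for t, v, b in zip(tr.time_s, vals, bg):
                rows.append((t, tr.cell_id, ch, v, b))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> list[RoiTrace]:
    """Parse the long-format trace CSV into per-cell traces.

    Rows may arrive in any order; they are sorted by time within each
    cell/channel.  Missing columns, non-monotone time after sorting
    (duplicate time points) and channel-length mismatches raise
    :class:`SchemaError` naming the offender.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    traces = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        channels: dict[str, np.ndarray] = {}
        background: dict[str, np.ndarray] = {}
        time_ref = None
        for ch, sub in group.groupby("channel", sort=True):
            sub = sub.sort_values("time_s")
            t = sub["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                bad = int(np.argmax(np.diff(t) <= 0)) + 1
                raise SchemaError(
                    f"{path}: cell {cell_id!r} channel {ch!r}: time not strictly "
                    f"increasing at row {bad} (t = {t[bad]})"
                )
            if time_ref is None:
                time_ref = t
            elif t.size != time_ref.size or not np.allclose(t, time_ref):
                raise SchemaError(
                    f"{path}: cell {cell_id!r}: channel {ch!r} time base differs "
                    "from the other channels"
                )
            channels[str(ch)] = sub["roi_mean"].to_numpy(dtype=float)
            background[str(ch)] = sub["bg_mean"].to_numpy(dtype=float)
        traces.append(RoiTrace(str(cell_id), time_ref, channels, background))
    return traces


def write_phase_json(phases: Sequence[ProtocolPhase], path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "phases": [
            {"name": p.name, "t_start_s": p.t_start_s, "t_end_s": p.t_end_s} for p in phases
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_phase_json(path: str | Path) -> list[ProtocolPhase]:
    raw = json.loads(Path(path).read_text())
    items = raw["phases"] if isinstance(raw, dict) else raw
    try:
        phases = [ProtocolPhase(p["name"], p["t_start_s"], p["t_end_s"]) for p in items]
        return validate_phases(phases)
    except (KeyError, TypeError, ValueError) as e:
        raise SchemaError(f"{path}: {e}") from e


def write_titration_csv(data: TitrationDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "free_zn_nM": data.free_zn_nM,
            "response": data.response,
            "replicate_id": data.replicate_id,
        }
    ).to_csv(path, index=False)


def read_titration_csv(path: str | Path) -> TitrationDataset:
    df = pd.read_csv(path)
    missing = [c for c in ("free_zn_nM", "response", "replicate_id") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return TitrationDataset(
        free_zn_nM=df["free_zn_nM"].to_numpy(dtype=float),
        response=df["response"].to_numpy(dtype=float),
        replicate_id=df["replicate_id"].to_numpy(),
    )


def write_fit_report(fit: TitrationFit, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "converged": fit.converged,
        "message": fit.message,
        "n_points": fit.n_points,
        "residual_sse": fit.residual_sse,
        "standard_errors": fit.standard_errors,
    }
    if fit.converged and fit.params is not None:
        payload["kd_nM"] = fit.params.kd_nM
        payload["hill_n"] = fit.params.hill_n
        payload["f_min"] = fit.endpoints.f_min
        payload["f_max"] = fit.endpoints.f_max
    Path(path).write_text(json.dumps(payload, indent=2))


def write_quantification_csv(cells: Sequence[CellQuantification], path: str | Path) -> None:
    rows = []
    for c in cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "excluded": c.excluded,
                "exclude_reason": c.exclude_reason,
                "resting_fs": float(c.resting_fs) if c.resting_fs is not None else np.nan,
                "peak_fs": float(c.peak_fs) if c.peak_fs is not None else np.nan,
                "resting_conc_pM": c.resting_conc_pM,
                "peak_conc_pM": c.peak_conc_pM,
                "f_min": c.endpoints.f_min if c.endpoints else np.nan,
                "f_max": c.endpoints.f_max if c.endpoints else np.nan,
                "qc_flags": ";".join(c.qc_flags),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary_json(summary: ExperimentSummary, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **asdict(summary)}
    Path(path).write_text(json.dumps(payload, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI stage's outputs."""

    tool_version: str
    timestamp: str
    config: dict
    config_hash: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)


def write_manifest(
    out_dir: str | Path,
    config: dict,
    inputs: Sequence[str | Path] = (),
    outputs: Sequence[str | Path] = (),
) -> Path:
    from . import __version__

    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = RunManifest(
        tool_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config=json.loads(config_json),
        config_hash=hashlib.sha256(config_json.encode()).hexdigest(),
        inputs={str(p): _sha256(Path(p)) for p in inputs},
        outputs=[str(p) for p in outputs],
    )
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2))
    return path
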