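"""Plain-text motion-capture I/O: TRC marker files and gait-event sidecars.

TRC is the tab-delimited marker-trajectory format written by most optical
motion-capture pipelines: a five-line header (file type, metadata names,
metadata values, marker names, per-marker X/Y/Z column labels) followed by
one row per frame. Units are auto-detected from the header (mm or m);
internally everything is meters. Gait events (heel strike, toe off) travel
in a small JSON sidecar: ``{"heel_strike": t, "toe_off": t}`` in seconds.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ik import MarkerTrial

__all__ = ["read_trc", "write_trc", "read_events", "write_events"]


def write_trc(
    path: str | Path,
    trial: MarkerTrial,
    units: str = "mm",
    data_rate: float | None = None,
) -> None:
    """Write a trial as a standard TRC file (positions converted to ``units``)."""
    path = Path(path)
    n, m = trial.n_frames, len(trial.marker_names)
    if data_rate is None:
        dt = np.median(np.diff(trial.times)) if n > 1 else 1.0
        data_rate = 1.0 / dt
    factor = {"mm": 1000.0, "m": 1.0}[units]
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
        "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{data_rate:.6f}\t{data_rate:.6f}\t{n}\t{m}\t{units}\t"
        f"{data_rate:.6f}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(trial.marker_names) + "\t\t",
        "\t\t"
        + "\t".join(
            f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(m)
        ),
        "",
    ]
    for i in range(n):
        cells = [str(i + 1), f"{trial.times[i]:.6f}"]
        for k in range(m):
            p = trial.positions[i, k] * factor
            if np.all(np.isfinite(p)):
                cells.extend(f"{v:.6f}" for v in p)
            else:
                cells.extend(["", "", ""])
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_trc(path: str | Path, events: dict[str, float] | None = None) -> MarkerTrial:
    """Read a TRC file; empty cells become NaN (occluded samples)."""
    raw = Path(path).read_text().splitlines()
    if len(raw) < 5:
        raise ValueError(f"{path}: not a TRC file (fewer than 5 header lines)")
    meta_names = raw[1].split("\t")
    meta_vals = raw[2].split("\t")
    meta = dict(zip(meta_names, meta_vals))
    units = meta.get("Units", "mm").strip()
    factor = {"mm": 1e-3, "m": 1.0}.get(units)
    if factor is None:
        raise ValueError(f"{path}: unsupported units {units!r}")
    header = raw[3].split("\t")
    marker_names = [h.strip() for h in header[2:] if h.strip()]
    times, rows = [], []
    for line in raw[5:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        times.append(float(cells[1]))
        vals = [
            float(c) if c.strip() else np.nan for c in cells[2 : 2 + 3 * len(marker_names)]
        ]
        vals.extend([np.nan] * (3 * len(marker_names) - len(vals)))
        rows.append(vals)
    positions = np.asarray(rows, dtype=float).reshape(len(rows), len(marker_names), 3)
    return MarkerTrial(
        marker_names=marker_names,
        times=np.asarray(times, dtype=float),
        positions=positions * factor,
        events=events,
    )


def read_events(path: str | Path) -> dict[str, float]:
    d = json.loads(Path(path).read_text())
    return {"heel_strike": float(d["heel_strike"]), "toe_off": float(d["toe_off"])}


def write_events(path: str | Path, events: dict[str, float]) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "heel_strike": events["heel_strike"],
                "toe_off": events["toe_off"],
            },
            indent=1,
        )
    )
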