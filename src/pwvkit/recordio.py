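"""Plain-text recording and report I/O.

On-disk dialect: a CSV file with ``#key=value`` comment header lines
carrying all metadata (format version, sampling rate, electrode distance,
start time, sample count, provenance as JSON), a ``time,prox,dist`` column
header and one row per sample with full-precision floats, so a write/read
round trip is exact.  The time column is stored explicitly so that grid
uniformity can be verified on read.  All units are SI.
"""

from __future__ import annotations

import json
import math
import os
from typing import Any

import numpy as np

from .dspcore import TimeSeries
from .errors import RecordingFormatError
from .pwvcalc import PulseRecording

__all__ = ["write_recording", "read_recording", "write_report", "FORMAT_VERSION"]

FORMAT_VERSION = 1
REPORT_SCHEMA = "pwvkit-report-v1"

_REQUIRED_KEYS = ("fs", "distance")
_COLUMNS = "time,prox,dist"


def write_recording(path: str | os.PathLike, rec: PulseRecording) -> None:
    """Write a recording in the pwvkit CSV dialect.

    Floats are emitted with shortest round-trip precision, so reading the
    file back reproduces every sample bit-exactly.
    """
    lines = [
        f"#pwvkit_recording={FORMAT_VERSION}",
        f"#fs={rec.fs!r}",
        f"#distance={rec.distance!r}",
        f"#start_time={rec.prox.start_time!r}",
        f"#n_samples={rec.prox.n}",
        "#channels=prox,dist",
    ]
    if rec.provenance:
        lines.append(f"#provenance={json.dumps(rec.provenance, sort_keys=True)}")
    lines.append(_COLUMNS)
    t = rec.prox.times
    p = rec.prox.samples
    d = rec.dist.samples
    rows = [
        f"{float(t[i])!r},{float(p[i])!r},{float(d[i])!r}" for i in range(rec.prox.n)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines + rows))
        fh.write("\n")


def _parse_header_value(key: str, raw: str, line_no: int) -> Any:
    if key == "provenance":
        try:
            return json.loads(raw)
        except json.JSONDecodeError as exc:
            raise RecordingFormatError(f"bad provenance JSON: {exc}", line=line_no)
    if key in ("fs", "distance", "start_time"):
        try:
            return float(raw)
        except ValueError:
            raise RecordingFormatError(f"header {key}={raw!r} is not a number", line=line_no)
    if key == "n_samples":
        try:
            return int(raw)
        except ValueError:
            raise RecordingFormatError(f"header n_samples={raw!r} is not an integer", line=line_no)
    return raw


def read_recording(path: str | os.PathLike) -> PulseRecording:
    """Read and validate a recording written by :func:`write_recording`.

    Checks performed: required metadata present, exactly two data channels,
    numeric rows (with line numbers on failure), declared sample count, a
    uniform time grid, and agreement between the declared rate and the time
    column to 1e-6 relative.
    """
    meta: dict[str, Any] = {}
    times: list[float] = []
    prox: list[float] = []
    dist: list[float] = []
    saw_columns = False
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise RecordingFormatError(
                        f"malformed header comment {line!r}", line=line_no
                    )
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = _parse_header_value(key.strip(), value, line_no)
                continue
            if not saw_columns:
                cols = [c.strip() for c in line.split(",")]
                if len(cols) != 3:
                    raise RecordingFormatError(
                        f"unsupported channel count: expected 3 columns "
                        f"(time,prox,dist), found {len(cols)}",
                        line=line_no,
                    )
                if cols != _COLUMNS.split(","):
                    raise RecordingFormatError(
                        f"unexpected column header {line!r}", line=line_no
                    )
                saw_columns = True
                continue
            fields = line.split(",")
            if len(fields) != 3:
                raise RecordingFormatError(
                    f"expected 3 comma-separated values, found {len(fields)}",
                    line=line_no,
                )
            try:
                tv, pv, dv = (float(f) for f in fields)
            except ValueError:
                raise RecordingFormatError(f"non-numeric row {line!r}", line=line_no)
            if math.isnan(tv) or math.isnan(pv) or math.isnan(dv):
                raise RecordingFormatError("NaN sample value", line=line_no)
            times.append(tv)
            prox.append(pv)
            dist.append(dv)

    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise RecordingFormatError(f"missing required header key {key!r}")
    if not saw_columns or not times:
        raise RecordingFormatError("file contains no data rows")

    fs = meta["fs"]
    if not fs > 0:
        raise RecordingFormatError(f"declared fs must be positive, got {fs}")
    n = len(times)
    if "n_samples" in meta and meta["n_samples"] != n:
        raise RecordingFormatError(
            f"declared n_samples={meta['n_samples']} but found {n} data rows"
        )
    t = np.asarray(times)
    if n >= 2:
        period = 1.0 / fs
        expected = t[0] + np.arange(n) * period
        dev = np.abs(t - expected)
        worst = int(np.argmax(dev))
        if dev[worst] > 1e-6 * period:
            raise RecordingFormatError(
                "non-uniform time grid: row deviates from the declared "
                f"1/fs={period!r} spacing by {dev[worst]:.3g} s",
                line=worst + 1,  # approximate: header offset not tracked here
            )
        fs_est = (n - 1) / (t[-1] - t[0])
        if abs(fs_est - fs) > 1e-6 * fs:
            raise RecordingFormatError(
                f"declared fs={fs} disagrees with time column (estimated {fs_est!r})"
            )
    start_time = meta.get("start_time", t[0])
    provenance = meta.get("provenance", {})
    if not isinstance(provenance, dict):
        provenance = {"raw": provenance}
    return PulseRecording(
        prox=TimeSeries(np.asarray(prox), fs, start_time=start_time),
        dist=TimeSeries(np.asarray(dist), fs, start_time=start_time),
        distance=meta["distance"],
        provenance=provenance,
    )


def write_report(path: str | os.PathLike, payload: dict) -> None:
    """Write a JSON analysis report with the versioned schema marker."""
    body = {"schema": REPORT_SCHEMA}
    body.update(payload)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
        fh.write("\n")
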