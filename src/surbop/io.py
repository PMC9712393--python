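"""Shape-file interchange: Bruker JCAMP-DX-style and plain two-column text.

Both dialects store one (amplitude %, phase degrees) pair per timestep;
amplitudes are percentages of a calibration peak amplitude, so converting to
control amplitudes in Hz requires the peak nutation frequency the shape is
meant to be played at.  The JCAMP-style dialect carries the point list inside
a ``##XYPOINTS= (XY..XY)`` block; this writer additionally records the pulse
duration in a private ``##$SHAPE_DURATION`` field (seconds) so files written
here round-trip without external timing information.  All writes use fixed
formatting, so output is deterministic given the inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__ as _version
from .pulse import ShapedPulse, cartesian_to_polar, polar_to_cartesian

import numpy as np

__all__ = [
    "ShapeFileRecord",
    "ShapeFileError",
    "read_record",
    "write_record",
    "read_shape",
    "write_shape",
    "convert",
]

_PCT_TOL = 1e-9


class ShapeFileError(ValueError):
    """Malformed shape file; message includes the offending line number."""


@dataclass
class ShapeFileRecord:
    """Dialect-independent content of a shape file."""

    amplitudes_percent: np.ndarray
    phases_deg: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        amp = np.asarray(self.amplitudes_percent, dtype=float)
        ph = np.asarray(self.phases_deg, dtype=float)
        if amp.ndim != 1 or amp.shape != ph.shape or amp.size == 0:
            raise ShapeFileError("amplitude and phase lists must match and be non-empty")
        if np.any(amp < -_PCT_TOL) or np.any(amp > 100.0 + _PCT_TOL):
            raise ShapeFileError("amplitudes must lie within [0, 100] percent")
        self.amplitudes_percent = amp
        self.phases_deg = ph

    @property
    def n_points(self) -> int:
        return self.amplitudes_percent.size


_POINT_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*[, \t]\s*([-+0-9.eE]+)\s*$")


def _detect_dialect(lines) -> str:
    for line in lines:
        if line.strip():
            return "bruker" if line.lstrip().startswith("##") else "text"
    raise ShapeFileError("file is empty")


def _parse_point(line, lineno):
    m = _POINT_RE.match(line)
    if not m:
        raise ShapeFileError(f"line {lineno}: cannot parse shape point {line!r}")
    try:
        amp, phase = float(m.group(1)), float(m.group(2))
    except ValueError:
        raise ShapeFileError(f"line {lineno}: non-numeric shape point {line!r}") from None
    if not (-_PCT_TOL <= amp <= 100.0 + _PCT_TOL):
        raise ShapeFileError(
            f"line {lineno}: amplitude {amp} % outside the valid range [0, 100]"
        )
    return amp, phase


def _read_bruker(lines) -> ShapeFileRecord:
    metadata = {}
    amps, phases = [], []
    npoints = None
    in_points = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("##"):
            key, _, value = line.lstrip()[2:].partition("=")
            key = key.strip()
            value = value.strip()
            if key.upper() == "END":
                break
            if key.upper() == "NPOINTS":
                try:
                    npoints = int(value)
                except ValueError:
                    raise ShapeFileError(f"line {lineno}: bad ##NPOINTS value {value!r}")
            elif key.upper() == "XYPOINTS":
                in_points = True
                continue
            else:
                metadata[key] = value
            in_points = key.upper() == "XYPOINTS"
        elif in_points:
            amp, phase = _parse_point(line, lineno)
            amps.append(amp)
            phases.append(phase)
        else:
            raise ShapeFileError(f"line {lineno}: unexpected content {line!r}")
    if not amps:
        raise ShapeFileError("no ##XYPOINTS data found")
    if npoints is not None and npoints != len(amps):
        raise ShapeFileError(
            f"##NPOINTS={npoints} but {len(amps)} points were read"
        )
    return ShapeFileRecord(np.array(amps), np.array(phases), metadata)


def _read_text(lines) -> ShapeFileRecord:
    amps, phases = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        amp, phase = _parse_point(line, lineno)
        amps.append(amp)
        phases.append(phase)
    if not amps:
        raise ShapeFileError("no shape points found")
    return ShapeFileRecord(np.array(amps), np.array(phases))


def read_record(path) -> ShapeFileRecord:
    """Read either dialect (auto-detected) into a :class:`ShapeFileRecord`."""
    lines = Path(path).read_text().splitlines()
    if _detect_dialect(lines) == "bruker":
        return _read_bruker(lines)
    return _read_text(lines)


def write_record(record: ShapeFileRecord, path, dialect: str = "bruker") -> None:
    path = Path(path)
    if dialect == "text":
        lines = [
            f"{a:.6f} {p:.6f}"
            for a, p in zip(record.amplitudes_percent, record.phases_deg)
        ]
        path.write_text("\n".join(lines) + "\n")
        return
    if dialect != "bruker":
        raise ValueError("dialect must be 'bruker' or 'text'")
    meta = dict(record.metadata)
    header = [
        f"##TITLE= {meta.pop('TITLE', 'shaped pulse')}",
        "##JCAMP-DX= 5.00 $$ shape file",
        "##DATA TYPE= Shape Data",
        f"##ORIGIN= surbop {_version}",
        f"##MINX= {record.amplitudes_percent.min():.6e}",
        f"##MAXX= {record.amplitudes_percent.max():.6e}",
        f"##MINY= {record.phases_deg.min():.6e}",
        f"##MAXY= {record.phases_deg.max():.6e}",
    ]
    for key, value in meta.items():
        header.append(f"##{key}= {value}")
    header.append(f"##NPOINTS= {record.n_points}")
    header.append("##XYPOINTS= (XY..XY)")
    body = [
        f"  {a:.12e}, {p:.12e}"
        for a, p in zip(record.amplitudes_percent, record.phases_deg)
    ]
    path.write_text("\n".join(header + body + ["##END="]) + "\n")


def read_shape(
    path,
    peak_amplitude_hz: float,
    dt: float | None = None,
    duration: float | None = None,
) -> ShapedPulse:
    """Load a shape file as a :class:`ShapedPulse`.

    100 % amplitude maps to ``peak_amplitude_hz``.  The timestep is taken
    from ``dt``, else from ``duration / n_points``, else from a
    ``##$SHAPE_DURATION`` metadata field (seconds) if the file carries one.
    """
    if peak_amplitude_hz <= 0:
        raise ValueError("peak_amplitude_hz must be positive")
    record = read_record(path)
    if dt is None:
        if duration is None:
            stored = record.metadata.get("$SHAPE_DURATION")
            if stored is None:
                raise ValueError(
                    "timestep unknown: pass dt= or duration=, or use a file "
                    "with a ##$SHAPE_DURATION field"
                )
            duration = float(stored)
        dt = float(duration) / record.n_points
    amp_hz = np.clip(record.amplitudes_percent, 0.0, 100.0) / 100.0 * peak_amplitude_hz
    u_x, u_y = polar_to_cartesian(amp_hz, record.phases_deg)
    return ShapedPulse(u_x, u_y, float(dt), label=record.metadata.get("TITLE", ""))


def write_shape(
    pulse: ShapedPulse,
    path,
    peak_amplitude_hz: float | None = None,
    dialect: str = "bruker",
    title: str | None = None,
) -> None:
    """Write a pulse as a shape file.

    Amplitudes are expressed as percentages of ``peak_amplitude_hz`` (default:
    the pulse's own peak); an amplitude above the calibration peak is a range
    error.  The Bruker dialect stores the total duration so the file can be
    read back without external timing information.
    """
    amp, phase = cartesian_to_polar(pulse.u_x, pulse.u_y)
    peak = float(peak_amplitude_hz) if peak_amplitude_hz else float(amp.max())
    if peak <= 0:
        raise ValueError("peak amplitude must be positive (all-zero pulse needs an explicit peak)")
    pct = 100.0 * amp / peak
    if np.any(pct > 100.0 + 1e-6):
        raise ValueError("pulse amplitude exceeds the calibration peak amplitude")
    record = ShapeFileRecord(
        np.clip(pct, 0.0, 100.0),
        phase,
        metadata={
            "TITLE": title or pulse.label or "shaped pulse",
            "$SHAPE_DURATION": f"{pulse.duration:.9e}",
            "$SHAPE_AMPLITUDE_HZ": f"{peak:.6f}",
        },
    )
    write_record(record, path, dialect=dialect)


def convert(in_path, out_path, dialect: str | None = None) -> None:
    """Translate a shape file between dialects at the percent/phase level."""
    if dialect is None:
        dialect = "text" if str(out_path).endswith(".txt") else "bruker"
    write_record(read_record(in_path), out_path, dialect=dialect)
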