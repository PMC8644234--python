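"""Core data records and text-format I/O.

Every downstream analysis consumes one of five records defined here:

``SampledTrace``
    a strictly increasing time grid (seconds) with one signal channel,
    either PSII chlorophyll fluorescence or the P700 absorbance signal;
``ProtocolAnnotation``
    the light-protocol events (actinic light, saturating pulses, far-red
    light, single-turnover flashes) attached to a trace;
``Spectrum``
    a circular-dichroism spectrum on an increasing wavelength grid;
``PointSet2D``
    lattice-point coordinates (Angstrom) picked from electron micrographs
    of PSII semi-crystalline arrays, optionally with per-point supercomplex
    orientation vectors;
``BinaryMask``
    a boolean raster marking crystalline regions of a grana membrane.

All readers normalise times to seconds internally, whatever unit the source
file declares (instruments export microseconds, milliseconds or seconds
depending on the protocol; a single flash-decay experiment spans 15 us-50 s).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .exceptions import FormatError, ValidationError

__all__ = [
    "SampledTrace",
    "ProtocolAnnotation",
    "Spectrum",
    "PointSet2D",
    "BinaryMask",
    "read_trace",
    "write_trace",
    "detect_pulses",
    "read_annotation",
    "write_annotation",
    "read_spectrum",
    "write_spectrum",
    "read_points",
    "write_points",
    "read_mask",
    "write_mask",
]

EVENT_KINDS = (
    "actinic_on",
    "actinic_off",
    "sat_pulse_on",
    "sat_pulse_off",
    "fr_on",
    "fr_off",
    "st_flash",
)

_PAIRED = {
    "actinic_on": "actinic_off",
    "sat_pulse_on": "sat_pulse_off",
    "fr_on": "fr_off",
}


@dataclass
class SampledTrace:
    """One signal channel on a strictly increasing time grid (seconds)."""

    t: np.ndarray
    y: np.ndarray
    channel: str = "fluorescence"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1:
            raise ValidationError("trace arrays must be 1-D")
        if len(self.t) != len(self.y):
            raise ValidationError(
                f"time and signal lengths differ ({len(self.t)} vs {len(self.y)})"
            )
        if len(self.t) < 4:
            raise ValidationError("a trace needs at least 4 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValidationError("signal contains non-finite values")
        if self.channel not in ("fluorescence", "p700"):
            raise ValidationError(f"unknown channel {self.channel!r}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def window(self, t0: float, t1: float) -> "np.ndarray":
        """Boolean index of samples with t0 <= t <= t1."""
        return (self.t >= t0) & (self.t <= t1)

    def plot(self, ax=None, logx: bool = False, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.y, **kw)
        if logx:
            ax.set_xscale("log")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(self.channel)
        return ax


@dataclass
class ProtocolAnnotation:
    """Ordered light-protocol events and the actinic intensity (PAR)."""

    events: list  # list of (time_s, kind)
    par: Optional[float] = None  # umol photons m^-2 s^-1

    def __post_init__(self):
        self.events = [(float(t), str(k)) for t, k in self.events]
        times = [t for t, _ in self.events]
        if times != sorted(times):
            raise ValidationError("events must be time-ordered")
        for _, kind in self.events:
            if kind not in EVENT_KINDS:
                raise ValidationError(f"unknown event kind {kind!r}")
        # every *_on needs a matching later *_off
        for on, off in _PAIRED.items():
            opens: list[float] = []
            for t, kind in self.events:
                if kind == on:
                    opens.append(t)
                elif kind == off:
                    if not opens:
                        raise ValidationError(f"{off} at t={t} without prior {on}")
                    t_on = opens.pop(0)
                    if t <= t_on:
                        raise ValidationError(f"{on}/{off} pair has non-positive duration")
            if opens:
                raise ValidationError(f"{on} at t={opens[0]} never closed by {off}")

    def pairs(self, kind_on: str) -> list[tuple[float, float]]:
        """Matched (t_on, t_off) pairs for a paired event kind."""
        kind_off = _PAIRED[kind_on]
        ons = [t for t, k in self.events if k == kind_on]
        offs = [t for t, k in self.events if k == kind_off]
        return list(zip(ons, offs))

    def times(self, kind: str) -> list[float]:
        return [t for t, k in self.events if k == kind]


@dataclass
class Spectrum:
    """CD signal on a strictly increasing wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    signal: np.ndarray
    qy_norm_factor: Optional[float] = None

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.wavelength_nm) != len(self.signal):
            raise ValidationError("wavelength and signal lengths differ")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("CD signal contains non-finite values")

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelength_nm[0] <= lo and hi <= self.wavelength_nm[-1]


@dataclass
class PointSet2D:
    """Lattice-point coordinates in Angstrom (raster convention: y downward)."""

    points: np.ndarray  # (N, 2) in Angstrom
    orientations: Optional[np.ndarray] = None  # (N, 2) unit vectors
    pixel_size_A: float = 1.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point coordinates must be finite")
        if self.pixel_size_A <= 0:
            raise ValidationError("pixel size must be positive")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 2)
            if len(self.orientations) != len(self.points):
                raise ValidationError("one orientation per point required")
            norms = np.linalg.norm(self.orientations, axis=1)
            if np.any(norms <= 0):
                raise ValidationError("orientation vectors must be non-zero")
            self.orientations = self.orientations / norms[:, None]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BinaryMask:
    """Boolean raster; nonzero pixels mark the crystalline phase."""

    data: np.ndarray
    pixel_size_A: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValidationError("mask must be a non-empty 2-D raster")
        if self.pixel_size_A <= 0:
            raise ValidationError("pixel size must be positive")


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"us": 1e-6, "µs": 1e-6, "ms": 1e-3, "s": 1.0, "min": 60.0}

#: dialect -> (separator regex, default time unit, header policy)
DIALECTS = ("generic_csv", "dualpam_export", "pea_export")


def _unit_from_name(name: str, default: str) -> str:
    m = re.search(r"[_\(\[ ]?(us|µs|ms|min|s)\)?\]?$", name.strip().lower())
    return m.group(1) if m else default


def _split_line(line: str, dialect: str) -> list[str]:
    if dialect == "generic_csv":
        return [c.strip() for c in line.split(",")]
    # dualpam/pea exports: semicolon, tab or whitespace separated
    if ";" in line:
        return [c.strip() for c in line.split(";")]
    if "\t" in line:
        return [c.strip() for c in line.split("\t")]
    return line.split()


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_trace(path, dialect: str = "generic_csv", channel: Optional[str] = None) -> SampledTrace:
    """Read a two-column delimited trace; time is converted to seconds.

    ``generic_csv``
        comma separated; optional single header line. The time-column
        header may carry a unit suffix (``t_us``, ``time_ms`` ...);
        without a header (or suffix) times are taken as seconds.
    ``dualpam_export``
        semicolon- or tab-separated with at least one header line;
        columns matched case-insensitively by name ("Time", "Fluo",
        "P700"), unknown columns ignored. Time defaults to seconds
        unless the header carries a unit suffix.
    ``pea_export``
        whitespace/tab separated, optional header; time defaults to
        microseconds (fast-induction instruments log in us).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")

    default_unit = "us" if dialect == "pea_export" else "s"
    header_toks = _split_line(lines[0], dialect)
    has_header = not all(_is_number(tok) for tok in header_toks)

    t_col, y_col, unit = 0, 1, default_unit
    chan = channel
    if has_header:
        names = [h.lower() for h in header_toks]
        t_idx = [i for i, n in enumerate(names) if n.startswith(("t", "time"))]
        if t_idx:
            t_col = t_idx[0]
            unit = _unit_from_name(names[t_col], default_unit)
        if dialect == "dualpam_export":
            want = {"fluo": "fluorescence", "fluorescence": "fluorescence", "p700": "p700"}
            y_idx = [
                (i, want[key])
                for i, n in enumerate(names)
                for key in want
                if n.startswith(key)
            ]
            if not y_idx:
                raise FormatError(f"{path}: no Fluo/P700 column in header {header_toks}")
            # prefer the requested channel when both are present
            if channel is not None:
                match = [iv for iv in y_idx if iv[1] == channel]
                if not match:
                    raise FormatError(f"{path}: no column for channel {channel!r}")
                y_col, chan = match[0]
            else:
                y_col, chan = y_idx[0]
        else:
            cand = [i for i in range(len(names)) if i != t_col]
            if not cand:
                raise FormatError(f"{path}: fewer than two columns")
            y_col = cand[0]
            if chan is None and names[y_col].startswith("p700"):
                chan = "p700"

    rows = lines[1:] if has_header else lines
    t, y = [], []
    for lineno, ln in enumerate(rows, start=2 if has_header else 1):
        toks = _split_line(ln, dialect)
        if has_header and dialect == "dualpam_export" and not _is_number(toks[0]):
            continue  # extra header lines are tolerated
        try:
            t.append(float(toks[t_col]))
            y.append(float(toks[y_col]))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: unparseable line {lineno}: {ln!r}") from exc
    scale = _UNIT_SCALE[unit]
    trace = SampledTrace(
        np.asarray(t) * scale,
        np.asarray(y),
        channel=chan or "fluorescence",
        meta={"source": str(path), "dialect": dialect},
    )
    return trace


def write_trace(trace: SampledTrace, path, dialect: str = "generic_csv") -> Path:
    """Write a trace in a dialect :func:`read_trace` round-trips exactly."""
    path = Path(path)
    if dialect == "generic_csv":
        lines = ["t_s,signal"]
        lines += [f"{t:.17g},{y:.17g}" for t, y in zip(trace.t, trace.y)]
    elif dialect == "dualpam_export":
        name = "Fluo" if trace.channel == "fluorescence" else "P700"
        lines = [f"Time\t{name}"]
        lines += [f"{t:.17g}\t{y:.17g}" for t, y in zip(trace.t, trace.y)]
    elif dialect == "pea_export":
        lines = ["t_us\tF"]
        lines += [f"{t * 1e6:.17g}\t{y:.17g}" for t, y in zip(trace.t, trace.y)]
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# pulse detection
# ---------------------------------------------------------------------------

def detect_pulses(
    trace: SampledTrace,
    min_rise: float = 0.2,
    min_sep: float = 1.0,
    baseline_window_s: float = 2.0,
    min_duration_s: float = 0.05,
    par: Optional[float] = None,
) -> ProtocolAnnotation:
    """Locate saturating-pulse windows in a fluorescence trace.

    A pulse is a contiguous run of samples rising more than ``min_rise``
    (relative) above the running-median baseline, lasting at least
    ``min_duration_s``. Overlapping candidates within ``min_sep`` keep the
    earlier one. A flat trace yields an empty annotation, not an error.
    """
    if trace.channel != "fluorescence":
        raise ValidationError("pulse detection expects a fluorescence trace")
    if not 0 < min_rise < 1:
        raise ValidationError("min_rise must lie in (0, 1)")
    t, y = trace.t, trace.y
    dt = float(np.median(np.diff(t)))
    win = max(3, int(round(baseline_window_s / dt)) | 1)
    baseline = median_filter(y, size=win, mode="nearest")
    above = y > baseline * (1.0 + min_rise)

    events: list[tuple[float, str]] = []
    last_onset = -np.inf
    i, n = 0, len(y)
    min_len = max(1, int(round(min_duration_s / dt)))
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if (j - i + 1) >= min_len and t[i] - last_onset > min_sep:
                events.append((float(t[i]), "sat_pulse_on"))
                events.append((float(t[j]) + dt * 0.5, "sat_pulse_off"))
                last_onset = t[i]
            i = j + 1
        else:
            i += 1
    events.sort(key=lambda e: e[0])
    return ProtocolAnnotation(events=events, par=par)


# ---------------------------------------------------------------------------
# annotation / spectrum / point-set / mask I/O
# ---------------------------------------------------------------------------

def write_annotation(ann: ProtocolAnnotation, path) -> Path:
    path = Path(path)
    payload = {"par": ann.par, "events": [[t, k] for t, k in ann.events]}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_annotation(path) -> ProtocolAnnotation:
    payload = json.loads(Path(path).read_text())
    try:
        return ProtocolAnnotation(
            events=[(float(t), str(k)) for t, k in payload["events"]],
            par=payload.get("par"),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a protocol annotation") from exc


def read_spectrum(path) -> Spectrum:
    """Two-column (wavelength_nm, CD signal) delimited text."""
    path = Path(path)
    wl, sig = [], []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    for lineno, ln in enumerate(lines, start=1):
        toks = _split_line(ln, "pea_export") if "," not in ln else _split_line(ln, "generic_csv")
        if lineno == 1 and not all(_is_number(tok) for tok in toks):
            continue
        try:
            wl.append(float(toks[0]))
            sig.append(float(toks[1]))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: unparseable line {lineno}: {ln!r}") from exc
    return Spectrum(np.asarray(wl), np.asarray(sig))


def write_spectrum(spec: Spectrum, path) -> Path:
    path = Path(path)
    lines = ["wavelength_nm,cd"]
    lines += [f"{w:.17g},{s:.17g}" for w, s in zip(spec.wavelength_nm, spec.signal)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_points(path, pixel_size_A: float = 1.0) -> PointSet2D:
    """Read (x, y[, angle_deg]) rows; pixel coordinates are scaled to Angstrom.

    The optional third column is the in-plane orientation of the supercomplex
    diagonal, in degrees measured from the +x axis.
    """
    path = Path(path)
    xs, ys, angles = [], [], []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    for lineno, ln in enumerate(lines, start=1):
        toks = _split_line(ln, "generic_csv") if "," in ln else ln.split()
        if lineno == 1 and not all(_is_number(tok) for tok in toks):
            continue
        try:
            xs.append(float(toks[0]))
            ys.append(float(toks[1]))
            if len(toks) >= 3:
                angles.append(float(toks[2]))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: unparseable line {lineno}: {ln!r}") from exc
    pts = np.column_stack([xs, ys]) * pixel_size_A
    ori = None
    if angles and len(angles) == len(xs):
        rad = np.deg2rad(angles)
        ori = np.column_stack([np.cos(rad), np.sin(rad)])
    return PointSet2D(pts, orientations=ori, pixel_size_A=pixel_size_A)


def write_points(ps: PointSet2D, path) -> Path:
    """TSV of pixel coordinates (inverse of :func:`read_points`)."""
    path = Path(path)
    px = ps.points / ps.pixel_size_A
    lines = ["x_px\ty_px" + ("\tangle_deg" if ps.orientations is not None else "")]
    for i, (x, y) in enumerate(px):
        row = f"{x:.17g}\t{y:.17g}"
        if ps.orientations is not None:
            ang = np.degrees(np.arctan2(ps.orientations[i, 1], ps.orientations[i, 0]))
            row += f"\t{ang:.17g}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_mask(path, pixel_size_A: float = 1.0) -> BinaryMask:
    """PNG or TIFF raster; any nonzero pixel counts as crystalline."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse colour channels
        arr = arr.max(axis=-1)
    return BinaryMask(arr != 0, pixel_size_A=pixel_size_A)


def write_mask(mask: BinaryMask, path) -> Path:
    path = Path(path)
    arr = (mask.data.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr, mode="L").save(path)
    return path
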