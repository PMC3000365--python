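"""Fragment-analysis traces and the bp <-> CAG-repeat conversion.

A trace is a sampled capillary-electrophoresis electropherogram: fluorescence
intensity as a function of called fragment size in bp.  The amplicon carries
the CAG tract plus 86 bp of flanking sequence, so a fragment of mean size
``mu_m`` bp corresponds to ``(mu_m - 86) / 3`` CAG triplets.  Everything
downstream (peak fitting, interval statistics, drift estimation) works through
this conversion.

Traces are interchanged as two-column delimited text (``size_bp``,
``intensity``); ``#``-prefixed lines are comments.  An optional flat key-value
sidecar file (``<trace>.meta``) carries the mouse identifier, tissue and age.
The abscissa is assumed to be already size-called in bp -- ladder calibration
is an upstream, instrument-specific step and is out of scope here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "FLANK_BP",
    "BP_PER_REPEAT",
    "TISSUES",
    "TraceMeta",
    "Trace",
    "TraceParseError",
    "read_trace",
    "write_trace",
    "repeats_from_size",
    "size_from_repeats",
]

#: Length of the constant flanking sequence around the CAG tract, in bp.
FLANK_BP = 86.0
#: One CAG repeat unit is a triplet.
BP_PER_REPEAT = 3.0

TISSUES = frozenset(
    {"tail", "heart", "lung", "spleen", "liver", "cortex", "striatum", "other"}
)


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed into a valid :class:`Trace`."""

    def __init__(self, message: str, path=None, row: int | None = None):
        self.path = path
        self.row = row
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if row is not None:
                loc += f", row {row}"
            loc += "]"
        super().__init__(message + loc)


@dataclass(frozen=True)
class TraceMeta:
    """Per-sample metadata: which mouse, which tissue, what age."""

    mouse: str = ""
    tissue: str = "other"
    age_weeks: float | None = None

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue {self.tissue!r}; expected one of {sorted(TISSUES)}"
            )
        if self.age_weeks is not None and not self.age_weeks > 0:
            raise ValueError("age_weeks must be positive")


@dataclass
class Trace:
    """A sampled electropherogram.

    ``size_bp`` must be strictly increasing, ``intensity`` non-negative and of
    the same length (>= 3 points).
    """

    size_bp: np.ndarray
    intensity: np.ndarray
    meta: TraceMeta | None = None

    def __post_init__(self):
        self.size_bp = np.asarray(self.size_bp, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.size_bp.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("size_bp and intensity must be 1-D")
        if self.size_bp.size != self.intensity.size:
            raise ValueError("size_bp and intensity must have equal length")
        if self.size_bp.size < 3:
            raise ValueError("a trace needs at least 3 points")
        if not np.all(np.isfinite(self.size_bp)) or not np.all(
            np.isfinite(self.intensity)
        ):
            raise ValueError("trace values must be finite")
        if np.any(np.diff(self.size_bp) <= 0):
            raise ValueError("sizes not increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")

    @property
    def area(self) -> float:
        """Trapezoidal integral of intensity over fragment size."""
        return float(np.trapezoid(self.intensity, self.size_bp))

    def with_meta(self, meta: TraceMeta) -> "Trace":
        return replace(self, meta=meta)


def repeats_from_size(mean_size_bp):
    """Convert a fragment size in bp to a CAG repeat count.

    ``mu_t = (mu_m - 86) / 3``; fractional values are meaningful for fitted
    peak means.  Accepts scalars or arrays.
    """
    size = np.asarray(mean_size_bp, dtype=float)
    if np.any(size < FLANK_BP):
        raise ValueError(
            f"fragment size below the {FLANK_BP:.0f} bp flank length"
        )
    out = (size - FLANK_BP) / BP_PER_REPEAT
    return float(out) if np.isscalar(mean_size_bp) else out


def size_from_repeats(repeats):
    """Inverse of :func:`repeats_from_size`: ``86 + 3 * repeats``."""
    r = np.asarray(repeats, dtype=float)
    if np.any(r < 0):
        raise ValueError("repeat count must be non-negative")
    out = FLANK_BP + BP_PER_REPEAT * r
    return float(out) if np.isscalar(repeats) else out


PathLike = Union[str, "os.PathLike[str]"]


def _sidecar_path(path: PathLike) -> Path:
    return Path(str(path) + ".meta")


def _read_sidecar(path: Path) -> TraceMeta | None:
    if not path.exists():
        return None
    kv: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        kv[key.strip()] = val.strip()
    age = kv.get("age_weeks")
    return TraceMeta(
        mouse=kv.get("mouse", ""),
        tissue=kv.get("tissue", "other"),
        age_weeks=float(age) if age else None,
    )


def read_trace(path: PathLike) -> Trace:
    """Read a two-column delimited trace file (tab, comma or whitespace).

    ``#`` lines are comments and an optional single header row is skipped.
    Rows with non-finite values are dropped; negative intensities or
    non-increasing sizes raise :class:`TraceParseError` identifying the row.
    """
    p = Path(path)
    if not p.exists():
        raise TraceParseError("trace file not found", path=p)
    sizes: list[float] = []
    intens: list[float] = []
    rows: list[int] = []
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        for delim in ("\t", ",", None):
            parts = line.split(delim)
            parts = [q for q in parts if q != ""]
            if len(parts) >= 2:
                break
        if len(parts) < 2:
            raise TraceParseError("expected two columns", path=p, row=lineno)
        try:
            s, y = float(parts[0]), float(parts[1])
        except ValueError:
            if not sizes:  # header row
                continue
            raise TraceParseError("non-numeric row", path=p, row=lineno)
        if not (np.isfinite(s) and np.isfinite(y)):
            continue  # non-finite rows rejected
        if y < 0:
            raise TraceParseError("negative intensities", path=p, row=lineno)
        if sizes and s <= sizes[-1]:
            raise TraceParseError("sizes not increasing", path=p, row=lineno)
        sizes.append(s)
        intens.append(y)
        rows.append(lineno)
    if len(sizes) < 3:
        raise TraceParseError("fewer than 3 usable rows", path=p)
    meta = _read_sidecar(_sidecar_path(p))
    return Trace(np.array(sizes), np.array(intens), meta=meta)


def write_trace(trace: Trace, path: PathLike) -> None:
    """Write a trace (and its metadata sidecar, if any) as delimited text."""
    p = Path(path)
    with p.open("w") as fh:
        fh.write("size_bp\tintensity\n")
        for s, y in zip(trace.size_bp, trace.intensity):
            fh.write(f"{s:.10g}\t{y:.10g}\n")
    if trace.meta is not None:
        m = trace.meta
        lines = [f"mouse: {m.mouse}", f"tissue: {m.tissue}"]
        if m.age_weeks is not None:
            lines.append(f"age_weeks: {m.age_weeks:g}")
        _sidecar_path(p).write_text("\n".join(lines) + "\n")
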