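"""Fetal heart rate record model and CSV/JSON-sidecar I/O.

An :class:`FHRRecord` holds a uniformly sampled fetal heart rate trace in
beats per minute (bpm), conventionally at 4 Hz as produced by cardiotocography
monitors, together with the clinical metadata (umbilical-artery pH,
gestational age, ...) needed downstream for labeling and normalization.

Missing samples are encoded as 0 bpm: Doppler transducer dropout produces
runs of zeros in the raw trace, and the preprocessing stage is responsible
for excising or interpolating them.  Time is implicit — sample ``i`` occurs
at ``i / fs`` seconds — so uniform sampling is a precondition of the reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ClinicalMeta", "FHRRecord", "read_record", "write_record", "FormatError"]

PH_RANGE = (6.5, 7.6)
GA_RANGE = (30.0, 45.0)


class FormatError(ValueError):
    """Raised when a record file cannot be parsed or violates preconditions."""


@dataclass
class ClinicalMeta:
    """Per-record clinical metadata.

    ph
        Umbilical-artery pH measured after delivery (objective outcome label);
        must lie in [6.5, 7.6] when present.
    ga_weeks
        Gestational age in completed weeks, in [30, 45] when present.
    ma_years, apgar1, apgar5, birth_weight_g
        Optional maternal age / Apgar scores / birth weight.
    """

    ph: Optional[float] = None
    ga_weeks: Optional[float] = None
    ma_years: Optional[float] = None
    apgar1: Optional[float] = None
    apgar5: Optional[float] = None
    birth_weight_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ph is not None and not (PH_RANGE[0] <= self.ph <= PH_RANGE[1]):
            raise ValueError(f"ph={self.ph} outside plausible range {PH_RANGE}")
        if self.ga_weeks is not None and not (GA_RANGE[0] <= self.ga_weeks <= GA_RANGE[1]):
            raise ValueError(f"ga_weeks={self.ga_weeks} outside plausible range {GA_RANGE}")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalMeta":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown metadata keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FHRRecord:
    """A uniformly sampled FHR trace (bpm) plus clinical metadata."""

    record_id: str
    samples: np.ndarray
    fs: float = 4.0
    meta: ClinicalMeta = field(default_factory=ClinicalMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.any(self.samples < 0) or not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite and non-negative (0 encodes missing)")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (implicit uniform grid)."""
        return np.arange(self.n) / self.fs


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_record(path, format: str = "csv") -> FHRRecord:
    """Read an FHR record from disk.

    The CSV dialect is one header line with columns ``time_s,fhr_bpm``; the
    sampling rate is inferred from the time column (which must be uniform and
    monotone).  A JSON metadata sidecar ``<file>.meta.json`` is read when
    present.
    """
    path = Path(path)
    if format == "wfdb":
        raise FormatError(
            "WFDB input is not supported by this build; convert to the CSV "
            "interchange format (columns time_s,fhr_bpm)"
        )
    if format != "csv":
        raise FormatError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"malformed CSV {path}: {exc}") from exc
    for col in ("time_s", "fhr_bpm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r} (line 1)")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["fhr_bpm"].to_numpy(dtype=float)
    if len(t) < 1:
        raise FormatError(f"{path}: empty record")
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 2  # +2: header line + 1-based
            raise FormatError(f"{path}: non-monotone time column at line {bad}")
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
            bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=0, atol=1e-6))) + 2
            raise FormatError(f"{path}: non-uniform sampling at line {bad}")
        fs = 1.0 / dt[0]
    else:
        fs = 4.0
    meta = ClinicalMeta()
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = ClinicalMeta.from_dict(json.loads(sidecar.read_text()))
    return FHRRecord(record_id=path.stem, samples=x, fs=float(fs), meta=meta)


def write_record(record: FHRRecord, path, format: str = "csv") -> None:
    """Write a record as CSV plus a JSON metadata sidecar.

    Round-trips bit-exactly through :func:`read_record`: the time column is
    regenerated from ``fs`` and sample values are written at full float
    precision.  Optional metadata fields that are absent are omitted from the
    sidecar.
    """
    path = Path(path)
    if format == "wfdb":
        raise FormatError("WFDB output is not supported by this build; use csv")
    if format != "csv":
        raise FormatError(f"unknown format {format!r}")
    df = pd.DataFrame({"time_s": record.times(), "fhr_bpm": record.samples})
    df.to_csv(path, index=False, float_format="%.17g")
    _sidecar_path(path).write_text(json.dumps(record.meta.to_dict(), indent=1))
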