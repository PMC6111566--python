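"""Three-step artifact removal for raw cardiotocographic FHR traces.

Doppler-derived FHR signals are contaminated by maternal/fetal movement and
transducer displacement, which produce (a) runs of zeros where the signal was
lost, (b) isolated physiologically impossible spikes, and (c) abrupt jumps
between unstable segments.  The cleaning pipeline is:

1. locate a *stable start*: the first run of ``stable_run`` adjacent non-zero
   samples whose range does not exceed ``stable_tol_bpm``;
2. excise missing-data gaps: zero-runs lasting at least ``missing_gap_s``
   seconds are deleted outright (the trace is concatenated across the gap),
   shorter zero runs being left to the spike stage;
3. linearly interpolate spikes (samples <= ``spike_low_bpm`` or
   >= ``spike_high_bpm``, both bounds inclusive);
4. spline-interpolate unstable samples whose difference from the last
   accepted stable value exceeds ``jump_tol_bpm``.

The output is truncated to the first ``target_len_samples`` clean samples
(20 min at 4 Hz by default) so every downstream feature sees a fixed-length
segment.  The whole pass is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .records import FHRRecord

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "PreprocessError",
    "find_stable_start",
    "excise_missing",
    "interpolate_spikes",
    "interpolate_jumps",
    "preprocess",
]


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    stable_run: int = 5
    stable_tol_bpm: float = 10.0
    missing_gap_s: float = 10.0
    spike_low_bpm: float = 50.0
    spike_high_bpm: float = 200.0
    jump_tol_bpm: float = 25.0
    target_len_samples: int = 4800

    def __post_init__(self) -> None:
        if self.spike_low_bpm >= self.spike_high_bpm:
            raise ValueError("spike_low_bpm must be < spike_high_bpm")
        for name in ("stable_tol_bpm", "missing_gap_s", "jump_tol_bpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.target_len_samples <= 0 or self.stable_run < 2:
            raise ValueError("target_len_samples > 0 and stable_run >= 2 required")


@dataclass
class PreprocessReport:
    start_index: int = 0
    n_spikes_interpolated: int = 0
    n_jumps_interpolated: int = 0
    n_missing_samples_excluded: int = 0
    warnings: list = None

    def __post_init__(self) -> None:
        if self.warnings is None:
            self.warnings = []


def find_stable_start(record: FHRRecord, cfg: PreprocessConfig | None = None) -> int:
    """Smallest index of a ``stable_run``-sample window with range <= tolerance.

    Zero (missing) samples never belong to a stable window.
    """
    cfg = cfg or PreprocessConfig()
    x = record.samples
    w = cfg.stable_run
    if x.size < w:
        raise PreprocessError("record shorter than one stable window")
    windows = np.lib.stride_tricks.sliding_window_view(x, w)
    ok = (
        (windows.max(axis=1) - windows.min(axis=1) <= cfg.stable_tol_bpm)
        & np.all(windows > cfg.spike_low_bpm, axis=1)
        & np.all(windows < cfg.spike_high_bpm, axis=1)
    )
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise PreprocessError("no stable segment found")
    return int(idx[0])


def _zero_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive zeros."""
    iszero = np.concatenate(([0], (x == 0).astype(int), [0]))
    edges = np.diff(iszero)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts, stops))


def excise_missing(
    samples: np.ndarray, cfg: PreprocessConfig | None = None, fs: float = 4.0
) -> tuple[np.ndarray, int]:
    """Delete zero-runs of duration >= ``missing_gap_s`` (threshold inclusive)."""
    cfg = cfg or PreprocessConfig()
    x = np.asarray(samples, dtype=float)
    min_len = int(round(cfg.missing_gap_s * fs))
    keep = np.ones(x.size, dtype=bool)
    excluded = 0
    for a, b in _zero_runs(x):
        if b - a >= min_len:
            keep[a:b] = False
            excluded += b - a
    out = x[keep]
    if out.size == 0:
        raise PreprocessError("signal entirely missing")
    return out, excluded


def _linear_fill(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace ``bad`` samples by linear interpolation between valid neighbors,
    extending by the nearest valid value at the boundaries."""
    good = ~bad
    if not good.any():
        raise PreprocessError("no valid samples to interpolate from")
    idx = np.arange(x.size)
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[good], x[good])
    return out


def interpolate_spikes(
    samples: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, int]:
    """Linearly interpolate spikes, i.e. samples <= spike_low or >= spike_high.

    Both bounds are inclusive (a reading of exactly 50 or 200 bpm is treated
    as an artifact).  Short missing runs (zeros) fall under the <= low rule.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(samples, dtype=float)
    bad = (x <= cfg.spike_low_bpm) | (x >= cfg.spike_high_bpm)
    if not bad.any():
        return x.copy(), 0
    return _linear_fill(x, bad), int(bad.sum())


def interpolate_jumps(
    samples: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, int, list[str]]:
    """Spline-interpolate samples that jump > ``jump_tol_bpm`` from the last
    accepted stable value.

    The scan runs left to right: each candidate is compared against the most
    recent *accepted* sample, so one outlier does not drag the reference and
    cascade into rejecting the rest of the trace.  Rejected samples are
    replaced by a natural cubic spline through the four nearest stable
    neighbors on each side (fewer near the edges; two anchors degenerate to a
    line).
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(samples, dtype=float)
    n = x.size
    stable = np.ones(n, dtype=bool)
    last = x[0]
    for i in range(1, n):
        if abs(x[i] - last) > cfg.jump_tol_bpm:
            stable[i] = False
        else:
            last = x[i]
    warnings: list[str] = []
    n_bad = int((~stable).sum())
    if n_bad == 0:
        return x.copy(), 0, warnings
    if n_bad > n // 2:
        warnings.append(f"{n_bad}/{n} samples marked unstable (> 50%)")
    out = x.copy()
    good_idx = np.flatnonzero(stable)
    bad_idx = np.flatnonzero(~stable)
    for i in bad_idx:
        pos = np.searchsorted(good_idx, i)
        anchors = np.concatenate([good_idx[max(0, pos - 4) : pos], good_idx[pos : pos + 4]])
        if anchors.size >= 2:
            spl = CubicSpline(anchors, x[anchors], bc_type="natural")
            out[i] = float(spl(i))
        elif anchors.size == 1:
            out[i] = x[anchors[0]]
    return out, n_bad, warnings


def preprocess(
    record: FHRRecord, cfg: PreprocessConfig | None = None
) -> tuple[FHRRecord, PreprocessReport]:
    """Full cleaning pass; returns the fixed-length clean record and a report.

    Raises :class:`PreprocessError` if fewer than ``target_len_samples`` clean
    samples remain (the trace is then too short for the standard 20-min
    analysis window; no zero padding is performed).
    """
    cfg = cfg or PreprocessConfig()
    report = PreprocessReport()
    report.start_index = find_stable_start(record, cfg)
    x = record.samples[report.start_index :]
    x, report.n_missing_samples_excluded = excise_missing(x, cfg, fs=record.fs)
    # Spike and jump repair can, in rare constellations, leave a residual
    # violation (a spline value out of range, or a new >tol step next to a
    # repaired sample); iterate to a fixed point so the output contracts
    # (range strictly inside (low, high), steps <= tol) always hold.
    for _ in range(10):
        x, n_sp = interpolate_spikes(x, cfg)
        x, n_j, warns = interpolate_jumps(x, cfg)
        report.n_spikes_interpolated += n_sp
        report.n_jumps_interpolated += n_j
        report.warnings.extend(warns)
        in_range = (x > cfg.spike_low_bpm) & (x < cfg.spike_high_bpm)
        if in_range.all() and (np.abs(np.diff(x)) <= cfg.jump_tol_bpm).all():
            break
    if x.size < cfg.target_len_samples:
        raise PreprocessError(
            f"record too short: {x.size} clean samples < {cfg.target_len_samples}"
        )
    x = x[: cfg.target_len_samples]
    clean = FHRRecord(
        record_id=record.record_id, samples=x, fs=record.fs, meta=record.meta
    )
    return clean, report
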