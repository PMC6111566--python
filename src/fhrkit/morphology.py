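"""FIGO-style morphological analysis: baseline, accelerations, decelerations.

The baseline is the resting level of the fetal heart rate with transient
episodes excluded.  It is estimated with an iteratively trimmed centered
moving average seeded by the global median: samples deviating more than
15 bpm from the current estimate are discarded before each re-averaging
pass, so accelerations/decelerations of any duration do not drag the
baseline toward themselves, and stretches excluded wholesale (long
decelerations) are bridged by interpolation.  Edges use shrinking windows.

Episodes follow the clinical definitions: an acceleration is a rise of at
least 15 bpm above baseline sustained for at least 15 s; a deceleration is a
drop of more than 15 bpm below baseline for at least 15 s, sub-classified by
duration as mild (< 120 s), prolonged (120–300 s, bounds inclusive) or
severe (> 300 s).  The mean baseline is categorized as reassuring
(110–160 bpm), non-reassuring (100–109 or 161–180 bpm) or abnormal
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import FHRRecord

__all__ = [
    "BaselineEstimate",
    "Episode",
    "estimate_baseline",
    "detect_accelerations",
    "detect_decelerations",
    "morph_features",
    "episodes_to_tsv",
    "MORPH_FEATURE_NAMES",
]

MORPH_FEATURE_NAMES = [
    "meanBL", "sdBL", "minBL", "maxBL", "ACC", "DEC_mild", "DEC_prolong", "DEC_severe",
]

EPISODE_THRESHOLD_BPM = 15.0
EPISODE_MIN_DURATION_S = 15.0
MERGE_GAP_S = 10.0  # sub-threshold gaps shorter than this are event-internal
TRIM_THRESHOLD_BPM = 15.0
SEED_BAND_BPM = 10.0  # trim band around the long-median seed estimate
DETECTION_SMOOTH_S = 5.0  # deviation smoothing ahead of thresholding
EXTENSION_THRESHOLD_BPM = 2.0  # qualified episodes extend to baseline return


@dataclass
class BaselineEstimate:
    baseline: np.ndarray  # bpm, same length as input
    window_s: float
    category: str  # reassuring | non_reassuring | abnormal


@dataclass
class Episode:
    kind: str  # acceleration | deceleration
    start_idx: int  # 0-based, half-open [start, end)
    end_idx: int
    peak_dev_bpm: float
    dec_class: Optional[str] = None  # mild | prolonged | severe, decelerations only

    def duration_s(self, fs: float = 4.0) -> float:
        return (self.end_idx - self.start_idx) / fs


def _masked_moving_mean(
    x: np.ndarray, mask: np.ndarray, w: int, min_frac: float = 0.0
) -> np.ndarray:
    """Centered moving mean of x over samples where mask is True; shrinking
    windows at the edges.  Positions whose window retains no samples — or
    fewer than ``min_frac`` of its width, i.e. windows lying inside a long
    excluded episode where only stray samples survive — yield NaN for the
    caller to bridge."""
    kernel = np.ones(w)
    vals = np.convolve(np.where(mask, x, 0.0), kernel, mode="same")
    cnts = np.convolve(mask.astype(float), kernel, mode="same")
    width = np.convolve(np.ones_like(x), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnts > np.maximum(min_frac * width, 0.0), vals / cnts, np.nan)
    return out


def categorize_baseline(mean_bl: float) -> str:
    if 110.0 <= mean_bl <= 160.0:
        return "reassuring"
    if 100.0 <= mean_bl < 110.0 or 160.0 < mean_bl <= 180.0:
        return "non_reassuring"
    return "abnormal"


def estimate_baseline(clean: FHRRecord, window_s: float = 240.0) -> BaselineEstimate:
    """Iteratively trimmed moving-average baseline.

    The first reference is the global signal median (baseline-dominated on a
    20-min record, and robust to episodes of any duration).  Each refinement
    pass keeps only samples within 15 bpm of the current estimate, recomputes
    a centered moving mean over ``window_s`` from the kept samples (shrinking
    windows at the edges), and bridges windows left empty by long excluded
    episodes with linear interpolation.  A few passes replace the global
    reference by a drift-tracking local one, so accelerations and
    decelerations do not drag the baseline while slow trends are followed.

    ``window_s`` must exceed 30 s so 15-s episodes cannot register as
    baseline shifts; the 240 s default tracks drift while averaging over
    contraction-scale structure.
    """
    if window_s <= 30:
        raise ValueError("window_s must be > 30 s")
    from scipy.ndimage import binary_closing, median_filter

    x = clean.samples
    fs = clean.fs
    w = max(3, int(round(window_s * fs)))
    idx = np.arange(x.size)
    # Seed: rolling median over a window long enough that even prolonged
    # (5-min-scale) decelerations are a minority of every window; edges are
    # padded with the global median so an episode near a record boundary
    # cannot dominate a shrunken window.
    w_seed = min(x.size, 3 * w) // 2 * 2 + 1
    b = median_filter(x, size=w_seed, mode="constant", cval=float(np.median(x)))
    # Exclusion gaps shorter than the 15-s episode scale are noise dips
    # inside an event, not returns to baseline: close them before averaging.
    close = np.ones(max(1, int(round(EPISODE_MIN_DURATION_S * fs)) | 1), dtype=bool)
    for _ in range(3):
        excl = np.abs(x - b) > SEED_BAND_BPM
        excl = binary_closing(excl, structure=close)
        keep = ~excl
        if not keep.any():
            break
        est = _masked_moving_mean(x, keep, w, min_frac=0.25)
        bad = ~np.isfinite(est)
        if bad.any():  # bridge across fully-excluded stretches
            est[bad] = np.interp(idx[bad], idx[~bad], est[~bad])
        b = est
    baseline = np.clip(b, 50.0, 200.0)
    return BaselineEstimate(
        baseline=baseline, window_s=window_s, category=categorize_baseline(float(baseline.mean()))
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.concatenate(([0], mask.astype(int), [0]))
    edges = np.diff(m)
    return list(zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)))


def _detect_episodes(
    dev: np.ndarray, fs: float, kind: str, strict: bool
) -> list[Episode]:
    """Maximal supra-threshold runs of the deviation series, merging runs
    separated by short sub-threshold gaps, then filtering on duration.

    The deviation is smoothed over ~5 s before thresholding: episodes are
    15-s-scale patterns, and sample-scale variability should not fragment a
    single clinical event into several runs.  A qualified run is then
    extended outward to where the raw deviation returns to baseline
    (< 2 bpm): clinically an episode lasts until the trace returns to the
    baseline, not until it re-crosses the 15-bpm qualification offset.
    Peak deviation is read from the raw series.
    """
    thr = EPISODE_THRESHOLD_BPM
    w = max(1, int(round(DETECTION_SMOOTH_S * fs)) // 2 * 2 + 1)
    sm = np.convolve(dev, np.ones(w), "same") / np.convolve(
        np.ones_like(dev), np.ones(w), "same"
    )
    mask = sm > thr if strict else sm >= thr
    runs = _runs(mask)
    if not runs:
        return []
    merged = [list(runs[0])]
    max_gap = int(round(MERGE_GAP_S * fs))
    for a, b in runs[1:]:
        if a - merged[-1][1] < max_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_len = int(round(EPISODE_MIN_DURATION_S * fs))
    qualified = [(a, b) for a, b in merged if b - a >= min_len]
    # extend to baseline return and fuse any overlaps that creates
    ext = EXTENSION_THRESHOLD_BPM
    spans: list[list[int]] = []
    for a, b in qualified:
        while a > 0 and dev[a - 1] > ext:
            a -= 1
        while b < dev.size and dev[b] > ext:
            b += 1
        if spans and a <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], b)
        else:
            spans.append([a, b])
    episodes = []
    for a, b in spans:
        ep = Episode(kind=kind, start_idx=int(a), end_idx=int(b),
                     peak_dev_bpm=float(dev[a:b].max()))
        if kind == "deceleration":
            d = ep.duration_s(fs)
            ep.dec_class = "mild" if d < 120 else ("prolonged" if d <= 300 else "severe")
        episodes.append(ep)
    return episodes


def detect_accelerations(clean: FHRRecord, baseline: BaselineEstimate) -> list[Episode]:
    """Runs of signal >= baseline + 15 bpm lasting >= 15 s (gap-merged)."""
    if len(baseline.baseline) != clean.n:
        raise ValueError("baseline length mismatch")
    return _detect_episodes(clean.samples - baseline.baseline, clean.fs,
                            "acceleration", strict=False)


def detect_decelerations(clean: FHRRecord, baseline: BaselineEstimate) -> list[Episode]:
    """Runs of signal < baseline - 15 bpm lasting >= 15 s, duration-classed."""
    if len(baseline.baseline) != clean.n:
        raise ValueError("baseline length mismatch")
    return _detect_episodes(baseline.baseline - clean.samples, clean.fs,
                            "deceleration", strict=True)


def episodes_to_tsv(record_id: str, episodes: list[Episode], path) -> None:
    """Write episodes as a BED-like TSV:
    record_id, start_idx, end_idx, kind, class."""
    lines = ["record_id\tstart_idx\tend_idx\tkind\tclass"]
    for e in sorted(episodes, key=lambda e: e.start_idx):
        lines.append(
            f"{record_id}\t{e.start_idx}\t{e.end_idx}\t{e.kind}\t{e.dec_class or '.'}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def morph_features(clean: FHRRecord, window_s: float = 240.0) -> tuple[dict, set]:
    """The eight morphological features: baseline statistics + episode counts."""
    est = estimate_baseline(clean, window_s)
    accs = detect_accelerations(clean, est)
    decs = detect_decelerations(clean, est)
    bl = est.baseline
    feats = {
        "meanBL": float(bl.mean()),
        "sdBL": float(bl.std()),
        "minBL": float(bl.min()),
        "maxBL": float(bl.max()),
        "ACC": float(len(accs)),
        "DEC_mild": float(sum(e.dec_class == "mild" for e in decs)),
        "DEC_prolong": float(sum(e.dec_class == "prolonged" for e in decs)),
        "DEC_severe": float(sum(e.dec_class == "severe" for e in decs)),
    }
    return feats, set()
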