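"""Epoch-level RR conversion and the 17 time-domain HRV features.

Doppler cardiotocography yields no true beat-to-beat intervals, so the
heart-rate trace is converted sample-wise to an epoch-to-epoch interval
series RR = 60000 / FHR (ms).  The features are the classical HRV
time-domain battery adapted to this surrogate series:

=========  =====================================================
meanRR..   mean / min / max / median of RR (ms)
SDNN       standard deviation of RR over the whole segment
SDANN      sd of per-segment (default 5-min) RR means
SDNNi      mean of per-segment RR sds
RMSSD      root mean square of successive differences
NNx/pNNx   count / percentage of successive pairs differing > x ms
STV        mean absolute difference of successive epoch (2.5 s) means
II         interval index: STV / sd of epoch means
LTI        long-term irregularity: IQR of sqrt(s_j^2 + s_{j+1}^2)
           over successive epoch means s_j
delta      mean over 1-min blocks of (max - min RR within block)
delta_total  max - min RR over the whole series
Tri        triangular index: N / max bin count of the RR histogram
TINN       base width (ms) of the least-squares triangular fit to
           the RR histogram
=========  =====================================================

STV/II/LTI follow the Arduini / de Haan family of fetal variability
indices built on 2.5-s epoch means.  Population (ddof=0) standard
deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import FHRRecord

__all__ = ["RRSeries", "TimeDomainConfig", "fhr_to_rr", "time_features",
           "TIME_FEATURE_NAMES"]

TIME_FEATURE_NAMES = [
    "meanRR", "minRR", "maxRR", "medianRR", "SDNN", "SDANN", "SDNNi", "RMSSD",
    "NNx", "pNNx", "STV", "II", "LTI", "delta", "delta_total", "Tri", "TINN",
]


@dataclass
class RRSeries:
    rr_ms: np.ndarray
    fs_source: float = 4.0

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if np.any(self.rr_ms <= 0):
            raise ValueError("rr_ms must be strictly positive")


@dataclass
class TimeDomainConfig:
    nnx_ms: float = 50.0
    seg_s: float = 300.0
    epoch_s: float = 2.5
    hist_bin_ms: float = 7.8125  # 1/128 s, HRV task-force convention

    def __post_init__(self) -> None:
        for name in ("nnx_ms", "seg_s", "epoch_s", "hist_bin_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def fhr_to_rr(clean: FHRRecord) -> RRSeries:
    """Elementwise RR(i) = 60000 / FHR(i), in ms.

    Zero samples indicate an unpreprocessed trace and raise.
    """
    if np.any(clean.samples == 0):
        raise ZeroDivisionError("record contains zero samples; run preprocess first")
    return RRSeries(rr_ms=60000.0 / clean.samples, fs_source=clean.fs)


def _epoch_means(rr: np.ndarray, fs: float, epoch_s: float) -> np.ndarray:
    k = int(round(epoch_s * fs))
    n = (rr.size // k) * k
    return rr[:n].reshape(-1, k).mean(axis=1)


def _tinn(counts: np.ndarray, edges: np.ndarray) -> float:
    """Least-squares triangular interpolation of the RR histogram.

    Searches bin edges N <= peak and M >= peak for the triangle that is zero
    outside [N, M], rises linearly to the peak-bin height at the peak center
    and falls linearly after it, minimizing the squared error to the
    histogram evaluated at bin centers; returns M - N in ms.
    """
    centers = (edges[:-1] + edges[1:]) / 2
    p = int(np.argmax(counts))
    y = float(counts[p])
    cx = centers[p]
    best = (np.inf, edges[0], edges[-1])
    for ni in range(0, p + 1):
        for mi in range(p + 1, len(edges)):
            n_edge, m_edge = edges[ni], edges[mi]
            tri = np.zeros_like(centers)
            left = (centers >= n_edge) & (centers <= cx)
            right = (centers > cx) & (centers <= m_edge)
            if cx > n_edge:
                tri[left] = y * (centers[left] - n_edge) / (cx - n_edge)
            else:
                tri[left] = y
            if m_edge > cx:
                tri[right] = y * (m_edge - centers[right]) / (m_edge - cx)
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0]:
                best = (err, n_edge, m_edge)
    return float(best[2] - best[1])


def time_features(
    rr: RRSeries, cfg: TimeDomainConfig | None = None
) -> tuple[dict, set]:
    """The 17 time-domain features; returns (features, warning flags)."""
    cfg = cfg or TimeDomainConfig()
    x = rr.rr_ms
    fs = rr.fs_source
    flags: set[str] = set()
    diffs = np.diff(x)

    seg = int(round(cfg.seg_s * fs))
    nseg = x.size // seg
    if nseg >= 1:
        segs = x[: nseg * seg].reshape(nseg, seg)
        sdann = float(segs.mean(axis=1).std())
        sdnni = float(segs.std(axis=1).mean())
    else:
        sdann = sdnni = 0.0
        flags.add("too_short_for_segments")

    nnx = int(np.sum(np.abs(diffs) > cfg.nnx_ms))
    pnnx = 100.0 * nnx / diffs.size if diffs.size else 0.0

    em = _epoch_means(x, fs, cfg.epoch_s)
    if em.size == 0:
        em = np.array([x.mean()])
        flags.add("too_short_for_epochs")
    ed = np.diff(em)
    stv = float(np.mean(np.abs(ed))) if ed.size else 0.0
    em_sd = float(em.std())
    if em_sd == 0.0:
        ii = 0.0
        flags.add("constant_epoch_means")
    else:
        ii = stv / em_sd
    if em.size >= 2:
        mod = np.sqrt(em[:-1] ** 2 + em[1:] ** 2)
        q75, q25 = np.percentile(mod, [75, 25])
        lti = float(q75 - q25)
    else:
        lti = 0.0

    blk = int(round(60.0 * fs))
    nblk = x.size // blk
    if nblk >= 1:
        blocks = x[: nblk * blk].reshape(nblk, blk)
        delta = float((blocks.max(axis=1) - blocks.min(axis=1)).mean())
    else:
        delta = float(x.max() - x.min())

    lo = np.floor(x.min() / cfg.hist_bin_ms) * cfg.hist_bin_ms
    hi = np.ceil(x.max() / cfg.hist_bin_ms) * cfg.hist_bin_ms
    if hi <= lo:
        hi = lo + cfg.hist_bin_ms
    edges = np.arange(lo, hi + cfg.hist_bin_ms / 2, cfg.hist_bin_ms)
    counts, _ = np.histogram(x, bins=edges)
    tri = float(x.size / counts.max())
    tinn = _tinn(counts.astype(float), edges)

    feats = {
        "meanRR": float(x.mean()),
        "minRR": float(x.min()),
        "maxRR": float(x.max()),
        "medianRR": float(np.median(x)),
        "SDNN": float(x.std()),
        "SDANN": sdann,
        "SDNNi": sdnni,
        "RMSSD": float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0,
        "NNx": float(nnx),
        "pNNx": float(pnnx),
        "STV": stv,
        "II": ii,
        "LTI": lti,
        "delta": delta,
        "delta_total": float(x.max() - x.min()),
        "Tri": tri,
        "TINN": tinn,
    }
    return feats, flags
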