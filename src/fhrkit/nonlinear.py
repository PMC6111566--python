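"""Nonlinear HRV estimators: fractal dimension, entropies, complexity,
long-range scaling, phase-rectified averaging and the Poincaré map.

All estimators operate on the epoch-level RR series (ms) and are
deterministic given input and configuration.

* Higuchi fractal dimension — curve-length scaling over subsampled lags,
  in [1, 2] (1 for smooth curves, 2 for white noise).
* ApEn / SampEn — template-matching regularity at embedding dimension m
  and tolerance r = r_coeff * sd; ApEn includes self-matches, SampEn
  excludes them.
* Lempel-Ziv complexity — successive differences ternary-encoded
  (equal -> 2, increase -> 1, decrease -> 0) then parsed with the 1976
  sequential pattern-counting scheme; normalized C(n) = c(n) log2(n)/n.
* Hurst exponent — rescaled-range (R/S) slope over dyadic window sizes.
* DFA — detrended fluctuation analysis scaling exponents (alpha over
  scales 4–64, alpha1 4–16, alpha2 16–64; 0.5 white noise, 1.0 1/f,
  1.5 random walk).
* PRSA — phase-rectified signal averaging around increase/decrease
  anchors; acceleration/deceleration capacity via the quartet formula
  (P(0)+P(1)-P(-1)-P(-2))/4 and the corresponding local slopes.
* Poincaré SD1/SD2 — dispersions across/along the identity line of the
  lag-1 return map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EntropyConfig", "HiguchiConfig", "PRSAConfig", "LZCResult",
    "higuchi_fd", "apen", "sampen", "lzc", "hurst", "dfa_alpha",
    "prsa_features", "poincare", "NONLINEAR_FEATURE_NAMES",
]

NONLINEAR_FEATURE_NAMES = [
    "FD_Hig", "ApEn", "SampEn", "LZC", "Hurst", "alpha",
    "AAC", "ADC", "APRS", "DPRS", "SD1", "SD2",
]


@dataclass
class EntropyConfig:
    m: int = 2
    r_coeff: float = 0.15
    metric: str = "euclidean"  # or "chebyshev"

    def __post_init__(self) -> None:
        if self.m < 1 or self.r_coeff <= 0:
            raise ValueError("m >= 1 and r_coeff > 0 required")
        if self.metric not in ("euclidean", "chebyshev"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def p_norm(self) -> float:
        return 2.0 if self.metric == "euclidean" else np.inf


@dataclass
class HiguchiConfig:
    kmax: int = 32

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError("kmax >= 2 required")


@dataclass
class PRSAConfig:
    T: int = 1   # anchor comparison lag
    L: int = 10  # half-window (samples)

    def __post_init__(self) -> None:
        if self.T < 1 or self.L < 2:
            raise ValueError("T >= 1 and L >= 2 required")


@dataclass
class LZCResult:
    encoded: str
    c_n: int
    C_n: float


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def higuchi_fd(x, cfg: HiguchiConfig | None = None) -> float:
    """Higuchi fractal dimension, clipped to [1, 2].

    For each lag k and offset m, the subsampled curve length is
    L_m(k) = (sum |x(m+ik) - x(m+(i-1)k)|) * (N-1) / (floor((N-m)/k) * k^2);
    lengths are averaged over offsets and the dimension is minus the slope
    of log<L(k)> against log k.
    """
    cfg = cfg or HiguchiConfig()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 * cfg.kmax:
        raise ValueError(f"need length >= 10*kmax = {10 * cfg.kmax}")
    if np.ptp(x) == 0:
        return 1.0
    ks = np.arange(1, cfg.kmax + 1)
    lk = np.empty(ks.size)
    for j, k in enumerate(ks):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            nmax = idx.size - 1  # = floor((n-1-m)/k)
            lm = np.abs(np.diff(x[idx])).sum() * (n - 1) / (nmax * k * k)
            lengths.append(lm)
        lk[j] = np.mean(lengths)
    slope = np.polyfit(np.log(ks), np.log(lk), 1)[0]
    return float(np.clip(-slope, 1.0, 2.0))


def _phi(x: np.ndarray, m: int, r: float, p: float) -> float:
    """Phi^m(r): mean log of per-template match fractions (self-matches in)."""
    emb = _embed(x, m)
    tree = cKDTree(emb)
    counts = tree.query_ball_point(emb, r, p=p, return_length=True)
    return float(np.mean(np.log(counts / emb.shape[0])))


def apen(x, cfg: EntropyConfig | None = None) -> float:
    """Approximate entropy, Phi^m(r) - Phi^{m+1}(r); self-matches included."""
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    r = cfg.r_coeff * sd
    return _phi(x, cfg.m, r, cfg.p_norm) - _phi(x, cfg.m + 1, r, cfg.p_norm)


def sampen(x, cfg: EntropyConfig | None = None) -> float:
    """Sample entropy, -ln(A/B) with self-matches excluded.

    A and B count ordered template pairs (i != j) of length m+1 and m over
    the common N - m template set.  When no (m+1)-template finds a match the
    estimator is undefined; the conservative upper bound ln(B) is returned.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    r = cfg.r_coeff * sd
    n_templates = x.size - cfg.m

    def pairs(m: int) -> int:
        emb = _embed(x, m)[:n_templates]
        tree = cKDTree(emb)
        counts = tree.query_ball_point(emb, r, p=cfg.p_norm, return_length=True)
        return int(counts.sum() - n_templates)  # remove self-matches

    b = pairs(cfg.m)
    a = pairs(cfg.m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(b))
    return float(-np.log(a / b))


def encode_ternary(x) -> str:
    """Symbolize successive differences: equal -> '2', rise -> '1', fall -> '0'."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    d = np.diff(x)
    sym = np.where(d == 0, "2", np.where(d > 0, "1", "0"))
    return "".join(sym)


def lz76_count(s: str) -> int:
    """Lempel-Ziv 1976 sequential complexity: number of phrases in the
    exhaustive-history parse, counting an unfinished terminal phrase."""
    n = len(s)
    if n == 0:
        return 0
    c = 1
    i = 1  # start of current phrase
    while i < n:
        # longest prefix of s[i:] occurring in s starting before i
        ell = 0
        while i + ell < n and s.find(s[i : i + ell + 1], 0, i + ell) != -1:
            ell += 1
        if i + ell >= n:
            c += 1  # unfinished terminal phrase
            break
        c += 1
        i += ell + 1
    return c


def lzc(x) -> LZCResult:
    """Ternary-encoded Lempel-Ziv complexity with length normalization."""
    s = encode_ternary(x)
    c = lz76_count(s)
    n = len(s)
    return LZCResult(encoded=s, c_n=c, C_n=float(c * np.log2(n) / n))


def _expected_rs(n: int) -> float:
    """Anis-Lloyd-Peters expected R/S of an i.i.d. series of length n."""
    i = np.arange(1, n)
    tail = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        from scipy.special import gammaln

        front = np.exp(gammaln((n - 1) / 2) - gammaln(n / 2)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2)
    return float((n - 0.5) / n * front * tail)


def hurst(x, corrected: bool = True, min_window: int = 32) -> float:
    """Rescaled-range Hurst exponent over dyadic window sizes min_window..N/2.

    With ``corrected=True`` (default) the Anis-Lloyd-Peters finite-sample
    expectation is subtracted in log-space and 0.5 added back, removing the
    well-known upward small-window bias of plain R/S.  Short windows carry
    the largest transient bias for persistent signals, hence the 32-sample
    floor.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 256:
        raise ValueError("need length >= 256")
    if np.ptp(x) == 0:
        return 0.5
    sizes = []
    s = min_window
    while s <= n // 2:
        sizes.append(s)
        s *= 2
    log_rs, log_s = [], []
    for s in sizes:
        nblk = n // s
        blocks = x[: nblk * s].reshape(nblk, s)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        rng = z.max(axis=1) - z.min(axis=1)
        sd = blocks.std(axis=1)
        ok = sd > 0
        if not ok.any():
            continue
        rs = np.log((rng[ok] / sd[ok]).mean())
        if corrected:
            rs -= np.log(_expected_rs(s))
        log_rs.append(rs)
        log_s.append(np.log(s))
    slope = float(np.polyfit(log_s, log_rs, 1)[0])
    return slope + 0.5 if corrected else slope


def dfa_alpha(x, scales: tuple = (4, 64), split: int = 16) -> dict:
    """DFA-1 scaling exponents: alpha (4-64), alpha1 (4-16), alpha2 (16-64)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 256:
        raise ValueError("need length >= 256")
    if np.ptp(x) == 0:
        return {"alpha": 0.0, "alpha1": 0.0, "alpha2": 0.0}
    profile = np.cumsum(x - x.mean())
    smin, smax = scales
    ss = np.unique(np.round(np.geomspace(smin, smax, 16)).astype(int))
    fluct = []
    for s in ss:
        nblk = n // s
        segs = profile[: nblk * s].reshape(nblk, s)
        t = np.arange(s)
        # per-segment linear detrend
        coef = np.polynomial.polynomial.polyfit(t, segs.T, 1)
        trend = coef[0][:, None] + coef[1][:, None] * t
        fluct.append(np.sqrt(np.mean((segs - trend) ** 2)))
    fluct = np.asarray(fluct)
    log_s, log_f = np.log(ss), np.log(fluct)

    def fit(lo, hi):
        m = (ss >= lo) & (ss <= hi)
        return float(np.polyfit(log_s[m], log_f[m], 1)[0])

    return {"alpha": fit(smin, smax), "alpha1": fit(smin, split), "alpha2": fit(split, smax)}


def prsa_features(x, cfg: PRSAConfig | None = None) -> tuple[dict, set]:
    """Phase-rectified signal averaging features {AAC, ADC, APRS, DPRS}.

    Acceleration anchors are samples rising over lag T (x[i] > x[i-T]);
    deceleration anchors fall.  Windows [-L, L) around each anchor are
    averaged into a PRSA curve P(tau); the capacity is the quartet contrast
    (P(0) + P(1) - P(-1) - P(-2)) / 4 and the slope is the least-squares
    line through P over tau in [-2, 2].
    """
    cfg = cfg or PRSAConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 4 * cfg.L:
        raise ValueError("series too short for PRSA window")
    flags: set[str] = set()

    def curve(anchor_mask: np.ndarray) -> np.ndarray | None:
        idx = np.flatnonzero(anchor_mask)
        idx = idx[(idx >= cfg.L) & (idx <= x.size - cfg.L)]
        if idx.size == 0:
            return None
        offs = np.arange(-cfg.L, cfg.L)
        return x[idx[:, None] + offs[None, :]].mean(axis=0)

    rising = np.zeros(x.size, dtype=bool)
    falling = np.zeros(x.size, dtype=bool)
    rising[cfg.T :] = x[cfg.T :] > x[: -cfg.T]
    falling[cfg.T :] = x[cfg.T :] < x[: -cfg.T]

    out = {"AAC": 0.0, "ADC": 0.0, "APRS": 0.0, "DPRS": 0.0}
    taus = np.arange(-2, 3)
    for name_cap, name_slope, mask in (("AAC", "APRS", rising), ("ADC", "DPRS", falling)):
        p = curve(mask)
        if p is None:
            flags.add(f"no_{name_cap.lower()}_anchors")
            continue
        at = lambda tau: p[tau + cfg.L]
        out[name_cap] = float((at(0) + at(1) - at(-1) - at(-2)) / 4.0)
        seg = np.array([at(t) for t in taus])
        out[name_slope] = float(np.polyfit(taus, seg, 1)[0])
    return out, flags


def poincare(rr) -> tuple[float, float]:
    """Lag-1 return-map ellipse axes.

    SD1 — dispersion across the identity line, the RMS of
    (rr_{i+1} - rr_i)/sqrt(2) (successive differences scatter around zero,
    so no mean is subtracted and SD1 = RMSSD/sqrt(2) holds exactly);
    SD2 — dispersion along the identity line, the population sd of
    (rr_{i+1} + rr_i)/sqrt(2).
    """
    x = np.asarray(rr, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    d = (x[1:] - x[:-1]) / np.sqrt(2.0)
    s = (x[1:] + x[:-1]) / np.sqrt(2.0)
    return float(np.sqrt(np.mean(d**2))), float(s.std())


def nonlinear_features(
    rr_ms: np.ndarray,
    entropy_cfg: EntropyConfig | None = None,
    higuchi_cfg: HiguchiConfig | None = None,
    prsa_cfg: PRSAConfig | None = None,
) -> tuple[dict, set]:
    """The twelve nonlinear features on the RR series (ms)."""
    x = np.asarray(rr_ms, dtype=float)
    flags: set[str] = set()
    if np.ptp(x) == 0:
        flags.add("constant_series")
    prsa, prsa_flags = prsa_features(x, prsa_cfg)
    flags |= prsa_flags
    sd1, sd2 = poincare(x)
    dfa = dfa_alpha(x)
    feats = {
        "FD_Hig": higuchi_fd(x, higuchi_cfg),
        "ApEn": apen(x, entropy_cfg),
        "SampEn": sampen(x, entropy_cfg),
        "LZC": lzc(x).C_n,
        "Hurst": hurst(x),
        "alpha": dfa["alpha"],
        "AAC": prsa["AAC"],
        "ADC": prsa["ADC"],
        "APRS": prsa["APRS"],
        "DPRS": prsa["DPRS"],
        "SD1": sd1,
        "SD2": sd2,
    }
    return feats, flags
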