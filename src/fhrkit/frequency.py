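"""Spectral analysis of the RR series and the ten band-power features.

The fetal-specific spectral bands are VLF 0–0.03 Hz (slow control
mechanisms), LF 0.03–0.15 Hz (sympathetic activity), MF 0.15–0.50 Hz
(fetal movement / maternal breathing) and HF 0.50–1.00 Hz (fetal
breathing); Ratio_Band = LF / (MF + HF) indexes sympathovagal balance.
Bands are half-open [lo, hi) and contiguous, so band powers sum exactly
to the total.

Three interchangeable PSD backends operate on the mean-detrended RR
series (ms, uniformly sampled at the FHR grid rate):

* ``welch`` — scipy Welch averaged periodogram (1024-sample Hamming
  segments, 50% overlap);
* ``burg`` — order-16 autoregressive fit (Burg recursion via
  statsmodels), evaluated on a 1024-point frequency grid;
* ``lombscargle`` — scipy Lomb-Scargle periodogram at the sample
  timestamps on the same grid, scaled to one-sided density units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import burg as _burg_fit

from .timedomain import RRSeries

__all__ = ["PSDEstimate", "BandDefinition", "compute_psd", "freq_features",
           "FREQ_FEATURE_NAMES", "RATIO_CAP"]

FREQ_FEATURE_NAMES = [
    "Power_VLF", "Power_LF", "Power_MF", "Power_HF", "Power_Total",
    "Percent_VLF", "Percent_LF", "Percent_MF", "Percent_HF", "Ratio_Band",
]

RATIO_CAP = 1e6  # sentinel when MF + HF power vanishes

_NFREQ = 1024
_WELCH_NPERSEG = 1024
_BURG_ORDER = 16


@dataclass
class BandDefinition:
    vlf: tuple = (0.0, 0.03)
    lf: tuple = (0.03, 0.15)
    mf: tuple = (0.15, 0.50)
    hf: tuple = (0.50, 1.00)

    def items(self):
        return [("VLF", self.vlf), ("LF", self.lf), ("MF", self.mf), ("HF", self.hf)]


@dataclass
class PSDEstimate:
    freqs: np.ndarray  # Hz, increasing, spanning [0, fs/2]
    power: np.ndarray  # ms^2/Hz, one-sided
    method: str = "welch"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


def compute_psd(rr: RRSeries, method: str = "welch", params: dict | None = None) -> PSDEstimate:
    """One-sided PSD of the detrended RR series on [0, fs/2]."""
    params = params or {}
    x = rr.rr_ms - rr.rr_ms.mean()
    fs = rr.fs_source
    if method == "welch":
        if x.size < _WELCH_NPERSEG:
            raise ValueError(f"welch requires >= {_WELCH_NPERSEG} samples")
        nperseg = params.get("nperseg", _WELCH_NPERSEG)
        f, p = sps.welch(
            x, fs=fs, window="hamming", nperseg=nperseg,
            noverlap=nperseg // 2, detrend="constant",
        )
        return PSDEstimate(freqs=f, power=p, method=method)
    if method == "burg":
        if x.size < _NFREQ:
            raise ValueError(f"burg requires >= {_NFREQ} samples")
        order = params.get("order", _BURG_ORDER)
        rho, sigma2 = _burg_fit(x, order=order, demean=True)
        f = np.linspace(0.0, fs / 2, _NFREQ)
        # AR(p): x_t = sum rho_k x_{t-k} + e_t;  S(f) = sigma2 / (fs |A(f)|^2), one-sided x2
        k = np.arange(1, order + 1)
        a = 1.0 - np.exp(-2j * np.pi * np.outer(f / fs, k)) @ rho
        p = 2.0 * sigma2 / (fs * np.abs(a) ** 2)
        return PSDEstimate(freqs=f, power=p, method=method)
    if method in ("lombscargle", "lomb"):
        if x.size < 2:
            raise ValueError("lombscargle requires >= 2 samples")
        f = np.linspace(0.0, fs / 2, _NFREQ)
        t = np.arange(x.size) / fs
        pg = sps.lombscargle(t, x, 2 * np.pi * f[1:])
        # E[P_LS] = var(x) for white noise; scale to one-sided density 2*var/fs
        p = np.concatenate(([0.0], pg * 2.0 / fs))
        return PSDEstimate(freqs=f, power=p, method="lombscargle")
    raise ValueError(f"unknown PSD method {method!r}")


def _band_power(psd: PSDEstimate, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], interpolating at the
    band edges so contiguous bands partition the spectrum exactly."""
    f, p = psd.freqs, psd.power
    lo = max(lo, f[0])
    hi = min(hi, f[-1])
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    fi = np.concatenate(([lo], f[inner], [hi]))
    pi = np.concatenate(([np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]))
    return float(np.trapezoid(pi, fi))


def freq_features(psd: PSDEstimate, bands: BandDefinition | None = None) -> tuple[dict, set]:
    """Band powers (ms^2), percentages of total, and the LF/(MF+HF) ratio."""
    bands = bands or BandDefinition()
    flags: set[str] = set()
    powers = {name: _band_power(psd, lo, hi) for name, (lo, hi) in bands.items()}
    total = sum(powers.values())
    feats = {f"Power_{k}": v for k, v in powers.items()}
    feats["Power_Total"] = total
    if total == 0.0:
        flags.add("zero_total_power")
        for k in powers:
            feats[f"Percent_{k}"] = 0.0
    else:
        for k, v in powers.items():
            feats[f"Percent_{k}"] = 100.0 * v / total
    denom = powers["MF"] + powers["HF"]
    if denom == 0.0:
        flags.add("ratio_band_capped")
        feats["Ratio_Band"] = RATIO_CAP if powers["LF"] > 0 else 0.0
    else:
        feats["Ratio_Band"] = min(powers["LF"] / denom, RATIO_CAP)
    return {k: feats[k] for k in FREQ_FEATURE_NAMES}, flags
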