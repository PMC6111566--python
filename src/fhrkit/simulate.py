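"""Synthetic cardiotocographic signal and cohort generation.

Every pipeline stage is testable without clinical recordings.  Two levels
are provided:

* :func:`generate_record` synthesizes a single FHR trace with known ground
  truth: a 110–160 bpm baseline with slow sinusoidal drift, beat-scale
  variability produced as a 1/f-like colored-noise process in the RR (ms)
  domain and mapped back to bpm, smooth plateau accelerations/decelerations
  of controlled amplitude and duration, isolated spikes outside [50, 200]
  bpm and zero-run dropouts.  The exact injected episode list and the
  noise-free baseline are returned so detectors can be scored directly.

* :func:`generate_cohort` synthesizes a labeled two-class *feature matrix*
  (normal vs pathological, pH straddling 7.15, gestational age 37–43 weeks
  with an injected linear GA trend).  Per-feature class effects are
  expressed in units of the empirical feature standard deviation measured
  on a small bank of simulated records, with signs matching the clinical
  direction (pathological: higher baseline, shorter RR, lower short-term
  variability, lower fractal dimension/complexity).  Feature draws are
  independent Gaussians — adequate for calibrating selection and
  classification harnesses, not a physiological cardiovascular model.

:func:`generate_cohort_records` produces actual signal-level cohorts (at
small n) for end-to-end runs through preprocessing and extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .records import FHRRecord, ClinicalMeta
from .features import FEATURE_NAMES, FeatureMatrix, extract_all
from .preprocess import preprocess

__all__ = [
    "SynthConfig", "CohortConfig", "generate_record", "generate_cohort",
    "generate_cohort_records", "DESIGNATED_FEATURES", "EFFECT_SIGNS",
    "fractional_gaussian_noise",
]


def fractional_gaussian_noise(n: int, hurst_h: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise via Davies-Harte circulant embedding.

    Unit-variance stationary increments of fractional Brownian motion with
    Hurst exponent ``hurst_h``; used to calibrate long-range-dependence
    estimators.
    """
    k = np.arange(n)
    gamma = 0.5 * ((k + 1) ** (2 * hurst_h) - 2 * k ** (2 * hurst_h)
                   + np.abs(k - 1) ** (2 * hurst_h))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.maximum(np.fft.rfft(row).real, 0.0)
    m = len(row)
    w = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
    w[0] = np.sqrt(2) * w[0].real
    w[-1] = np.sqrt(2) * w[-1].real
    return np.fft.irfft(np.sqrt(lam * m / 2) * w)[:n]

# Discriminative features a pathological cohort shifts, with direction:
# +1 = higher in pathological, -1 = lower.
DESIGNATED_FEATURES = [
    "meanBL", "minBL", "maxBL", "meanRR", "minRR", "maxRR", "STV", "FD_Hig", "LZC",
]
EFFECT_SIGNS = {
    "meanBL": +1.0, "minBL": +1.0, "maxBL": +1.0,
    "meanRR": -1.0, "minRR": -1.0, "maxRR": -1.0,
    "STV": -1.0, "FD_Hig": -1.0, "LZC": -1.0,
}


@dataclass
class SynthConfig:
    duration_s: float = 1500.0
    fs: float = 4.0
    baseline_bpm: float = 140.0
    baseline_drift_bpm: float = 5.0
    n_accels: int = 2
    n_decels_mild: int = 1
    n_decels_prolonged: int = 0
    n_decels_severe: int = 0
    accel_amp_bpm: float = 20.0
    decel_amp_bpm: float = 20.0
    variability_sd_ms: float = 10.0
    spectral_slope: float = 1.0  # 1/f exponent of the RR-domain noise
    spike_rate_per_min: float = 0.0
    dropout_runs: list = field(default_factory=list)  # (start_s, dur_s)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s * self.fs <= 4800 + 400 * self.fs and self.n_decels_severe:
            raise ValueError("duration too short for a severe deceleration")
        for a in (self.accel_amp_bpm, self.decel_amp_bpm, self.variability_sd_ms):
            if a < 0:
                raise ValueError("amplitudes must be >= 0")


@dataclass
class CohortConfig:
    n_normal: int = 447
    n_pathological: int = 105
    effect: float = 2.0  # class shift on designated features, in sd units
    ph_normal_range: tuple = (7.15, 7.45)
    ph_path_range: tuple = (6.85, 7.14)
    ga_range: tuple = (37.0, 43.0)
    ga_slope_sd_per_week: float = 0.1  # injected linear GA trend (all features)
    designated: tuple = tuple(DESIGNATED_FEATURES)
    base_seed: int = 7  # seeds the record bank behind the feature statistics
    n_base_records: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.ph_normal_range[0] >= 7.15 and self.ph_path_range[1] < 7.15):
            raise ValueError("class pH ranges must respect the 7.15 rule")


def _colored_noise(
    n: int, slope: float, rng: np.random.Generator, hp_hz: float = 0.0, fs: float = 1.0
) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^slope.

    ``hp_hz`` optionally zeroes components below that frequency: the record
    generator band-limits the variability process so ultra-slow wander stays
    in the explicit baseline-drift term rather than leaking into the
    variability channel.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-slope / 2.0)
    scale[f < hp_hz] = 0.0
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


_RAMP_S = 10.0  # raised-cosine ramp on each side of an episode plateau


def _episode_shape(n: int, fs: float, start_s: float, plateau_s: float, amp: float) -> np.ndarray:
    """Plateau of +-amp with raised-cosine ramps, sampled on the record grid."""
    t = np.arange(n) / fs
    y = np.zeros(n)
    r = _RAMP_S
    t0, t1 = start_s, start_s + plateau_s
    up = (t >= t0 - r) & (t < t0)
    y[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - (t0 - r)) / r))
    y[(t >= t0) & (t <= t1)] = 1.0
    down = (t > t1) & (t <= t1 + r)
    y[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - t1) / r))
    return amp * y


_PLATEAU_RANGES = {  # nominal plateau duration (s) per episode class
    "acceleration": (20.0, 45.0),
    "mild": (30.0, 90.0),
    "prolonged": (150.0, 260.0),
    "severe": (330.0, 400.0),
}


def generate_record(cfg: SynthConfig | None = None) -> tuple[FHRRecord, dict]:
    """Synthesize one FHR record; returns (record, ground_truth).

    Ground truth holds the injected episode list (kind, class, start_s,
    plateau_s, amp_bpm), the noise-free baseline curve in bpm, spike and
    dropout positions, and the configuration.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    baseline = cfg.baseline_bpm + cfg.baseline_drift_bpm * np.sin(
        2 * np.pi * t / cfg.duration_s
    )
    rr_base = 60000.0 / baseline
    # variability band-limited to periods < 3 min; slower wander is baseline
    noise = _colored_noise(
        n, cfg.spectral_slope, rng, hp_hz=1.0 / 180.0, fs=cfg.fs
    ) * cfg.variability_sd_ms
    fhr = 60000.0 / (rr_base + noise)

    # episode placement: non-overlapping, inside the first 20-min window,
    # clear of the record start so the stable-start search stays early
    wanted = (
        [("acceleration", "acceleration", cfg.accel_amp_bpm)] * cfg.n_accels
        + [("deceleration", "mild", -cfg.decel_amp_bpm)] * cfg.n_decels_mild
        + [("deceleration", "prolonged", -cfg.decel_amp_bpm)] * cfg.n_decels_prolonged
        + [("deceleration", "severe", -cfg.decel_amp_bpm)] * cfg.n_decels_severe
    )
    rng.shuffle(wanted)
    drawn = [(k, kl, a, float(rng.uniform(*_PLATEAU_RANGES[kl]))) for k, kl, a in wanted]
    drawn.sort(key=lambda e: -e[3])  # place longest first: better packing
    placed: list[tuple[float, float]] = []
    episodes = []
    t_hi = min(cfg.duration_s, 4800 / cfg.fs) - 2 * _RAMP_S - 20.0
    for kind, klass, amp, plateau in drawn:
        ok = False
        for _ in range(200):
            start = float(rng.uniform(60.0, t_hi - plateau))
            span = (start - _RAMP_S - 30.0, start + plateau + _RAMP_S + 30.0)
            if all(span[1] < a or span[0] > b for a, b in placed):
                ok = True
                break
        if not ok:
            raise ValueError("could not place episodes without overlap; reduce counts")
        placed.append((span[0], span[1]))
        fhr = fhr + _episode_shape(n, cfg.fs, start, plateau, amp)
        episodes.append(
            {"kind": kind, "class": klass, "start_s": start,
             "plateau_s": plateau, "amp_bpm": amp}
        )

    n_spikes = rng.poisson(cfg.spike_rate_per_min * cfg.duration_s / 60.0)
    spike_idx = np.sort(rng.choice(np.arange(40, n - 2), size=min(n_spikes, n // 20),
                                   replace=False)) if n_spikes else np.array([], dtype=int)
    for i in spike_idx:
        fhr[i] = rng.uniform(5.0, 45.0) if rng.random() < 0.5 else rng.uniform(205.0, 235.0)

    dropout_idx = []
    for start_s, dur_s in cfg.dropout_runs:
        a = int(round(start_s * cfg.fs))
        b = min(n, a + int(round(dur_s * cfg.fs)))
        fhr[a:b] = 0.0
        dropout_idx.append((a, b))

    record = FHRRecord(
        record_id=f"synth-{cfg.seed}", samples=np.maximum(fhr, 0.0), fs=cfg.fs,
        meta=ClinicalMeta(),
    )
    truth = {
        "episodes": episodes,
        "baseline_bpm": baseline,
        "spike_indices": spike_idx.tolist(),
        "dropouts": dropout_idx,
        "config": cfg,
    }
    return record, truth


@lru_cache(maxsize=4)
def _base_feature_stats(base_seed: int, n_base: int) -> tuple:
    """Empirical per-feature mean and sd over a bank of simulated records
    with jittered generator parameters; anchors cohort feature draws."""
    rows = []
    rng = np.random.default_rng(base_seed)
    for k in range(n_base):
        cfg = SynthConfig(
            baseline_bpm=float(rng.uniform(125.0, 150.0)),
            baseline_drift_bpm=float(rng.uniform(2.0, 7.0)),
            variability_sd_ms=float(rng.uniform(6.0, 16.0)),
            n_accels=int(rng.integers(0, 4)),
            n_decels_mild=int(rng.integers(0, 3)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, _ = generate_record(cfg)
        clean, _ = preprocess(rec)
        rows.append(extract_all(clean).as_array())
    arr = np.array(rows)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd = np.maximum(sd, np.maximum(1e-6, 1e-3 * np.abs(mu)))
    return tuple(mu), tuple(sd)


def generate_cohort(cfg: CohortConfig | None = None) -> FeatureMatrix:
    """Feature-level two-class cohort with pH labels and GA metadata."""
    cfg = cfg or CohortConfig()
    mu, sd = map(np.asarray, _base_feature_stats(cfg.base_seed, cfg.n_base_records))
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_normal + cfg.n_pathological
    labels = np.array(["normal"] * cfg.n_normal + ["pathological"] * cfg.n_pathological)
    ga = rng.uniform(*cfg.ga_range, size=n_total)
    x = mu[None, :] + rng.standard_normal((n_total, 47)) * sd[None, :]
    # linear GA trend, the signal ga_normalize is meant to remove
    ga_c = ga - np.mean(cfg.ga_range)
    x = x + cfg.ga_slope_sd_per_week * np.outer(ga_c, sd)
    if cfg.effect != 0.0:
        shift = np.zeros(47)
        for name in cfg.designated:
            j = FEATURE_NAMES.index(name)
            shift[j] = EFFECT_SIGNS.get(name, 1.0) * cfg.effect * sd[j]
        x[labels == "pathological"] += shift[None, :]
    ph = np.concatenate([
        rng.uniform(*cfg.ph_normal_range, size=cfg.n_normal),
        rng.uniform(*cfg.ph_path_range, size=cfg.n_pathological),
    ])
    ids = [f"rec{k:04d}" for k in range(n_total)]
    values = pd.DataFrame(x, index=ids, columns=FEATURE_NAMES)
    values["_ph"] = ph  # kept out of the canonical columns below
    ph_col = values.pop("_ph")
    mat = FeatureMatrix(values=values, labels=labels, ga=ga)
    mat.ph = ph_col.to_numpy()
    return mat


def generate_cohort_records(
    n_normal: int = 6,
    n_pathological: int = 6,
    effect: float = 2.0,
    seed: int = 0,
    duration_s: float = 1500.0,
) -> list[tuple[FHRRecord, dict]]:
    """Signal-level cohort: raw records with class-dependent generator
    parameters and pH/GA metadata, for end-to-end pipeline runs."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_normal + n_pathological):
        pathological = k >= n_normal
        base = rng.uniform(130.0, 146.0) + (4.0 * effect if pathological else 0.0)
        var = max(3.0, rng.uniform(8.0, 14.0) * (1.0 - 0.15 * effect if pathological else 1.0))
        cfg = SynthConfig(
            duration_s=duration_s,
            baseline_bpm=float(min(base, 168.0)),
            variability_sd_ms=float(var),
            n_accels=int(rng.integers(0, 3)),
            n_decels_mild=int(rng.integers(0, 2)),
            spike_rate_per_min=0.4,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = generate_record(cfg)
        if pathological:
            rec.meta = ClinicalMeta(ph=float(rng.uniform(6.9, 7.14)),
                                    ga_weeks=float(rng.uniform(37, 43)))
        else:
            rec.meta = ClinicalMeta(ph=float(rng.uniform(7.15, 7.45)),
                                    ga_weeks=float(rng.uniform(37, 43)))
        rec.record_id = f"cohort-{k:03d}"
        out.append((rec, truth))
    return out
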