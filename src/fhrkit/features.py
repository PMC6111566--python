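"""47-feature assembly, gestational-age normalization and feature selection.

The canonical feature vector concatenates the four domains in fixed order:
8 morphological + 17 time-domain + 10 frequency-domain + 12 nonlinear = 47.

Gestational age (GA) systematically shifts many HRV parameters, so before
classification each feature can be regressed on GA (ordinary least squares
fit on the *training* rows only) and replaced by its residual plus the
training grand mean; min-max scaling is the alternative.  Fitting on train
folds only avoids information leakage into held-out folds; a global
"paper mode" fit is available for protocol comparison.

Three selection/reduction schemes are provided: per-feature two-sided
Mann-Whitney U tests (select features with p < alpha, no multiplicity
correction by default), per-feature ROC AUC ranking (oriented so
AUC >= 0.5), and PCA on z-scored features retaining the smallest number of
leading components reaching the target explained-variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .records import FHRRecord
from .morphology import morph_features, MORPH_FEATURE_NAMES
from .timedomain import fhr_to_rr, time_features, TimeDomainConfig, TIME_FEATURE_NAMES
from .frequency import compute_psd, freq_features, BandDefinition, FREQ_FEATURE_NAMES
from .nonlinear import (
    nonlinear_features,
    EntropyConfig,
    HiguchiConfig,
    PRSAConfig,
    NONLINEAR_FEATURE_NAMES,
)

__all__ = [
    "FEATURE_NAMES", "FeatureVector", "FeatureMatrix", "SelectionResult",
    "ExtractionConfig", "extract_all", "ga_normalize", "minmax_normalize",
    "select_st", "select_auc", "reduce_pca", "feature_auc",
]

FEATURE_NAMES: list[str] = (
    MORPH_FEATURE_NAMES + TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES + NONLINEAR_FEATURE_NAMES
)
assert len(FEATURE_NAMES) == 47


@dataclass
class ExtractionConfig:
    baseline_window_s: float = 240.0
    time: TimeDomainConfig = field(default_factory=TimeDomainConfig)
    bands: BandDefinition = field(default_factory=BandDefinition)
    psd_method: str = "welch"
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    higuchi: HiguchiConfig = field(default_factory=HiguchiConfig)
    prsa: PRSAConfig = field(default_factory=PRSAConfig)


@dataclass
class FeatureVector:
    record_id: str
    values: dict  # exactly the 47 canonical names, canonical order
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if list(self.values) != FEATURE_NAMES:
            raise ValueError("values must hold exactly the 47 canonical features in order")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)


@dataclass
class FeatureMatrix:
    """Rows of feature vectors with per-row class labels and gestational age."""

    values: pd.DataFrame  # index = record_id, columns = FEATURE_NAMES
    labels: np.ndarray  # "normal" | "pathological"
    ga: Optional[np.ndarray] = None  # weeks

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if list(self.values.columns) != FEATURE_NAMES:
            raise ValueError("columns must be the 47 canonical features in order")
        if len(self.labels) != len(self.values):
            raise ValueError("labels must parallel rows")
        if self.ga is not None:
            self.ga = np.asarray(self.ga, dtype=float)
            if len(self.ga) != len(self.values):
                raise ValueError("ga must parallel rows")

    @property
    def n(self) -> int:
        return len(self.values)

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            values=self.values.iloc[idx],
            labels=self.labels[idx],
            ga=None if self.ga is None else self.ga[idx],
        )

    def to_csv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "record_id", self.values.index)
        df["label"] = self.labels
        if self.ga is not None:
            df["ga"] = self.ga
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        vals = df[FEATURE_NAMES].copy()
        vals.index = df["record_id"]
        ga = df["ga"].to_numpy() if "ga" in df.columns else None
        return cls(values=vals, labels=df["label"].to_numpy(), ga=ga)


@dataclass
class SelectionResult:
    method: str  # st | auc | pca
    selected: list  # feature names (st/auc) or retained-component labels (pca)
    scores: dict  # per-feature p-values / AUCs, or per-component variance ratios
    loadings: Optional[np.ndarray] = None  # pca only: (n_components, 47)
    n_components: Optional[int] = None
    transformer: object = None  # fitted PCA pipeline state (pca only)


def extract_all(clean: FHRRecord, cfg: ExtractionConfig | None = None) -> FeatureVector:
    """Extract all 47 features from a preprocessed record."""
    cfg = cfg or ExtractionConfig()
    try:
        morph, f1 = morph_features(clean, cfg.baseline_window_s)
        rr = fhr_to_rr(clean)
        tfeat, f2 = time_features(rr, cfg.time)
        psd = compute_psd(rr, method=cfg.psd_method)
        ffeat, f3 = freq_features(psd, cfg.bands)
        nl, f4 = nonlinear_features(rr.rr_ms, cfg.entropy, cfg.higuchi, cfg.prsa)
    except Exception as exc:
        raise type(exc)(f"record {clean.record_id!r}: {exc}") from exc
    values = {**morph, **tfeat, **ffeat, **nl}
    values = {k: float(values[k]) for k in FEATURE_NAMES}
    return FeatureVector(record_id=clean.record_id, values=values,
                         flags=f1 | f2 | f3 | f4)


def _fit_ga_lines(train: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature OLS fit value = a + b*ga on train; returns (a, b, grand mean)."""
    if train.ga is None:
        raise ValueError("gestational age required for GA normalization")
    ga = train.ga
    x = train.values.to_numpy()
    mean = x.mean(axis=0)
    if np.ptp(ga) == 0:
        return mean, np.zeros(x.shape[1]), mean
    gc = ga - ga.mean()
    b = gc @ (x - mean) / (gc @ gc)
    a = mean - b * ga.mean()
    return a, b, mean


def ga_normalize(train: FeatureMatrix, apply_to: FeatureMatrix | None = None) -> FeatureMatrix:
    """Remove the linear GA trend fitted on train rows; no leakage.

    Each feature becomes residual-from-the-train-fitted-line plus the train
    grand mean, so the output stays on the original scale but is
    decorrelated from gestational age.
    """
    target = train if apply_to is None else apply_to
    if target.ga is None:
        raise ValueError("gestational age required for GA normalization")
    a, b, mean = _fit_ga_lines(train)
    pred = a[None, :] + np.outer(target.ga, b)
    out = target.values.to_numpy() - pred + mean[None, :]
    return FeatureMatrix(
        values=pd.DataFrame(out, index=target.values.index, columns=FEATURE_NAMES),
        labels=target.labels, ga=target.ga,
    )


def minmax_normalize(train: FeatureMatrix, apply_to: FeatureMatrix | None = None) -> FeatureMatrix:
    """(v - min_train) / (max_train - min_train); held-out rows may leave [0, 1].

    Zero-range features map to 0.
    """
    target = train if apply_to is None else apply_to
    x = train.values.to_numpy()
    lo, hi = x.min(axis=0), x.max(axis=0)
    rng = hi - lo
    safe = np.where(rng == 0, 1.0, rng)
    out = (target.values.to_numpy() - lo[None, :]) / safe[None, :]
    out[:, rng == 0] = 0.0
    return FeatureMatrix(
        values=pd.DataFrame(out, index=target.values.index, columns=FEATURE_NAMES),
        labels=target.labels, ga=target.ga,
    )


def _split_classes(mat: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    pos = mat.labels == "normal"
    neg = mat.labels == "pathological"
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be represented")
    return pos, neg


def select_st(mat: FeatureMatrix, alpha: float = 0.05,
              bh_correct: bool = False) -> SelectionResult:
    """Two-sided Mann-Whitney U per feature; select p < alpha.

    Exact enumeration for samples of <= 20 per class without ties, the
    tie-corrected normal approximation otherwise.  No multiple-testing
    correction by default; ``bh_correct=True`` applies Benjamini-Hochberg.
    """
    pos, neg = _split_classes(mat)
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("need >= 2 rows per class")
    pvals = {}
    for name in FEATURE_NAMES:
        a = mat.values[name].to_numpy()[pos]
        b = mat.values[name].to_numpy()[neg]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[name] = 1.0
            continue
        small = max(len(a), len(b)) <= 20
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (small and not ties) else "asymptotic"
        pvals[name] = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    if bh_correct:
        names = list(pvals)
        order = np.argsort([pvals[n] for n in names])
        m = len(names)
        thresh = {}
        for rank, i in enumerate(order, start=1):
            thresh[names[i]] = alpha * rank / m
        selected = [n for n in FEATURE_NAMES if pvals[n] < thresh[n]]
    else:
        selected = [n for n in FEATURE_NAMES if pvals[n] < alpha]
    return SelectionResult(method="st", selected=selected, scores=pvals)


def feature_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of a single feature used as a raw score, oriented >= 0.5.

    Computed from the Mann-Whitney U statistic (tie-aware): A = U / (n1*n2),
    returned as max(A, 1-A).  A constant feature scores 0.5.
    """
    pos = values[labels == "normal"]
    neg = values[labels == "pathological"]
    if np.ptp(np.concatenate([pos, neg])) == 0:
        return 0.5
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    a = u / (len(pos) * len(neg))
    return float(max(a, 1.0 - a))


def select_auc(mat: FeatureMatrix, threshold: float = 0.71,
               top_k: Optional[int] = None) -> SelectionResult:
    """Rank features by oriented per-feature ROC AUC; select above threshold
    (or the top_k highest)."""
    _split_classes(mat)
    aucs = {
        name: feature_auc(mat.values[name].to_numpy(), mat.labels)
        for name in FEATURE_NAMES
    }
    ranked = sorted(FEATURE_NAMES, key=lambda n: aucs[n], reverse=True)
    if top_k is not None:
        selected = ranked[:top_k]
    else:
        selected = [n for n in ranked if aucs[n] > threshold]
    return SelectionResult(method="auc", selected=selected, scores=aucs)


def reduce_pca(mat: FeatureMatrix, var_target: float = 0.95) -> SelectionResult:
    """PCA on z-scored features; retain the smallest leading set of components
    whose cumulative explained-variance ratio reaches var_target."""
    if mat.n < 2:
        raise ValueError("need >= 2 rows for PCA")
    x = mat.values.to_numpy()
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd_safe
    pca = PCA()
    pca.fit(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_target) + 1)
    k = min(k, len(cum))
    scores = {f"PC{i + 1}": float(r) for i, r in enumerate(pca.explained_variance_ratio_)}
    state = {"mu": mu, "sd": sd_safe, "pca": pca, "k": k}
    return SelectionResult(
        method="pca",
        selected=[f"PC{i + 1}" for i in range(k)],
        scores=scores,
        loadings=pca.components_[:k],
        n_components=k,
        transformer=state,
    )


def apply_selection(mat: FeatureMatrix, sel: SelectionResult) -> np.ndarray:
    """Design matrix after applying a fitted selection/reduction."""
    x = mat.values.to_numpy()
    if sel.method in ("st", "auc"):
        if not sel.selected:
            return x  # nothing passed the filter: fall back to all features
        cols = [FEATURE_NAMES.index(n) for n in sel.selected]
        return x[:, cols]
    if sel.method == "pca":
        st = sel.transformer
        z = (x - st["mu"]) / st["sd"]
        return st["pca"].transform(z)[:, : st["k"]]
    raise ValueError(f"unknown selection method {sel.method!r}")
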