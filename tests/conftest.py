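"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately written as plain nested
loops straight from the defining formulas, independent of the package's
vectorized/tree-based code paths, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from fhrkit import SynthConfig, generate_record, preprocess


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def clean_record():
    """A preprocessed artifact-free synthetic record (4800 samples)."""
    rec, _ = generate_record(SynthConfig(seed=3))
    clean, _ = preprocess(rec)
    return clean


@pytest.fixture(scope="session")
def corrupted_record():
    """A synthetic record with spikes and a dropout run."""
    rec, truth = generate_record(
        SynthConfig(seed=4, spike_rate_per_min=2.0, dropout_runs=[(300.0, 12.0)])
    )
    return rec, truth


# ------------------------------------------------------------------ oracles

def sampen_bruteforce(x, m, r):
    """Sample entropy by exhaustive O(N^2) pair counting (Chebyshev/Euclidean
    handled by the caller via `dist`); self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m  # number of templates considered for both lengths

    def count(mm):
        c = 0
        for i in range(nt):
            for j in range(nt):
                if i == j:
                    continue
                d = 0.0
                for k in range(mm):
                    d += (x[i + k] - x[j + k]) ** 2
                if np.sqrt(d) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(b))
    return float(-np.log(a / b))


def apen_bruteforce(x, m, r):
    """Approximate entropy by exhaustive counting; self-matches included."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def phi(mm):
        nv = n - mm + 1
        total = 0.0
        for i in range(nv):
            c = 0
            for j in range(nv):
                d = 0.0
                for k in range(mm):
                    d += (x[i + k] - x[j + k]) ** 2
                if np.sqrt(d) <= r:
                    c += 1
            total += np.log(c / nv)
        return total / nv

    return float(phi(m) - phi(m + 1))


def lz76_recursive(s: str) -> int:
    """Independent LZ76 phrase counter, written recursively over the
    exhaustive-history definition rather than with a scanning loop."""

    def longest_reproducible(prefix: str, rest: str) -> int:
        # largest l such that rest[:l] occurs in (prefix + rest[:l-1])
        l = 0
        while l < len(rest) and rest[: l + 1] in (prefix + rest[:l]):
            l += 1
        return l

    def parse(prefix: str, rest: str) -> int:
        if not rest:
            return 0
        l = longest_reproducible(prefix, rest)
        if l >= len(rest):
            return 1  # unfinished terminal phrase
        return 1 + parse(prefix + rest[: l + 1], rest[l + 1 :])

    return parse("", s)


def mannwhitney_exact_p(a, b):
    """Two-sided Mann-Whitney p by exhaustive enumeration of all rank splits
    (assumes no ties)."""
    from itertools import combinations

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1.0
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    mu = n1 * (n - n1) / 2
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        r = ranks[list(idx)].sum()
        u = r - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def prsa_bruteforce(x, T, L):
    """Loop-based PRSA: anchor selection, window averaging, quartet
    capacities and [-2, 2] slopes."""
    x = np.asarray(x, dtype=float)
    out = {}
    for name_cap, name_slope, cmp in (("AAC", "APRS", 1), ("ADC", "DPRS", -1)):
        windows = []
        for i in range(max(T, L), len(x) - L + 1):
            rises = x[i] > x[i - T] if cmp == 1 else x[i] < x[i - T]
            if rises:
                windows.append(x[i - L : i + L])
        if not windows:
            out[name_cap] = 0.0
            out[name_slope] = 0.0
            continue
        p = np.mean(windows, axis=0)

        def at(tau):
            return p[tau + L]

        out[name_cap] = (at(0) + at(1) - at(-1) - at(-2)) / 4.0
        taus = np.arange(-2, 3)
        vals = np.array([at(t) for t in taus])
        slope = np.polyfit(taus, vals, 1)[0]
        out[name_slope] = float(slope)
    return out
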