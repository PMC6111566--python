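import numpy as np
import pytest
from conftest import apen_bruteforce, lz76_recursive, prsa_bruteforce, sampen_bruteforce

from fhrkit import (
    EntropyConfig,
    HiguchiConfig,
    PRSAConfig,
    apen,
    dfa_alpha,
    higuchi_fd,
    hurst,
    lzc,
    poincare,
    prsa_features,
    sampen,
)
from fhrkit.nonlinear import NONLINEAR_FEATURE_NAMES, nonlinear_features
from fhrkit.simulate import fractional_gaussian_noise


class TestHiguchi:
    def test_straight_line_has_dimension_one(self):
        assert higuchi_fd(np.arange(4800.0)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_has_dimension_two(self):
        x = np.random.default_rng(7).standard_normal(4800)
        assert higuchi_fd(x) == pytest.approx(2.0, abs=0.1)

    def test_constant_returns_lower_limit(self):
        assert higuchi_fd(np.full(4800, 5.0)) == 1.0

    def test_clipping_contract(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            d = higuchi_fd(np.cumsum(rng.standard_normal(1000)), HiguchiConfig(kmax=16))
            assert 1.0 <= d <= 2.0


class TestEntropies:
    def test_constant_series(self):
        assert apen(np.full(200, 3.0)) == 0.0
        assert sampen(np.full(200, 3.0)) == 0.0

    def test_alternating_series_fully_regular(self):
        # finite-N boundary effects leave O(1/n) residuals
        x = np.tile([400.0, 420.0], 100)
        assert apen(x) == pytest.approx(0.0, abs=0.05)
        assert sampen(x) == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("metric", ["euclidean", "chebyshev"])
    def test_sampen_matches_bruteforce_exactly(self, seed, metric):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 28)
        cfg = EntropyConfig(m=2, r_coeff=0.3, metric=metric)
        got = sampen(x, cfg)
        if metric == "chebyshev":
            # oracle in Chebyshev: rescale via max-coordinate distance
            expect = _sampen_cheb_oracle(x, 2, 0.3 * x.std())
        else:
            expect = sampen_bruteforce(x, 2, 0.3 * x.std())
        assert got == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_apen_matches_bruteforce_exactly(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 30)
        got = apen(x, EntropyConfig(m=2, r_coeff=0.3))
        expect = apen_bruteforce(x, 2, 0.3 * x.std())
        assert got == pytest.approx(expect, abs=1e-12)

    def test_shuffling_raises_apen(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, 300)
        shuffled = vals.copy()
        rng.shuffle(shuffled)
        assert apen(shuffled) > apen(np.sort(vals))

    def test_sampen_non_increasing_in_tolerance(self):
        x = np.random.default_rng(5).standard_normal(400)
        vals = [sampen(x, EntropyConfig(r_coeff=r)) for r in (0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_self_match_bias_direction(self):
        # self-matches inflate ApEn's conditional probabilities, biasing it
        # below SampEn on irregular data
        x = np.random.default_rng(6).standard_normal(600)
        assert apen(x) <= sampen(x) + 0.3


def _sampen_cheb_oracle(x, m, r):
    n = len(x)
    nt = n - m

    def count(mm):
        c = 0
        for i in range(nt):
            for j in range(nt):
                if i != j and max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if b == 0:
        return 0.0
    return float(np.log(b)) if a == 0 else float(-np.log(a / b))


class TestLZC:
    def test_constant_series_two_phrases(self):
        res = lzc(np.ones(10))
        assert res.encoded == "2" * 9
        assert res.c_n == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_independent_parser(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        x = rng.uniform(0, 1, n + 1)
        res = lzc(x)
        assert res.c_n == lz76_recursive(res.encoded)

    def test_random_ternary_normalization_limit(self):
        # C(n) with the log2 normalization tends to log2(3) for uniform
        # ternary symbols
        rng = np.random.default_rng(9)
        diffs = rng.choice([-1.0, 0.0, 1.0], size=4800)
        x = np.cumsum(diffs)
        res = lzc(x)
        assert res.C_n == pytest.approx(np.log2(3), abs=0.12)

    def test_encoding_rule(self):
        res = lzc(np.array([1.0, 1.0, 2.0, 1.5]))
        assert res.encoded == "210"


class TestScalingExponents:
    def test_dfa_white_noise(self):
        x = np.random.default_rng(10).standard_normal(4800)
        assert dfa_alpha(x)["alpha"] == pytest.approx(0.5, abs=0.1)

    def test_dfa_random_walk(self):
        x = np.cumsum(np.random.default_rng(11).standard_normal(4800))
        assert dfa_alpha(x)["alpha"] == pytest.approx(1.5, abs=0.1)

    def test_dfa_pink_noise(self):
        from fhrkit.simulate import _colored_noise

        x = _colored_noise(4800, 1.0, np.random.default_rng(12))
        assert dfa_alpha(x)["alpha"] == pytest.approx(1.0, abs=0.15)

    def test_hurst_white_noise(self):
        x = np.random.default_rng(13).standard_normal(4800)
        assert hurst(x) == pytest.approx(0.5, abs=0.1)

    def test_hurst_recovers_persistent_fgn(self):
        vals = [
            hurst(fractional_gaussian_noise(4800, 0.8, np.random.default_rng(s)))
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.1)

    def test_hurst_sane_range(self, clean_record):
        from fhrkit import fhr_to_rr

        h = hurst(fhr_to_rr(clean_record).rr_ms)
        assert np.isfinite(h) and 0.0 < h < 1.2

    def test_shuffling_destroys_long_range_structure(self):
        from fhrkit.simulate import _colored_noise

        rng = np.random.default_rng(14)
        x = _colored_noise(4800, 1.0, rng)
        shuffled = x.copy()
        rng.shuffle(shuffled)
        assert dfa_alpha(shuffled)["alpha"] == pytest.approx(0.5, abs=0.15)
        assert hurst(shuffled) == pytest.approx(0.5, abs=0.15)

    def test_constant_inputs_flagged_values(self):
        assert hurst(np.full(300, 1.0)) == 0.5
        assert dfa_alpha(np.full(300, 1.0))["alpha"] == 0.0


class TestPRSA:
    def test_constant_series_all_zero(self):
        feats, flags = prsa_features(np.full(100, 5.0))
        assert all(v == 0.0 for v in feats.values())
        assert flags

    def test_sign_symmetry(self):
        x = np.random.default_rng(15).standard_normal(500)
        f_pos, _ = prsa_features(x)
        f_neg, _ = prsa_features(-x)
        assert f_pos["AAC"] == pytest.approx(-f_neg["ADC"], abs=1e-9)
        assert f_pos["APRS"] == pytest.approx(-f_neg["DPRS"], abs=1e-9)

    def test_alternating_quartet_closed_form(self):
        # +-a alternation: quartet contrast cancels exactly
        x = np.tile([5.0, -5.0], 50)
        feats, _ = prsa_features(x)
        assert feats["AAC"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_loop_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(300)
        got, _ = prsa_features(x, PRSAConfig(T=1, L=10))
        expect = prsa_bruteforce(x, T=1, L=10)
        for k in ("AAC", "ADC", "APRS", "DPRS"):
            assert got[k] == pytest.approx(expect[k], abs=1e-9)


class TestPoincare:
    def test_sd1_equals_rmssd_over_sqrt2(self):
        x = np.random.default_rng(16).uniform(350, 650, 1000)
        sd1, _ = poincare(x)
        rmssd = np.sqrt(np.mean(np.diff(x) ** 2))
        assert sd1 == pytest.approx(rmssd / np.sqrt(2), abs=1e-9)

    def test_constant(self):
        assert poincare(np.full(10, 430.0)) == (0.0, 0.0)

    def test_alternating_hand_values(self):
        sd1, sd2 = poincare(np.tile([400.0, 420.0], 50))
        assert sd1 == pytest.approx(20.0 / np.sqrt(2), abs=1e-9)
        assert sd2 == pytest.approx(0.0, abs=1e-9)


def test_feature_bundle_deterministic(clean_record):
    from fhrkit import fhr_to_rr

    rr = fhr_to_rr(clean_record).rr_ms
    a, fa = nonlinear_features(rr)
    b, fb = nonlinear_features(rr)
    assert a == b and fa == fb
    assert list(a) == NONLINEAR_FEATURE_NAMES
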