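import numpy as np
import pandas as pd
import pytest
from conftest import mannwhitney_exact_p
from sklearn.metrics import roc_auc_score

from fhrkit import (
    FEATURE_NAMES,
    FeatureMatrix,
    extract_all,
    ga_normalize,
    minmax_normalize,
    reduce_pca,
    select_auc,
    select_st,
)
from fhrkit.features import FeatureVector, feature_auc
from fhrkit.morphology import MORPH_FEATURE_NAMES
from fhrkit.timedomain import TIME_FEATURE_NAMES
from fhrkit.frequency import FREQ_FEATURE_NAMES
from fhrkit.nonlinear import NONLINEAR_FEATURE_NAMES

CANONICAL = [
    "meanBL", "sdBL", "minBL", "maxBL", "ACC", "DEC_mild", "DEC_prolong",
    "DEC_severe",
    "meanRR", "minRR", "maxRR", "medianRR", "SDNN", "SDANN", "SDNNi", "RMSSD",
    "NNx", "pNNx", "STV", "II", "LTI", "delta", "delta_total", "Tri", "TINN",
    "Power_VLF", "Power_LF", "Power_MF", "Power_HF", "Power_Total",
    "Percent_VLF", "Percent_LF", "Percent_MF", "Percent_HF", "Ratio_Band",
    "FD_Hig", "ApEn", "SampEn", "LZC", "Hurst", "alpha", "AAC", "ADC",
    "APRS", "DPRS", "SD1", "SD2",
]


def _matrix(x, labels, ga=None, ids=None):
    ids = ids or [f"r{k}" for k in range(len(x))]
    return FeatureMatrix(
        values=pd.DataFrame(np.asarray(x, dtype=float), index=ids,
                            columns=FEATURE_NAMES),
        labels=np.asarray(labels),
        ga=ga,
    )


def _random_matrix(rng, n_pos, n_neg, ga=False):
    x = rng.standard_normal((n_pos + n_neg, 47))
    labels = ["normal"] * n_pos + ["pathological"] * n_neg
    g = rng.uniform(37, 43, n_pos + n_neg) if ga else None
    return _matrix(x, labels, ga=g)


class TestCanonicalOrder:
    def test_feature_order_is_stable(self):
        # golden schema: the order feature CSVs rely on
        assert FEATURE_NAMES == CANONICAL

    def test_domain_partition(self):
        assert len(MORPH_FEATURE_NAMES) == 8
        assert len(TIME_FEATURE_NAMES) == 17
        assert len(FREQ_FEATURE_NAMES) == 10
        assert len(NONLINEAR_FEATURE_NAMES) == 12
        assert len(FEATURE_NAMES) == 47


class TestExtractAll:
    def test_exactly_47_features(self, clean_record):
        fv = extract_all(clean_record)
        assert list(fv.values) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_deterministic(self, clean_record):
        a = extract_all(clean_record)
        b = extract_all(clean_record)
        assert a.values == b.values

    def test_constant_record_flagged_not_nan(self):
        from fhrkit import FHRRecord

        fv = extract_all(FHRRecord("const", np.full(4800, 140.0)))
        assert all(np.isfinite(v) for v in fv.values.values())
        assert fv.flags  # degenerate cases surfaced as flags

    def test_vector_schema_enforced(self):
        with pytest.raises(ValueError, match="canonical"):
            FeatureVector("x", {"meanBL": 1.0})
        vals = {k: 0.0 for k in FEATURE_NAMES}
        vals["SDNN"] = float("nan")
        with pytest.raises(ValueError, match="non-finite"):
            FeatureVector("x", vals)


class TestNormalization:
    def test_ga_trend_removed(self):
        rng = np.random.default_rng(0)
        n = 200
        ga = rng.uniform(37, 43, n)
        x = rng.standard_normal((n, 47))
        x[:, 0] = 2.0 * ga + rng.standard_normal(n) * 0.5
        mat = _matrix(x, ["normal"] * n, ga=ga)
        out = ga_normalize(mat)
        r = np.corrcoef(out.values.iloc[:, 0], ga)[0, 1]
        assert abs(r) < 0.1

    def test_constant_ga_reduces_to_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 47))
        mat = _matrix(x, ["normal"] * 20, ga=np.full(20, 40.0))
        out = ga_normalize(mat)
        np.testing.assert_allclose(out.values.to_numpy(), x, atol=1e-12)

    def test_heldout_rows_use_train_coefficients(self):
        rng = np.random.default_rng(2)
        train = _random_matrix(rng, 30, 30, ga=True)
        test = _random_matrix(rng, 5, 5, ga=True)
        out = ga_normalize(train, test)
        # manual recomputation for one feature
        j = 3
        ga, v = train.ga, train.values.iloc[:, j].to_numpy()
        b = np.polyfit(ga, v, 1)
        pred = np.polyval(b, test.ga)
        expect = test.values.iloc[:, j].to_numpy() - pred + v.mean()
        np.testing.assert_allclose(out.values.iloc[:, j].to_numpy(), expect,
                                   atol=1e-9)

    def test_minmax_maps_train_to_unit_interval(self):
        rng = np.random.default_rng(3)
        mat = _random_matrix(rng, 20, 20)
        out = minmax_normalize(mat)
        v = out.values.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_minmax_heldout_not_clipped(self):
        x = np.zeros((2, 47))
        x[1, :] = 10.0
        train = _matrix(x, ["normal", "pathological"])
        y = np.full((1, 47), 20.0)
        test = _matrix(y, ["normal"], ids=["h"])
        out = minmax_normalize(train, test)
        np.testing.assert_allclose(out.values.to_numpy(), 2.0)

    def test_minmax_zero_range_column(self):
        x = np.ones((5, 47))
        mat = _matrix(x, ["normal"] * 3 + ["pathological"] * 2)
        out = minmax_normalize(mat)
        np.testing.assert_allclose(out.values.to_numpy(), 0.0)


class TestSelectST:
    def test_separated_classes_selected(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((40, 47))
        x[:20, 0] += 100.0  # non-overlapping on feature 0
        mat = _matrix(x, ["normal"] * 20 + ["pathological"] * 20)
        sel = select_st(mat)
        assert FEATURE_NAMES[0] in sel.selected
        assert sel.scores[FEATURE_NAMES[0]] < 0.001

    def test_identical_distributions_not_selected(self):
        x = np.tile(np.arange(10.0)[:, None], (2, 47))
        mat = _matrix(x, ["normal"] * 10 + ["pathological"] * 10)
        sel = select_st(mat)
        assert sel.scores[FEATURE_NAMES[5]] > 0.9
        assert FEATURE_NAMES[5] not in sel.selected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_sample_p_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((10, 47))
        mat = _matrix(x, ["normal"] * 5 + ["pathological"] * 5)
        sel = select_st(mat)
        for j in (0, 10, 46):
            a = x[:5, j]
            b = x[5:, j]
            assert sel.scores[FEATURE_NAMES[j]] == pytest.approx(
                mannwhitney_exact_p(a, b), abs=1e-12
            )

    def test_one_class_missing_errors(self):
        x = np.zeros((4, 47))
        mat = _matrix(x, ["normal"] * 4)
        with pytest.raises(ValueError):
            select_st(mat)


class TestSelectAUC:
    def test_perfect_separation(self):
        x = np.zeros((4, 47))
        x[:, 0] = [1.0, 2.0, 3.0, 4.0]
        mat = _matrix(x, ["pathological", "pathological", "normal", "normal"])
        sel = select_auc(mat)
        assert sel.scores[FEATURE_NAMES[0]] == pytest.approx(1.0)

    def test_label_independent_feature_near_half(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((500, 47))
        mat = _matrix(x, ["normal"] * 250 + ["pathological"] * 250)
        sel = select_auc(mat)
        assert 0.45 <= sel.scores[FEATURE_NAMES[7]] <= 0.55

    def test_matches_sklearn_roc_auc(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal(60)
        labels = np.array(["normal"] * 25 + ["pathological"] * 35)
        rng.shuffle(labels)
        ours = feature_auc(vals, labels)
        ref = roc_auc_score((labels == "normal").astype(int), vals)
        assert ours == pytest.approx(max(ref, 1 - ref), abs=1e-9)

    def test_top_k(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((60, 47))
        x[:30, :3] += 3.0
        mat = _matrix(x, ["normal"] * 30 + ["pathological"] * 30)
        sel = select_auc(mat, top_k=3)
        assert set(sel.selected) == set(FEATURE_NAMES[:3])


class TestPCA:
    def test_two_factor_construction(self):
        rng = np.random.default_rng(8)
        n = 300
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        load = rng.standard_normal((2, 47))
        x = np.outer(f1, load[0]) + np.outer(f2, load[1])
        x += rng.standard_normal((n, 47)) * 1e-4
        mat = _matrix(x, ["normal"] * 150 + ["pathological"] * 150)
        sel = reduce_pca(mat, var_target=0.95)
        assert sel.n_components == 2

    def test_variance_conservation(self):
        rng = np.random.default_rng(9)
        mat = _random_matrix(rng, 40, 40)
        sel = reduce_pca(mat)
        pca = sel.transformer["pca"]
        z = (mat.values.to_numpy() - sel.transformer["mu"]) / sel.transformer["sd"]
        total = np.var(z, axis=0, ddof=1).sum()
        assert np.sum(pca.explained_variance_) == pytest.approx(total, rel=1e-9)

    def test_transformed_coordinates_centered(self):
        rng = np.random.default_rng(10)
        mat = _random_matrix(rng, 30, 30)
        sel = reduce_pca(mat)
        from fhrkit.features import apply_selection

        coords = apply_selection(mat, sel)
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        assert coords.shape[1] == sel.n_components <= 47

    def test_too_few_rows(self):
        mat = _matrix(np.zeros((1, 47)), ["normal"])
        with pytest.raises(ValueError):
            reduce_pca(mat)


def test_matrix_csv_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    mat = _random_matrix(rng, 5, 5, ga=True)
    path = tmp_path / "mat.csv"
    mat.to_csv(path)
    back = FeatureMatrix.from_csv(path)
    np.testing.assert_allclose(back.values.to_numpy(), mat.values.to_numpy())
    np.testing.assert_array_equal(back.labels, mat.labels)
    np.testing.assert_allclose(back.ga, mat.ga)


def test_selection_does_not_mutate_matrix():
    rng = np.random.default_rng(12)
    mat = _random_matrix(rng, 10, 10)
    before = mat.values.to_numpy().copy()
    select_st(mat)
    select_auc(mat)
    reduce_pca(mat)
    np.testing.assert_array_equal(mat.values.to_numpy(), before)
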