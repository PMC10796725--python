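"""Correlations, autoscaling and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endograin import stats_explore as SE


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestPairwisePearson:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [3.0, 5, 7, 9]})
        res = SE.pairwise_pearson(df, "x", "y")
        assert res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_pairwise_complete_deletion(self):
        df = pd.DataFrame({"x": [1.0, 2, np.nan, 4, 5], "y": [2.0, 4, 6, np.nan, 10]})
        res = SE.pairwise_pearson(df, "x", "y")
        assert res.n == 3

    def test_constant_column_undefined_not_a_number(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        res = SE.pairwise_pearson(df, "x", "y")
        assert res.r is None and not res.defined

    def test_too_few_pairs_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2], "y": [2.0, 1]})
        assert SE.pairwise_pearson(df, "x", "y").r is None

    @given(st.floats(min_value=0.1, max_value=10), st.floats(min_value=-5, max_value=5))
    @settings(max_examples=30, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 2, 4, 7, 11])
        y = np.array([2.0, 1, 5, 6, 9])
        df1 = pd.DataFrame({"x": x, "y": y})
        df2 = pd.DataFrame({"x": a * x + b, "y": y})
        assert SE.pairwise_pearson(df2, "x", "y").r == pytest.approx(
            SE.pairwise_pearson(df1, "x", "y").r
        )


class TestAutoscale:
    def test_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame(rng.normal(3, 7, (20, 4)), columns=list("abcd"))
        scaled, record = SE.autoscale(df)
        assert np.abs(scaled.mean()).max() < 1e-12
        assert np.allclose(scaled.std(ddof=1), 1.0)
        assert np.allclose(record.means, df.mean())

    def test_idempotent_on_standardized_data(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        once, _ = SE.autoscale(df)
        twice, _ = SE.autoscale(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_constant_column_rejected_by_name(self, rng):
        df = pd.DataFrame({"ok": rng.normal(size=6), "flat": np.ones(6)})
        with pytest.raises(ValueError, match="flat"):
            SE.autoscale(df)


class TestPca:
    def test_collinear_data_one_component(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        model = SE.pca(df, n_components=1)
        assert model.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_loadings_orthonormal(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 6)))
        L = SE.pca(df).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_reconstruction_and_correlation_eigendecomposition_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(18, 5)), columns=list("abcde"))
        model = SE.pca(df)
        scaled, _ = SE.autoscale(df)
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.abs(recon - scaled.to_numpy()).max() < 1e-8
        # independent oracle: eigendecomposition of the correlation matrix
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        expected_pct = 100 * evals / evals.sum()
        assert np.allclose(model.explained_variance_pct, expected_pct, atol=1e-8)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        model = SE.pca(df, n_components=2)
        scaled, _ = SE.autoscale(df)
        sk = SkPCA(n_components=2).fit(scaled.to_numpy())
        assert np.allclose(
            np.abs(model.loadings.to_numpy().T), np.abs(sk.components_), atol=1e-8
        )

    def test_explained_variance_sums_to_100_at_full_rank(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 4)))
        model = SE.pca(df)
        assert model.explained_variance_pct.sum() == pytest.approx(100.0)

    def test_sign_convention_largest_loading_positive(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 4)))
        L = SE.pca(df).loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_rows_with_missing_values_dropped_and_logged(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"),
                          index=[f"v{i}" for i in range(10)])
        df.loc["v3", "b"] = np.nan
        model = SE.pca(df, n_components=2)
        assert model.n_rows_dropped == 1 and model.dropped_rows == ["v3"]
        assert len(model.scores) == 9

    def test_more_components_than_rank_rejected(self, rng):
        x = rng.normal(size=8)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            SE.pca(df, n_components=2)


class TestCorrelationReport:
    def test_named_pairs_have_expected_subset_sizes(self, table3, table4):
        report = SE.correlation_report(table3, table4)
        by_pair = {(r.x, r.y, r.subset): r for r in report}
        assert by_pair[("area_um2", "porosity_pct", "area-bearing varieties, both panels")].n == 45
        assert by_pair[("fat_g", "gi_mean", "non-waxy GI panel")].n == 24
        assert by_pair[("ashes_g", "eccentricity", "GI panel")].n == 21
        assert by_pair[("ashes_g", "eccentricity", "GI panel without Valente")].n == 20

    def test_amylose_gi_correlation_negative_under_any_censor_policy(self):
        from endograin.tables import load_table3

        for policy in ("impute0", "impute2.5", "impute5", "exclude"):
            t3 = load_table3(censored_amylose=policy)
            res = SE.pairwise_pearson(t3, "amylose_pct", "gi_mean")
            assert res.r < 0
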