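import numpy as np
import pandas as pd
import pytest

import amidoqsar as aq
from amidoqsar.qsar import (
    GaConfig,
    concordance_ccc,
    exhaustive_best_subset,
    r_squared,
)
from amidoqsar.synthdata import LinearSimSpec, gen_linear_dataset


class TestLogTransform:
    @pytest.mark.parametrize("pct,expected", [(100, 2.0), (0.1, -1.0), (10, 1.0)])
    def test_values(self, pct, expected):
        assert aq.log_transform([pct])[0] == pytest.approx(expected)

    def test_nonpositive_warns_and_yields_nan(self):
        with pytest.warns(UserWarning, match="non-positive"):
            out = aq.log_transform([10.0, 0.0, -3.0])
        assert np.isnan(out[1]) and np.isnan(out[2]) and out[0] == 1.0


class TestPruneDescriptors:
    def test_constant_and_zero_columns_removed(self, rng):
        X = pd.DataFrame(
            {
                "ok": rng.normal(size=20),
                "const": np.r_[np.full(19, 7.0), 8.0],
                "zero": np.zeros(20),
            }
        )
        kept, removed = aq.prune_descriptors(X)
        assert list(kept.columns) == ["ok"]
        rules = dict(removed)
        assert rules["zero"] == "zero"
        assert rules["const"] == "constant"

    def test_duplicated_column_drops_the_later_one(self, rng):
        a = rng.normal(size=15)
        X = pd.DataFrame({"first": a, "second": a.copy()})
        kept, removed = aq.prune_descriptors(X)
        assert list(kept.columns) == ["first"]
        assert removed[0][0] == "second" and "correlated" in removed[0][1]

    def test_planted_near_duplicates(self, rng):
        n = 60
        base = rng.normal(size=(n, 15))
        cols = {f"x{k}": base[:, k] for k in range(15)}
        # five near-duplicates (r ~ 0.98) of the first five columns
        for k in range(5):
            cols[f"dup{k}"] = base[:, k] + 0.15 * rng.normal(size=n)
        X = pd.DataFrame(cols)
        kept, removed = aq.prune_descriptors(X)
        assert len(kept.columns) == 15
        assert {c for c, _ in removed} == {f"dup{k}" for k in range(5)}

    def test_everything_removed_raises(self):
        X = pd.DataFrame({"z": np.zeros(5)})
        with pytest.raises(ValueError, match="all descriptor columns"):
            aq.prune_descriptors(X)


class TestActivityRankedSplit:
    def test_study_size_gives_29_7(self, rng):
        y = rng.normal(size=36)
        split = aq.activity_ranked_split(y, seed=3)
        assert (split == "test").sum() == 7
        assert (split == "train").sum() == 29

    def test_ten_rows_one_per_bin(self, rng):
        y = rng.normal(size=10)
        split = aq.activity_ranked_split(y, seed=0)
        assert (split == "test").sum() == 5

    def test_each_bin_contributes(self, rng):
        y = np.arange(36, dtype=float)
        split = aq.activity_ranked_split(y, seed=9)
        test_idx = np.flatnonzero((split == "test").to_numpy())
        # ranked bins of ~7: every fifth of the activity range is sampled
        bins = np.array_split(np.argsort(y, kind="stable"), 5)
        for b in bins:
            assert 1 <= len(set(b) & set(test_idx)) <= 2

    def test_deterministic_for_fixed_seed(self, rng):
        y = rng.normal(size=36)
        s1 = aq.activity_ranked_split(y, seed=42)
        s2 = aq.activity_ranked_split(y, seed=42)
        assert (s1 == s2).all()

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            aq.activity_ranked_split(np.arange(4.0))


class TestFitMlr:
    def test_exact_line(self):
        x = np.arange(10.0)[:, None]
        model = aq.fit_mlr(x, 2.0 * x.ravel())
        assert model.intercept == pytest.approx(0.0, abs=1e-10)
        assert model.coefficients["x0"] == pytest.approx(2.0, abs=1e-10)
        assert model.p_prime == 2

    def test_noiseless_recovery(self):
        ds = gen_linear_dataset(LinearSimSpec(sigma=0.0, seed=2))
        model = aq.fit_mlr(ds.X, ds.y)
        expected = dict(zip(ds.X.columns, (0.06, 1.25, 3.81, -0.94)))
        assert model.intercept == pytest.approx(-3.90, abs=1e-9)
        for name, b in expected.items():
            assert model.coefficients[name] == pytest.approx(b, abs=1e-9)

    def test_rank_deficiency_reported(self, rng):
        a = rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            aq.fit_mlr(X, rng.normal(size=20))

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError, match="more training rows"):
            aq.fit_mlr(rng.normal(size=(4, 4)), rng.normal(size=4))


class TestQ2Loo:
    def test_noiseless_is_one(self):
        ds = gen_linear_dataset(LinearSimSpec(sigma=0.0, seed=5))
        assert aq.q2_loo(ds.X, ds.y) == pytest.approx(1.0, abs=1e-9)

    def test_hat_identity_matches_explicit_refits(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        press = 0.0
        for i in range(15):
            mask = np.ones(15, bool)
            mask[i] = False
            A = np.column_stack([np.ones(14), X[mask]])
            beta, *_ = np.linalg.lstsq(A, y[mask], rcond=None)
            press += (y[i] - np.r_[1.0, X[i]] @ beta) ** 2
        oracle = 1.0 - press / np.sum((y - y.mean()) ** 2)
        assert aq.q2_loo(X, y) == pytest.approx(oracle, abs=1e-10)

    def test_pure_noise_is_nonpositive_usually(self):
        # fitting 4 descriptors to pure noise yields Q2 > 0 by chance about
        # 5 % of the time (rate measured at 0.945 over 1000 replicates)
        neg = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            q2 = aq.q2_loo(r.normal(size=(29, 4)), r.normal(size=29))
            neg += q2 <= 0
        assert neg >= 0.90 * 200


class TestQ2Lmo:
    def test_noiseless_is_one(self):
        ds = gen_linear_dataset(LinearSimSpec(sigma=0.0, seed=8))
        assert aq.q2_lmo(ds.X, ds.y, iterations=50, seed=1) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_single_row_exclusion_equals_loo(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(scale=0.3, size=20)
        assert aq.q2_lmo(X, y, leave_fraction=1 / 20) == pytest.approx(
            aq.q2_loo(X, y), abs=1e-12
        )

    def test_stable_across_seeds_at_1000_iterations(self):
        ds = gen_linear_dataset(LinearSimSpec(n=40, sigma=0.3, seed=17))
        vals = [
            aq.q2_lmo(ds.X, ds.y, iterations=1000, seed=s) for s in range(3)
        ]
        assert np.ptp(vals) < 0.01


class TestYScramble:
    def test_identity_permutation_is_degenerate_control(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(scale=0.2, size=20)
        r2, q2 = aq.y_scramble(X, y, permutations=[np.arange(20)])
        assert r2 == pytest.approx(r_squared(X, y), abs=1e-10)
        assert q2 == pytest.approx(aq.q2_loo(X, y), abs=1e-10)

    def test_null_means_match_classical_expectations(self, rng):
        # refitted scrambled R2 has expectation p/(n-1) under the null
        X = rng.normal(size=(29, 4))
        y = rng.normal(size=29)
        r2m, q2m = aq.y_scramble(X, y, n_scrambles=600, seed=0)
        assert r2m == pytest.approx(4 / 28, abs=0.03)
        assert q2m < 0.02
        corr, _ = aq.y_scramble(X, y, n_scrambles=600, seed=0, statistic="correlation")
        assert corr == pytest.approx(1 / 28, abs=0.02)


class TestExternalStats:
    def test_perfect_predictions(self):
        stats = aq.external_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.5, 2.5])
        for k in ("Q2_F1", "Q2_F2", "Q2_F3", "CCC_ext"):
            assert stats[k] == pytest.approx(1.0)
        assert stats["RMSE_ext"] == 0.0 and stats["MAE_ext"] == 0.0

    def test_constant_bias(self, rng):
        y = rng.normal(size=12)
        stats = aq.external_stats(y, y + 0.4, rng.normal(size=20))
        assert stats["MAE_ext"] == pytest.approx(0.4)
        assert stats["CCC_ext"] < 1.0
        assert stats["R2_ext"] == pytest.approx(1.0)

    def test_hand_example_q2f1(self):
        # y_train mean 1, test y=(0,1,2), preds (0,1,1): Q2F1 = 1 - 1/2
        stats = aq.external_stats([0, 1, 2], [0, 1, 1], [0, 1, 2])
        assert stats["Q2_F1"] == pytest.approx(0.5)

    def test_ccc_needs_two_points(self):
        with pytest.raises(ValueError):
            concordance_ccc([1.0], [1.0])


class TestKIndices:
    def test_orthogonal_columns_give_zero(self):
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        assert aq.k_index(X) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_columns_give_one(self, rng):
        a = rng.normal(size=30)
        assert aq.k_index(np.column_stack([a, 3 * a])) == pytest.approx(1.0)

    def test_delta_k_positive_for_planted_response(self):
        ds = gen_linear_dataset(LinearSimSpec(sigma=0.0, seed=3))
        kxx, dk = aq.kxx_delta_k(ds.X, ds.y)
        assert 0 <= kxx <= 1
        assert dk > 0

    def test_zero_variance_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            aq.k_index(np.column_stack([np.ones(5), np.arange(5.0)]))


class TestGaSelect:
    def make_pool(self, p, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:4] = (1.5, -2.0, 1.0, 0.8)
        y = X @ beta + rng.normal(scale=0.2, size=n)
        return X, y

    def test_small_pool_uses_exhaustive_scan(self):
        X, y = self.make_pool(12)
        ranked = aq.ga_select(X, y, GaConfig(k=4, seed=0))
        oracle = exhaustive_best_subset(X, y, 4)
        assert ranked[0] == oracle[0]
        assert ranked[0][0] == (0, 1, 2, 3)

    def test_ga_finds_planted_subset_in_large_pool(self):
        X, y = self.make_pool(20, seed=1)
        cfg = GaConfig(population=50, generations=60, k=4, seed=7)
        ranked = aq.ga_select(X, y, cfg)
        oracle = exhaustive_best_subset(X, y, 4)
        assert ranked[0][0] == oracle[0][0] == (0, 1, 2, 3)
        assert ranked[0][1] == pytest.approx(oracle[0][1], abs=1e-12)

    def test_k1_matches_single_descriptor_scan(self):
        X, y = self.make_pool(10, seed=2)
        ranked = aq.ga_select(X, y, GaConfig(k=1, seed=0))
        assert ranked[0] == exhaustive_best_subset(X, y, 1)[0]

    def test_deterministic_from_seed(self):
        X, y = self.make_pool(20, seed=3)
        cfg = GaConfig(population=30, generations=25, k=4, seed=11)
        assert aq.ga_select(X, y, cfg) == aq.ga_select(X, y, cfg)

    def test_pool_smaller_than_k_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller than model size"):
            aq.ga_select(rng.normal(size=(10, 3)), rng.normal(size=10), GaConfig(k=4))


class TestApplicabilityDomain:
    def test_warning_leverage_of_study_model(self, study_dataset, study_model):
        model, _ = study_model
        ad = aq.applicability_domain(model, study_dataset)
        assert round(ad.h_star, 3) == 0.517  # 3 * 5 / 29

    def test_leverages_sum_to_p_prime(self, study_dataset, study_model):
        model, _ = study_model
        ad = aq.applicability_domain(model, study_dataset)
        assert ad.leverages[ad.is_training].sum() == pytest.approx(5.0)

    def test_centroid_row_has_leverage_one_over_n(self, rng):
        X = rng.normal(size=(21, 3))
        # a row equal to the mean of the others is the centroid of the whole
        X[-1] = X[:-1].mean(axis=0)
        y = rng.normal(size=21)
        ids = [f"r{i}" for i in range(21)]
        model = aq.fit_mlr(pd.DataFrame(X, index=ids, columns=list("abc")), y, ids=ids)
        ds = aq.QsarDataset(
            ids=ids,
            X=model.training_X,
            y=pd.Series(y, index=ids),
        )
        ad = aq.applicability_domain(model, ds)
        assert ad.leverages[-1] == pytest.approx(1 / 21, abs=1e-9)

    def test_study_outlier_structure(self, study_dataset, study_model):
        # the cyano/tetrahydropyrimidine compound c5 is the unique response
        # outlier; no compound exceeds the warning leverage
        model, _ = study_model
        ad = aq.applicability_domain(model, study_dataset)
        flagged = [i for i, o in zip(ad.ids, ad.outlier) if o]
        assert flagged == ["c5"]
        assert not ad.outside_domain.any()

    def test_williams_plot_renders(self, tmp_path, study_dataset, study_model):
        model, _ = study_model
        ad = aq.applicability_domain(model, study_dataset)
        out = tmp_path / "williams.png"
        ad.williams_plot(out)
        assert out.exists() and out.stat().st_size > 0

    def test_report_frame_shape(self, study_dataset, study_model):
        model, _ = study_model
        df = aq.applicability_domain(model, study_dataset).to_frame()
        assert len(df) == 36
        assert set(df.columns) == {
            "leverage", "std_cv_residual", "training", "outlier", "outside_domain",
        }


class TestValidateModel:
    def test_noiseless_pipeline_is_perfect(self):
        ds = gen_linear_dataset(LinearSimSpec(n=40, sigma=0.0, seed=6))
        split = aq.activity_ranked_split(ds.y, seed=2)
        ds = aq.QsarDataset(ids=ds.ids, X=ds.X, y=ds.y, split=split)
        model, rep = aq.validate_model(ds, lmo_iterations=50, n_scrambles=50)
        assert rep.R2 == pytest.approx(1.0, abs=1e-9)
        assert rep.Q2_LOO == pytest.approx(1.0, abs=1e-9)
        assert rep.Q2_F1 == pytest.approx(1.0, abs=1e-9)
        assert rep.CCC_ext == pytest.approx(1.0, abs=1e-9)
        assert rep.RMSE_ext == pytest.approx(0.0, abs=1e-9)

    def test_study_pipeline_runs_and_reports_all_statistics(self, study_model):
        _, rep = study_model
        d = rep.as_dict()
        assert set(d) == {
            "R2", "R2_adj", "Q2_LOO", "Q2_LMO", "R2_Yscr", "Q2_Yscr",
            "Q2_F1", "Q2_F2", "Q2_F3", "CCC_ext", "RMSE_ext", "MAE_ext",
            "R2_ext", "Kxx", "delta_K",
        }
        assert 0 <= rep.R2 <= 1
        assert rep.Q2_LOO <= 1 and rep.Q2_LMO <= 1
        assert rep.Q2_Yscr < rep.Q2_LOO
        assert rep.RMSE_ext >= 0 and rep.MAE_ext >= 0
        assert -1 <= rep.CCC_ext <= 1
        assert 0 <= rep.Kxx <= 1
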