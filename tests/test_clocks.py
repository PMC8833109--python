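"""Clock construction: splits, elastic net, stability, PC and mega clocks."""

import numpy as np
import pandas as pd
import pytest

from omiclocks import (DataError, OmicsMatrix, build_mega_matrix,
                       clock_age_table, compute_ocaa, pc_clock, predict_age,
                       qc_pipeline, simulate_cohort, split_cohort,
                       train_clock)
from omiclocks.clocks import ClockModel
from tests.conftest import one_assay_config


def _noise_matrix(rng, n=600, p=40, name="noise"):
    ids = pd.Index([f"I{i:04d}" for i in range(n)], name="individual_id")
    data = pd.DataFrame(rng.normal(size=(n, p)), index=ids,
                        columns=[f"f{j}" for j in range(p)])
    return OmicsMatrix(name, data), pd.Series(
        rng.uniform(16, 100, n), index=ids, name="chron_age")


class TestSplit:
    def test_test_fraction_size(self):
        ids = [f"I{i}" for i in range(1000)]
        train, test = split_cohort(ids, fraction=0.75, seed=1)
        assert len(test) == 250 and len(train) == 750
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(ids)

    def test_preference_saturates_with_enough_complete(self):
        ids = [f"I{i}" for i in range(1000)]
        complete = ids[:300]
        _, test = split_cohort(ids, complete_ids=complete, seed=3)
        assert set(test) <= set(complete)

    def test_same_seed_same_split(self):
        ids = [f"I{i}" for i in range(100)]
        assert split_cohort(ids, seed=9) == split_cohort(ids, seed=9)

    def test_bad_fraction_rejected(self):
        from omiclocks import ConfigError
        with pytest.raises(ConfigError):
            split_cohort(["a", "b"], fraction=1.5)


class TestTrainClock:
    def test_perfect_predictor_survives_penalisation(self, rng):
        matrix, age = _noise_matrix(rng, n=600, p=30)
        data = matrix.data.copy()
        data["oracle"] = (age - age.mean()) / age.std(ddof=1)
        matrix = OmicsMatrix("perfect", data)
        tr, te = split_cohort(matrix.individual_ids, seed=5)
        model = train_clock(matrix, age, tr, te, n_lambdas=40, seed=5)
        assert model.test_r > 0.99
        assert "oracle" in model.coefficients

    def test_pure_noise_clock_has_no_skill(self, rng):
        import warnings
        matrix, age = _noise_matrix(rng, n=1000, p=40)
        tr, te = split_cohort(matrix.individual_ids, seed=6)
        with warnings.catch_warnings():  # may shrink everything to zero
            warnings.simplefilter("ignore")
            model = train_clock(matrix, age, tr, te, n_lambdas=30, seed=6)
        assert model.test_r is None or np.isnan(model.test_r) \
            or abs(model.test_r) < 0.15

    def test_informative_assay_reaches_high_accuracy(self, full_clock):
        assert full_clock.test_r > 0.85
        assert 0 < full_clock.n_selected

    def test_too_few_complete_rows_raises(self, rng):
        matrix, age = _noise_matrix(rng, n=30, p=5)
        with pytest.raises(DataError, match="complete training rows"):
            train_clock(matrix, age, list(matrix.individual_ids[:12]),
                        folds=10)

    def test_json_round_trip(self, full_clock, tmp_path):
        p = tmp_path / "clock.json"
        full_clock.to_json(p)
        back = ClockModel.from_json(p)
        assert back.coefficients == full_clock.coefficients
        assert back.lambda_ == full_clock.lambda_


class TestPredict:
    def test_training_prediction_reproduces_stored_r(self, informative_assay,
                                                     full_clock):
        matrix, chron_age, _, _ = informative_assay
        oca = predict_age(full_clock, matrix.subset(full_clock.train_ids))
        both = pd.concat([oca, chron_age], axis=1, join="inner").dropna()
        r = np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1]
        assert r == pytest.approx(full_clock.train_r, abs=1e-9)

    def test_row_permutation_equivariance(self, informative_assay, full_clock):
        matrix, _, _, _ = informative_assay
        sub = matrix.subset(matrix.complete_ids()[:50])
        perm = sub.data.sample(frac=1, random_state=0)
        oca = predict_age(full_clock, sub)
        oca_perm = predict_age(full_clock, OmicsMatrix(sub.assay_name, perm))
        assert np.allclose(oca.loc[perm.index], oca_perm)

    def test_missing_feature_gives_missing_oca(self, informative_assay,
                                               full_clock):
        matrix, _, _, _ = informative_assay
        data = matrix.data.copy()
        feat = next(iter(full_clock.coefficients))
        data.iloc[0, data.columns.get_loc(feat)] = np.nan
        oca = predict_age(full_clock, OmicsMatrix(matrix.assay_name, data))
        assert np.isnan(oca.iloc[0]) and oca.notna().sum() > 0

    def test_absent_model_feature_raises_by_name(self, informative_assay,
                                                 full_clock):
        matrix, _, _, _ = informative_assay
        feat = next(iter(full_clock.coefficients))
        smaller = OmicsMatrix(matrix.assay_name,
                              matrix.data.drop(columns=feat))
        with pytest.raises(DataError, match=feat):
            predict_age(full_clock, smaller)

    def test_ocaa_definition_and_unbiasedness(self, informative_assay,
                                              full_clock):
        matrix, chron_age, _, (_, test_ids) = informative_assay
        oca = predict_age(full_clock, matrix.subset(test_ids))
        ocaa = compute_ocaa(oca, chron_age)
        assert np.allclose(ocaa.dropna(),
                           (oca - chron_age.loc[oca.index]).dropna())
        se = ocaa.std() / np.sqrt(ocaa.notna().sum())
        assert abs(ocaa.mean()) < 3 * se

    def test_clock_age_table_standardisation(self, informative_assay,
                                             full_clock):
        matrix, chron_age, _, (_, test_ids) = informative_assay
        oca = predict_age(full_clock, matrix)
        tab = clock_age_table("c", oca, chron_age, eval_ids=test_ids)
        z = tab.loc[tab.index.intersection(pd.Index(test_ids)),
                    "ocaa_std"].dropna()
        assert abs(z.mean()) < 1e-9 and z.std(ddof=1) == pytest.approx(1.0)


class TestStabilitySelection:
    def test_core_features_stable_and_core_clock_close_to_full(
            self, stability_core, full_clock):
        result, core = stability_core
        assert result.core_features
        assert all(result.selection_frequency[f] > result.threshold
                   for f in result.core_features)
        assert len(core.coefficients) <= len(result.core_features)
        assert abs(core.test_r - full_clock.test_r) < 0.05

    def test_perfect_predictor_always_selected(self, rng):
        matrix, age = _noise_matrix(rng, n=300, p=10)
        data = matrix.data.copy()
        data["oracle"] = (age - age.mean()) / age.std(ddof=1)
        matrix = OmicsMatrix("perfect", data)
        from omiclocks import stability_select
        result, core = stability_select(matrix, age, iterations=20,
                                        n_lambdas=20, seed=8)
        assert result.selection_frequency["oracle"] == 1.0
        assert "oracle" in core.coefficients

    def test_pure_noise_yields_no_core_features(self, rng):
        matrix, age = _noise_matrix(rng, n=400, p=60)
        from omiclocks import stability_select
        with pytest.raises(DataError, match="lowering the threshold"):
            with pytest.warns(UserWarning):
                stability_select(matrix, age, iterations=25, n_lambdas=20,
                                 seed=9)


class TestMegaMatrix:
    def test_merge_on_intersection_with_prefixes(self, rng):
        a, age = _noise_matrix(rng, n=100, p=4, name="alpha")
        b, _ = _noise_matrix(rng, n=100, p=3, name="beta")
        b = OmicsMatrix("beta", b.data.iloc[20:])
        mega = build_mega_matrix([a, b])
        assert mega.n_individuals == 80 and mega.n_features == 7
        assert all(":" in c for c in mega.feature_ids)

    def test_single_assay_merge_is_identity_up_to_prefix(self, rng):
        a, _ = _noise_matrix(rng, n=50, p=4, name="solo")
        mega = build_mega_matrix([a])
        assert np.allclose(mega.data.to_numpy(), a.data.to_numpy())

    def test_duplicate_prefixed_ids_rejected(self, rng):
        a, _ = _noise_matrix(rng, n=40, p=3, name="dup")
        with pytest.raises(DataError, match="duplicate"):
            build_mega_matrix([a, a])

    def test_selection_shares_sum_to_one(self, rng):
        from omiclocks import mega_selection_shares
        a, age = _noise_matrix(rng, n=500, p=10, name="alpha")
        da = a.data.copy()
        da["sig"] = (age - age.mean()) / age.std(ddof=1) \
            + rng.normal(0, 0.3, 500)
        b, _ = _noise_matrix(rng, n=500, p=10, name="beta")
        db = b.data.copy()
        db["sig"] = (age - age.mean()) / age.std(ddof=1) \
            + rng.normal(0, 0.3, 500)
        mega = build_mega_matrix([OmicsMatrix("alpha", da),
                                  OmicsMatrix("beta", db)])
        tr, te = split_cohort(mega.individual_ids, seed=4)
        model = train_clock(mega, age, tr, te, n_lambdas=30, seed=4)
        shares = mega_selection_shares(model)
        assert set(shares) <= {"alpha", "beta"}
        assert sum(shares.values()) == pytest.approx(1.0)


class TestPcClocks:
    def test_full_rank_pc_clock_matches_full_clock(self, informative_assay,
                                                   full_clock):
        matrix, chron_age, _, split = informative_assay
        complete = matrix.subset(matrix.complete_ids())
        k = min(len(split[0]) - 1, complete.n_features)
        model = pc_clock(complete, k, chron_age, split, seed=41,
                         n_lambdas=40)
        assert abs(model.test_r - full_clock.test_r) < 0.02

    def test_age_dominated_first_pcs_suffice(self, informative_assay,
                                             full_clock):
        matrix, chron_age, _, split = informative_assay
        model = pc_clock(matrix, 3, chron_age, split, seed=41, n_lambdas=40)
        assert abs(model.test_r - full_clock.test_r) < 0.1

    def test_single_pc_of_noise_has_no_skill(self, rng):
        matrix, age = _noise_matrix(rng, n=600, p=30)
        split = split_cohort(matrix.individual_ids, seed=12)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = pc_clock(matrix, 1, age, split, seed=12, n_lambdas=20)
        assert model.test_r is None or np.isnan(model.test_r) \
            or abs(model.test_r) < 0.15

    def test_components_beyond_rank_rejected(self, rng):
        matrix, age = _noise_matrix(rng, n=100, p=8)
        split = split_cohort(matrix.individual_ids, seed=2)
        with pytest.raises(DataError, match="rank"):
            pc_clock(matrix, 50, age, split)


class TestParameterRecovery:
    def test_ocaa_tracks_latent_acceleration_and_attenuates_with_noise(self):
        """corr(OCAA, delta) > 0 when features load on delta, and grows
        with the delta-loading/noise ratio over a weak-loading grid (at
        strong loadings the penalised fit partially cancels delta, so the
        attenuation regime is the informative one)."""
        grid = [0.0, 0.1, 0.3]
        mean_corr = []
        for g, scale in enumerate(grid):
            corrs = []
            for rep in range(8):
                cfg = one_assay_config(seed=300 + 10 * g + rep, n=400, p=30,
                                       age_scale=0.4, delta_scale=scale)
                study = simulate_cohort(cfg)
                matrix, _ = qc_pipeline(study.omics[0])
                tr, te = split_cohort(matrix.individual_ids,
                                      seed=300 + 10 * g + rep)
                model = train_clock(matrix, study.cohort["chron_age"], tr,
                                    te, n_lambdas=20, folds=5,
                                    seed=300 + 10 * g + rep)
                oca = predict_age(model, matrix.subset(te))
                ocaa = compute_ocaa(oca, study.cohort["chron_age"]).dropna()
                delta = study.truth.loc[ocaa.index, "delta"]
                corrs.append(np.corrcoef(ocaa, delta)[0, 1])
            mean_corr.append(np.mean(corrs))
        assert mean_corr[0] < mean_corr[1] < mean_corr[2]
        # positive tracking at every non-zero loading: one-sided t test
        from scipy import stats
        t, p = stats.ttest_1samp(corrs, 0, alternative="greater")
        assert p < 0.01
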