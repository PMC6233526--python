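"""Conformal core: splits, nonconformity, p-values, aggregation, persistence."""

import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import minimize

from targetprofiler.conformal import (
    ACPModel,
    ICPModel,
    SplitConfig,
    TrainConfig,
    _fit_linear_svm,
    fit_icp,
    load_model,
    nonconformity,
    pvalue,
    save_model,
    split_proper_calibration,
    train_acp,
)
from targetprofiler.dataset import DatasetRecord, TargetDataset


def make_dataset(n_a=100, n_n=100, n_assumed=50):
    records = (
        [DatasetRecord(f"CC(N){'C' * (i + 1)}", "A", False, f"A{i}") for i in range(n_a)]
        + [DatasetRecord(f"CC(F){'C' * (i + 1)}", "N", False, f"N{i}") for i in range(n_n)]
        + [DatasetRecord(f"CCO{'C' * (i + 1)}", "N", True, f"X{i}") for i in range(n_assumed)]
    )
    return TargetDataset("T1", records)


class TestSplit:
    def test_sizes_and_assumed_always_proper(self):
        ds = make_dataset(100, 100, 50)
        proper, calibration = split_proper_calibration(ds, SplitConfig(0.2, 10, seed=1), 0)
        assert sum(1 for r in calibration if r.activity == "A") == 20
        assert sum(1 for r in calibration if r.activity == "N") == 20
        assert not any(r.assumed_nonactive for r in calibration)
        assert sum(1 for r in proper if r.assumed_nonactive) == 50
        assert len(proper) + len(calibration) == len(ds.records)

    def test_different_icp_index_different_membership_same_sizes(self):
        ds = make_dataset(50, 50, 0)
        p0, c0 = split_proper_calibration(ds, SplitConfig(0.2, 10, seed=1), 0)
        p1, c1 = split_proper_calibration(ds, SplitConfig(0.2, 10, seed=1), 1)
        assert len(c0) == len(c1)
        assert {r.entry_id for r in c0} != {r.entry_id for r in c1}

    def test_half_fraction(self):
        ds = make_dataset(10, 10, 0)
        _, calibration = split_proper_calibration(ds, SplitConfig(0.5, 1, seed=1), 0)
        assert len(calibration) == 10

    def test_reproducible_under_seed(self):
        ds = make_dataset(30, 30, 5)
        a = split_proper_calibration(ds, SplitConfig(0.2, 10, seed=3), 4)
        b = split_proper_calibration(ds, SplitConfig(0.2, 10, seed=3), 4)
        assert a == b

    def test_tiny_class_is_fatal(self):
        ds = TargetDataset(
            "T1",
            [
                DatasetRecord("CC", "A", False, "A0"),
                DatasetRecord("CCC", "N", False, "N0"),
                DatasetRecord("CCCC", "N", False, "N1"),
            ],
        )
        with pytest.raises(ValueError, match="class A"):
            split_proper_calibration(ds, SplitConfig(0.2, 1, seed=0), 0)


class TestNonconformity:
    @pytest.mark.parametrize(
        "d,label,expected", [(3.0, "A", -3.0), (3.0, "N", 3.0), (0.0, "A", 0.0), (0.0, "N", 0.0)]
    )
    def test_sign_convention(self, d, label, expected):
        assert nonconformity(d, label) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            nonconformity(1.0, "B")


class TestPValue:
    def test_above_all_scores_gives_floor(self):
        calib = np.arange(10, dtype=float)
        assert pvalue(100.0, calib) == pytest.approx(1 / 11)

    def test_below_all_scores_gives_one(self):
        calib = np.arange(10, dtype=float)
        assert pvalue(-5.0, calib) == 1.0

    def test_tie_at_median_of_nine(self):
        # alpha equals the median of 9 scores: 5 scores are >= alpha
        calib = np.sort(np.arange(9, dtype=float))
        assert pvalue(4.0, calib) == pytest.approx(6 / 10)

    def test_matches_naive_count_on_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            calib = np.sort(rng.normal(size=rng.integers(1, 30)))
            alpha = rng.normal()
            naive = (np.sum(calib >= alpha) + 1) / (calib.size + 1)
            assert pvalue(alpha, calib) == pytest.approx(naive, abs=1e-15)

    def test_smoothed_is_bounded_by_unsmoothed_neighbourhood(self):
        rng = np.random.default_rng(13)
        calib = np.sort(rng.normal(size=50))
        alphas = rng.normal(size=100)
        p_hard = pvalue(alphas, calib)
        p_soft = pvalue(alphas, calib, smoothed=True, rng=np.random.default_rng(1))
        assert np.all(p_soft <= p_hard + 1e-12)
        assert np.all(p_soft > 0)

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            pvalue(0.0, np.array([]))


class TestFitICP:
    def test_separable_data_calibration_scores_conform(self):
        # classes at x=+1 and x=-1 in a 1-feature space
        proper = [DatasetRecord("C", "A", False, f"A{i}") for i in range(10)] + [
            DatasetRecord("O", "N", False, f"N{i}") for i in range(10)
        ]
        calibration = proper[:5] + proper[10:15]
        from targetprofiler.signatures import SignatureConfig, build_dictionary, featurize, parse_smiles

        config = TrainConfig(cost=10.0, heights=SignatureConfig({0}))
        dictionary = build_dictionary(
            [featurize(parse_smiles(r.smiles), config.heights) for r in proper]
        )
        icp = fit_icp(proper, calibration, config, dictionary)
        # true-class examples sit on the conforming side: negative nonconformity
        assert np.all(icp.calib_scores_A < 0)
        assert np.all(icp.calib_scores_N < 0)

    def test_determinism_across_identical_calls(self):
        ds = make_dataset(30, 30, 0)
        m1 = train_acp(ds, SplitConfig(0.2, 2, seed=5), TrainConfig(cost=1.0))
        m2 = train_acp(ds, SplitConfig(0.2, 2, seed=5), TrainConfig(cost=1.0))
        for a, b in zip(m1.icps, m2.icps):
            np.testing.assert_array_equal(a.weights, b.weights)
            np.testing.assert_array_equal(a.calib_scores_A, b.calib_scores_A)

    def test_weights_match_independent_primal_solver(self):
        # 2-feature hand dataset; oracle = direct minimization of the
        # L2-regularized hinge objective with scipy
        rng = np.random.default_rng(21)
        X = np.vstack(
            [rng.normal([2, 0.5], 0.4, size=(40, 2)), rng.normal([-2, -0.5], 0.4, size=(40, 2))]
        )
        y = np.array([1] * 40 + [0] * 40)
        cost = 1.0
        w_impl, b_impl = _fit_linear_svm(sparse.csr_matrix(X), y, cost, seed=0)

        ysign = np.where(y == 1, 1.0, -1.0)

        def objective(theta):
            w, b = theta[:2], theta[2]
            margins = ysign * (X @ w + b)
            return 0.5 * w @ w + cost * np.maximum(0.0, 1.0 - margins).sum()

        res = minimize(objective, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
        w_ref, b_ref = res.x[:2], res.x[2]
        assert np.allclose(w_impl, w_ref, atol=5e-2)
        assert abs(b_impl - b_ref) < 5e-2

    def test_single_class_proper_set_fatal(self):
        proper = [DatasetRecord("C", "A", False, f"A{i}") for i in range(5)]
        calibration = proper
        from targetprofiler.signatures import build_dictionary, featurize, parse_smiles

        dictionary = build_dictionary([featurize(parse_smiles("C"))])
        with pytest.raises(ValueError, match="single-class"):
            fit_icp(proper, calibration, TrainConfig(), dictionary)


class TestAggregation:
    def test_single_icp_aggregation_is_identity(self, small_dataset):
        model = train_acp(small_dataset, SplitConfig(0.2, 1, seed=2), TrainConfig())
        smiles = small_dataset.records[0].smiles
        X = model._features([smiles])
        p_a_icp, p_n_icp = model.icps[0].pvalues(X)
        result = model.predict(smiles)
        assert result.p_A == pytest.approx(p_a_icp[0])
        assert result.p_N == pytest.approx(p_n_icp[0])

    def test_mean_rule_on_hand_pvalues(self):
        # two ICPs yielding p_A = 0.2 and 0.4 must aggregate to 0.3
        d = ICPModel(
            weights=np.array([1.0]),
            intercept=0.0,
            calib_scores_A=np.array([-1.0, 0.0, 1.0, 2.0]),
            calib_scores_N=np.array([-1.0, 0.0, 1.0, 2.0]),
        )
        d2 = ICPModel(
            weights=np.array([1.0]),
            intercept=0.0,
            calib_scores_A=np.array([-3.0, -2.0, -1.0, 2.0]),
            calib_scores_N=np.array([-1.0, 0.0, 1.0, 2.0]),
        )
        X = sparse.csr_matrix(np.array([[1.5]]))
        p1 = pvalue(-1.5, d.calib_scores_A)
        p2 = pvalue(-1.5, d2.calib_scores_A)
        from targetprofiler.signatures import SignatureDictionary

        acp = ACPModel(
            icps=[d, d2],
            dictionary=SignatureDictionary(index={"h1:C": 0}, frozen=True),
            train_config=TrainConfig(),
            split_config=SplitConfig(n_icp=2),
        )
        p_a, _ = acp.predict_p_matrix(X)
        assert p_a[0] == pytest.approx((p1 + p2) / 2)

    def test_aggregate_within_min_max_of_icps(self, small_acp, small_test_triples):
        X = small_acp._features([s for s, _, _ in small_test_triples[:40]])
        per_icp = np.array([icp.pvalues(X)[0] for icp in small_acp.icps])
        agg, _ = small_acp.predict_p_matrix(X)
        assert np.all(agg >= per_icp.min(axis=0) - 1e-12)
        assert np.all(agg <= per_icp.max(axis=0) + 1e-12)


class TestPredictionSets:
    def test_nestedness_in_significance(self, small_acp, small_test_triples):
        results = small_acp.predict_many([s for s, _, _ in small_test_triples[:50]])
        grid = np.linspace(0.05, 0.95, 19)
        for r in results:
            sets = [r.prediction_set(e) for e in grid]
            for bigger_eps_set, smaller_eps_set in zip(sets[1:], sets):
                assert bigger_eps_set <= smaller_eps_set

    def test_confidence_definition(self, small_acp, small_test_triples):
        r = small_acp.predict(small_test_triples[0][0])
        assert r.confidence == pytest.approx(1.0 - min(r.p_A, r.p_N))


class TestPersistence:
    def test_round_trip_predictions_identical(self, small_acp, small_test_triples, tmp_path):
        path = tmp_path / "model.acp"
        save_model(small_acp, path)
        loaded = load_model(path)
        queries = [s for s, _, _ in small_test_triples[:20]]
        before = small_acp.predict_many(queries)
        after = loaded.predict_many(queries)
        assert [(r.p_A, r.p_N) for r in before] == [(r.p_A, r.p_N) for r in after]

    def test_manifest_lists_every_icp(self, small_acp, tmp_path):
        import json
        import zipfile

        path = tmp_path / "model.acp"
        save_model(small_acp, path)
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
        assert len(manifest["icp_files"]) == len(small_acp.icps) == manifest["n_icp"]

    def test_truncated_archive_fails_loudly(self, small_acp, tmp_path):
        path = tmp_path / "model.acp"
        save_model(small_acp, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="archive"):
            load_model(path)


def test_single_icp_per_class_validity_across_grid():
    """A single Mondrian ICP is class-conditionally valid at every significance
    level: error rate stays within the 3-sigma binomial band of epsilon."""
    import math

    from targetprofiler.experiments import validity_experiment

    preds = validity_experiment(seed=7, n_train_per_class=500, n_test_per_class=250, n_icp=1)
    n_calib = 100  # 0.2 of 500 per class
    for cls, p_true in (("A", preds.p_A), ("N", preds.p_N)):
        mask = preds.y.astype(str) == cls
        n_cls = int(mask.sum())
        for eps in np.arange(0.05, 0.951, 0.05):
            err = float((p_true[mask] <= eps).mean())
            # realized coverage given one calibration draw is Beta-distributed,
            # so the band carries both test and calibration sampling variance
            slack = 3 * math.sqrt(eps * (1 - eps) * (1 / n_cls + 1 / n_calib))
            assert err <= eps + slack, (cls, eps, err)


def test_assumed_nonactives_never_reach_any_calibration_set():
    """End-to-end: augmented records stay out of every ICP's calibration set."""
    ds = make_dataset(40, 40, 30)
    config = SplitConfig(0.25, 8, seed=17)
    assumed_ids = {r.entry_id for r in ds.records if r.assumed_nonactive}
    for i in range(config.n_icp):
        proper, calibration = split_proper_calibration(ds, config, i)
        assert not ({r.entry_id for r in calibration} & assumed_ids)
        assert assumed_ids <= {r.entry_id for r in proper}
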