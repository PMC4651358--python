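"""Basis functions, least squares, description length, selection, prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import swarmstate as ss
from swarmstate.rbf import (
    BasisFunction, RBFModel, augmented_problem, description_length,
    evaluate_basis, fit_weights, predict, predict_displacements, rms_error,
    select_model,
)
from swarmstate.tracks_io import Species
from swarmstate.vectors import InteractionRow, rotate_row

from conftest import make_regression_dataset

ROT = np.array([[0.0, -1.0], [1.0, 0.0]])


class TestEvaluateBasis:
    def test_gaussian_closed_forms(self):
        b = BasisFunction("gaussian", (0.0, 0.0), scale=2.0)
        assert evaluate_basis(b, np.array([0.0, 0.0])) == 1.0
        assert evaluate_basis(b, np.array([2.0, 0.0])) == pytest.approx(np.exp(-0.5))

    def test_wavelet_ricker_zero_crossing(self):
        b = BasisFunction("wavelet", (1.0, 1.0), scale=3.0)
        x = np.array([1.0 + 3.0, 1.0])
        assert evaluate_basis(b, x) == pytest.approx(0.0, abs=1e-15)
        assert evaluate_basis(b, np.array([1.0, 1.0])) == 1.0

    def test_tophat_sharpens_and_flattens(self):
        x = np.array([0.5, 0.0])
        sharp = BasisFunction("tophat", (0.0, 0.0), 1.0, shape_exponent=3.0)
        flat = BasisFunction("tophat", (0.0, 0.0), 1.0, shape_exponent=0.5)
        gauss_like = np.exp(-0.25)
        assert evaluate_basis(sharp, x) > gauss_like   # flatter top near centre
        assert evaluate_basis(flat, x) < gauss_like
        # beyond the scale the sharpened profile falls off faster
        far = np.array([1.5, 0.0])
        assert evaluate_basis(sharp, far) < evaluate_basis(flat, far)

    def test_dimension_mismatch(self):
        b = BasisFunction("gaussian", (0.0, 0.0, 0.0), 1.0)
        with pytest.raises(ValueError, match="dimension"):
            evaluate_basis(b, np.array([1.0, 2.0]))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            BasisFunction("box", (0.0,), 1.0)
        with pytest.raises(ValueError):
            BasisFunction("gaussian", (0.0,), -1.0)


class TestCandidateDictionary:
    def test_size_kinds_and_determinism(self, small_dataset):
        d1 = ss.candidate_dictionary(small_dataset, 3, seed=5)
        d2 = ss.candidate_dictionary(small_dataset, 3, seed=5)
        assert d1 == d2
        assert {b.kind for b in d1} == {"gaussian", "wavelet", "tophat"}

    def test_scales_positive_within_pairwise_range(self, small_dataset):
        dic = ss.candidate_dictionary(small_dataset, 24, seed=6)
        X, _, _ = augmented_problem(small_dataset)
        dmax = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1)).max()
        for b in dic:
            assert 0.0 < b.scale <= dmax

    def test_size_validation(self, small_dataset):
        with pytest.raises(ValueError):
            ss.candidate_dictionary(small_dataset, 0, seed=0)
        with pytest.raises(ValueError):
            ss.candidate_dictionary(small_dataset, 10, seed=0, max_size=5)


class TestFitWeights:
    def test_exactly_representable_target(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-5, 5, (60, 2))
        b1 = BasisFunction("gaussian", (0.0, 0.0), 2.0)
        y = 1.0 + 2.0 * evaluate_basis(b1, X)
        w, rss = fit_weights([b1], X, y)
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0, 2.0], atol=1e-10)
        assert rss <= 1e-16 * len(X)

    def test_empty_subset_is_ordinary_linear_regression(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-5, 5, (40, 3))
        y = rng.normal(size=40)
        w, rss = fit_weights([], X, y)
        A = np.column_stack([np.ones(40), X])
        w_ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(w, w_ols, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-10, 10, (50, 2))
        bases = [BasisFunction("gaussian", tuple(rng.uniform(-10, 10, 2)),
                               float(rng.uniform(2, 8))) for _ in range(3)]
        y = rng.normal(size=50)
        w, rss = fit_weights(bases, X, y)
        A = np.column_stack([np.ones(50), X] +
                            [evaluate_basis(b, X) for b in bases])
        w_ne = np.linalg.solve(A.T @ A, A.T @ y)
        rss_ne = float(np.sum((y - A @ w_ne) ** 2))
        np.testing.assert_allclose(w, w_ne, rtol=1e-8)
        assert rss == pytest.approx(rss_ne, rel=1e-8)

    def test_rank_deficiency_warns_not_fails(self):
        X = np.ones((20, 2))           # constant columns duplicate the intercept
        y = np.arange(20.0)
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_weights([], X, y)


class TestDescriptionLength:
    def test_parameter_increment_is_half_log_n(self):
        base = description_length(200, 10.0, 3)
        assert description_length(200, 10.0, 4) - base == pytest.approx(
            0.5 * np.log(200))
        assert description_length(200, 10.0, 4, penalty_multiplier=2.0) - \
            description_length(200, 10.0, 3, penalty_multiplier=2.0) == \
            pytest.approx(np.log(200))

    def test_halving_rss_drops_half_n_log_two(self):
        a = description_length(100, 8.0, 3)
        b = description_length(100, 4.0, 3)
        assert a - b == pytest.approx(50 * np.log(2))

    def test_unidentifiable_model_rejected(self):
        with pytest.raises(ValueError, match="identifiable"):
            description_length(5, 1.0, 5)

    def test_pure_noise_basis_rarely_selected(self):
        """Monte-Carlo selection consistency: between nested models whose
        extra basis fits only noise, the DL criterion picks the larger
        model in well under 10% of replicates."""
        larger = 0
        b_extra = BasisFunction("gaussian", (0.0, 0.0), 3.0)
        for rep in range(100):
            rng = np.random.default_rng(rep)
            X = rng.uniform(-5, 5, (80, 2))
            y = 0.5 * X[:, 0] + rng.normal(0, 1.0, 80)
            _, rss_small = fit_weights([], X, y)
            _, rss_big = fit_weights([b_extra], X, y)
            if description_length(80, rss_big, 4) < description_length(80, rss_small, 3):
                larger += 1
        assert larger < 10


class TestSelectModel:
    def test_affine_only_data_selects_no_bases(self):
        """Irrelevant dictionaries are rejected in >= 90% of replicates when
        the displacements come from a pure linear map."""
        empty = 0
        for rep in range(50):
            rng = np.random.default_rng(500 + rep)
            V = rng.uniform(-50, 50, (120, 2))
            A = np.array([[0.02, 0.01], [-0.01, 0.02]])   # commutes with ROT
            D = V @ A.T + rng.normal(0, 0.5, (120, 2))
            rows = [InteractionRow(target_id=f"r{i}", time=pd.Timestamp("2008-01-01"),
                                   v=V[i], w=np.zeros(0), y=D[i],
                                   position=np.zeros(2), m=1, n=0)
                    for i in range(120)]
            ds = ss.InteractionDataset(rows=rows, focal_species=Species.SHEEP,
                                       m=1, n=0)
            dic = [BasisFunction("gaussian", tuple(rng.uniform(-50, 50, 2)),
                                 float(rng.uniform(10, 30))) for _ in range(6)]
            model = select_model(ds, dic, max_size=6)
            empty += (len(model.bases) == 0)
        assert empty >= 45

    def test_single_true_basis_matches_exhaustive_search(self):
        ds, dic, true_idx = make_regression_dataset(seed=101, n_rows=200,
                                                    n_dict=12, noise=0.05)
        model = select_model(ds, dic, max_size=6)
        X, y, dim_v = augmented_problem(ds)
        best = np.inf
        for r in range(4):   # larger subsets only add cost at tiny noise
            for S in itertools.combinations(range(12), r):
                _, rss = fit_weights([dic[j] for j in S], X, y, dim_v=dim_v)
                best = min(best, description_length(len(X), rss, dim_v + len(S)))
        assert model.mdl_bits == pytest.approx(best, abs=1e-6)
        assert {dic.index(b) for b in model.bases} == set(true_idx)

    def test_greedy_rss_never_increases_during_forward_adds(self, small_dataset):
        dic = ss.candidate_dictionary(small_dataset, 30, seed=7)
        model = select_model(small_dataset, dic, max_size=10)
        adds = [t["rss"] for t in model.trace if t.get("op") in ("affine", "add")]
        assert all(b <= a + 1e-9 for a, b in zip(adds, adds[1:]))

    def test_max_size_validation(self, small_dataset):
        dic = ss.candidate_dictionary(small_dataset, 5, seed=8)
        with pytest.raises(ValueError):
            select_model(small_dataset, dic, max_size=0)
        with pytest.raises(ValueError):
            select_model(small_dataset, [], max_size=5)


def _null_model(m=1, n=1, n_cov=0):
    d = 2 * (m + n) + n_cov
    return RBFModel(focal_species=Species.SHEEP, m=m, n=n, covariate_spec=(),
                    dim_v=2 * (m + n), affine_weights=np.zeros(1 + d), bases=[],
                    basis_weights=np.zeros(0), training_n=0)


class TestPredict:
    def test_zero_surface_predicts_no_displacement(self, small_dataset):
        model = _null_model()
        row = small_dataset.rows[0]
        np.testing.assert_array_equal(predict(model, row), row.position)

    def test_rotation_equivariance_of_fitted_model(self, small_model, small_dataset):
        for row in small_dataset.rows[:50]:
            rot = rotate_row(row, "+90")
            lhs = predict(small_model, rot) - rot.position
            rhs = ROT @ (predict(small_model, row) - row.position)
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rotation_equivariance_property(self, small_model, seed):
        rng = np.random.default_rng(seed)
        row = InteractionRow(target_id="p", time=pd.Timestamp("2008-06-01"),
                             v=rng.uniform(-300, 300, 4), w=np.zeros(0),
                             y=rng.uniform(0, 100, 2),
                             position=rng.uniform(0, 1000, 2), m=1, n=1)
        rot = rotate_row(row, "+90")
        lhs = predict(small_model, rot) - rot.position
        rhs = ROT @ (predict(small_model, row) - row.position)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_known_map_displacements_recovered(self):
        """Fitted surface reproduces a contracting interaction map on
        held-out rows to within twice the dynamic noise level."""
        noise = 0.5
        tracks = ss.generate_from_known_map(lambda v: -0.1 * v, 30, 120,
                                            noise, seed=17, m=1)
        ds = ss.assemble_dataset(tracks, Species.SHEEP, m=1, n=0)
        half = len(ds) // 2
        train = ss.InteractionDataset(rows=ds.rows[:half],
                                      focal_species=Species.SHEEP, m=1, n=0)
        test = ss.InteractionDataset(rows=ds.rows[half:],
                                     focal_species=Species.SHEEP, m=1, n=0)
        dic = ss.candidate_dictionary(train, 30, seed=18)
        model = select_model(train, dic, max_size=10)
        pred = predict_displacements(model, test)
        truth = np.array([-0.1 * r.v for r in test.rows])
        assert np.sqrt(np.mean((pred - truth) ** 2)) < 2 * noise

    def test_mismatched_row_rejected(self, small_model):
        row = InteractionRow(target_id="q", time=pd.Timestamp("2008-01-01"),
                             v=np.zeros(2), w=np.zeros(0), y=np.zeros(2),
                             position=np.zeros(2), m=1, n=0)
        with pytest.raises(ValueError):
            predict(small_model, row)


class TestRMSError:
    def test_zero_on_noiseless_representable_data(self):
        ds, dic, _ = make_regression_dataset(seed=900, n_rows=150, noise=0.0)
        model = select_model(ds, dic, max_size=6)
        assert rms_error(model, ds) < 1e-6

    def test_zero_map_on_stationary_noisy_animals_gives_sigma_root_two(self):
        sigma = 5.0
        truth = ss.generate_from_known_map(lambda v: np.zeros(2), 20, 600,
                                           0.0, seed=19, m=1)
        obs = ss.observe(truth, ss.ObservationParams(noise_sigma_m=sigma), seed=20)
        ds = ss.assemble_dataset(obs, Species.SHEEP, m=1, n=0)
        model = _null_model(m=1, n=0)
        # observed hourly displacement is a difference of two independent
        # noise draws: per-coordinate variance 2 sigma^2
        assert rms_error(model, ds) == pytest.approx(sigma * np.sqrt(2), rel=0.03)

    def test_monthly_stratification_preserves_pooled_rss(self, small_model,
                                                         small_dataset):
        err = (small_dataset.displacements()
               - predict_displacements(small_model, small_dataset))
        pooled = float(np.sum(err**2))
        by_month = 0.0
        for month in {r.time.month for r in small_dataset.rows}:
            rows = [r for r in small_dataset.rows if r.time.month == month]
            sub = ss.InteractionDataset(rows=rows, focal_species=Species.SHEEP,
                                        m=1, n=1)
            by_month += rms_error(small_model, sub) ** 2 * 2 * len(sub)
        assert by_month == pytest.approx(pooled, rel=1e-10)

    def test_empty_dataset_rejected(self, small_model):
        with pytest.raises(ValueError):
            rms_error(small_model, ss.InteractionDataset(
                rows=[], focal_species=Species.SHEEP, m=1, n=1))


def test_model_json_roundtrip_exact(small_model, small_dataset, tmp_path):
    path = tmp_path / "model.json"
    small_model.save(path)
    back = RBFModel.load(path)
    assert back.bases == small_model.bases
    np.testing.assert_array_equal(back.affine_weights, small_model.affine_weights)
    np.testing.assert_array_equal(back.basis_weights, small_model.basis_weights)
    np.testing.assert_array_equal(
        predict_displacements(back, small_dataset),
        predict_displacements(small_model, small_dataset))
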