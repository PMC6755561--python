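"""Latent-factor model: SGD mechanics, adaptive negatives, fit behaviour."""

import numpy as np
import pytest

from cfscreen import data, factorization, synthetic
from cfscreen.data import BioactivityMatrix
from cfscreen.factorization import (
    FactorModel,
    extract_implicit_fingerprints,
    fit,
    init_factors,
    predict,
    rank_ligands,
    sample_adaptive_negative,
    sgd_step,
)


def complete_matrix(values, mode="binary"):
    values = np.asarray(values, dtype=float)
    T, L = values.shape
    rows, cols = np.indices((T, L))
    return BioactivityMatrix(
        np.array([f"t{i}" for i in range(T)], dtype=object),
        np.array([f"l{j}" for j in range(L)], dtype=object),
        rows.ravel(),
        cols.ravel(),
        values.ravel(),
        mode,
    )


class TestInit:
    def test_deterministic(self):
        a = init_factors(5, 7, 3, seed=42)
        b = init_factors(5, 7, 3, seed=42)
        assert np.array_equal(a.P, b.P) and np.array_equal(a.Q, b.Q)

    def test_scale(self):
        model = init_factors(200, 300, 25, seed=1)
        expected_sd = 0.1 / np.sqrt(25)
        assert np.concatenate([model.P.ravel(), model.Q.ravel()]).std() == pytest.approx(
            expected_sd, rel=0.05
        )

    @pytest.mark.parametrize("T, L, f", [(0, 5, 2), (5, 0, 2), (5, 5, 0)])
    def test_invalid_dimensions(self, T, L, f):
        with pytest.raises(ValueError):
            init_factors(T, L, f)


class TestPredict:
    def test_scalar_product(self):
        model = FactorModel(P=np.array([[2.0]]), Q=np.array([[3.0]]), n_factors=1)
        assert predict(model, 0, 0) == 6.0

    def test_zero_target_vector(self):
        model = init_factors(3, 4, 2, seed=0)
        model.P[1] = 0.0
        assert all(predict(model, 1, l) == 0.0 for l in range(4))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        model = init_factors(4, 6, 3, seed=2)
        for t in range(4):
            for l in range(6):
                expected = sum(model.P[t, j] * model.Q[j, l] for j in range(3))
                assert predict(model, t, l) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range(self):
        model = init_factors(3, 4, 2, seed=0)
        with pytest.raises(IndexError):
            predict(model, 3, 0)


class TestSgdStep:
    def test_zero_error_zero_reg_is_noop(self):
        model = FactorModel(P=np.array([[1.0, 2.0]]), Q=np.array([[0.5], [0.25]]),
                            n_factors=2, regularization=0.0, step_size=0.1)
        a = predict(model, 0, 0)
        P0, Q0 = model.P.copy(), model.Q.copy()
        sgd_step(model, 0, 0, a)
        assert np.array_equal(model.P, P0) and np.array_equal(model.Q, Q0)

    def test_uses_preupdate_values_of_both_vectors(self):
        model = FactorModel(P=np.array([[0.3, -0.2]]), Q=np.array([[0.7], [0.4]]),
                            n_factors=2, regularization=0.01, step_size=0.05)
        p, q = model.P[0].copy(), model.Q[:, 0].copy()
        e = 1.0 - p @ q
        expect_p = p + 0.05 * (e * q - 0.01 * p)
        expect_q = q + 0.05 * (e * p - 0.01 * q)
        sgd_step(model, 0, 0, 1.0)
        assert np.allclose(model.P[0], expect_p, atol=1e-15)
        assert np.allclose(model.Q[:, 0], expect_q, atol=1e-15)

    def test_repeated_steps_converge_to_label(self):
        model = FactorModel(P=np.array([[0.1]]), Q=np.array([[0.1]]),
                            n_factors=1, regularization=0.0, step_size=0.1)
        errors = []
        for _ in range(500):
            sgd_step(model, 0, 0, 1.0)
            errors.append(abs(1.0 - predict(model, 0, 0)))
        assert errors[-1] < 1e-6
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_pure_regularization_decay(self):
        model = FactorModel(P=np.array([[0.5]]), Q=np.array([[0.0]]),
                            n_factors=1, regularization=1.0, step_size=0.1)
        sgd_step(model, 0, 0, 0.0)  # prediction 0, label 0 -> only decay on p
        assert abs(model.P[0, 0]) < 0.5

    def test_divergence_detected(self):
        model = FactorModel(P=np.array([[1e200]]), Q=np.array([[1e200]]),
                            n_factors=1, regularization=0.0, step_size=10.0)
        with pytest.raises(factorization.DivergenceError):
            sgd_step(model, 0, 0, 0.0)


class TestAdaptiveNegative:
    def test_single_candidate(self):
        model = init_factors(2, 5, 2, seed=3)
        assert sample_adaptive_negative(model, 0, np.array([4])) == 4

    def test_all_zero_model_ties_to_lowest_index(self):
        model = init_factors(2, 6, 2, seed=3)
        model.P[:] = 0.0
        assert sample_adaptive_negative(model, 0, np.array([5, 3, 4])) == 3

    def test_argmax_matches_bruteforce(self):
        model = init_factors(3, 20, 4, seed=4)
        cands = np.array([17, 2, 9, 5, 11, 0, 19, 7, 3, 13])
        expected = max(sorted(cands), key=lambda l: predict(model, 1, l))
        assert sample_adaptive_negative(model, 1, cands) == expected

    def test_empty_candidates(self):
        model = init_factors(2, 5, 2, seed=3)
        with pytest.raises(ValueError, match="no negatives"):
            sample_adaptive_negative(model, 0, np.array([], dtype=int))


class TestFit:
    def test_zero_epochs_returns_init(self):
        m = complete_matrix([[1, 0], [0, 1]])
        model, trace = fit(m, n_factors=2, n_epochs=0, seed=5)
        ref = init_factors(2, 2, 2, seed=5)
        assert np.array_equal(model.P, ref.P) and np.array_equal(model.Q, ref.Q)
        assert len(trace) == 0

    def test_rank_one_exact_factorization(self):
        # complete noiseless rank-1 matrix: outer([1,2],[1,0.5,2])
        values = np.outer([1.0, 2.0], [1.0, 0.5, 2.0])
        m = complete_matrix(values)
        model, trace = fit(m, n_factors=1, regularization=0.0, step_size=0.05,
                           n_epochs=2000, negatives_per_positive=0, seed=6)
        assert trace["objective"].iloc[-1] < 1e-4

    def test_bit_reproducible(self, small_split):
        kwargs = dict(n_factors=4, n_epochs=8, seed=21)
        m1, t1 = fit(small_split.train, **kwargs)
        m2, t2 = fit(small_split.train, **kwargs)
        assert np.array_equal(m1.P, m2.P) and np.array_equal(m1.Q, m2.Q)
        assert t1.equals(t2)

    def test_objective_nonincreasing_at_small_step(self):
        cfg = synthetic.SimulationConfig(n_targets=15, n_ligands=40, true_rank=2,
                                         density=1.0, label_noise=0.0, seed=22)
        truth = synthetic.simulate_ground_truth(cfg)
        m = synthetic.simulate_assays(truth, cfg)
        _, trace = fit(m, n_factors=2, regularization=1e-3, step_size=1e-3,
                       n_epochs=60, negatives_per_positive=0, seed=22)
        assert (np.diff(trace["objective"]) <= 1e-9).all()

    def test_full_density_noiseless_high_training_accuracy(self):
        """A rank-matched fit separates most labels on noiseless complete data.

        Exact interpolation is impossible (the thresholded matrix is not
        itself low rank), but accuracy must end far above the 70% base rate.
        """
        cfg = synthetic.SimulationConfig(n_targets=20, n_ligands=60, true_rank=3,
                                         density=1.0, label_noise=0.0, seed=23)
        truth = synthetic.simulate_ground_truth(cfg)
        m = synthetic.simulate_assays(truth, cfg)
        model, _ = fit(m, n_factors=3, regularization=0.0, step_size=0.05,
                       n_epochs=1500, negatives_per_positive=0, seed=23)
        preds = factorization.predict_pairs(model, m.rows, m.cols)
        assert (((preds > 0.5) == (m.labels == 1)).mean()) > 0.85

    def test_trace_counts_adaptive_negatives(self, small_split):
        _, trace = fit(small_split.train, n_factors=3, n_epochs=2,
                       negatives_per_positive=1, seed=24)
        n_pos = int((small_split.train.labels == 1).sum())
        assert (trace["n_negatives"] == n_pos).all()

    def test_early_stop_truncates_trace(self):
        values = np.outer([1.0, 1.0], [1.0, 1.0])
        m = complete_matrix(values)
        _, trace = fit(m, n_factors=1, regularization=0.0, step_size=0.2,
                       n_epochs=5000, negatives_per_positive=0, seed=25,
                       early_stop_tol=1e-5)
        assert len(trace) < 5000


class TestRankLigands:
    def test_ties_by_ascending_ligand_index(self):
        model = init_factors(2, 6, 2, seed=26)
        model.P[0] = 0.0  # all scores equal (zero)
        ranked = rank_ligands(model, 0, np.array([5, 1, 3]))
        assert list(ranked.ligand_ids) == [1, 3, 5]

    def test_descending_by_score(self):
        model = FactorModel(P=np.array([[1.0]]), Q=np.array([[0.1, 0.9, 0.5]]),
                            n_factors=1)
        ranked = rank_ligands(model, 0, np.array([0, 1, 2]))
        assert list(ranked.ligand_ids) == [1, 2, 0]

    def test_matches_sort_oracle(self):
        model = init_factors(3, 30, 4, seed=27)
        cands = np.arange(20)
        ranked = rank_ligands(model, 2, cands)
        oracle = sorted(cands, key=lambda l: (-predict(model, 2, l), l))
        assert list(ranked.ligand_ids) == oracle

    def test_multilevel_ranks_ascending(self):
        model = FactorModel(P=np.array([[1.0]]), Q=np.array([[3.0, 1.0, 2.0]]),
                            n_factors=1, mode="multilevel")
        ranked = rank_ligands(model, 0, np.array([0, 1, 2]))
        assert list(ranked.ligand_ids) == [1, 2, 0]  # lower label = stronger


class TestImplicitFingerprints:
    def test_dimensions_and_dot_consistency(self, small_split):
        model, _ = fit(small_split.train, n_factors=6, n_epochs=3, seed=28)
        t_fp, l_fp = extract_implicit_fingerprints(model)
        assert all(v.shape == (6,) for v in t_fp.values())
        assert all(v.shape == (6,) for v in l_fp.values())
        t0 = str(small_split.train.targets[0])
        l0 = str(small_split.train.ligands[0])
        assert t_fp[t0] @ l_fp[l0] == pytest.approx(predict(model, 0, 0), abs=1e-15)

    def test_untrained_zero_model_gives_zero_fingerprints(self):
        model = init_factors(3, 4, 2, seed=29)
        model.P[:] = 0.0
        model.Q[:] = 0.0
        t_fp, l_fp = extract_implicit_fingerprints(model)
        assert all((v == 0).all() for v in t_fp.values())
        assert all((v == 0).all() for v in l_fp.values())

    def test_csv_roundtrip_bit_exact(self, tmp_path):
        model = init_factors(4, 5, 3, seed=30)
        t_fp, _ = extract_implicit_fingerprints(model)
        path = tmp_path / "fp.csv"
        factorization.export_fingerprints_csv(t_fp, path)
        back = factorization.read_fingerprints_csv(path)
        assert set(back) == set(t_fp)
        for key in t_fp:
            assert np.array_equal(back[key], t_fp[key])

    def test_model_save_load_roundtrip(self, tmp_path, small_split):
        model, _ = fit(small_split.train, n_factors=3, n_epochs=2, seed=31)
        path = tmp_path / "model.npz"
        factorization.save_model(model, path)
        back = factorization.load_model(path)
        assert np.array_equal(back.P, model.P) and np.array_equal(back.Q, model.Q)
        assert back.n_factors == 3 and back.mode == model.mode
        assert list(back.target_ids) == list(model.target_ids)
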