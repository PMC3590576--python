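"""Fixed-size KLR: prototypes, Nyström map, trust-region Newton, end equivalence."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from turnklr.fsklr import (
    PrototypeSet,
    apply_nystrom_map,
    build_nystrom_map,
    fit_primal_tron,
    fs_klr_predict,
    fs_klr_train,
    load_model,
    nystrom_extension,
    save_model,
    select_prototypes,
)
from turnklr.klr import (
    Hyperparams,
    KernelSpec,
    decision_function_dual,
    fit_dual_irls,
    gram_matrix,
)

GAMMA = 0.5


class TestPrototypes:
    def test_m_equals_n_returns_every_point(self, blobs_50x5):
        X, _ = blobs_50x5
        pvs = select_prototypes(X, m=50, seed=0)
        np.testing.assert_array_equal(np.sort(pvs.indices), np.arange(50))

    def test_two_blobs_one_prototype_each(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.1, size=(30, 2)), rng.normal(10, 0.1, size=(30, 2))]
        )
        pvs = select_prototypes(X, m=2, seed=1)
        sides = sorted(int(idx >= 30) for idx in pvs.indices)
        assert sides == [0, 1]

    def test_seed_determinism(self, blobs_50x5):
        X, _ = blobs_50x5
        a = select_prototypes(X, m=8, seed=3)
        b = select_prototypes(X, m=8, seed=3)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_prototypes_are_data_rows(self, blobs_50x5):
        X, _ = blobs_50x5
        pvs = select_prototypes(X, m=6, seed=2)
        np.testing.assert_array_equal(pvs.vectors, X[pvs.indices])

    def test_m_too_large_rejected(self, blobs_50x5):
        X, _ = blobs_50x5
        with pytest.raises(ValueError):
            select_prototypes(X, m=51, seed=0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_prototypes(np.zeros((0, 3)), m=1, seed=0)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            PrototypeSet(indices=np.array([0, 0]), vectors=np.zeros((2, 2)), m=2)


class TestNystrom:
    def test_single_prototype(self):
        pvs = PrototypeSet(indices=np.array([0]), vectors=np.array([[1.0, 2.0]]), m=1)
        nmap = build_nystrom_map(pvs, gamma=GAMMA)
        assert nmap.p == 1
        assert nmap.eigvals[0] == pytest.approx(1.0)

    def test_duplicated_prototypes_lose_rank(self):
        V = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        pvs = PrototypeSet(indices=np.arange(3), vectors=V, m=3)
        nmap = build_nystrom_map(pvs, gamma=GAMMA)
        assert nmap.p < 3

    def test_eigenvalues_match_dense_solver(self, blobs_50x5):
        X, _ = blobs_50x5
        pvs = select_prototypes(X, m=10, seed=0)
        nmap = build_nystrom_map(pvs, gamma=GAMMA)
        K = gram_matrix(pvs.vectors, pvs.vectors, KernelSpec(GAMMA))
        dense = np.sort(np.linalg.eigvalsh(K))[::-1]
        np.testing.assert_allclose(nmap.eigvals, dense[: nmap.p], atol=1e-10)

    def test_exact_on_landmarks(self, blobs_50x5):
        X, _ = blobs_50x5
        pvs = select_prototypes(X, m=12, seed=1)
        nmap = build_nystrom_map(pvs, gamma=GAMMA)
        Phi = apply_nystrom_map(nmap, pvs.vectors)
        K = gram_matrix(pvs.vectors, pvs.vectors, KernelSpec(GAMMA))
        assert np.abs(Phi @ Phi.T - K).max() < 1e-8

    def test_full_sample_reconstructs_kernel(self, blobs_50x5):
        X, _ = blobs_50x5
        pvs = select_prototypes(X, m=50, seed=0)
        nmap = build_nystrom_map(pvs, gamma=GAMMA)
        Phi = apply_nystrom_map(nmap, X)
        K = gram_matrix(X, X, KernelSpec(GAMMA))
        assert np.linalg.norm(Phi @ Phi.T - K, "fro") <= 1e-8

    def test_reconstruction_error_non_increasing_on_nested_sets(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        K = gram_matrix(X, X, KernelSpec(GAMMA))
        errors = []
        for m in (5, 10, 20, 40):
            pvs = PrototypeSet(indices=np.arange(m), vectors=X[:m], m=m)
            nmap = build_nystrom_map(pvs, gamma=GAMMA)
            Phi = apply_nystrom_map(nmap, X)
            errors.append(np.linalg.norm(K - Phi @ Phi.T, "fro"))
        assert all(b <= a + 1e-10 for a, b in zip(errors, errors[1:]))
        assert errors[-1] <= 1e-8

    def test_eigen_extension_identity_on_toy(self):
        # λ̃ᵢ = (n/m)λᵢ, ũᵢ = √(m/n)(1/λᵢ)K_{n,m}uᵢ; the map's i-th column
        # must equal √(λ̃ᵢ)·ũᵢ exactly, and the extension is exact on the
        # landmarks themselves
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 3))
        pvs = PrototypeSet(indices=np.arange(4), vectors=X[:4], m=4)
        nmap = build_nystrom_map(pvs, gamma=GAMMA)
        Phi = apply_nystrom_map(nmap, X)
        lam_tilde, U_tilde = nystrom_extension(nmap, X)
        np.testing.assert_allclose(Phi, U_tilde * np.sqrt(lam_tilde), atol=1e-8)
        n, m = 10, 4
        np.testing.assert_allclose(lam_tilde, (n / m) * nmap.eigvals, atol=1e-12)

    def test_width_mismatch_rejected(self, blobs_50x5):
        X, _ = blobs_50x5
        pvs = select_prototypes(X, m=5, seed=0)
        nmap = build_nystrom_map(pvs, gamma=GAMMA)
        with pytest.raises(ValueError):
            apply_nystrom_map(nmap, np.zeros((3, 4)))


class TestTron:
    def _toy(self, n=20, p=5, seed=11):
        rng = np.random.default_rng(seed)
        Phi = rng.normal(size=(n, p))
        y = np.where(Phi[:, 0] + 0.3 * rng.normal(size=n) > 0, 1, -1)
        return Phi, y

    def test_objective_matches_scipy_oracle(self):
        Phi, y = self._toy()
        lam = 2.0
        res = fit_primal_tron(Phi, y, lam=lam)

        def obj(theta):
            w, b = theta[:5], theta[5]
            f = Phi @ w + b
            return 0.5 * w @ w + 0.5 * lam * np.logaddexp(0, -y * f).sum()

        oracle = minimize(obj, np.zeros(6), method="BFGS", tol=1e-12)
        assert res.objective == pytest.approx(oracle.fun, abs=1e-6)

    def test_objective_no_worse_than_origin(self):
        Phi, y = self._toy(seed=12)
        lam = 1.0
        res = fit_primal_tron(Phi, y, lam=lam)
        assert res.objective <= lam / 2 * len(y) * np.log(2) + 1e-12

    def test_superlinear_tail(self):
        # truncated CG steps early, near-full Newton at the end: the final
        # gradient reductions are much steeper than the early ones
        Phi, y = self._toy(n=200, p=8, seed=13)
        res = fit_primal_tron(Phi, y, lam=1.0, tol=1e-10)
        gn = np.array(res.grad_norms)
        ratios = gn[1:] / gn[:-1]
        assert ratios[-1] < 0.1
        assert ratios[-1] < np.median(ratios)

    def test_degenerate_identical_rows_balanced_labels(self):
        Phi = np.ones((10, 3))
        y = np.array([1, -1] * 5)
        res = fit_primal_tron(Phi, y, lam=1.0)
        np.testing.assert_allclose(res.w, 0.0, atol=1e-6)
        assert res.b == pytest.approx(0.0, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_primal_tron(np.ones((4, 2)), np.ones(4), lam=1.0)


class TestEndToEnd:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_rank_matches_exact_dual_klr(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 5))
        X[:25] += 1.0
        y = np.array([1] * 25 + [-1] * 25)
        hyper = Hyperparams(lam=2.0, gamma=GAMMA)
        spec = KernelSpec(GAMMA)
        K = gram_matrix(X, X, spec)
        dual = fit_dual_irls(K, y, lam=hyper.lam, X=X, spec=spec)
        p_dual = expit(decision_function_dual(dual, X))
        model = fs_klr_train(X, y, hyper, m=50, seed=seed, tol=1e-8)
        p_fs, _ = fs_klr_predict(model, X)
        assert np.abs(p_fs - p_dual).max() < 1e-3

    def test_training_determinism(self, blobs_50x5):
        X, y = blobs_50x5
        hyper = Hyperparams(lam=1.0, gamma=GAMMA)
        m1 = fs_klr_train(X, y, hyper, m=10, seed=5)
        m2 = fs_klr_train(X, y, hyper, m=10, seed=5)
        np.testing.assert_array_equal(m1.w, m2.w)
        np.testing.assert_array_equal(
            m1.map.prototypes.indices, m2.map.prototypes.indices
        )

    def test_single_class_rejected(self, blobs_50x5):
        X, _ = blobs_50x5
        with pytest.raises(ValueError):
            fs_klr_train(X, np.ones(50), Hyperparams(), m=5, seed=0)

    def test_threshold_boundary_is_turn(self, blobs_50x5):
        X, y = blobs_50x5
        hyper = Hyperparams(lam=1.0, gamma=GAMMA, threshold=0.5)
        model = fs_klr_train(X, y, hyper, m=20, seed=0)
        probs, labels = fs_klr_predict(model, X)
        on_boundary = probs >= 0.5
        assert (labels[on_boundary] == "t").all()
        assert (labels[~on_boundary] == "n").all()

    def test_raising_threshold_never_adds_turns(self, blobs_50x5):
        X, y = blobs_50x5
        counts = []
        for thr in (0.3, 0.45, 0.6, 0.8):
            hyper = Hyperparams(lam=1.0, gamma=GAMMA, threshold=thr)
            model = fs_klr_train(X, y, hyper, m=20, seed=0)
            _, labels = fs_klr_predict(model, X)
            counts.append((labels == "t").sum())
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_model_json_roundtrip_bit_identical(self, tmp_path, blobs_50x5):
        X, y = blobs_50x5
        model = fs_klr_train(X, y, Hyperparams(lam=1.0, gamma=GAMMA), m=15, seed=4)
        p1, l1 = fs_klr_predict(model, X)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        p2, l2 = fs_klr_predict(back, X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(l1, l2)
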