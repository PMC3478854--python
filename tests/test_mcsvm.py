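"""Binary SMO machines, kernels, and the WTA/MWV/DAG compositions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitvision import mcsvm
from fruitvision.mcsvm import KernelSpec


def brute_force_dual(K, y, C, steps=41):
    """Literal grid search over the dual for 2-point problems."""
    best, best_obj = None, -np.inf
    grid = np.linspace(0, C, steps)
    for a0 in grid:
        # the equality constraint ties a1 to a0 for 2 points
        if y[0] * y[1] < 0:
            a1 = a0
        else:
            a1 = -a0
            if a1 < 0:
                continue
        a = np.array([a0, a1])
        obj = mcsvm.dual_objective_value(K, y, a)
        if obj > best_obj:
            best, best_obj = a, obj
    return best, best_obj


class TestKernels:
    def test_grb_self_similarity_is_one(self, rng):
        x = rng.normal(size=5)
        assert mcsvm.kernel_eval(KernelSpec("GRB", gamma=0.7), x, x) == 1.0

    def test_hpol_degree_one_equals_linear(self):
        x, x2 = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert mcsvm.kernel_eval(KernelSpec("HPOL", degree=1), x, x2) == 11
        assert mcsvm.kernel_eval(KernelSpec("LIN"), x, x2) == 11

    def test_grb_closed_form(self):
        v = mcsvm.kernel_eval(
            KernelSpec("GRB", gamma=1.0), np.zeros(2), np.array([1.0, 0.0])
        )
        assert v == pytest.approx(np.exp(-1), abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mcsvm.kernel_eval(KernelSpec("LIN"), np.zeros(2), np.zeros(3))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_gram_symmetric_and_psd(self, s):
        rng = np.random.default_rng(s)
        X = rng.normal(size=(8, 3))
        for spec in (KernelSpec("LIN"), KernelSpec("HPOL", degree=3),
                     KernelSpec("GRB", gamma=0.5)):
            K = mcsvm.gram_matrix(spec, X, X)
            assert K == pytest.approx(K.T, abs=1e-10)
            assert np.linalg.eigvalsh(K).min() >= -1e-8
            if spec.name == "GRB":
                assert 0 < K.min() and K.max() <= 1 + 1e-12


class TestBinarySMO:
    def test_two_point_worked_example(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        m = mcsvm.train_binary(X, y, KernelSpec("LIN"), C_reg=10.0, tol=1e-6)
        assert m.alpha == pytest.approx([0.5, 0.5], abs=1e-6)
        assert m.bias == pytest.approx(0.0, abs=1e-6)
        assert mcsvm.decision_function(m, np.array([0.3])) == pytest.approx(0.3, abs=1e-6)
        # agrees with a literal grid-search dual oracle
        K = mcsvm.gram_matrix(KernelSpec("LIN"), X, X)
        _, obj = brute_force_dual(K, y, 10.0)
        assert m.dual_objective == pytest.approx(obj, abs=1e-6)

    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X = np.concatenate([rng.normal([0, 0], 0.3, (15, 2)),
                            rng.normal([3, 3], 0.3, (15, 2))])
        y = np.repeat([1.0, -1.0], 15)
        m = mcsvm.train_binary(X, y, KernelSpec("LIN"), C_reg=10.0)
        assert (mcsvm.svm_output(m, X) == y).all()
        assert abs(np.sum(m.alpha * m.labels)) <= 1e-6
        assert ((m.alpha >= 0) & (m.alpha <= 10.0 + 1e-12)).all()

    def test_duplicating_points_preserves_decision_function(self, rng):
        X = np.concatenate([rng.normal([0, 0], 0.4, (10, 2)),
                            rng.normal([2.5, 0], 0.4, (10, 2))])
        y = np.repeat([1.0, -1.0], 10)
        # large box bound: no multiplier saturates, so the solution is the
        # (unique) hard-margin one and duplication cannot move it
        spec = KernelSpec("GRB", gamma=0.5)
        m1 = mcsvm.train_binary(X, y, spec, C_reg=100.0, tol=1e-6)
        m2 = mcsvm.train_binary(np.vstack([X, X]), np.concatenate([y, y]),
                                spec, C_reg=100.0, tol=1e-6)
        probe = rng.normal(1.0, 1.0, size=(20, 2))
        f1 = mcsvm.decision_function(m1, probe)
        f2 = mcsvm.decision_function(m2, probe)
        assert f1 == pytest.approx(f2, abs=1e-4)

    def test_one_class_input_raises(self):
        with pytest.raises(ValueError):
            mcsvm.train_binary(np.zeros((3, 2)), np.ones(3), KernelSpec("LIN"))

    def test_margin_support_points_classified_correctly(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.sign(X[:, 0] + 0.3 * rng.normal(size=20))
        y[y == 0] = 1
        m = mcsvm.train_binary(X, y, KernelSpec("GRB", gamma=0.5), C_reg=5.0)
        on_margin = (m.alpha > 1e-8) & (m.alpha < 5.0 - 1e-8)
        if on_margin.any():
            out = mcsvm.svm_output(m, m.support[on_margin])
            assert (out == m.labels[on_margin]).all()

    def test_dual_matches_slsqp_oracle_on_random_problems(self, rng):
        for trial in range(8):
            X = rng.normal(size=(12, 3))
            y = np.where(rng.random(12) < 0.5, 1.0, -1.0)
            if len(np.unique(y)) < 2:
                y[0] = -y[0]
            spec = KernelSpec("GRB", gamma=0.5) if trial % 2 else KernelSpec("LIN")
            m = mcsvm.train_binary(X, y, spec, C_reg=1.0, tol=1e-6)
            K = mcsvm.gram_matrix(spec, X, X)
            _, obj = mcsvm.dual_qp_reference(K, y, 1.0)
            assert m.dual_objective == pytest.approx(obj, abs=1e-4)


def three_blobs(rng, n=12):
    X = np.concatenate([rng.normal([0, 0], 0.3, (n, 2)),
                        rng.normal([4, 0], 0.3, (n, 2)),
                        rng.normal([0, 4], 0.3, (n, 2))])
    return X, np.repeat([1, 2, 3], n)


class TestMulticlass:
    @pytest.mark.parametrize("scheme,count", [("WTA", 3), ("MWV", 3), ("DAG", 3)])
    def test_machine_counts_and_separable_blobs(self, rng, scheme, count):
        X, y = three_blobs(rng)
        m = mcsvm.train_multiclass(X, y, scheme, KernelSpec("GRB", gamma=1.0))
        assert m.n_machines == count
        assert (np.atleast_1d(mcsvm.predict(m, X)) == y).all()

    @pytest.mark.parametrize("C,expected", [(2, 1), (6, 15), (18, 153)])
    def test_pairwise_machine_count_law(self, C, expected):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3 * C, 2)) + 5 * np.repeat(
            rng.normal(size=(C, 2)), 3, axis=0
        )
        y = np.repeat(np.arange(1, C + 1), 3)
        m = mcsvm.train_mwv(X, y, KernelSpec("LIN"), C_reg=1.0)
        assert m.n_machines == expected

    def test_wta_tie_goes_to_smallest_index(self):
        # stub machines with constant decision values via empty support
        def const_machine(v):
            return mcsvm.BinarySVMModel(
                support=np.zeros((0, 2)), labels=np.zeros(0), alpha=np.zeros(0),
                bias=-v, kernel=KernelSpec("LIN"), C_reg=1.0,
            )

        m = mcsvm.MulticlassModel(scheme="WTA", n_classes=3, machines={
            1: const_machine(0.5), 2: const_machine(0.5), 3: const_machine(0.1)
        })
        assert mcsvm.predict_wta(m, np.zeros(2)) == 1
        m.machines[2] = const_machine(0.9)
        assert mcsvm.predict_wta(m, np.zeros(2)) == 2

    def test_mwv_votes_and_circular_tie(self):
        def const_machine(v):
            return mcsvm.BinarySVMModel(
                support=np.zeros((0, 2)), labels=np.zeros(0), alpha=np.zeros(0),
                bias=-v, kernel=KernelSpec("LIN"), C_reg=1.0,
            )

        # circular outcome: 1 beats 2, 2 beats 3, 3 beats 1 -> one vote each
        m = mcsvm.MulticlassModel(scheme="MWV", n_classes=3, machines={
            (1, 2): const_machine(+1.0),
            (2, 3): const_machine(+1.0),
            (1, 3): const_machine(-1.0),
        })
        assert mcsvm.predict_mwv(m, np.zeros(2)) == 1

    def test_sweep_winner_is_returned_by_mwv_and_dag(self, rng):
        """A class that wins all its pairwise machines holds the unique
        maximum vote count and survives every DAG elimination."""
        X, y = three_blobs(rng)
        m = mcsvm.train_mwv(X, y, KernelSpec("GRB", gamma=1.0))
        dag = mcsvm.train_dag(X, y, KernelSpec("GRB", gamma=1.0))
        for x, true in zip(X[::7], y[::7]):
            wins = all(
                (mcsvm.svm_output(mach, x) == (1 if i == true else -1))
                for (i, j), mach in m.machines.items()
                if true in (i, j)
            )
            if wins:
                assert mcsvm.predict_mwv(m, x) == true
                assert mcsvm.predict_dag(dag, x)[0] == true

    @pytest.mark.parametrize("C", [2, 3, 6, 10])
    def test_dag_always_evaluates_c_minus_1(self, rng, C):
        X = np.concatenate(
            [rng.normal(3 * k, 0.2, (4, 2)) for k in range(C)]
        )
        y = np.repeat(np.arange(1, C + 1), 4)
        m = mcsvm.train_dag(X, y, KernelSpec("GRB", gamma=1.0))
        _, evals = mcsvm.predict_dag(m, X[0])
        assert evals == C - 1

    def test_two_class_dag_equals_mwv(self, rng):
        X = np.concatenate([rng.normal([0, 0], 0.5, (10, 2)),
                            rng.normal([3, 0], 0.5, (10, 2))])
        y = np.repeat([1, 2], 10)
        m = mcsvm.train_mwv(X, y, KernelSpec("LIN"))
        dag = mcsvm.train_dag(X, y, KernelSpec("LIN"))
        probe = rng.normal(1.5, 1.5, size=(25, 2))
        mwv_labels = mcsvm.predict_mwv(m, probe)
        dag_labels = mcsvm.predict_dag(dag, probe)[0]
        assert np.array_equal(mwv_labels, dag_labels)

    def test_relabeling_classes_permutes_wta_machines(self, rng):
        X, y = three_blobs(rng)
        perm = {1: 2, 2: 3, 3: 1}
        y2 = np.vectorize(perm.get)(y)
        m1 = mcsvm.train_wta(X, y, KernelSpec("LIN"), tol=1e-6)
        m2 = mcsvm.train_wta(X, y2, KernelSpec("LIN"), tol=1e-6)
        probe = rng.normal(1, 2, size=(10, 2))
        for i in (1, 2, 3):
            f1 = mcsvm.decision_function(m1.machines[i], probe)
            f2 = mcsvm.decision_function(m2.machines[perm[i]], probe)
            assert f1 == pytest.approx(f2, abs=1e-4)


class TestTuneKernel:
    def test_single_point_grid_returned(self, rng):
        X, y = three_blobs(rng)
        grid = [KernelSpec("GRB", gamma=1.0)]
        fold_ids = np.tile([0, 1, 2], 12)
        best, errs = mcsvm.tune_kernel(X, y, "MWV", grid, fold_ids)
        assert best is grid[0] and len(errs) == 1

    def test_grb_beats_linear_on_rings(self):
        rng = np.random.default_rng(21)
        n = 50
        inner = rng.normal(0, 0.25, (n, 2))
        ang = rng.uniform(0, 2 * np.pi, n)
        outer = np.stack([2 * np.cos(ang), 2 * np.sin(ang)], 1)
        outer += rng.normal(0, 0.25, (n, 2))
        X = np.concatenate([inner, outer])
        y = np.repeat([1, 2], n)
        grid = [KernelSpec("LIN"), KernelSpec("GRB", gamma=1.0)]
        fold_ids = np.tile([0, 1, 2, 0, 1], 20)
        best, errs = mcsvm.tune_kernel(X, y, "MWV", grid, fold_ids)
        assert best.name == "GRB"
        assert errs[1] < errs[0]

    def test_result_is_grid_member(self, rng):
        X, y = three_blobs(rng)
        grid = mcsvm.default_grid()
        fold_ids = np.tile([0, 1], 18)
        best, _ = mcsvm.tune_kernel(X, y, "WTA", grid, fold_ids)
        assert best in grid


def test_model_serialization_roundtrip(tmp_path, rng):
    X, y = three_blobs(rng)
    m = mcsvm.train_mwv(X, y, KernelSpec("GRB", gamma=0.8))
    path = tmp_path / "model.json"
    mcsvm.save_multiclass(m, path)
    loaded = mcsvm.load_multiclass(path)
    probe = rng.normal(1, 2, size=(12, 2))
    assert np.array_equal(mcsvm.predict_mwv(m, probe), mcsvm.predict_mwv(loaded, probe))
    assert loaded.scheme == "MWV" and loaded.n_classes == 3
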