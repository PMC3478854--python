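"""Binary soft-margin kernel SVMs and their multiclass compositions.

The binary machine is trained in the dual by sequential minimal
optimization (SMO): repeatedly pick a pair of Lagrange multipliers that
violates the KKT conditions, solve the two-variable subproblem in closed
form, and update the threshold, until no multiplier violates KKT beyond
the tolerance.  The decision function follows the convention

    f(x) = sum_n y_n alpha_n k(x_n, x) - b

with the output O(x) = sgn(f(x)) and sgn(0) := +1 so predictions are
total functions.

Three multiclass schemes compose banks of binary machines over classes
1..C:

* WTA (winner-takes-all, one-vs-all): C machines, class i against the
  rest; predict the argmax of the decision values, ties to the smallest
  class index.
* MWV (max-wins-voting, one-vs-one): C(C-1)/2 machines, one per pair
  (i, j) with i < j; each votes for i when its output is +1, else for j;
  predict the most-voted class, ties to the smallest index.
* DAG: the same one-vs-one bank evaluated along a decision DAG — keep a
  candidate list [1..C], evaluate the (first, last) machine, drop the
  loser, repeat; exactly C-1 evaluations per prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize


class ConvergenceError(RuntimeError):
    """SMO failed to satisfy the KKT conditions within the pass budget."""


# ---------------------------------------------------------------------------
# kernels


KERNEL_NAMES = ("LIN", "HPOL", "GRB", "IPOL", "TANH")


@dataclass(frozen=True)
class KernelSpec:
    """A named kernel with its parameters.

    LIN:  k(x, x') = x . x'
    HPOL: k(x, x') = (x . x')^d
    IPOL: k(x, x') = (x . x' + 1)^d
    GRB:  k(x, x') = exp(-gamma ||x - x'||^2)
    TANH: k(x, x') = tanh(kappa x . x' + c)
    """

    name: str = "LIN"
    degree: int = 2
    gamma: float = 1.0
    kappa: float = 1.0
    offset: float = 0.0

    def __post_init__(self):
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}")
        if self.name in ("HPOL", "IPOL") and (
            self.degree < 1 or int(self.degree) != self.degree
        ):
            raise ValueError("polynomial degree must be a positive integer")
        if self.name == "GRB" and not self.gamma > 0:
            raise ValueError("GRB scale gamma must be > 0")


def gram_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kernel matrix K[i, j] = k(A[i], B[j])."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    dots = A @ B.T
    if spec.name == "LIN":
        return dots
    if spec.name == "HPOL":
        return dots**spec.degree
    if spec.name == "IPOL":
        return (dots + 1.0) ** spec.degree
    if spec.name == "TANH":
        return np.tanh(spec.kappa * dots + spec.offset)
    # GRB
    sq = (
        np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :] - 2.0 * dots
    )
    return np.exp(-spec.gamma * np.clip(sq, 0.0, None))


def kernel_eval(spec: KernelSpec, x: np.ndarray, x2: np.ndarray) -> float:
    """Evaluate the kernel on a single pair of equal-length vectors."""
    x = np.asarray(x, dtype=np.float64).ravel()
    x2 = np.asarray(x2, dtype=np.float64).ravel()
    if x.shape != x2.shape:
        raise ValueError("vectors must have equal length")
    return float(gram_matrix(spec, x[None, :], x2[None, :])[0, 0])


def default_gamma(X: np.ndarray) -> float:
    """Data-driven GRB scale 1 / (p * var(X)), the common 'scale' heuristic."""
    X = np.asarray(X, dtype=np.float64)
    v = X.var()
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0


# ---------------------------------------------------------------------------
# binary SVM via SMO


@dataclass
class BinarySVMModel:
    """One trained two-class machine (only rows with alpha > 0 are stored)."""

    support: np.ndarray          # S x p support points
    labels: np.ndarray           # signed labels in {-1, +1}
    alpha: np.ndarray            # dual coefficients, 0 < alpha <= C_reg
    bias: float                  # b in f(x) = sum y a k(x_n, x) - b
    kernel: KernelSpec
    C_reg: float
    dual_objective: float = 0.0
    n_iterations: int = 0


def _smo_solve(
    K: np.ndarray, y: np.ndarray, C: float, tol: float, max_passes: int
) -> tuple[np.ndarray, float, int]:
    """SMO with second-order working-set selection.

    Maintains the bias-free decision values ``f = (alpha*y) @ K`` and the
    per-sample KKT quantity ``g_i = y_i - f_i``.  The first index is the
    maximal violator of the "up" set; the second is the "down"-set
    violator giving the largest guaranteed objective decrease
    ``(g_i - g_j)^2 / eta_ij`` — the selection rule that keeps the solver
    fast on degenerate (low-rank) Gram matrices.  The loop stops when the
    maximal violation ``m - M`` drops to ``tol``; the bias is the
    midpoint of the feasible interval, ``b = -(m + M) / 2`` in the
    f(x) = sum y a k - b convention.  Ties go to the lowest index, so the
    solve is deterministic.
    """
    n = len(y)
    alpha = np.zeros(n)
    f = np.zeros(n)  # sum_j y_j alpha_j K_ij, no bias
    pos = y > 0
    diagK = np.diag(K).copy()
    steps = 0
    while True:
        g = y - f
        up = (pos & (alpha < C)) | (~pos & (alpha > 0))
        down = (~pos & (alpha < C)) | (pos & (alpha > 0))
        if not up.any() or not down.any():  # cannot happen with both classes
            b = 0.0
            break
        gu = np.where(up, g, -np.inf)
        gd = np.where(down, g, np.inf)
        i = int(np.argmax(gu))
        m, M = gu[i], float(np.min(gd))
        if m - M <= tol:
            b = -0.5 * (m + M)
            break
        if steps >= max_passes:
            raise ConvergenceError(
                f"SMO did not converge in {max_passes} steps "
                f"(n={n}, C={C}, tol={tol}, violation={m - M:.3e})"
            )
        # second-order choice of j among down-set violators
        cand = down & (g < m)
        diff = m - g
        eta_vec = np.maximum(diagK[i] + diagK - 2.0 * K[i], 1e-12)
        gain = np.where(cand, diff * diff / eta_vec, -np.inf)
        j = int(np.argmax(gain))
        steps += 1
        yi, yj = y[i], y[j]
        ai, aj = alpha[i], alpha[j]
        s = yi * yj
        if s < 0:
            lo, hi = max(0.0, aj - ai), min(C, C + aj - ai)
        else:
            lo, hi = max(0.0, ai + aj - C), min(C, ai + aj)
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        # E_i - E_j = (f_i - y_i) - (f_j - y_j) = g_j - g_i
        delta = yj * (g[j] - g[i])
        if eta > 1e-15:
            ajn = aj + delta / eta
            ajn = min(max(ajn, lo), hi)
        else:  # flat direction: move to the descending end of the segment
            ajn = hi if delta > 0 else lo
        ain = ai + s * (aj - ajn)
        # snap to the box so near-bound multipliers leave the working sets
        snap = 1e-10 * max(C, 1.0)
        if ain < snap:
            ain = 0.0
        elif ain > C - snap:
            ain = C
        if ajn < snap:
            ajn = 0.0
        elif ajn > C - snap:
            ajn = C
        di, dj = ain - ai, ajn - aj
        alpha[i], alpha[j] = ain, ajn
        f += yi * di * K[i] + yj * dj * K[j]
    return alpha, b, steps


def dual_objective_value(K: np.ndarray, y: np.ndarray, alpha: np.ndarray) -> float:
    """Dual objective W(a) = sum a - 1/2 sum_ij a_i a_j y_i y_j K_ij."""
    ya = alpha * y
    return float(alpha.sum() - 0.5 * ya @ K @ ya)


def dual_qp_reference(
    K: np.ndarray, y: np.ndarray, C: float
) -> tuple[np.ndarray, float]:
    """Reference solver for the SVM dual, for validating the SMO solver.

    Maximizes W(a) subject to 0 <= a <= C and sum a_i y_i = 0 with a
    general-purpose SLSQP run from a feasible interior start.  Intended
    for small problems only; completely independent of the SMO code path.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    Q = np.outer(y, y) * K
    Q = 0.5 * (Q + Q.T)

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    # feasible interior start: equal total mass on each signed side
    n_pos = int((y > 0).sum())
    m = min(n_pos, n - n_pos) * C / 2.0
    a0 = np.where(y > 0, m / n_pos, m / (n - n_pos))
    res = minimize(
        neg_obj,
        a0,
        jac=neg_grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    return res.x, float(-res.fun)


def train_binary(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    C_reg: float = 1.0,
    tol: float = 1e-3,
    max_passes: int = 1_000_000,
) -> BinarySVMModel:
    """Train one soft-margin binary SVM in the dual with SMO.

    ``y`` holds signed labels in {-1, +1}; both classes must be present.
    The bias is taken from the KKT conditions of the on-margin support
    points (averaged); if every support point is at the box bound the
    midpoint of the feasible bias interval is used.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both signed classes must be present")
    K = gram_matrix(spec, X, X)
    alpha, b, sweeps = _smo_solve(K, y, C_reg, tol, max_passes)

    # recompute the bias from on-margin support points for robustness
    sv = alpha > 1e-10
    margin = sv & (alpha < C_reg - 1e-10)
    f_nob = (alpha * y) @ K  # decision values before subtracting b
    if margin.any():
        b = float(np.mean(f_nob[margin] - y[margin]))
    else:
        # all multipliers at a box bound: take the midpoint of the feasible
        # bias interval given by the bound points' KKT inequalities
        g = f_nob - y
        at_c = alpha >= C_reg - 1e-10
        at_0 = alpha <= 1e-10
        uppers = g[((y > 0) & at_0) | ((y < 0) & at_c)]
        lowers = g[((y < 0) & at_0) | ((y > 0) & at_c)]
        lo = lowers.max() if len(lowers) else g.min()
        hi = uppers.min() if len(uppers) else g.max()
        b = float((lo + hi) / 2.0)

    obj = dual_objective_value(K, y, alpha)
    return BinarySVMModel(
        support=X[sv].copy(),
        labels=y[sv].copy(),
        alpha=alpha[sv].copy(),
        bias=b,
        kernel=spec,
        C_reg=C_reg,
        dual_objective=obj,
        n_iterations=sweeps,
    )


def decision_function(model: BinarySVMModel, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_n y_n alpha_n k(x_n, x) - b for one or many points."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if model.support.shape[0] == 0:
        vals = np.full(X2.shape[0], -model.bias)
    else:
        K = gram_matrix(model.kernel, X2, model.support)
        vals = K @ (model.alpha * model.labels) - model.bias
    return vals[0] if single else vals


def svm_output(model: BinarySVMModel, X: np.ndarray) -> np.ndarray:
    """O(x) = sgn(f(x)) with sgn(0) := +1."""
    f = decision_function(model, X)
    return np.where(np.asarray(f) >= 0, 1, -1)


# ---------------------------------------------------------------------------
# multiclass schemes


SCHEMES = ("WTA", "MWV", "DAG")


@dataclass
class MulticlassModel:
    scheme: str
    n_classes: int
    machines: dict = field(default_factory=dict)
    # WTA: machines[i] for i in 1..C (class i vs rest)
    # MWV/DAG: machines[(i, j)] for 1 <= i < j <= C (class i is +1)

    @property
    def n_machines(self) -> int:
        return len(self.machines)


def _check_training_set(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    y = np.asarray(y, dtype=np.int64).ravel()
    classes = np.unique(y)
    C = int(classes.max())
    if classes.min() < 1:
        raise ValueError("class labels must be integers in 1..C")
    if C < 2 or len(classes) != C:
        raise ValueError("every class in 1..C needs at least one sample")
    return y, C


def train_wta(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    C_reg: float = 1.0,
    tol: float = 1e-3,
) -> MulticlassModel:
    """One-vs-all bank: machine i sees class i as +1, all others as -1."""
    X = np.asarray(X, dtype=np.float64)
    y, C = _check_training_set(X, y)
    machines = {
        i: train_binary(X, np.where(y == i, 1.0, -1.0), spec, C_reg, tol)
        for i in range(1, C + 1)
    }
    return MulticlassModel(scheme="WTA", n_classes=C, machines=machines)


def train_mwv(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    C_reg: float = 1.0,
    tol: float = 1e-3,
) -> MulticlassModel:
    """One-vs-one bank: machine (i, j) trained on classes i (+1) and j (-1)."""
    X = np.asarray(X, dtype=np.float64)
    y, C = _check_training_set(X, y)
    machines = {}
    for i in range(1, C):
        for j in range(i + 1, C + 1):
            sel = (y == i) | (y == j)
            machines[(i, j)] = train_binary(
                X[sel], np.where(y[sel] == i, 1.0, -1.0), spec, C_reg, tol
            )
    return MulticlassModel(scheme="MWV", n_classes=C, machines=machines)


def train_dag(
    X: np.ndarray, y: np.ndarray, spec: KernelSpec, C_reg: float = 1.0,
    tol: float = 1e-3,
) -> MulticlassModel:
    """The DAG scheme shares the one-vs-one bank; only prediction differs."""
    model = train_mwv(X, y, spec, C_reg, tol)
    return replace(model, scheme="DAG")


def predict_wta(model: MulticlassModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the C one-vs-all decision values; ties to smallest index."""
    X2 = np.atleast_2d(np.asarray(X, dtype=np.float64))
    F = np.stack(
        [decision_function(model.machines[i], X2) for i in range(1, model.n_classes + 1)],
        axis=1,
    )
    labels = np.argmax(F, axis=1) + 1  # np.argmax takes the first maximum
    return labels if np.asarray(X).ndim > 1 else int(labels[0])


def predict_mwv(model: MulticlassModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over the one-vs-one bank; ties to smallest index."""
    X2 = np.atleast_2d(np.asarray(X, dtype=np.float64))
    C = model.n_classes
    votes = np.zeros((X2.shape[0], C), dtype=np.int64)
    for (i, j), m in model.machines.items():
        out = svm_output(m, X2)
        votes[:, i - 1] += out == 1
        votes[:, j - 1] += out == -1
    labels = np.argmax(votes, axis=1) + 1
    return labels if np.asarray(X).ndim > 1 else int(labels[0])


def predict_dag(
    model: MulticlassModel, x: np.ndarray
) -> tuple[int, int] | tuple[np.ndarray, int]:
    """Sequential elimination over the one-vs-one bank.

    Keeps the candidate list [1..C]; each step evaluates the machine for
    (first, last): output +1 eliminates the last candidate (x is not in
    class j), output -1 eliminates the first.  Returns the surviving
    class and the number of binary evaluations, which is always C - 1.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim > 1:
        results = [predict_dag(model, row) for row in x]
        return np.array([r[0] for r in results]), results[0][1] if results else 0
    candidates = list(range(1, model.n_classes + 1))
    evaluations = 0
    while len(candidates) > 1:
        i, j = candidates[0], candidates[-1]
        out = int(svm_output(model.machines[(i, j)], x))
        evaluations += 1
        if out == 1:
            candidates.pop()      # not class j
        else:
            candidates.pop(0)     # not class i
    return candidates[0], evaluations


def train_multiclass(
    X: np.ndarray,
    y: np.ndarray,
    scheme: str,
    spec: KernelSpec,
    C_reg: float = 1.0,
    tol: float = 1e-3,
) -> MulticlassModel:
    scheme = scheme.upper()
    if scheme == "WTA":
        return train_wta(X, y, spec, C_reg, tol)
    if scheme == "MWV":
        return train_mwv(X, y, spec, C_reg, tol)
    if scheme == "DAG":
        return train_dag(X, y, spec, C_reg, tol)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def predict(model: MulticlassModel, X: np.ndarray) -> np.ndarray:
    if model.scheme == "WTA":
        return predict_wta(model, X)
    if model.scheme == "MWV":
        return predict_mwv(model, X)
    out = predict_dag(model, X)
    return out[0]


# ---------------------------------------------------------------------------
# kernel tuning


def default_grid() -> list[KernelSpec]:
    """LIN, HPOL d in 1..5, GRB gamma in 2^-6 .. 2^4."""
    grid: list[KernelSpec] = [KernelSpec("LIN")]
    grid += [KernelSpec("HPOL", degree=d) for d in range(1, 6)]
    grid += [KernelSpec("GRB", gamma=2.0**e) for e in range(-6, 5)]
    return grid


def tune_kernel(
    X: np.ndarray,
    y: np.ndarray,
    scheme: str,
    grid: list[KernelSpec],
    fold_ids: np.ndarray,
    C_reg: float = 1.0,
) -> tuple[KernelSpec, np.ndarray]:
    """Exhaustive grid search minimizing mean CV error over a fold plan.

    ``fold_ids`` assigns each sample to a cross-validation fold.  Ties go
    to the earliest grid entry, so the search is deterministic.  Returns
    the winning spec and the per-spec mean CV error rates.
    """
    if not grid:
        raise ValueError("empty kernel grid")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    fold_ids = np.asarray(fold_ids)
    errors = np.empty(len(grid))
    for g, spec in enumerate(grid):
        fold_err = []
        for f in np.unique(fold_ids):
            tr, te = fold_ids != f, fold_ids == f
            m = train_multiclass(X[tr], y[tr], scheme, spec, C_reg)
            fold_err.append(float(np.mean(predict(m, X[te]) != y[te])))
        errors[g] = np.mean(fold_err)
    return grid[int(np.argmin(errors))], errors


# ---------------------------------------------------------------------------
# serialization


def _spec_to_dict(spec: KernelSpec) -> dict:
    return {
        "name": spec.name,
        "degree": spec.degree,
        "gamma": spec.gamma,
        "kappa": spec.kappa,
        "offset": spec.offset,
    }


def _spec_from_dict(d: dict) -> KernelSpec:
    return KernelSpec(**d)


def multiclass_to_dict(model: MulticlassModel) -> dict:
    machines = []
    for key, m in model.machines.items():
        machines.append(
            {
                "key": list(key) if isinstance(key, tuple) else key,
                "support": m.support.tolist(),
                "labels": m.labels.tolist(),
                "alpha": m.alpha.tolist(),
                "bias": m.bias,
                "kernel": _spec_to_dict(m.kernel),
                "C_reg": m.C_reg,
            }
        )
    return {
        "version": 1,
        "kind": "multiclass_svm",
        "scheme": model.scheme,
        "n_classes": model.n_classes,
        "machines": machines,
    }


def save_multiclass(model: MulticlassModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(multiclass_to_dict(model), fh)


def multiclass_from_dict(payload: dict) -> MulticlassModel:
    if payload.get("kind") != "multiclass_svm":
        raise ValueError("not a multiclass SVM payload")
    machines = {}
    for m in payload["machines"]:
        key = tuple(m["key"]) if isinstance(m["key"], list) else m["key"]
        machines[key] = BinarySVMModel(
            support=np.array(m["support"], dtype=np.float64).reshape(
                len(m["alpha"]), -1
            ),
            labels=np.array(m["labels"], dtype=np.float64),
            alpha=np.array(m["alpha"], dtype=np.float64),
            bias=float(m["bias"]),
            kernel=_spec_from_dict(m["kernel"]),
            C_reg=float(m["C_reg"]),
        )
    return MulticlassModel(
        scheme=payload["scheme"],
        n_classes=int(payload["n_classes"]),
        machines=machines,
    )


def load_multiclass(path) -> MulticlassModel:
    with open(path) as fh:
        return multiclass_from_dict(json.load(fh))
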