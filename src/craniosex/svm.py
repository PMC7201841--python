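"""Soft-margin RBF support vector classifier for fused skull features.

The classifier solves the dual problem

    max_alpha  W(alpha) = sum_i alpha_i
                 - 1/2 sum_ij y_i y_j alpha_i alpha_j k(x_i, x_j)
    s.t.       0 <= alpha_i <= C,   sum_i alpha_i y_i = 0,

with the RBF kernel k(x, x') = exp(-||x - x'||^2 / delta^2), by a
maximal-violating-pair SMO ascent (pairwise coordinate updates that keep
the equality constraint satisfied exactly).  The decision function is

    f(x) = sum_i y_i alpha_i k(x, x_i) + b ,

whose sign is the predicted sex (+1 male, -1 female).  Hyperparameters
(C, delta) are chosen by stratified cross-validated accuracy on the log2
grids 2^-5..2^15 and 2^-15..2^5 with exponent step 0.5 (41 x 41 cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Standardizer",
    "SVMModel",
    "GridSearchResult",
    "EvalReport",
    "ConvergenceError",
    "C_EXPONENTS",
    "DELTA_EXPONENTS",
    "rbf_kernel",
    "rbf_kernel_matrix",
    "solve_dual",
    "decision_function",
    "predict",
    "grid_search",
    "stratified_split",
    "evaluate",
]

C_EXPONENTS = np.arange(-5.0, 15.0 + 1e-9, 0.5)       # 41 values
DELTA_EXPONENTS = np.arange(-15.0, 5.0 + 1e-9, 0.5)   # 41 values

_EPS = 1e-12


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-scoring by training-set statistics.

    Constant features (sd = 0) are passed through unchanged with a warning;
    held-out data must be transformed with the same training stats.
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            warnings.warn("constant feature(s) passed through unstandardized",
                          stacklevel=2)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        safe_sd = np.where(self.sd > 0, self.sd, 1.0)
        return (X - self.mean) / safe_sd


def rbf_kernel(x, xi, delta: float) -> float:
    """k(x, xi) = exp(-||x - xi||^2 / delta^2), in (0, 1]."""
    if delta <= 0:
        raise ValueError("kernel width delta must be positive")
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if x.shape != xi.shape:
        raise ValueError("vectors must have equal length")
    return float(np.exp(-np.sum((x - xi) ** 2) / delta ** 2))


def rbf_kernel_matrix(X: np.ndarray, Z: np.ndarray, delta: float) -> np.ndarray:
    if delta <= 0:
        raise ValueError("kernel width delta must be positive")
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    sq = (np.sum(X ** 2, axis=1)[:, None] + np.sum(Z ** 2, axis=1)[None, :]
          - 2.0 * X @ Z.T)
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / delta ** 2)


@dataclass(frozen=True)
class SVMModel:
    """Trained soft-margin kernel SVM (dual form)."""

    support_vectors: np.ndarray      # training points with alpha > 0
    support_alphas: np.ndarray
    support_labels: np.ndarray
    bias: float
    C: float
    delta: float
    dual_objective: float
    kkt_gap: float
    n_iter: int
    converged: bool
    standardizer: Standardizer | None = None
    tie_flags: list = field(default_factory=list, repr=False)


def _dual_objective(alpha: np.ndarray, y: np.ndarray, K: np.ndarray) -> float:
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def solve_dual(X: np.ndarray, y: np.ndarray, C: float, delta: float,
               tol: float = 1e-3, max_iter: int = 100_000,
               K: np.ndarray | None = None, strict: bool = True) -> SVMModel:
    """Maximize the dual by maximal-violating-pair SMO.

    Pairwise updates move along directions that preserve sum alpha_i y_i = 0
    exactly (it stays 0 to machine precision since alpha starts at 0) and
    clip to the box [0, C].  Convergence: the KKT gap
    max_{i in I_up} (y_i - f_i) - min_{j in I_low} (y_j - f_j) < tol.
    The bias b is the average of y_k - f_k over free support vectors
    (0 < alpha < C), or the midpoint of the KKT interval when none is free.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training set")
    if C <= 0:
        raise ValueError("penalty C must be positive")
    m = len(y)
    if K is None:
        K = rbf_kernel_matrix(X, X, delta)

    alpha = np.zeros(m)
    grad = -np.ones(m)               # gradient of the minimization form
    eps = 1e-12 * max(C, 1.0)
    yg = np.empty(m)
    n_iter = 0
    gap = np.inf
    for n_iter in range(1, max_iter + 1):
        np.multiply(-y, grad, out=yg)    # yg_i = y_i - f_i at the current alpha
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y < 0) & (alpha < C - eps)) | ((y > 0) & (alpha > eps))
        if not up.any() or not low.any():
            gap = 0.0
            break
        i = int(np.argmax(np.where(up, yg, -np.inf)))
        j = int(np.argmin(np.where(low, yg, np.inf)))
        gap = yg[i] - yg[j]
        if gap < tol:
            break
        quad = max(K[i, i] + K[j, j] - 2.0 * K[i, j], _EPS)
        t = gap / quad
        # direction d_i = y_i, d_j = -y_j keeps y . alpha constant
        t_hi = min((C - alpha[i]) if y[i] > 0 else alpha[i],
                   alpha[j] if y[j] > 0 else (C - alpha[j]))
        t = min(t, t_hi)
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        np.clip(alpha, 0.0, C, out=alpha)
        grad += t * y * (K[:, i] - K[:, j])
    converged = gap < tol
    if strict and not converged:
        raise ConvergenceError(
            f"SMO did not converge in {max_iter} iterations "
            f"(KKT gap {gap:.3e}, C={C:g}, delta={delta:g}, m={m})")

    f = (alpha * y) @ K              # decision values without bias
    free = (alpha > eps) & (alpha < C - eps)
    if free.any():
        bias = float(np.mean(y[free] - f[free]))
    else:
        ygf = y - f
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y < 0) & (alpha < C - eps)) | ((y > 0) & (alpha > eps))
        hi = np.max(ygf[up]) if up.any() else 0.0
        lo = np.min(ygf[low]) if low.any() else 0.0
        bias = float(0.5 * (hi + lo))

    sv = alpha > eps
    return SVMModel(
        support_vectors=X[sv].copy(),
        support_alphas=alpha[sv].copy(),
        support_labels=y[sv].copy(),
        bias=bias,
        C=float(C),
        delta=float(delta),
        dual_objective=_dual_objective(alpha, y, K),
        kkt_gap=float(gap),
        n_iter=n_iter,
        converged=bool(converged),
    )


def decision_function(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_i y_i alpha_i k(x, x_i) + b for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.standardizer is not None:
        X = model.standardizer.transform(X)
    if model.support_vectors.size == 0:
        return np.full(len(X), model.bias)
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("feature length does not match the trained model")
    Kx = rbf_kernel_matrix(X, model.support_vectors, model.delta)
    return Kx @ (model.support_alphas * model.support_labels) + model.bias


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Sign of the decision function; exact ties report +1 (flagged)."""
    f = decision_function(model, X)
    ties = np.flatnonzero(f == 0.0)
    if ties.size:
        model.tie_flags.extend(int(t) for t in ties)
    return np.where(f >= 0.0, 1, -1).astype(int)


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold assignment with per-class round-robin after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y), dtype=int)
    for cls in (-1, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


@dataclass(frozen=True)
class GridSearchResult:
    C_grid: np.ndarray
    delta_grid: np.ndarray
    cv_accuracy: np.ndarray          # shape (len(C_grid), len(delta_grid))
    best_C: float
    best_delta: float
    best_accuracy: float


def grid_search(X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0,
                C_grid: np.ndarray | None = None,
                delta_grid: np.ndarray | None = None,
                tol: float = 1e-3, max_iter: int = 3000) -> GridSearchResult:
    """Cross-validated accuracy over the log2 (C, delta) grid.

    Stratified ``folds``-fold CV at every grid cell; ties in accuracy break
    toward smaller C, then smaller delta.  Fits that exhaust the iteration
    budget at extreme grid corners are scored with their current iterate
    (the optimum cells converge well before the budget).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if C_grid is None:
        C_grid = 2.0 ** C_EXPONENTS
    if delta_grid is None:
        delta_grid = 2.0 ** DELTA_EXPONENTS
    m = len(y)
    if m < folds:
        raise ValueError("fewer samples than folds")
    assign = _stratified_folds(y, folds, seed)
    for f in range(folds):
        if len(np.unique(y[assign != f])) < 2:
            raise ValueError("a training fold contains a single class")

    acc = np.zeros((len(C_grid), len(delta_grid)))
    for d_idx, delta in enumerate(delta_grid):
        K = rbf_kernel_matrix(X, X, delta)
        for c_idx, C in enumerate(C_grid):
            correct = 0
            for f in range(folds):
                tr = assign != f
                va = ~tr
                model = solve_dual(X[tr], y[tr], C=C, delta=delta,
                                   tol=tol, max_iter=max_iter,
                                   K=K[np.ix_(tr, tr)], strict=False)
                pred = predict(model, X[va])
                correct += int(np.sum(pred == y[va]))
            acc[c_idx, d_idx] = correct / m

    # lexicographic tie-break: smaller C first, then smaller delta
    best_val = acc.max()
    cands = np.argwhere(acc >= best_val - 1e-12)
    cands = cands[np.lexsort((cands[:, 1], cands[:, 0]))]
    c_idx, d_idx = cands[0]
    return GridSearchResult(
        C_grid=np.asarray(C_grid), delta_grid=np.asarray(delta_grid),
        cv_accuracy=acc,
        best_C=float(C_grid[c_idx]), best_delta=float(delta_grid[d_idx]),
        best_accuracy=float(acc[c_idx, d_idx]),
    )


def stratified_split(labels: np.ndarray, train_frac: float = 0.7,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-class 70/30 split; returns (train_idx, test_idx).

    Each class contributes round(train_frac * n_class) training samples
    (round-half-up); e.g. 73 males and 60 females give 51 + 42 = 93 training
    and 22 + 18 = 40 test samples.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        rng.shuffle(idx)
        n_train = int(np.floor(train_frac * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass(frozen=True)
class EvalReport:
    """Per-class confusion counts and correct rates (percent, 1 decimal)."""

    male_tested: int
    male_correct: int
    female_tested: int
    female_correct: int

    @property
    def male_misjudged(self) -> int:
        return self.male_tested - self.male_correct

    @property
    def female_misjudged(self) -> int:
        return self.female_tested - self.female_correct

    @property
    def male_rate(self) -> float:
        return correct_rate(self.male_correct, self.male_tested)

    @property
    def female_rate(self) -> float:
        return correct_rate(self.female_correct, self.female_tested)

    def as_dict(self) -> dict:
        return {
            "male": {"tested": self.male_tested, "correct": self.male_correct,
                     "misjudged": self.male_misjudged, "rate": self.male_rate},
            "female": {"tested": self.female_tested,
                       "correct": self.female_correct,
                       "misjudged": self.female_misjudged,
                       "rate": self.female_rate},
        }


def correct_rate(correct: int, tested: int) -> float:
    """Per-class correct rate: correct/tested x 100, rounded to 1 decimal."""
    if tested == 0:
        return float("nan")
    return round(correct / tested * 100.0, 1)


def evaluate(model: SVMModel, X_test: np.ndarray, y_test: np.ndarray) -> EvalReport:
    """Confusion-count evaluation of a trained model on a held-out set."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    pred = predict(model, X_test)
    male = y_test == 1
    female = y_test == -1
    return EvalReport(
        male_tested=int(male.sum()),
        male_correct=int(np.sum(pred[male] == 1)),
        female_tested=int(female.sum()),
        female_correct=int(np.sum(pred[female] == -1)),
    )
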