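"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — explicit Python loops, brute-force
pair counting, a generic convex solve — and shares no code with the
implementation paths it verifies.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

ALPHABET = tuple("ARNDCQEGHILKMFPSTWYV")


# ---------------------------------------------------------------------------
# naive encoder loops
# ---------------------------------------------------------------------------

def naive_sdt(scores: np.ndarray, lg_max: int) -> np.ndarray:
    L = scores.shape[0]
    out = []
    for a in range(20):
        for lg in range(1, lg_max + 1):
            total = 0.0
            for j in range(L - lg):
                total += scores[j, a] * scores[j + lg, a]
            out.append(total / (L - lg))
    return np.array(out)


def naive_ddt(scores: np.ndarray, lg_max: int) -> np.ndarray:
    L = scores.shape[0]
    out = []
    for a1 in range(20):
        for a2 in range(20):
            if a1 == a2:
                continue
            for lg in range(1, lg_max + 1):
                total = 0.0
                for j in range(L - lg):
                    total += scores[j, a1] * scores[j + lg, a2]
                out.append(total / (L - lg))
    return np.array(out)


def naive_dt(scores: np.ndarray, lg_max: int) -> np.ndarray:
    return np.concatenate([naive_sdt(scores, lg_max), naive_ddt(scores, lg_max)])


def naive_avepscore20(scores: np.ndarray) -> np.ndarray:
    return np.array([sum(col) / len(col) for col in scores.T])


def naive_avepscore400(scores: np.ndarray, residues: str) -> np.ndarray:
    out = []
    for r in ALPHABET:
        rows = [scores[j] for j, res in enumerate(residues) if res == r]
        if rows:
            out.extend(np.mean(rows, axis=0))
        else:
            out.extend([0.0] * 20)
    return np.array(out)


def naive_pscore100(scores: np.ndarray) -> np.ndarray:
    out = []
    for col in scores.T:
        for t in (0, 25, 50, 75, 100):
            out.append(np.percentile(col, t))
    return np.array(out)


def naive_acc(scores: np.ndarray, lg_max: int) -> np.ndarray:
    L = scores.shape[0]
    out = []
    for a in range(20):
        m = scores[:, a].mean()
        for lg in range(1, lg_max + 1):
            total = 0.0
            for j in range(L - lg):
                total += (scores[j, a] - m) * (scores[j + lg, a] - m)
            out.append(total / (L - lg))
    return np.array(out)


# ---------------------------------------------------------------------------
# brute-force AUC
# ---------------------------------------------------------------------------

def bruteforce_auc(values, labels) -> float:
    """Mann-Whitney AUC by exhaustive positive-negative pair counting."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = values[labels == 1]
    neg = values[labels == -1]
    credit = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                credit += 1.0
            elif p == n:
                credit += 0.5
    return credit / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# direct dual QP solve of the soft-margin RBF SVM
# ---------------------------------------------------------------------------

def rbf_kernel_matrix(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-gamma * d2)


def solve_dual_qp(X: np.ndarray, y: np.ndarray, C: float, gamma: float):
    """Solve max_a 1'a - (1/2) a'Qa, 0 <= a <= C, y'a = 0 by SLSQP + polish.

    Returns (alpha, bias). The polish step re-solves the stationarity system
    exactly on the identified free set, giving ~1e-10 accuracy on small
    well-conditioned instances.
    """
    n = len(y)
    K = rbf_kernel_matrix(X, X, gamma)
    Q = K * np.outer(y, y)

    def objective(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    res = minimize(
        objective,
        x0=np.full(n, min(C, 1.0) / 2),
        jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y.astype(float)}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 2000},
    )
    alpha = res.x

    # active-set polish: solve KKT stationarity exactly on the free set
    tol = 1e-6 * max(C, 1.0)
    free = (alpha > tol) & (alpha < C - tol)
    at_c = alpha >= C - tol
    if free.any():
        nf = int(free.sum())
        A = np.zeros((nf + 1, nf + 1))
        A[:nf, :nf] = Q[np.ix_(free, free)]
        A[:nf, nf] = y[free]
        A[nf, :nf] = y[free]
        rhs = np.concatenate([
            1.0 - Q[np.ix_(free, at_c)] @ alpha[at_c] if at_c.any() else np.ones(nf),
            [-(y[at_c] @ alpha[at_c]) if at_c.any() else 0.0],
        ])
        sol = np.linalg.solve(A, rhs)
        polished = alpha.copy()
        polished[free] = sol[:nf]
        polished[~free & ~at_c] = 0.0
        polished[at_c] = C
        if np.all(polished >= -1e-9) and np.all(polished <= C + 1e-9):
            alpha = np.clip(polished, 0.0, C)

    # bias from free support vectors (or margin midpoint if none are free)
    f_no_b = (alpha * y) @ K
    free = (alpha > tol) & (alpha < C - tol)
    if free.any():
        bias = float(np.mean(y[free] - f_no_b[free]))
    else:
        sv = alpha > tol
        up = y == 1
        bias = -0.5 * (np.max(f_no_b[sv & up]) + np.min(f_no_b[sv & ~up]))
    return alpha, bias


def qp_decision_values(X_train, y_train, X_eval, C, gamma):
    alpha, bias = solve_dual_qp(X_train, y_train, C, gamma)
    K = rbf_kernel_matrix(X_eval, X_train, gamma)
    return K @ (alpha * y_train) + bias
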