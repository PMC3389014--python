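"""Independent oracle implementations used only by the test suite.

Everything here is written with explicit loops and public scikit-learn /
scipy building blocks, sharing no code with the package, so agreement
between the two routes is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.svm import SVC


def svc_hyperplane(X, y, cost, tol=1e-3):
    """(w, b) from the public SVC estimator, oriented toward class +1."""
    m = SVC(kernel="linear", C=cost, tol=tol).fit(X, y)
    return m.coef_[0], float(m.intercept_[0])


def primal_objective(w, b, X, y, cost):
    margins = y * (X @ w + b)
    return 0.5 * float(w @ w) + cost * float(np.sum(np.maximum(0.0, 1.0 - margins)))


def qp_primal_solve(X, y, cost):
    """Soft-margin primal solved as a generic constrained QP (trust-constr).

    Variables z = (w, b, xi); minimize 0.5||w||^2 + C*sum(xi) subject to
    y_i(w.x_i + b) >= 1 - xi_i and xi_i >= 0.  Returns the optimal objective.
    """
    from scipy.optimize import Bounds, LinearConstraint

    n, p = X.shape
    m = p + 1 + n

    def obj(z):
        w = z[:p]
        return 0.5 * w @ w + cost * np.sum(z[p + 1:])

    def obj_grad(z):
        g = np.zeros_like(z)
        g[:p] = z[:p]
        g[p + 1:] = cost
        return g

    H = np.zeros((m, m))
    H[:p, :p] = np.eye(p)

    # y_i (w.x_i + b) + xi_i >= 1
    A = np.zeros((n, m))
    A[:, :p] = X * y[:, None]
    A[:, p] = y
    A[:, p + 1:] = np.eye(n)
    lb = np.full(m, -np.inf)
    lb[p + 1:] = 0.0  # xi >= 0

    z0 = np.zeros(m)
    z0[p + 1:] = 1.0  # feasible start: w=0, b=0, xi=1
    res = minimize(
        obj, z0, jac=obj_grad, hess=lambda z: H,
        method="trust-constr",
        constraints=[LinearConstraint(A, 1.0, np.inf)],
        bounds=Bounds(lb, np.full(m, np.inf)),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000},
    )
    assert res.status in (1, 2), res.message
    # polish the interior-point solution with an SLSQP warm start; evaluate
    # every candidate hyperplane by its exact hinge objective (optimal xi is
    # implied by (w, b), so this is always feasible)
    candidates = [res.x]
    res2 = minimize(
        obj, res.x, jac=obj_grad, method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda z: A @ z - 1.0,
                      "jac": lambda z: A}],
        bounds=list(zip(lb, np.full(m, np.inf))),
        options={"maxiter": 500, "ftol": 1e-16},
    )
    if res2.success:
        candidates.append(res2.x)
    return min(primal_objective(z[:p], z[p], X, y, cost) for z in candidates)


def pair_counting_auc(scores, labels):
    """AUC as the fraction of concordant positive/negative pairs (ties = 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels > 0]
    neg = scores[labels < 0]
    total = concordant = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                concordant += 1
            elif sp == sn:
                concordant += 0.5
    return concordant / total


def binomial_tail(k, n, p):
    """P(X >= k) by exact rational combinatorics (Fraction arithmetic)."""
    from fractions import Fraction
    from math import comb

    pf = Fraction(p).limit_denominator(10**6) if not isinstance(p, Fraction) else p
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return total


# --------------------------------------------------------------------------
# Naive re-implementation of the full nested procedure (explicit loops, no
# shared code with svmorph.nested_selection).
# --------------------------------------------------------------------------

def _naive_fit_transforms(X, age, sex):
    """OLS coefficients via the normal equations (pinv) plus mean/sd."""
    D = np.c_[np.ones(len(age)), age, sex]
    beta = np.linalg.pinv(D.T @ D) @ D.T @ X
    resid = X - D @ beta
    mu = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    return beta, mu, sd


def _naive_apply(beta, mu, sd, X, age, sex):
    D = np.c_[np.ones(np.atleast_1d(age).shape[0]), age, sex]
    resid = X - D @ beta
    safe = np.where(sd < 1e-12, 1.0, sd)
    Z = (resid - mu) / safe
    Z[:, sd < 1e-12] = 0.0
    return Z


def _naive_inner_q(Z, y, cost):
    """Second-level LOO accuracy curve with one fixed ranking per fold."""
    n, p = Z.shape
    counts = list(range(p - 1, 0, -1))
    correct = {k: 0 for k in counts}
    valid = 0
    for j in range(n):
        tr = [t for t in range(n) if t != j]
        ytr = y[tr]
        if len(set(ytr.tolist())) < 2:
            continue
        valid += 1
        Ztr = Z[tr]
        w, _ = svc_hyperplane(Ztr, ytr, cost)
        order = np.argsort(np.abs(w), kind="stable")  # least relevant first
        for k in counts:
            keep = sorted(order[p - k:].tolist())
            wk, bk = svc_hyperplane(Ztr[:, keep], ytr, cost)
            pred = 1.0 if Z[j, keep] @ wk + bk >= 0 else -1.0
            if pred == y[j]:
                correct[k] += 1
    acc = {k: correct[k] / valid for k in counts}
    best = max(acc.values())
    return min(k for k in counts if acc[k] == best), acc


def naive_nested_loocv(X, y, age, sex, cost=1.0):
    """Per-fold (q, selected indices, prediction) of the full outer procedure."""
    n, p = X.shape
    out = []
    for i in range(n):
        tr = [t for t in range(n) if t != i]
        beta, mu, sd = _naive_fit_transforms(X[tr], age[tr], sex[tr])
        Z = _naive_apply(beta, mu, sd, X[tr], age[tr], sex[tr])
        q, _ = _naive_inner_q(Z, y[tr], cost)
        w, _ = svc_hyperplane(Z, y[tr], cost)
        order = np.argsort(np.abs(w), kind="stable")
        selected = order[::-1][:q].tolist()  # most discriminant first
        keep = sorted(selected)
        wq, bq = svc_hyperplane(Z[:, keep], y[tr], cost)
        z_new = _naive_apply(beta, mu, sd, X[i:i + 1], age[i:i + 1], sex[i:i + 1])[0]
        pred = 1.0 if z_new[keep] @ wq + bq >= 0 else -1.0
        out.append({"q": q, "selected": selected, "pred": pred})
    return out
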