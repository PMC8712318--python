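"""Least-absolute-deviation (median) regression.

Minimizes sum_i |y_i - x_i' beta| (quantile regression at tau = 0.5).
The solver is iteratively reweighted least squares (IRLS, the classic
smoothing w_i = 1 / max(|r_i|, eps)) followed by an optional vertex
polish: an LAD optimum always lies at a basic solution interpolating p
observations, so the polish performs a simplex-style descent over
interpolating bases (swap one basis observation at a time, move on
strict improvement).  On small problems the descent terminates at the
exact linear-programming optimum; on large ones a restricted polish
keeps the cost linear in n.

A batched IRLS (:func:`lad_fit_batch`) fits many bootstrap-replicate
designs simultaneously with einsum-batched normal equations; it skips
the polish, which is immaterial for bootstrap standard errors.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lad_objective", "lad_fit", "lad_fit_batch", "RankDeficientError"]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


def lad_objective(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    """Sum of absolute residuals."""
    return float(np.abs(y - X @ beta).sum())


def _check_rank(X: np.ndarray, column_names=None) -> None:
    n, p = X.shape
    if n <= p:
        raise RankDeficientError(
            f"need more observations ({n}) than parameters ({p})"
        )
    # pivoted QR flags the dependent columns by name
    _, r, piv = _qr_pivot(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        bad = sorted(piv[rank:].tolist())
        if column_names is not None:
            bad = [column_names[i] for i in bad]
        raise RankDeficientError(f"design matrix rank deficient; collinear columns: {bad}")


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def _irls(y, X, *, max_iter=60, tol=1e-12):
    """IRLS iterations for the LAD objective; returns the best beta seen."""
    scale = 1.0 + float(np.median(np.abs(y)))
    eps = 1e-10 * scale
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    best = beta
    best_obj = lad_objective(y, X, beta)
    for _ in range(max_iter):
        r = y - X @ beta
        w = 1.0 / np.maximum(np.abs(r), eps)
        Xw = X * w[:, None]
        A = Xw.T @ X
        b = Xw.T @ y
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        obj = lad_objective(y, X, beta)
        if obj < best_obj - 0.0:
            improved = best_obj - obj
            best, best_obj = beta, obj
            if improved < tol * (1.0 + best_obj):
                break
        else:
            break
    return best, best_obj


def _solve_basis(y, X, basis):
    try:
        return np.linalg.solve(X[basis], y[basis])
    except np.linalg.LinAlgError:
        return None


def _vertex_descent(y, X, beta, obj, *, candidates=None, max_rounds=200):
    """Simplex-style descent over p-point interpolating bases.

    ``candidates`` restricts which observations may enter the basis
    (None = all).  Moves to the best strictly improving neighbor basis;
    terminates at a basis none of whose single swaps improves -- on a
    nondegenerate LP that is the global optimum.
    """
    n, p = X.shape
    r = np.abs(y - X @ beta)
    basis = list(np.argsort(r)[:p])
    b0 = _solve_basis(y, X, basis)
    if b0 is not None:
        o0 = lad_objective(y, X, b0)
        if o0 < obj:
            beta, obj = b0, o0
    pool = range(n) if candidates is None else candidates
    for _ in range(max_rounds):
        best_swap = None
        best_obj = obj
        in_basis = set(basis)
        for i, out in enumerate(basis):
            for t in pool:
                if t in in_basis:
                    continue
                trial = basis.copy()
                trial[i] = t
                bt = _solve_basis(y, X, trial)
                if bt is None:
                    continue
                ot = lad_objective(y, X, bt)
                if ot < best_obj - 1e-13 * (1.0 + best_obj):
                    best_obj = ot
                    best_swap = (trial, bt)
        if best_swap is None:
            break
        basis, beta = best_swap[0], best_swap[1]
        obj = best_obj
    return beta, obj


def lad_fit(
    y: np.ndarray,
    X: np.ndarray,
    *,
    polish: str = "auto",
    column_names=None,
    max_iter: int = 60,
) -> np.ndarray:
    """Fit median regression coefficients.

    ``polish``:

    * ``"full"`` -- vertex descent over all observations (exact LP
      optimum on nondegenerate data; cost grows with n * p per round);
    * ``"restricted"`` -- descent restricted to the 4p observations with
      the smallest IRLS residuals (near-exact, linear in n);
    * ``"none"`` -- plain IRLS;
    * ``"auto"`` -- ``"full"`` when n * p <= 2,000 else ``"restricted"``.

    Raises :class:`RankDeficientError` on collinear designs, naming the
    offending columns when ``column_names`` is given.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _check_rank(X, column_names)
    n, p = X.shape
    shortcut = two_group_shortcut(y, X)
    if shortcut is not None:
        return shortcut
    beta, obj = _irls(y, X, max_iter=max_iter)
    if polish == "auto":
        polish = "full" if n * p <= 2000 else "restricted"
    if polish == "full":
        beta, obj = _vertex_descent(y, X, beta, obj)
    elif polish == "restricted":
        r = np.abs(y - X @ beta)
        cand = np.argsort(r)[: max(4 * p, 20)].tolist()
        beta, obj = _vertex_descent(y, X, beta, obj, candidates=cand, max_rounds=40)
    elif polish != "none":
        raise ValueError(f"unknown polish mode {polish!r}")
    return beta


def two_group_shortcut(y: np.ndarray, X: np.ndarray) -> np.ndarray | None:
    """Exact LAD solution for the intercept + binary-indicator design.

    With X = [1, g], g in {0, 1}, the objective separates into two
    location problems, so the optimum is (median(y | g=0),
    median(y | g=1) - median(y | g=0)).  Returns None when the design
    does not match.
    """
    if X.shape[1] != 2:
        return None
    if not np.all(X[:, 0] == 1.0):
        return None
    g = X[:, 1]
    if not np.isin(g, (0.0, 1.0)).all():
        return None
    mask = g == 1.0
    if not mask.any() or mask.all():
        return None
    m0 = float(np.median(y[~mask]))
    m1 = float(np.median(y[mask]))
    return np.array([m0, m1 - m0])


def bootstrap_two_group(
    y: np.ndarray, g: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate group-median-difference estimates for resampled rows.

    ``idx`` has shape (B, n); returns (estimates, valid) where replicates
    with an empty group are flagged invalid (to be dropped by the
    caller).  Group medians are computed with one sort per group by
    masking the other group's values to +inf.
    """
    yb = y[idx]
    gb = g[idx].astype(bool)
    B, n = yb.shape
    est = np.empty(B)
    valid = np.empty(B, dtype=bool)
    out = np.empty(B)
    for target, grp in ((0, ~gb), (1, gb)):
        counts = grp.sum(axis=1)
        ok = counts > 0
        masked = np.where(grp, yb, np.inf)
        masked.sort(axis=1)
        lo = np.maximum((counts - 1) // 2, 0)
        hi = counts // 2
        med = 0.5 * (
            np.take_along_axis(masked, lo[:, None], axis=1)[:, 0]
            + np.take_along_axis(masked, np.minimum(hi, n - 1)[:, None], axis=1)[:, 0]
        )
        if target == 0:
            est = med
            valid = ok
        else:
            out = med - est
            valid &= ok
    return out, valid


def lad_fit_batch(
    Y: np.ndarray,
    X3: np.ndarray,
    *,
    max_iter: int = 50,
    ridge: float = 1e-9,
    beta0: np.ndarray | None = None,
    chunk: int = 400,
) -> np.ndarray:
    """Batched IRLS median regression.

    ``Y`` has shape (B, n) and ``X3`` (B, n, p); returns (B, p)
    coefficients.  ``beta0`` warm-starts every batch member (e.g. the
    full-data fit when the members are bootstrap resamples), which cuts
    the iterations needed roughly in half.  A tiny ridge proportional to
    the column scale keeps near-singular replicate designs solvable;
    callers are expected to have dropped degenerate replicates
    beforehand.  Large batches are processed in ``chunk``-sized pieces
    to stay cache-friendly.
    """
    Y = np.asarray(Y, dtype=float)
    X3 = np.asarray(X3, dtype=float)
    B = X3.shape[0]
    if B > chunk:
        return np.vstack(
            [
                lad_fit_batch(
                    Y[i : i + chunk], X3[i : i + chunk],
                    max_iter=max_iter, ridge=ridge, beta0=beta0, chunk=chunk,
                )
                for i in range(0, B, chunk)
            ]
        )
    return _irls_batch(Y, X3, max_iter=max_iter, ridge=ridge, beta0=beta0)


def _irls_batch(Y, X3, *, max_iter, ridge, beta0):
    B, n, p = X3.shape
    scale = 1.0 + np.median(np.abs(Y), axis=1)  # (B,)
    eps = 1e-10 * scale[:, None]
    Xt = np.ascontiguousarray(X3.transpose(0, 2, 1))
    XtX = Xt @ X3
    lam = ridge * np.trace(XtX, axis1=1, axis2=2)[:, None, None] / p
    eye = np.eye(p)[None]
    if beta0 is not None:
        beta = np.broadcast_to(np.asarray(beta0, dtype=float), (B, p)).copy()
    else:
        rhs0 = Xt @ Y[:, :, None]
        beta = np.linalg.solve(XtX + lam * eye, rhs0)[..., 0]
    for _ in range(max_iter):
        r = Y - (X3 @ beta[:, :, None])[..., 0]
        w = 1.0 / np.maximum(np.abs(r), eps)
        Xw = X3 * w[:, :, None]
        A = Xt @ Xw
        rhs = Xt @ (w * Y)[:, :, None]
        new = np.linalg.solve(A + lam * eye, rhs)[..., 0]
        if np.allclose(new, beta, rtol=1e-9, atol=1e-12):
            beta = new
            break
        beta = new
    return beta
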