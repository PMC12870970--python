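"""Penalized cubic-spline smoothing engine with REML smoothness selection.

Implements the additive model

    y = b0 + covariates . g + f(age) + e,    e ~ N(0, s^2)

where f is a cubic B-spline of basis dimension ``k`` (default 5) penalized by
its integrated squared second derivative, subject to a sum-to-zero centering
constraint over the observed ages. The penalized smooth is recast as a mixed
model: the penalty null space (the linear-in-age direction) joins the fixed
effects and the range space becomes i.i.d. random effects with variance
``s_b^2 = r * s^2``. The ratio ``r`` is chosen by restricted maximum
likelihood on a log-spaced grid, evaluated with O(k^3) algebra per grid point
so that thousands of response vectors sharing one design are fitted together.

With the second-derivative penalty, ``r -> 0`` shrinks f to a straight line,
so the smooth's effective degrees of freedom (edf) tend to 1 on linear data
and are bounded by ``k - 1`` above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.interpolate import BSpline

__all__ = ["SmoothEngine", "SmoothBatchFit", "build_spline_basis", "second_derivative_penalty"]

_LOG_R_GRID = np.linspace(-18.0, 18.0, 91)  # natural-log grid of variance ratios
_DEGENERATE_TOL = 1e-12


def _knot_vector(age: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """Clamped knot vector with ``k - degree - 1`` interior knots at age quantiles."""
    lo, hi = float(np.min(age)), float(np.max(age))
    n_interior = k - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(age), qs)
        # keep knots strictly inside the boundary to avoid singular bases
        interior = np.clip(interior, lo + 1e-8 * (hi - lo), hi - 1e-8 * (hi - lo))
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def build_spline_basis(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Evaluate the B-spline design matrix at ``x`` (columns = basis functions)."""
    x = np.clip(np.asarray(x, dtype=float), knots[0], knots[-1])
    k = len(knots) - degree - 1
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()[:, :k]


def second_derivative_penalty(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Exact integral of products of basis second derivatives.

    For cubic splines the second derivatives are piecewise linear, so 2-point
    Gauss-Legendre quadrature on each inter-knot interval is exact.
    """
    k = len(knots) - degree - 1
    breaks = np.unique(knots)
    gl_x, gl_w = np.polynomial.legendre.leggauss(2)
    S = np.zeros((k, k))
    coefs = np.eye(k)
    splines = [BSpline(knots, coefs[i], degree).derivative(2) for i in range(k)]
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        pts = mid + half * gl_x
        d2 = np.array([sp(pts) for sp in splines])  # k x 2
        S += half * (d2 * gl_w) @ d2.T
    return S


@dataclass
class SmoothBatchFit:
    """Vectorized fit results for a batch of response vectors on one design."""

    coefs: np.ndarray          # (m, p + q) coefficients in the working basis
    fitted: np.ndarray         # (m, n)
    rss: np.ndarray            # (m,)
    edf_smooth: np.ndarray     # (m,) edf of the age smooth incl. its null space
    edf_total: np.ndarray      # (m,) parametric df + random-effect edf
    loglik: np.ndarray         # (m,) Gaussian ML log-likelihood
    bic: np.ndarray            # (m,) -2 loglik + log(n) * (edf_total + 1)
    smooth_p: np.ndarray       # (m,) approximate F-test p-value of the smooth
    r_hat: np.ndarray          # (m,) selected variance ratio
    degenerate: np.ndarray     # (m,) bool: (near-)zero response variance


class SmoothEngine:
    """Shared-design fitter: build once per (age, covariates), fit many CpGs."""

    def __init__(
        self,
        age: np.ndarray,
        covariate_design: np.ndarray | None = None,
        k: int = 5,
        degree: int = 3,
    ):
        age = np.asarray(age, dtype=float)
        n = age.size
        if np.unique(age).size < k:
            raise ValueError(
                f"need at least k={k} distinct ages for a basis of dimension {k}; "
                f"got {np.unique(age).size}"
            )
        self.age = age
        self.k = k
        self.degree = degree
        self.knots = _knot_vector(age, k, degree)

        B = build_spline_basis(age, self.knots, degree)  # n x k
        S = second_derivative_penalty(self.knots, degree)

        # sum-to-zero constraint over observed ages
        C = B.mean(axis=0, keepdims=True)  # 1 x k
        _, _, vt = np.linalg.svd(C)
        Zc = vt[1:].T  # k x (k-1)
        Bt = B @ Zc
        St = Zc.T @ S @ Zc

        # split penalty null space (linear trend) from range space
        d, U = np.linalg.eigh(St)
        order = np.argsort(d)[::-1]
        d, U = d[order], U[:, order]
        null_mask = d <= max(d.max(), 1.0) * 1e-10
        q = int((~null_mask).sum())
        d_pos = d[:q]
        self._W = np.hstack([U[:, q:], U[:, :q] / np.sqrt(d_pos)])  # maps [null|rand] coefs
        X_null = Bt @ U[:, q:]          # n x (k-1-q); 1 column for the 2nd-deriv penalty
        Z = Bt @ (U[:, :q] / np.sqrt(d_pos))  # n x q random-effect columns

        cov = (
            np.asarray(covariate_design, dtype=float).reshape(n, -1)
            if covariate_design is not None and np.size(covariate_design)
            else np.empty((n, 0))
        )
        X_f = np.hstack([np.ones((n, 1)), cov, X_null])
        self.n = n
        self.p = X_f.shape[1]
        self.q = Z.shape[1]
        self.n_null = X_null.shape[1]
        self._X = X_f
        self._Z = Z
        self._XtX = X_f.T @ X_f
        self._ZtZ = Z.T @ Z
        self._ZtX = Z.T @ X_f
        self._T = np.hstack([X_f, Z])
        self._TtT = self._T.T @ self._T
        # covariates-only design for the smooth-term F test
        X0 = X_f[:, : self.p - self.n_null]
        self._X0 = X0
        self._X0_pinv = np.linalg.pinv(X0)

    # ------------------------------------------------------------------ #

    def _reml_scores(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """-2 * restricted log-likelihood (up to constants) on the ratio grid.

        Returns (scores[grid, m], cross_products) for reuse in the final fit.
        """
        n, p, q = self.n, self.p, self.q
        A1 = self._X.T @ Y.T  # p x m
        A2 = self._Z.T @ Y.T  # q x m
        yty = np.einsum("ij,ij->i", Y, Y)
        scores = np.empty((_LOG_R_GRID.size, Y.shape[0]))
        Iq = np.eye(q)
        for g, log_r in enumerate(_LOG_R_GRID):
            r = np.exp(log_r)
            M = Iq + r * self._ZtZ
            cM = linalg.cho_factor(M, lower=True)
            logdetV = 2.0 * np.log(np.diag(cM[0])).sum()
            K = r * linalg.cho_solve(cM, Iq)
            F = self._XtX - self._ZtX.T @ K @ self._ZtX
            cF = linalg.cho_factor(F, lower=True)
            logdetF = 2.0 * np.log(np.diag(cF[0])).sum()
            KA2 = K @ A2
            a = A1 - self._ZtX.T @ KA2
            qyy = yty - np.einsum("ij,ij->j", A2, KA2)
            yPy = qyy - np.einsum("ij,ij->j", a, linalg.cho_solve(cF, a))
            yPy = np.maximum(yPy, _DEGENERATE_TOL)
            scores[g] = logdetV + logdetF + (n - p) * np.log(yPy)
        return scores, (A1, A2, yty)

    def fit_batch(self, Y: np.ndarray) -> SmoothBatchFit:
        """Fit every row of ``Y`` (m x n) by penalized least squares with REML ratio."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        m, n = Y.shape
        if n != self.n:
            raise ValueError(f"response length {n} != design length {self.n}")
        p, q = self.p, self.q

        var_y = Y.var(axis=1)
        degenerate = var_y <= _DEGENERATE_TOL

        scores, (A1, A2, yty) = self._reml_scores(Y)
        best = scores.argmin(axis=0)
        r_hat = np.exp(_LOG_R_GRID[best])

        Tty = np.vstack([A1, A2])  # (p+q) x m
        coefs = np.empty((m, p + q))
        edf_rand = np.empty(m)
        for g in np.unique(best):
            idx = np.flatnonzero(best == g)
            r = np.exp(_LOG_R_GRID[g])
            P = np.zeros(p + q)
            P[p:] = 1.0 / r
            Mats = self._TtT + np.diag(P)
            cM = linalg.cho_factor(Mats, lower=True)
            coefs[idx] = linalg.cho_solve(cM, Tty[:, idx]).T
            H = linalg.cho_solve(cM, self._TtT)  # hat matrix in coefficient space
            edf_rand[idx] = np.trace(H[p:, p:])

        fitted = coefs @ self._T.T
        rss = yty - 2 * np.einsum("ij,ji->i", coefs, Tty) + np.einsum(
            "ij,jk,ik->i", coefs, self._TtT, coefs
        )
        rss = np.maximum(rss, 0.0)
        edf_smooth = self.n_null + edf_rand
        edf_total = p + edf_rand

        sigma2 = np.maximum(rss / n, _DEGENERATE_TOL)
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + rss / (n * sigma2))
        bic = -2 * loglik + np.log(n) * (edf_total + 1)

        # approximate significance of the whole age smooth: penalized fit vs
        # covariates-only fit, F with (edf_smooth, n - edf_total) df
        res0 = Y - (Y @ self._X0_pinv.T) @ self._X0.T
        rss0 = np.einsum("ij,ij->i", res0, res0)
        df2 = np.maximum(n - edf_total, 1.0)
        denom = np.maximum(rss / df2, _DEGENERATE_TOL)
        fstat = np.maximum((rss0 - rss) / np.maximum(edf_smooth, 1e-8), 0.0) / denom
        smooth_p = stats.f.sf(fstat, edf_smooth, df2)
        smooth_p = np.where(degenerate, 1.0, smooth_p)

        return SmoothBatchFit(
            coefs=coefs,
            fitted=fitted,
            rss=rss,
            edf_smooth=edf_smooth,
            edf_total=edf_total,
            loglik=loglik,
            bic=bic,
            smooth_p=smooth_p,
            r_hat=r_hat,
            degenerate=degenerate,
        )

    # ------------------------------------------------------------------ #

    def predict(
        self,
        coefs: np.ndarray,
        new_age: np.ndarray,
        reference_covariates: np.ndarray | None = None,
    ) -> np.ndarray:
        """Evaluate fitted curves at ``new_age`` with covariates held fixed.

        ``reference_covariates`` is one row of covariate values (numeric
        medians / reference level dummies); omitted when the design has none.
        """
        coefs = np.atleast_2d(coefs)
        new_age = np.asarray(new_age, dtype=float)
        B_new = build_spline_basis(new_age, self.knots, self.degree)
        Zc_W = self._smooth_map()
        smooth_cols = np.hstack(
            [coefs[:, self.p - self.n_null : self.p], coefs[:, self.p :]]
        )  # null-space then random coefficients, matching self._W column order
        curves = smooth_cols @ (B_new @ Zc_W).T
        intercept = coefs[:, 0]
        offset = intercept.copy()
        n_cov = self.p - self.n_null - 1
        if n_cov:
            ref = (
                np.zeros(n_cov)
                if reference_covariates is None
                else np.asarray(reference_covariates, dtype=float).ravel()
            )
            if ref.size != n_cov:
                raise ValueError(f"expected {n_cov} reference covariate values, got {ref.size}")
            offset = offset + coefs[:, 1 : 1 + n_cov] @ ref
        return curves + offset[:, None]

    def _smooth_map(self) -> np.ndarray:
        """Map from constrained-basis coefficients back to the B-spline basis."""
        # recompute Zc from the stored pieces: W already folds in the eigen-split
        B = build_spline_basis(self.age, self.knots, self.degree)
        C = B.mean(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(C)
        return vt[1:].T @ self._W
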