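"""Penalized-spline additive models with null-space shrinkage.

Each 1-D smooth is a low-rank P-spline: a cubic B-spline basis on uniform
knots with a second-difference wiggliness penalty, plus a separate ridge
penalty on the penalty's null space (the constant/linear part).  The second
"double penalty" lets a term shrink to exactly nothing, which performs
automatic variable selection during fitting.  Terms are centered (sum of the
fitted contribution over training points is zero) by absorbing the
sum-to-zero constraint into the basis, which also makes the intercept
orthogonal to every term.

Smoothing weights are chosen either by GCV minimized with a bounded
quasi-Newton on the log-penalties from a few fixed restarts (default), or by
a REML-like criterion via extended Fellner-Schall multiplicative updates
("efs"), which costs one linear solve per iteration and is the choice for
subsample-heavy loops.

Per-term effective degrees of freedom (EDF) are the trace of the term's
block of (X'X + S)^-1 X'X; p-values are Wald tests of the term's penalized
coefficients against zero using the Bayesian covariance (X'X + S)^-1 s^2
with reference degrees of freedom equal to the rounded EDF — an approximate
recipe, adequate for ranking terms during elimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import interpolate, linalg, optimize, stats

from .config import FatiguecastError, ParameterError, RunConfig

_LAM_MIN, _LAM_MAX = 1e-8, 1e10
_SHAPES = ("rise", "fall", "arch", "dip", "flat")
SHAPE_SYMBOLS = {"rise": "╱", "fall": "╲", "arch": "⌢",
                 "dip": "⌣", "flat": "∼"}


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------

class SmoothBasis:
    """Centered spline basis for one term with its two penalty matrices.

    Attributes
    ----------
    S_w_raw, S_n_raw
        Wiggliness and null-space penalties in the raw basis (rank k-2 and
        rank 2 for a 1-D second-order penalty).
    S_w, S_n
        The same penalties after constraint absorption; their sum at any
        positive weights is positive definite, so a term can be shrunk away
        entirely.
    """

    def __init__(self, x, k: int = 10, kind: str = "bspline",
                 name: str = ""):
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ParameterError(f"term {name!r}: no finite values")
        distinct = np.unique(x)
        if distinct.size < 2:
            raise FatiguecastError(
                f"term {name!r}: constant column (should be masked upstream)")
        if distinct.size < k:
            k_new = max(4, int(distinct.size))
            warnings.warn(f"term {name!r}: only {distinct.size} distinct "
                          f"values; basis dimension reduced {k} -> {k_new}")
            k = k_new
        if k < 4:
            raise ParameterError("basis dimension must be >= 4")
        self.name, self.k, self.kind = name, k, kind
        self.xmin = float(x.min())
        self.xmax = float(x.max())
        # bulk range for partial-effect interpretation: spline behavior
        # outside the central 95% of the data is boundary extrapolation
        self.q_lo, self.q_hi = (float(v) for v in
                                np.quantile(x, [0.025, 0.975]))

        if kind == "bspline":
            n_interior = k - 4
            interior = np.linspace(self.xmin, self.xmax, n_interior + 2)[1:-1]
            self.knots = np.concatenate((
                np.repeat(self.xmin, 4), interior, np.repeat(self.xmax, 4)))
            B = self._raw_design(x)
            D2 = np.diff(np.eye(k), n=2, axis=0)
            S_w = D2.T @ D2
        elif kind == "poly":
            # Legendre polynomials of degree 1..k-1 on [-1, 1]; wiggliness =
            # ridge on degree >= 2 so the null space is again linear.
            B = self._raw_design(x)
            S_w = np.diag(np.r_[0.0, np.ones(k - 2)])
        else:
            raise ParameterError(f"unknown basis kind {kind!r}")

        # null-space penalty: projector onto the wiggliness null space
        w_eig, w_vec = linalg.eigh(S_w)
        null = w_eig < max(w_eig.max(), 1.0) * 1e-10
        U0 = w_vec[:, null]
        S_n = U0 @ U0.T

        # absorb the sum-to-zero constraint: Z spans {b : mean(B b) = 0}
        m = B.mean(axis=0)
        self.Z = linalg.null_space(m[None, :])
        self.S_w_raw, self.S_n_raw = S_w, S_n
        S_w_c = self.Z.T @ S_w @ self.Z
        S_n_c = self.Z.T @ S_n @ self.Z
        # unit-Frobenius scaling keeps smoothing weights comparable
        self._w_scale = np.linalg.norm(S_w_c) or 1.0
        self._n_scale = np.linalg.norm(S_n_c) or 1.0
        self.S_w = S_w_c / self._w_scale
        self.S_n = S_n_c / self._n_scale

    def _raw_design(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.xmin, self.xmax)
        if self.kind == "poly":
            span = self.xmax - self.xmin
            u = 2.0 * (x - self.xmin) / span - 1.0
            return legendre.legvander(u, self.k - 1)[:, 1:]
        return interpolate.BSpline.design_matrix(
            x, self.knots, 3, extrapolate=False).toarray()

    def design(self, x) -> np.ndarray:
        """Centered design columns for ``x`` (values clamped to the training
        range)."""
        return self._raw_design(x) @ self.Z

    @property
    def dim(self) -> int:
        return self.Z.shape[1]


def build_smooth_basis(x, k: int = 10, kind: str = "bspline",
                       name: str = "") -> SmoothBasis:
    """Build a centered penalized-spline basis with its wiggliness and
    null-space (shrinkage) penalty matrices."""
    return SmoothBasis(x, k=k, kind=kind, name=name)


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class SmoothTermFit:
    name: str
    k: int
    coef: np.ndarray
    lambda_wiggle: float
    lambda_null: float
    edf: float
    p_value: float


@dataclass
class GAMFit:
    intercept: float
    terms: list[SmoothTermFit]
    sigma2: float
    edf_total: float
    criterion: str
    criterion_value: float
    n: int
    bases: dict = field(repr=False, default_factory=dict)

    def term(self, name: str) -> SmoothTermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def lambdas(self) -> np.ndarray:
        """Interleaved (wiggliness, null) penalty weights per term."""
        return np.array([v for t in self.terms
                         for v in (t.lambda_wiggle, t.lambda_null)])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept, dtype=float)
        for t in self.terms:
            out += self.bases[t.name].design(X[t.name].to_numpy()) @ t.coef
        return out


def term_edf(fit: GAMFit, name: str) -> float:
    return fit.term(name).edf


def term_pvalue(fit: GAMFit, name: str) -> float:
    return fit.term(name).p_value


@dataclass(frozen=True)
class EffectCurve:
    """Partial effect of one feature on the latent (normalized) response."""

    name: str
    grid: np.ndarray
    values: np.ndarray


# ---------------------------------------------------------------------------
# the additive design
# ---------------------------------------------------------------------------

class GamDesign:
    """Assembled design for a fixed term set, reusable across row subsets.

    Bases (knots, constraint, penalty scaling) are built once from the full
    data so that subsample and cross-validation fits share a common
    parameterization; ``fit`` then operates on any row subset.
    """

    def __init__(self, X: pd.DataFrame, y, terms: list[str],
                 config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.terms = list(terms)
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        if np.isnan(self.y).any():
            raise ParameterError("response contains missing values")
        self.bases: dict[str, SmoothBasis] = {}
        blocks = [np.ones((n, 1))]
        self.slices: dict[str, slice] = {}
        pos = 1
        for name in self.terms:
            col = X[name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ParameterError(f"term {name!r} contains missing values")
            basis = SmoothBasis(col, k=self.config.basis_dim, name=name)
            self.bases[name] = basis
            blocks.append(basis.design(col))
            self.slices[name] = slice(pos, pos + basis.dim)
            pos += basis.dim
        self.X = np.concatenate(blocks, axis=1)
        self.M = pos

    # -- core linear algebra ----------------------------------------------

    def _penalty(self, lam: np.ndarray) -> np.ndarray:
        S = np.zeros((self.M, self.M))
        for j, name in enumerate(self.terms):
            sl = self.slices[name]
            b = self.bases[name]
            S[sl, sl] = lam[2 * j] * b.S_w + lam[2 * j + 1] * b.S_n
        return S

    def _solve(self, XtX, Xty, yty, n, lam):
        A = XtX + self._penalty(lam)
        try:
            c, low = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError as exc:
            raise FatiguecastError(
                f"rank-deficient penalized design (terms {self.terms})"
            ) from exc
        beta = linalg.cho_solve((c, low), Xty)
        Ainv = linalg.cho_solve((c, low), np.eye(self.M))
        F_diag = np.einsum("ij,ji->i", Ainv, XtX)
        rss = float(max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 1e-300))
        return beta, Ainv, F_diag, rss

    def _edf_by_term(self, F_diag) -> np.ndarray:
        return np.array([F_diag[self.slices[t]].sum() for t in self.terms])

    # -- smoothing selection ----------------------------------------------

    def _fit_efs(self, XtX, Xty, yty, n, lam0=None):
        """Extended Fellner-Schall multiplicative updates for a REML-like
        criterion; one Cholesky per iteration."""
        p = len(self.terms)
        lam = np.ones(2 * p) if lam0 is None else np.asarray(lam0, float).copy()
        pen_parts = []
        for name in self.terms:
            b = self.bases[name]
            pen_parts += [(self.slices[name], b.S_w), (self.slices[name], b.S_n)]
        maxiter = 200 if lam0 is None else 40
        for _ in range(maxiter):
            beta, Ainv, F_diag, rss = self._solve(XtX, Xty, yty, n, lam)
            edf_total = float(F_diag.sum())
            sigma2 = rss / max(n - edf_total, 1.0)
            new = lam.copy()
            for j in range(2 * p):
                sl, S_j = pen_parts[j]
                pair = j // 2
                sl2, S_w = pen_parts[2 * pair]
                _, S_n = pen_parts[2 * pair + 1]
                block = lam[2 * pair] * S_w + lam[2 * pair + 1] * S_n
                try:
                    tr_pinv = np.trace(linalg.solve(block, S_j,
                                                    assume_a="pos"))
                except linalg.LinAlgError:
                    tr_pinv = np.trace(np.linalg.pinv(block) @ S_j)
                num = max(tr_pinv - np.trace(Ainv[sl, sl] @ S_j), 0.0)
                b_j = beta[sl]
                den = float(b_j @ S_j @ b_j) / sigma2
                if den <= 1e-12 or num <= 1e-12:
                    factor = 100.0 if den <= 1e-12 else 0.01
                else:
                    factor = np.clip(num / den, 0.01, 100.0)
                new[j] = np.clip(lam[j] * factor, _LAM_MIN, _LAM_MAX)
            if np.max(np.abs(np.log(new) - np.log(lam))) < 3e-3:
                lam = new
                break
            lam = new
        return lam

    def _gcv(self, XtX, Xty, yty, n, lam):
        _, _, F_diag, rss = self._solve(XtX, Xty, yty, n, lam)
        edf_total = float(F_diag.sum())
        return n * rss / max(n - edf_total, 1e-6) ** 2

    def _fit_gcv(self, XtX, Xty, yty, n):
        p2 = 2 * len(self.terms)
        starts = [np.zeros(p2), np.full(p2, 5.0), np.full(p2, -5.0),
                  np.full(p2, 10.0)]
        best, best_val = None, np.inf
        bounds = [(np.log(_LAM_MIN), np.log(_LAM_MAX))] * p2
        for rho0 in starts[:max(1, self.config.optimizer_restarts)]:
            res = optimize.minimize(
                lambda rho: self._gcv(XtX, Xty, yty, n, np.exp(rho)),
                rho0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.config.optimizer_maxiter,
                         "ftol": 1e-10})
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        return np.exp(best)

    # -- public fitting API -------------------------------------------------

    def fit(self, rows=None, lambdas=None, method: str | None = None,
            lam0=None) -> GAMFit:
        """Fit on a row subset (all rows by default).

        ``lambdas`` (length 2 * n_terms, wiggliness/null interleaved) fixes
        the penalties; otherwise they are selected by ``method`` ("gcv" or
        "efs", defaulting to the config's criterion).  ``lam0`` warm-starts
        the EFS updates (pass a reference fit's penalties when refitting the
        same design on many row subsets); it is an explicit argument so fits
        stay pure functions of their inputs.
        """
        if rows is None:
            Xs, ys = self.X, self.y
        else:
            Xs, ys = self.X[rows], self.y[rows]
        # the double penalty keeps the system positive definite even when
        # the basis dimension approaches n, so only a bare minimum applies
        # here; the public fit_gam wrapper enforces 10 rows per term
        n = ys.size
        if self.terms and n < 10:
            raise FatiguecastError(f"only {n} rows to fit {len(self.terms)} "
                                   "terms (need >= 10)")
        XtX = Xs.T @ Xs
        Xty = Xs.T @ ys
        yty = float(ys @ ys)

        method = method or self.config.smooth_criterion
        if lambdas is not None:
            lam = np.asarray(lambdas, dtype=float)
        elif not self.terms:
            lam = np.zeros(0)
        elif method == "efs":
            lam = self._fit_efs(XtX, Xty, yty, n, lam0=lam0)
        else:
            lam = self._fit_gcv(XtX, Xty, yty, n)

        beta, Ainv, F_diag, rss = self._solve(XtX, Xty, yty, n, lam)
        edf_terms = self._edf_by_term(F_diag)
        edf_total = float(F_diag.sum())
        sigma2 = rss / max(n - edf_total, 1.0)
        crit = n * rss / max(n - edf_total, 1e-6) ** 2

        terms = []
        for j, name in enumerate(self.terms):
            sl = self.slices[name]
            p_val = _term_pvalue_fspace(Xs[:, sl], beta[sl],
                                        Ainv[sl, sl] * sigma2,
                                        edf_terms[j], n, edf_total)
            terms.append(SmoothTermFit(
                name=name, k=self.bases[name].k, coef=beta[sl].copy(),
                lambda_wiggle=float(lam[2 * j]) if lam.size else 0.0,
                lambda_null=float(lam[2 * j + 1]) if lam.size else 0.0,
                edf=float(edf_terms[j]), p_value=p_val))
        return GAMFit(intercept=float(beta[0]), terms=terms, sigma2=sigma2,
                      edf_total=edf_total, criterion=method,
                      criterion_value=float(crit), n=n, bases=self.bases)


def _term_pvalue_fspace(B, b, V, edf, n, edf_total) -> float:
    """Wald test of a smooth term against zero on the scale of its fitted
    values (f = B b), using the rank-r pseudo-inverse of the Bayesian
    covariance of f, with r = rounded EDF (at least 1).

    Testing in function space rather than coefficient space keeps power
    when the null-space shrinkage penalty concentrates the fit in heavily
    penalized directions; the eigen-system of cov(f) = B V B' is computed
    on the (small) coefficient side.
    """
    d = b.size
    r = int(np.clip(round(edf), 1, d))
    # symmetric factor of V, then eigvals of cov(f) via the d x d problem
    wV, UV = linalg.eigh(V)
    wV = np.clip(wV, 0.0, None)
    R = UV * np.sqrt(wV)             # V = R R'
    G = B @ R                        # cov(f) = G G'
    M = G.T @ G
    w, U = linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    keep = w[:r] > max(w[0], 1e-300) * 1e-10
    w, U = w[:r][keep], U[:, :r][:, keep]
    if w.size == 0:
        return 1.0
    # with eigenpairs (w_i, v_i = G u_i / sqrt(w_i)) of cov(f) = G G':
    # T = sum_i (v_i' f)^2 / w_i = sum_i (u_i' G' f)^2 / w_i^2
    f = B @ b
    proj = (G @ U).T @ f / w
    T = float(proj @ proj)
    dfe = max(n - edf_total, 1.0)
    return float(stats.f.sf(T / r, r, dfe))


def fit_gam(X: pd.DataFrame, y, terms: list[str],
            config: RunConfig | None = None, lambdas=None,
            method: str | None = None) -> GAMFit:
    """Fit an additive model with the given smooth terms.

    ``X`` must be complete (no missing entries) on the listed terms, with at
    least 10 rows per term.
    """
    config = config or RunConfig()
    y = np.asarray(y, dtype=float)
    if terms and y.size < 10 * len(terms):
        raise FatiguecastError(
            f"{y.size} rows for {len(terms)} terms (need >= 10 per term)")
    return GamDesign(X, y, terms, config).fit(lambdas=lambdas, method=method)


# ---------------------------------------------------------------------------
# partial effects and shape labels
# ---------------------------------------------------------------------------

def partial_effect(fit: GAMFit, name: str, grid=None,
                   n_grid: int = 101, full_range: bool = False
                   ) -> EffectCurve:
    """The term's contribution to the latent response over a feature grid.

    The default grid spans the central 95% of the training values: the
    spline's behavior beyond that is boundary extrapolation supported by a
    handful of points and would otherwise dominate shape classification.
    Pass ``full_range=True`` (or an explicit grid) for the whole range.
    """
    t = fit.term(name)
    basis = fit.bases[name]
    if grid is None:
        if full_range:
            grid = np.linspace(basis.xmin, basis.xmax, n_grid)
        else:
            grid = np.linspace(basis.q_lo, basis.q_hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    return EffectCurve(name=name, grid=grid, values=basis.design(grid) @ t.coef)


def classify_shape(curve: EffectCurve, rise_tol: float = 0.1,
                   flat_tol: float = 0.05) -> str:
    """Label a partial-effect curve: rise, fall, arch (rise-then-fall), dip
    (fall-then-rise), or flat.

    ``rise_tol`` is the minimum total movement (in response units) for a
    monotone or single-extremum label; curves with overall range below
    ``flat_tol`` are flat.  Monotonicity tolerates reversals up to 5% of the
    curve's range.
    """
    v = np.asarray(curve.values, dtype=float)
    rng = float(v.max() - v.min())
    if rng < flat_tol:
        return "flat"
    d = np.diff(v)
    eps = 0.05 * rng
    if np.all(d >= -eps) and v[-1] - v[0] >= rise_tol:
        return "rise"
    if np.all(d <= eps) and v[0] - v[-1] >= rise_tol:
        return "fall"
    i_max, i_min = int(np.argmax(v)), int(np.argmin(v))
    if 0 < i_max < v.size - 1:
        up, down = v[i_max] - v[0], v[i_max] - v[-1]
        if (np.all(d[:i_max] >= -eps) and np.all(d[i_max:] <= eps)
                and min(up, down) >= rise_tol):
            return "arch"
    if 0 < i_min < v.size - 1:
        down, up = v[0] - v[i_min], v[-1] - v[i_min]
        if (np.all(d[:i_min] <= eps) and np.all(d[i_min:] >= -eps)
                and min(up, down) >= rise_tol):
            return "dip"
    return "flat"
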