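"""Penalized-spline binomial logistic additive models.

The model is a logistic GAM for grouped binomial counts: for month ``i`` with
``total_i`` births of which ``girls_i`` are girls,

    girls_i ~ Binomial(total_i, p_i),    logit p_i = X_i beta,

where the design contains parametric columns (intercept, distributed-lag
blocks) and penalized spline smooths.  Each smooth carries a roughness penalty
and, optionally, a null-space shrinkage penalty, every penalty with its own
smoothing parameter ``lambda``.  Coefficients are estimated by penalized
iteratively reweighted least squares (PIRLS); smoothing parameters by
minimising a Laplace-approximate REML criterion (or GCV) over ``log lambda``.

Per-term effective degrees of freedom are traces of the corresponding block of
``(X'WX + S_lambda)^{-1} X'WX``; the Bayesian coefficient covariance
``(X'WX + S_lambda)^{-1}`` backs Wald intervals, smooth-term tests and
pointwise confidence bands for effect curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, xlogy
from scipy.stats import chi2, norm

from .splines import (
    SmoothTermSpec,
    absorb_sum_to_zero,
    cr_basis,
    cyclic_cr_basis,
    nullspace_penalty,
    place_knots,
)

__all__ = ["GamModel", "GamFit", "GamConvergenceError", "binomial_deviance"]

PIRLS_TOL = 1e-8
PIRLS_MAXIT = 200
LOGLAM_LIM = 18.0


class GamConvergenceError(RuntimeError):
    """Raised when the smoothing-parameter optimizer fails outright."""


def binomial_deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    """Deviance of grouped binomial counts ``y`` of ``n`` at probabilities ``mu``."""
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    d = xlogy(y, y) - xlogy(y, n * mu) + xlogy(n - y, n - y) - xlogy(n - y, n * (1.0 - mu))
    return float(2.0 * d.sum())


@dataclass
class _Term:
    name: str
    kind: str                      # "parametric" | "smooth"
    start: int
    stop: int
    penalties: list[np.ndarray] = field(default_factory=list)
    predictor: Callable[[np.ndarray], np.ndarray] | None = None  # grid -> design block
    x_range: tuple[float, float] | None = None
    spec: SmoothTermSpec | None = None

    @property
    def size(self) -> int:
        return self.stop - self.start


class GamModel:
    """Design builder for a binomial logistic additive model."""

    def __init__(self) -> None:
        self._blocks: list[np.ndarray] = []
        self.terms: list[_Term] = []
        self._p = 0

    # ------------------------------------------------------------------ build
    def add_intercept(self) -> "GamModel":
        return self.add_parametric("intercept", None)

    def add_parametric(self, name: str, columns: np.ndarray | None) -> "GamModel":
        """Add unpenalized columns; ``None`` adds an all-ones intercept column
        whose length is resolved when the response is supplied."""
        if columns is None:
            self.terms.append(_Term(name, "parametric", self._p, self._p + 1))
            self._blocks.append(np.empty((0, 1)))
            self._p += 1
            return self
        M = np.atleast_2d(np.asarray(columns, dtype=float))
        if M.shape[0] == 1 and M.shape[1] != 1:
            M = M.T
        self.terms.append(_Term(name, "parametric", self._p, self._p + M.shape[1]))
        self._blocks.append(M)
        self._p += M.shape[1]
        return self

    def add_linear(self, name: str, x: np.ndarray) -> "GamModel":
        return self.add_parametric(name, np.asarray(x, dtype=float).reshape(-1, 1))

    def add_smooth(
        self,
        name: str,
        x: np.ndarray,
        k: int = 10,
        cyclic: bool = False,
        shrinkage: bool = True,
        period: float | None = None,
    ) -> "GamModel":
        """Add a centred penalized spline smooth of covariate ``x``."""
        spec = SmoothTermSpec(name=name, k=k, cyclic=cyclic, shrinkage=shrinkage, period=period)
        x = np.asarray(x, dtype=float)
        if cyclic:
            lo = float(np.min(x))
            knots = lo + np.arange(spec.k) * (spec.period / spec.k)
            X, S = cyclic_cr_basis(x, knots, spec.period)
            basis = lambda g, kn=knots, per=spec.period: cyclic_cr_basis(np.asarray(g, float), kn, per)[0]
        else:
            knots = place_knots(x, spec.k)
            X, S = cr_basis(x, knots)
            basis = lambda g, kn=knots: cr_basis(np.asarray(g, float), kn)[0]
        pens = [S]
        if shrinkage:
            pens.append(nullspace_penalty(S))
        Xz, Sz, Z = absorb_sum_to_zero(X, pens)
        term = _Term(
            name,
            "smooth",
            self._p,
            self._p + Xz.shape[1],
            penalties=Sz,
            predictor=lambda g, b=basis, Zm=Z: b(g) @ Zm,
            x_range=(float(np.min(x)), float(np.max(x))),
            spec=spec,
        )
        self.terms.append(term)
        self._blocks.append(Xz)
        self._p += Xz.shape[1]
        return self

    # ------------------------------------------------------------------- fit
    def _design(self, n: int) -> np.ndarray:
        cols = []
        for b in self._blocks:
            cols.append(np.ones((n, 1)) if b.shape[0] == 0 else b)
        return np.hstack(cols)

    @property
    def n_lambda(self) -> int:
        return sum(len(t.penalties) for t in self.terms)

    def _embed_penalties(self) -> list[np.ndarray]:
        """Each penalty as a (p, p) matrix in full-coefficient coordinates."""
        out = []
        for t in self.terms:
            for S in t.penalties:
                Sfull = np.zeros((self._p, self._p))
                Sfull[t.start : t.stop, t.start : t.stop] = S
                out.append(Sfull)
        return out

    def fit(
        self,
        successes: np.ndarray,
        totals: np.ndarray,
        lam: np.ndarray | float | None = None,
        criterion: str = "reml",
    ) -> "GamFit":
        """Fit the model; ``lam`` fixes the smoothing parameters, else they are
        selected by minimising ``criterion`` ('reml' or 'gcv') on log-lambda."""
        y = np.asarray(successes, dtype=float)
        n = np.asarray(totals, dtype=float)
        if np.any(y < 0) or np.any(n < y):
            raise ValueError("need 0 <= successes <= totals")
        X = self._design(y.size)
        if X.shape[0] != y.size:
            raise ValueError("design rows do not match response length")
        Ss = self._embed_penalties()
        nlam = len(Ss)

        if nlam == 0:
            lam_vec = np.empty(0)
        elif lam is not None:
            lam_vec = np.full(nlam, float(lam)) if np.isscalar(lam) else np.asarray(lam, dtype=float)
            if lam_vec.size != nlam:
                raise ValueError(f"expected {nlam} smoothing parameters, got {lam_vec.size}")
        else:
            lam_vec = self._select_lambda(X, Ss, y, n, criterion)

        Slam = _penalty_sum(Ss, lam_vec, self._p)
        beta, eta, W, dev, conv, n_iter = _pirls(X, Slam, y, n)
        H = (X * W[:, None]).T @ X
        A = H + Slam
        Ainv = _spd_inverse(A)
        Fmat = Ainv @ H
        fit = GamFit(
            model=self,
            X=X,
            y=y,
            totals=n,
            beta=beta,
            cov=Ainv,
            lam=lam_vec,
            deviance=dev,
            eta=eta,
            edf_diag=np.diag(Fmat).copy(),
            converged=conv,
            n_iter=n_iter,
            criterion=criterion,
        )
        if not conv:
            warnings.warn(
                f"PIRLS did not reach tolerance {PIRLS_TOL} in {PIRLS_MAXIT} iterations "
                f"(last deviance {dev:.6g})",
                RuntimeWarning,
            )
        return fit

    # ------------------------------------------------- smoothing selection
    def _select_lambda(self, X, Ss, y, n, criterion) -> np.ndarray:
        nlam = len(Ss)
        p = self._p
        nobs = y.size
        block_ranks = _structural_ranks(self.terms)
        warm: dict = {"beta": None}

        def score(loglam: np.ndarray) -> float:
            ll = np.clip(loglam, -LOGLAM_LIM, LOGLAM_LIM)
            lam = np.exp(ll)
            Slam = _penalty_sum(Ss, lam, p)
            try:
                beta, eta, W, dev, conv, _ = _pirls(X, Slam, y, n, beta0=warm["beta"])
            except np.linalg.LinAlgError:
                return 1e12
            warm["beta"] = beta
            H = (X * W[:, None]).T @ X
            A = H + Slam
            try:
                cA = np.linalg.cholesky(A + 1e-10 * np.eye(p))
            except np.linalg.LinAlgError:
                return 1e12
            if criterion == "gcv":
                edf = float(np.trace(cho_solve((cA, True), H)))
                denom = max(nobs - edf, 1e-3)
                return nobs * dev / denom**2
            pen = float(beta @ Slam @ beta)
            logdetA = 2.0 * float(np.log(np.diag(cA)).sum())
            logdetS = _penalty_logdet(self.terms, lam)
            return 0.5 * (dev + pen) + 0.5 * logdetA - 0.5 * logdetS

        starts = [np.zeros(nlam), np.full(nlam, 3.0), np.full(nlam, -3.0)]
        best = min(starts, key=score)
        res = optimize.minimize(
            score, best, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 400 * nlam, "maxfev": 400 * nlam},
        )
        # polish restart: the simplex can stall on flat criterion surfaces
        res2 = optimize.minimize(
            score, res.x, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200 * nlam, "maxfev": 200 * nlam},
        )
        if not np.isfinite(res2.fun):
            raise GamConvergenceError(f"smoothing selection failed: criterion={res2.fun}")
        _ = block_ranks  # ranks folded into _penalty_logdet
        return np.exp(np.clip(res2.x, -LOGLAM_LIM, LOGLAM_LIM))


# ------------------------------------------------------------------ internals

def _penalty_sum(Ss, lam, p):
    Slam = np.zeros((p, p))
    for S, l in zip(Ss, lam):
        Slam += l * S
    return Slam


def _structural_ranks(terms):
    return {t.name: sum(np.linalg.matrix_rank(S) for S in t.penalties) for t in terms if t.kind == "smooth"}


def _penalty_logdet(terms, lam) -> float:
    """log pseudo-determinant of the total penalty, block by block."""
    out = 0.0
    i = 0
    for t in terms:
        if not t.penalties:
            continue
        Sb = np.zeros((t.size, t.size))
        for S in t.penalties:
            Sb += lam[i] * S
            i += 1
        w = np.linalg.eigvalsh(Sb)
        w = w[w > 1e-9 * max(w.max(), 1e-300)]
        out += float(np.log(w).sum())
    return out


def _spd_inverse(A: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    try:
        c = cho_factor(A)
        return cho_solve(c, np.eye(p))
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


def _pirls(X, Slam, y, n, beta0=None, tol=PIRLS_TOL, maxit=PIRLS_MAXIT):
    """Penalized IRLS for grouped binomial logistic regression."""
    nobs, p = X.shape
    if beta0 is None:
        mu = (y + 0.5) / (n + 1.0)
        eta = np.log(mu / (1.0 - mu))
        beta = None
    else:
        beta = np.asarray(beta0, dtype=float)
        eta = X @ beta
    pdev_old = np.inf
    conv = False
    for it in range(1, maxit + 1):
        mu = expit(eta)
        W = np.maximum(n * mu * (1.0 - mu), 1e-10)
        z = eta + (y - n * mu) / W
        XtW = X * W[:, None]
        A = XtW.T @ X + Slam
        b = XtW.T @ z
        try:
            c = cho_factor(A)
            beta_new = cho_solve(c, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        eta_new = X @ beta_new
        dev = binomial_deviance(y, n, expit(eta_new))
        pdev = dev + float(beta_new @ Slam @ beta_new)
        # step halving if the penalized deviance worsened
        step = 1.0
        while pdev > pdev_old + 1e-10 and beta is not None and step > 1e-8:
            step /= 2.0
            beta_try = beta + step * (beta_new - beta)
            eta_new = X @ beta_try
            dev = binomial_deviance(y, n, expit(eta_new))
            pdev = dev + float(beta_try @ Slam @ beta_try)
            beta_new = beta_try
        beta, eta = beta_new, eta_new
        if abs(pdev_old - pdev) < tol * (abs(pdev) + 0.1):
            conv = True
            break
        pdev_old = pdev
    mu = expit(eta)
    W = np.maximum(n * mu * (1.0 - mu), 1e-10)
    dev = binomial_deviance(y, n, mu)
    return beta, eta, W, dev, conv, it


# ------------------------------------------------------------------------ fit

@dataclass
class GamFit:
    """Fitted penalized logistic additive model."""

    model: GamModel
    X: np.ndarray
    y: np.ndarray
    totals: np.ndarray
    beta: np.ndarray
    cov: np.ndarray            # Bayesian covariance (X'WX + S)^-1
    lam: np.ndarray
    deviance: float
    eta: np.ndarray
    edf_diag: np.ndarray
    converged: bool
    n_iter: int
    criterion: str

    # ------------------------------------------------------------- accessors
    def _term(self, name: str) -> _Term:
        for t in self.model.terms:
            if t.name == name:
                return t
        raise KeyError(f"unknown term: {name!r}")

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.model.terms]

    def coef_block(self, name: str) -> np.ndarray:
        t = self._term(name)
        return self.beta[t.start : t.stop]

    def cov_block(self, name: str) -> np.ndarray:
        t = self._term(name)
        return self.cov[t.start : t.stop, t.start : t.stop]

    def edf(self, name: str) -> float:
        t = self._term(name)
        return float(self.edf_diag[t.start : t.stop].sum())

    @property
    def edf_total(self) -> float:
        return float(self.edf_diag.sum())

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.edf_total

    @property
    def fitted_probabilities(self) -> np.ndarray:
        return expit(self.eta)

    # ----------------------------------------------------------------- tests
    def parametric_table(self):
        """(name, estimate, se, z, p) for each parametric coefficient."""
        rows = []
        for t in self.model.terms:
            if t.kind != "parametric":
                continue
            for j in range(t.size):
                i = t.start + j
                est = self.beta[i]
                se = float(np.sqrt(self.cov[i, i]))
                z = est / se if se > 0 else np.inf
                label = t.name if t.size == 1 else f"{t.name}[{j}]"
                rows.append((label, float(est), se, float(z), float(2.0 * norm.sf(abs(z)))))
        return rows

    def smooth_test(self, name: str) -> tuple[float, float, float]:
        """Wald-type test of a smooth term against zero.

        Returns ``(statistic, reference_df, p_value)``.  The statistic is the
        full quadratic form of the term's coefficients against its Bayesian
        covariance; the reference is a chi-square whose (possibly fractional)
        degrees of freedom equal the term's effective degrees of freedom,
        floored at one.  The test is approximate — calibration is checked by
        simulation in the test suite.
        """
        t = self._term(name)
        if t.kind != "smooth":
            raise ValueError(f"{name!r} is not a smooth term")
        bt = self.coef_block(name)
        Vt = self.cov_block(name)
        w, U = np.linalg.eigh(Vt)
        if w.min() <= 0:
            raise np.linalg.LinAlgError(f"degenerate covariance for term {name!r}")
        stat = float(bt @ U @ np.diag(1.0 / w) @ U.T @ bt)
        df = max(1.0, self.edf(name))
        return stat, df, float(chi2.sf(stat, df))

    # ----------------------------------------------------------- prediction
    def predict_effect(
        self,
        name: str,
        grid: np.ndarray,
        level: float = 0.95,
        scale: str = "logit",
    ):
        """Centred partial effect of a smooth (or linear) term on a grid.

        Returns ``(effect, lower, upper)`` on the requested scale.  On the
        probability scale the curve is the fitted probability with all other
        terms held at their average contribution (the mean linear predictor).
        """
        t = self._term(name)
        grid = np.asarray(grid, dtype=float)
        if t.predictor is not None:
            lo, hi = t.x_range
            if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
                if not (t.spec and t.spec.cyclic):
                    warnings.warn(f"grid extends beyond the fitted range of {name!r}; extrapolating")
            Xg = t.predictor(grid)
        else:
            Xg = grid.reshape(-1, t.size)
        f = Xg @ self.coef_block(name)
        Vt = self.cov_block(name)
        se = np.sqrt(np.maximum((Xg @ Vt * Xg).sum(axis=1), 0.0))
        zq = norm.ppf(0.5 + level / 2.0)
        lo_, hi_ = f - zq * se, f + zq * se
        if scale == "logit":
            return f, lo_, hi_
        if scale == "probability":
            base = float(self.eta.mean())
            return expit(base + f), expit(base + lo_), expit(base + hi_)
        raise ValueError("scale must be 'logit' or 'probability'")
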