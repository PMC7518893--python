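"""Random-intercept linear mixed model with Satterthwaite t-tests.

Fits y = X beta + Z u + e by restricted maximum likelihood, where Z codes
a single grouping factor (experimental block) with u ~ N(0, sigma_b^2 I)
and e ~ N(0, sigma_e^2 I).  Degrees of freedom for contrasts of the fixed
effects use the Satterthwaite approximation: for a contrast c,

    df = 2 f(theta)^2 / (g' A g),   f(theta) = c' (X' V^-1 X)^-1 c,

with g the gradient of f with respect to the variance components theta =
(sigma_b^2, sigma_e^2) and A the asymptotic covariance of theta-hat from
the observed REML information.  When the information matrix is
ill-conditioned (e.g. the block variance estimate sits on the zero
boundary) the residual degrees of freedom are used instead and a warning
is recorded on the result.

This is deliberately a dense, small-n implementation: field expression
designs here have at most a few hundred rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["RandomInterceptModel", "RandomInterceptFit"]


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_block: float
    sigma2_resid: float
    reml_loglik: float
    n: int
    p: int
    theta_cov: np.ndarray | None
    warnings: list[str] = field(default_factory=list)

    def contrast(self, c: np.ndarray) -> dict:
        """Estimate, se, Satterthwaite df, t and p for the contrast c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        var = float(c @ self.cov_beta @ c)
        se = np.sqrt(var)
        df = self._satterthwaite_df(c, var)
        t = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        return {"estimate": est, "se": se, "df": df, "t": t, "p": p}

    def _satterthwaite_df(self, c: np.ndarray, var: float) -> float:
        resid_df = float(self.n - self.p)
        if self.theta_cov is None or not np.all(np.isfinite(self.theta_cov)):
            return resid_df
        theta = np.array([self.sigma2_block, self.sigma2_resid])
        grad = self._grad_contrast_var(c, theta)
        denom = float(grad @ self.theta_cov @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return resid_df
        df = 2.0 * var**2 / denom
        # guard against pathological approximations
        return float(np.clip(df, 1.0, resid_df * 10))

    def _grad_contrast_var(self, c, theta):
        h = np.maximum(1e-6, 1e-4 * np.abs(theta))
        grad = np.empty(2)
        for j in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] = max(tm[j] - h[j], 0.0)
            fp = self._model.contrast_var(c, tp)
            fm = self._model.contrast_var(c, tm)
            grad[j] = (fp - fm) / (tp[j] - tm[j])
        return grad


class RandomInterceptModel:
    """REML machinery for y = X beta + (block intercepts) + e."""

    def __init__(self, y, X, block):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        block = np.asarray(block)
        self.levels, codes = np.unique(block, return_inverse=True)
        self.Z = np.eye(len(self.levels))[codes]
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ValueError("more parameters than observations")

    # -- core linear algebra -------------------------------------------------
    def _V(self, theta):
        s2b, s2e = theta
        return s2b * (self.Z @ self.Z.T) + s2e * np.eye(self.n)

    def _gls(self, theta):
        V = self._V(theta)
        Vi = np.linalg.inv(V)
        XtVi = self.X.T @ Vi
        XtViX = XtVi @ self.X
        cov_beta = np.linalg.inv(XtViX)
        beta = cov_beta @ (XtVi @ self.y)
        return V, Vi, XtViX, cov_beta, beta

    def neg_reml(self, theta) -> float:
        theta = np.maximum(theta, [0.0, 1e-10])
        V, Vi, XtViX, _, beta = self._gls(theta)
        r = self.y - self.X @ beta
        sign, logdetV = np.linalg.slogdet(V)
        if sign <= 0:
            return np.inf
        sign2, logdetX = np.linalg.slogdet(XtViX)
        if sign2 <= 0:
            return np.inf
        return 0.5 * (logdetV + logdetX + r @ Vi @ r)

    def contrast_var(self, c, theta):
        theta = np.maximum(theta, [0.0, 1e-10])
        _, _, XtViX, cov_beta, _ = self._gls(theta)
        return float(c @ cov_beta @ c)

    # -- fitting -------------------------------------------------------------
    def fit(self) -> RandomInterceptFit:
        # OLS residual variance as a starting point
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta0
        s2 = float(resid @ resid / max(self.n - self.p, 1))
        starts = [(0.1 * s2, 0.9 * s2), (1e-4 * s2, s2), (s2, s2)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                self.neg_reml, x0=np.asarray(x0), method="L-BFGS-B",
                bounds=[(0.0, None), (1e-10, None)],
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = np.maximum(best.x, [0.0, 1e-10])
        V, Vi, XtViX, cov_beta, beta = self._gls(theta)
        warns: list[str] = []
        theta_cov = self._theta_cov(theta, warns)
        fit = RandomInterceptFit(
            beta=beta, cov_beta=cov_beta,
            sigma2_block=float(theta[0]), sigma2_resid=float(theta[1]),
            reml_loglik=-float(best.fun), n=self.n, p=self.p,
            theta_cov=theta_cov, warnings=warns,
        )
        fit._model = self
        return fit

    def _theta_cov(self, theta, warns: list[str]):
        """Inverse observed REML information via a numerical Hessian."""
        h = np.maximum(1e-6, 1e-3 * np.abs(theta))
        H = np.empty((2, 2))
        f0 = self.neg_reml(theta)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                fpp = self.neg_reml(theta + ei + ej)
                fpm = self.neg_reml(theta + ei - ej)
                fmp = self.neg_reml(theta - ei + ej)
                fmm = self.neg_reml(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            cond = np.linalg.cond(H)
            if not np.isfinite(cond) or cond > 1e10:
                raise np.linalg.LinAlgError("ill-conditioned information matrix")
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError("negative variance in theta covariance")
            return cov
        except np.linalg.LinAlgError as err:
            warns.append(
                f"Satterthwaite fallback to residual df: {err} "
                f"(block variance estimate {theta[0]:.3g})"
            )
            warnings.warn(warns[-1], stacklevel=2)
            return None
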