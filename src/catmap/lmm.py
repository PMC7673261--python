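"""Per-gene linear mixed models with one random intercept.

Every model in this package has the same shape: a fixed-effect design
(intercept only, or intercept + cell-subtype) plus a random intercept
per subject/donor, fitted independently to each gene,

    y = X beta + Z b + e,   b ~ N(0, sigma_b^2 I),   e ~ N(0, sigma_e^2 I).

For this one-variance-component case the REML criterion can be profiled
down to a 1-D search over the variance ratio lambda = sigma_b^2 /
sigma_e^2 after a single eigendecomposition of Z Z' that is shared by
all genes. That makes a fit ~2-3 orders of magnitude faster than a
generic mixed-model optimizer, which matters when fitting tens of
thousands of genes; the generic route (statsmodels ``MixedLM``) is kept
as an independent cross-check in the test suite.

A fit whose variance ratio is estimated at the lambda = 0 boundary is a
*singular fit*: the random intercept explains nothing and the model
collapses to OLS. Callers use this flag to fall back to the unadjusted
values (subject regression) or to plain residual degrees of freedom
(Satterthwaite tests).

Wald tests use the asymptotic normal / chi-square reference; the
optional Satterthwaite mode estimates denominator degrees of freedom
from the curvature of the REML likelihood (numerical gradient and
Hessian in the variance components), combining multi-dimensional
contrasts eigenvalue-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MixedDesign", "GeneFit", "build_design"]

_LAMBDA_SINGULAR = 1e-6
_LOG_LAM_LO, _LOG_LAM_HI = -14.0, 16.0


def build_design(subtypes: pd.Series | None, samples: list[str] | None = None):
    """Fixed-effect design matrix with treatment coding.

    ``subtypes=None`` yields the intercept-only design. Returns
    ``(X, coef_names, level_names)`` where ``coef_names[1:]`` are the
    non-reference subtype levels.
    """
    if subtypes is None:
        n = len(samples)
        return np.ones((n, 1)), ["(Intercept)"], []
    levels = sorted(pd.unique(subtypes))
    n = len(subtypes)
    X = np.ones((n, len(levels)))
    for j, level in enumerate(levels[1:], start=1):
        X[:, j] = (subtypes.to_numpy() == level).astype(float)
    return X, ["(Intercept)"] + levels[1:], levels


@dataclass
class GeneFit:
    """Fitted mixed model for one gene."""

    beta: np.ndarray
    cov_unscaled: np.ndarray  # (X' V^-1 X)^-1 with V in units of sigma_e^2
    sigma2: float  # residual variance sigma_e^2 (REML)
    lam: float  # variance ratio sigma_b^2 / sigma_e^2
    singular: bool
    n: int
    p: int

    @property
    def sigma2_subject(self) -> float:
        return self.lam * self.sigma2

    @property
    def cov_beta(self) -> np.ndarray:
        return self.sigma2 * self.cov_unscaled

    @property
    def df_resid(self) -> int:
        return self.n - self.p


class MixedDesign:
    """Shared design for fitting the same mixed model to many genes.

    Parameters
    ----------
    X : (n, p) fixed-effect design matrix.
    subjects : length-n array of subject labels (the random grouping).
    coef_names : optional names for the columns of ``X``.
    """

    def __init__(self, X: np.ndarray, subjects, coef_names=None):
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        codes, self.subject_levels = pd.factorize(np.asarray(subjects))
        self.subject_codes = codes
        self.n_subjects = len(self.subject_levels)
        self.coef_names = coef_names or [f"b{j}" for j in range(self.p)]
        Z = np.zeros((self.n, self.n_subjects))
        Z[np.arange(self.n), codes] = 1.0
        self.Z = Z
        # ZZ' is block one-matrices; eigendecompose once, reuse per gene.
        d, Q = np.linalg.eigh(Z @ Z.T)
        d[d < 1e-10] = 0.0
        self.d = d
        self.Q = Q
        self.Xt = Q.T @ self.X  # rotated design

    # -- REML machinery ----------------------------------------------------

    def _gls(self, yt: np.ndarray, w: np.ndarray):
        """Weighted LS in the rotated basis; returns beta, A, rss_w."""
        Xw = self.Xt * w[:, None]
        A = self.Xt.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yt)
        resid = yt - self.Xt @ beta
        rss = float(np.dot(w * resid, resid))
        return beta, A, resid, rss

    def _neg2_reml(self, lam: float, yt: np.ndarray) -> float:
        w = 1.0 / (1.0 + lam * self.d)
        _, A, _, rss = self._gls(yt, w)
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        nmp = self.n - self.p
        return nmp * np.log(max(rss, 1e-300)) + float(np.sum(np.log1p(lam * self.d))) + logdet

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.Q.T @ np.asarray(y, dtype=float)

    def fit_rotated(self, yt: np.ndarray) -> GeneFit:
        f0 = self._neg2_reml(0.0, yt)
        res = optimize.minimize_scalar(
            lambda u: self._neg2_reml(np.exp(u), yt),
            bounds=(_LOG_LAM_LO, _LOG_LAM_HI),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam = float(np.exp(res.x))
        singular = (res.fun >= f0 - 1e-10) or (lam <= _LAMBDA_SINGULAR)
        if singular:
            lam = 0.0
        w = 1.0 / (1.0 + lam * self.d)
        beta, A, _, rss = self._gls(yt, w)
        sigma2 = rss / max(self.n - self.p, 1)
        if sigma2 <= 0.0:  # noise-free gene: keep tests finite and directional
            sigma2 = 1e-30
        return GeneFit(
            beta=beta,
            cov_unscaled=np.linalg.inv(A),
            sigma2=sigma2,
            lam=lam,
            singular=singular,
            n=self.n,
            p=self.p,
        )

    def fit(self, y: np.ndarray) -> GeneFit:
        return self.fit_rotated(self.rotate(y))

    # -- subject regression (BLUP removal) ---------------------------------

    def remove_subject_effects(self, y: np.ndarray):
        """Return ``(adjusted, singular)``: y minus the BLUP random intercepts.

        The adjusted values are the fixed-effect fit plus residuals —
        i.e. the observation with its subject's predicted intercept
        subtracted. Singular fits (or zero-variance genes) return the
        input unchanged, flagged.
        """
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0.0:
            return y.copy(), True
        yt = self.rotate(y)
        fit = self.fit_rotated(yt)
        if fit.singular:
            return y.copy(), True
        w = 1.0 / (1.0 + fit.lam * self.d)
        resid_rot = yt - self.Xt @ fit.beta
        vinv_r = self.Q @ (w * resid_rot)  # V^-1 (y - X beta), in sigma_e^2 units
        blup = fit.lam * (self.Z.T @ vinv_r)
        return y - self.Z @ blup, False

    # -- variance-component likelihood in (sigma_b^2, sigma_e^2) -----------

    def _neg2_reml_theta(self, theta: np.ndarray, yt: np.ndarray) -> float:
        s2b, s2e = theta
        v = s2e + s2b * self.d
        if np.any(v <= 0):
            return np.inf
        w = 1.0 / v
        Xw = self.Xt * w[:, None]
        A = self.Xt.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yt)
        resid = yt - self.Xt @ beta
        quad = float(np.dot(w * resid, resid))
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return float(np.sum(np.log(v))) + logdet + quad

    def _cov_beta_theta(self, theta: np.ndarray) -> np.ndarray:
        s2b, s2e = theta
        w = 1.0 / (s2e + s2b * self.d)
        A = self.Xt.T @ (self.Xt * w[:, None])
        return np.linalg.inv(A)

    def _satterthwaite_machinery(self, fit: GeneFit, yt: np.ndarray):
        """Var(theta_hat) and finite-difference dCov(beta)/dtheta at theta_hat."""
        theta = np.array([fit.sigma2_subject, fit.sigma2])
        h = 1e-4 * np.maximum(theta, 1e-8 * max(fit.sigma2, 1e-12))
        # observed information of the REML log-likelihood (numeric Hessian)
        H = np.zeros((2, 2))
        f0 = self._neg2_reml_theta(theta, yt)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = self._neg2_reml_theta(theta + ei + ej, yt)
                fpm = self._neg2_reml_theta(theta + ei - ej, yt)
                fmp = self._neg2_reml_theta(theta - ei + ej, yt)
                fmm = self._neg2_reml_theta(theta - ei - ej, yt)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)) or not np.isfinite(f0):
            return None
        try:
            var_theta = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        dC = []
        for i in range(2):
            step = np.zeros(2)
            step[i] = h[i]
            Cp = self._cov_beta_theta(theta + step)
            Cm = self._cov_beta_theta(np.maximum(theta - step, [0.0, 1e-12]))
            dC.append((Cp - Cm) / (2 * h[i]))
        return var_theta, dC

    def _satt_df_contrast(self, fit: GeneFit, c: np.ndarray, machinery) -> float:
        if machinery is None:
            return float(fit.df_resid)
        var_theta, dC = machinery
        f_val = float(c @ fit.cov_beta @ c)
        grad = np.array([float(c @ dC[0] @ c), float(c @ dC[1] @ c)])
        denom = float(grad @ var_theta @ grad)
        if denom <= 0 or f_val <= 0:
            return float(fit.df_resid)
        df = 2.0 * f_val**2 / denom
        return float(np.clip(df, 1.0, 1e7))

    # -- hypothesis tests ---------------------------------------------------

    def contrast_tests(
        self, fit: GeneFit, contrasts: np.ndarray, yt: np.ndarray | None = None,
        df_method: str = "wald",
    ):
        """Two-sided tests of rows of ``contrasts`` (each c' beta = 0).

        Returns arrays ``(estimates, p_values)``. ``df_method='wald'``
        uses the normal reference; ``'satterthwaite'`` a t reference
        with likelihood-curvature degrees of freedom.
        """
        contrasts = np.atleast_2d(np.asarray(contrasts, dtype=float))
        est = contrasts @ fit.beta
        # snap float dust to an exact zero so noise-free ties stay ties
        scale = max(1.0, float(np.abs(fit.beta).max()))
        est = np.where(np.abs(est) < 1e-9 * scale, 0.0, est)
        var = np.einsum("ij,jk,ik->i", contrasts, fit.cov_beta, contrasts)
        var = np.maximum(var, 0.0)
        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = est / se
        degenerate = np.where(est == 0.0, 0.0, np.where(est > 0, np.inf, -np.inf))
        tstat = np.where(se <= 1e-150, degenerate, tstat)
        if df_method == "wald" or fit.singular:
            dfs = np.full(len(contrasts), float(fit.df_resid))
            if df_method == "wald":
                pvals = 2.0 * stats.norm.sf(np.abs(tstat))
            else:
                pvals = 2.0 * stats.t.sf(np.abs(tstat), dfs)
        elif df_method == "satterthwaite":
            machinery = self._satterthwaite_machinery(fit, yt)
            dfs = np.array([self._satt_df_contrast(fit, c, machinery) for c in contrasts])
            pvals = 2.0 * stats.t.sf(np.abs(tstat), dfs)
        else:
            raise ValueError(f"unknown df_method {df_method!r}")
        return est, pvals

    def f_test(
        self, fit: GeneFit, L: np.ndarray, yt: np.ndarray | None = None,
        df_method: str = "wald",
    ) -> float:
        """Joint test of L beta = 0; returns the p-value.

        Wald: chi-square with q df. Satterthwaite: F with denominator df
        combined over the eigencontrasts of L Cov(beta) L'.
        """
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        M = L @ fit.cov_beta @ L.T
        Lb = L @ fit.beta
        try:
            stat = float(Lb @ np.linalg.solve(M, Lb))
        except np.linalg.LinAlgError:
            return 1.0
        if not np.isfinite(stat) or stat < 0:
            return 1.0
        if df_method == "wald":
            return float(stats.chi2.sf(stat, q))
        if df_method != "satterthwaite":
            raise ValueError(f"unknown df_method {df_method!r}")
        if fit.singular:
            return float(stats.f.sf(stat / q, q, fit.df_resid))
        machinery = self._satterthwaite_machinery(fit, yt)
        eigval, eigvec = np.linalg.eigh(M)
        keep = eigval > 1e-12 * max(eigval.max(), 1e-300)
        nus = []
        for v in eigvec.T[keep]:
            c = v @ L
            nus.append(self._satt_df_contrast(fit, c, machinery))
        nus = np.asarray(nus)
        usable = nus > 2.0
        if not usable.any():
            ddf = float(fit.df_resid)
        else:
            E = float(np.sum(nus[usable] / (nus[usable] - 2.0)))
            ddf = 2.0 * E / (E - q) if E > q else float(fit.df_resid)
        return float(stats.f.sf(stat / q, q, max(ddf, 1.0)))
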