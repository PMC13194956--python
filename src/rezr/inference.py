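"""Small-sample inference for random-intercept linear mixed models.

The models used throughout the analysis share one structure: independent
top-level clusters (patients), optional further random intercepts nested
inside them (eye within patient), and an i.i.d. residual,

    y_i = X_i beta + 1 b_i + sum_k Z_ik u_ik + e_i,        i = 1..m,

with variance parameters theta = (s2_patient, s2_nested..., s2_resid).
This module evaluates the REML profile quantities for such models and
derives Satterthwaite denominator degrees of freedom for t- and F-type
tests — the small-sample machinery that the fitting backend does not
provide.  The Satterthwaite df for a contrast c is

    nu = 2 v^2 / (g' A g),   v = c' C(theta) c,

where C(theta) = (sum_i X_i' V_i^-1 X_i)^-1 is the fixed-effect
covariance, g the gradient of v in theta (central differences) and A the
inverse curvature of the restricted log-likelihood at theta-hat.  Multi-df
F tests use the eigendecomposition of L C L': each eigen-contrast gets
its own Satterthwaite df nu_j, and the denominator df solves
2E/(E - q) with E = sum nu_j/(nu_j - 2), matching the standard
mixed-model ANOVA construction.

Clusters sharing the same random-effect pattern are batched so that each
V_i is built and inverted once per batch — the likelihood evaluation is a
handful of small dense solves regardless of the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = ["RandomInterceptModel", "satterthwaite_ftest_df"]

_DF_MAX = 1e7


@dataclass
class _Batch:
    X: np.ndarray  # (b, n, p)
    y: np.ndarray  # (b, n)
    zzt: list[np.ndarray]  # per variance component, shared (n, n)


class RandomInterceptModel:
    """REML profile computations for nested random-intercept models.

    Parameters
    ----------
    y, X
        Response vector and fixed-effects design matrix.
    groups
        Top-level cluster labels (one random intercept per cluster).
    extra_levels
        Optional sequence of label arrays, each adding a random intercept
        for its labels nested within the top-level clusters (e.g. eye ids
        for an eye-within-patient intercept).
    """

    def __init__(self, y, X, groups, extra_levels=()):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        self.n_obs, self.n_params = X.shape
        self.n_vc = 1 + len(extra_levels)
        extra = [np.asarray(lv) for lv in extra_levels]

        batches: dict = {}
        for g in pd.unique(groups):
            idx = np.flatnonzero(groups == g)
            n = len(idx)
            zzts = [np.ones((n, n))]
            sig = [n]
            for lv in extra:
                codes = pd.factorize(lv[idx])[0]
                Z = np.eye(codes.max() + 1)[codes]
                zzts.append(Z @ Z.T)
                sig.append(tuple(codes))
            key = tuple(sig[:1]) + tuple(sig[1:])
            batches.setdefault(key, {"idx": [], "zzt": zzts})["idx"].append(idx)
        self._batches = []
        for batch in batches.values():
            idxs = batch["idx"]
            self._batches.append(
                _Batch(
                    X=np.stack([X[i] for i in idxs]),
                    y=np.stack([y[i] for i in idxs]),
                    zzt=batch["zzt"],
                )
            )
        self.n_groups = sum(b.X.shape[0] for b in self._batches)
        # profile() is re-evaluated at the same finite-difference points by
        # every contrast of a fit; memoise on the exact theta bytes
        self._cache: dict[bytes, tuple] = {}

    # -- core quantities ---------------------------------------------------

    def _accumulate(self, theta):
        """One pass over batches: X'V⁻¹X, X'V⁻¹y, y'V⁻¹y, sum log|V|."""
        theta = np.asarray(theta, dtype=float)
        s2_resid = theta[-1]
        p = self.n_params
        A1 = np.zeros((p, p))
        A2 = np.zeros(p)
        yVy = 0.0
        logdet = 0.0
        for batch in self._batches:
            n = batch.X.shape[1]
            V = s2_resid * np.eye(n)
            for t, zzt in zip(theta[:-1], batch.zzt):
                V = V + t * zzt
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return None
            Vinv = np.linalg.inv(V)
            logdet += batch.X.shape[0] * ld
            VinvX = np.einsum("ij,bjp->bip", Vinv, batch.X)
            A1 += np.einsum("bnp,bnq->pq", batch.X, VinvX)
            Vinvy = np.einsum("ij,bj->bi", Vinv, batch.y)
            A2 += np.einsum("bnp,bn->p", batch.X, Vinvy)
            yVy += float(np.einsum("bn,bn->", batch.y, Vinvy))
        return A1, A2, yVy, logdet

    def profile(self, theta):
        """REML log-likelihood, GLS beta and its covariance at theta."""
        key = np.asarray(theta, dtype=float).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        out = self._profile_uncached(theta)
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[key] = out
        return out

    def _profile_uncached(self, theta):
        acc = self._accumulate(theta)
        if acc is None:
            return -np.inf, None, None
        A1, A2, yVy, logdet = acc
        try:
            C = np.linalg.inv(A1)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        beta = C @ A2
        rVr = yVy - beta @ A2
        sign, ld1 = np.linalg.slogdet(A1)
        if sign <= 0 or rVr < 0:
            return -np.inf, None, None
        ll = -0.5 * (
            logdet + ld1 + rVr + (self.n_obs - self.n_params) * np.log(2 * np.pi)
        )
        return float(ll), beta, C

    def reml_loglik(self, theta) -> float:
        return self.profile(theta)[0]

    def beta_cov(self, theta) -> np.ndarray:
        return self.profile(theta)[2]

    def fit(self, theta0):
        """Polish a REML optimum with bounded L-BFGS-B from ``theta0``."""
        theta0 = np.maximum(np.asarray(theta0, dtype=float), 1e-10)

        def neg(theta):
            ll = self.reml_loglik(theta)
            return np.inf if not np.isfinite(ll) else -ll

        res = optimize.minimize(
            neg,
            theta0,
            method="L-BFGS-B",
            bounds=[(1e-10, None)] * len(theta0),
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x if np.isfinite(res.fun) and -res.fun >= self.reml_loglik(theta0) else theta0
        return np.asarray(theta, dtype=float)

    # -- curvature and Satterthwaite ---------------------------------------

    def _steps(self, theta):
        scale = max(theta[-1], 1e-8)
        return np.maximum(1e-3 * np.abs(theta), 1e-4 * scale)

    def theta_acov(self, theta) -> np.ndarray:
        """Asymptotic covariance of theta-hat: inverse REML curvature."""
        theta = np.asarray(theta, dtype=float)
        k = len(theta)
        h = self._steps(theta)
        f0 = self.reml_loglik(theta)
        H = np.zeros((k, k))
        fp = np.zeros(k)
        fm = np.zeros(k)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            fp[i] = self.reml_loglik(theta + ei)
            fm[i] = self.reml_loglik(theta - ei)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = self.reml_loglik(theta + ei + ej)
                fpm = self.reml_loglik(theta + ei - ej)
                fmp = self.reml_loglik(theta - ei + ej)
                fmm = self.reml_loglik(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        info = -H
        try:
            A = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(info)
        # non-PD curvature can occur at a variance boundary; fall back to
        # the PSD part so df stay finite and conservative
        w, Q = np.linalg.eigh(A)
        w = np.clip(w, 0.0, None)
        return (Q * w) @ Q.T

    def _var_grad(self, c, theta):
        """Gradient of Var(c'beta-hat) = c'C(theta)c in theta."""
        h = self._steps(theta)
        g = np.zeros(len(theta))
        for j in range(len(theta)):
            ej = np.zeros(len(theta))
            ej[j] = h[j]
            Cp = self.beta_cov(theta + ej)
            Cm = self.beta_cov(theta - ej)
            if Cp is None or Cm is None:
                Cp = self.beta_cov(theta + 2 * ej) if Cp is None else Cp
                Cm = self.beta_cov(theta) if Cm is None else Cm
            g[j] = (c @ Cp @ c - c @ Cm @ c) / (2 * h[j])
        return g

    def satterthwaite_df(self, c, theta, acov_theta) -> float:
        c = np.asarray(c, dtype=float)
        v = float(c @ self.beta_cov(theta) @ c)
        g = self._var_grad(c, theta)
        denom = float(g @ acov_theta @ g)
        if denom <= 0 or not np.isfinite(denom):
            return _DF_MAX
        return float(np.clip(2.0 * v * v / denom, 1.0, _DF_MAX))

    def contrast_test(self, c, beta, theta, acov_theta):
        """(estimate, se, df, t, p) for the scalar contrast c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ beta)
        se = float(np.sqrt(c @ self.beta_cov(theta) @ c))
        df = self.satterthwaite_df(c, theta, acov_theta)
        t = est / se if se > 0 else 0.0
        p = float(2.0 * sps.t.sf(abs(t), df))
        return est, se, df, t, p

    def ftest(self, L, beta, theta, acov_theta):
        """Wald F-test of L beta = 0 with Satterthwaite denominator df."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        C = self.beta_cov(theta)
        M = L @ C @ L.T
        lam, P = np.linalg.eigh(M)
        keep = lam > max(1e-12, 1e-10 * lam.max())
        lam, P = lam[keep], P[:, keep]
        q = int(keep.sum())
        if q == 0:
            return 0.0, 0, _DF_MAX, 1.0
        Lt = P.T @ L
        t2 = (Lt @ beta) ** 2 / lam
        F = float(t2.sum() / q)
        nus = np.array(
            [self.satterthwaite_df(Lt[j], theta, acov_theta) for j in range(q)]
        )
        good = nus > 2.0
        if good.any():
            E = float((nus[good] / (nus[good] - 2.0)).sum()) + float((~good).sum())
            df_den = 2.0 * E / (E - q) if E > q else _DF_MAX
        else:
            df_den = _DF_MAX
        df_den = float(np.clip(df_den, 1.0, _DF_MAX))
        p = float(sps.f.sf(F, q, df_den))
        return F, q, df_den, p


def satterthwaite_ftest_df(nus: np.ndarray, q: int) -> float:
    """Combine per-eigencontrast dfs into one F denominator df."""
    nus = np.asarray(nus, dtype=float)
    good = nus > 2.0
    if not good.any():
        return _DF_MAX
    E = float((nus[good] / (nus[good] - 2.0)).sum()) + float((~good).sum())
    return 2.0 * E / (E - q) if E > q else _DF_MAX
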