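"""Generalized linear mixed models with crossed Gaussian random intercepts.

Implements binomial-logit and Gaussian-identity mixed models with one or
more crossed random-intercept factors, estimated by Laplace-approximated
maximum marginal likelihood (the approximation is exact for the Gaussian
family).  For given variance parameters the fixed effects and random-effect
modes are found jointly by penalized iteratively reweighted least squares
(PIRLS); the profiled Laplace objective is then maximized over the log
random-effect standard deviations (and log residual SD for the Gaussian
family) with L-BFGS-B.

Fixed-effect standard errors are conditional Wald SEs taken from the
fixed-effect block of the inverse joint Hessian at the optimum, matching
the convention of standard mixed-model software.  With all random-effect
variances forced to zero the model reduces exactly to an ordinary GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.special import expit
from scipy.stats import norm

_TAU_FLOOR_LOG = -8.0  # log-SD lower bound; exp(-8) ~ 3e-4, effectively zero


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class GLMMFit:
    """Fitted mixed model: estimates, uncertainty, variance components."""

    params: pd.Series
    se: pd.Series
    re_sd: dict
    scale: float | None
    loglik: float
    converged: bool
    message: str
    family: str
    cov_params: pd.DataFrame
    random_effects: dict = field(default_factory=dict)
    n_obs: int = 0

    @property
    def z(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.z)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - q * self.se,
                             "upper": self.params + q * self.se})

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.params, "se": self.se,
                            "z": self.z, "p": self.pvalues})
        ci = self.conf_int()
        out["ci_lower"], out["ci_upper"] = ci["lower"], ci["upper"]
        return out


class MixedGLM:
    """Binomial or Gaussian mixed model with crossed random intercepts.

    Parameters
    ----------
    X : (n, p) design matrix of fixed effects (include the intercept).
    y : response; successes for the binomial family.
    groups : dict name -> (n,) array of group labels; each factor
        contributes iid N(0, tau_k^2) intercepts.
    family : "binomial" or "gaussian".
    trials : binomial trial counts (defaults to 1 = Bernoulli).
    names : fixed-effect column names.
    """

    def __init__(self, X, y, groups: dict, family: str = "binomial",
                 trials=None, names=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = self.X.shape
        if family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.trials = (np.ones(self.n) if trials is None
                       else np.asarray(trials, dtype=float))
        if family == "binomial" and np.any(self.y > self.trials):
            raise ValueError("successes exceed trials")
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(self.p)]
        self.group_names = list(groups)
        self.Z_blocks, self.block_levels = [], []
        for gname in self.group_names:
            labels = np.asarray(groups[gname])
            levels, codes = np.unique(labels, return_inverse=True)
            Z = sparse.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), codes)),
                shape=(self.n, len(levels)))
            self.Z_blocks.append(Z)
            self.block_levels.append(levels)
        self.q_per = [Z.shape[1] for Z in self.Z_blocks]
        self.q = int(sum(self.q_per))
        self.Z = (sparse.hstack(self.Z_blocks, format="csr")
                  if self.Z_blocks else sparse.csr_matrix((self.n, 0)))
        self.C = np.asarray(
            sparse.hstack([sparse.csr_matrix(self.X), self.Z]).todense())

    # -- likelihood pieces --------------------------------------------------

    def _loglik_obs(self, eta, scale=None):
        if self.family == "binomial":
            return float(self.y @ eta - self.trials @ np.logaddexp(0, eta))
        resid = self.y - eta
        return float(-0.5 * (resid @ resid) / scale**2
                     - self.n * np.log(scale)
                     - 0.5 * self.n * np.log(2 * np.pi))

    def _weights(self, eta, scale=None):
        if self.family == "binomial":
            mu = expit(eta)
            return np.maximum(self.trials * mu * (1 - mu), 1e-10)
        return np.full(self.n, 1.0 / scale**2)

    def _working_residual(self, eta, scale=None):
        if self.family == "binomial":
            return self.y - self.trials * expit(eta)
        return (self.y - eta) / scale**2

    def _dinv(self, taus):
        # tau floored at 1e-6: a 1e12 ridge pins the intercepts at zero,
        # giving the exact GLM reduction to well below 1e-4 on eta
        return np.concatenate([
            np.full(qk, 1.0 / max(t, 1e-6)**2)
            for qk, t in zip(self.q_per, taus)]) if self.q else np.empty(0)

    def _pirls(self, taus, scale, theta0=None, max_iter=100, tol=1e-10):
        """Maximize the penalized log-likelihood jointly over (beta, u)."""
        dinv = self._dinv(taus)
        pen = np.concatenate([np.zeros(self.p), dinv])
        theta = np.zeros(self.p + self.q) if theta0 is None else theta0.copy()
        C = self.C
        obj_prev = -np.inf
        for _ in range(max_iter):
            eta = C @ theta
            W = self._weights(eta, scale)
            g = C.T @ self._working_residual(eta, scale) - pen * theta
            H = (C.T * W) @ C
            H[np.arange(self.p + self.q), np.arange(self.p + self.q)] += pen
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            # step-halving line search on the penalized objective
            for half in range(30):
                cand = theta + step
                eta_c = C @ cand
                obj = (self._loglik_obs(eta_c, scale)
                       - 0.5 * float(pen @ cand**2))
                if np.isfinite(obj) and obj >= obj_prev - 1e-12:
                    break
                step *= 0.5
            theta = cand
            if abs(obj - obj_prev) < tol * (abs(obj_prev) + 1):
                obj_prev = obj
                break
            obj_prev = obj
        eta = C @ theta
        W = self._weights(eta, scale)
        H = (C.T * W) @ C
        H[np.arange(self.p + self.q), np.arange(self.p + self.q)] += pen
        return theta, obj_prev, H

    def _laplace(self, taus, scale, theta0=None):
        """Profiled Laplace log marginal likelihood at variance params."""
        theta, pen_obj, H = self._pirls(taus, scale, theta0)
        ll = pen_obj
        if self.q:
            dinv = self._dinv(taus)
            ll -= 0.5 * float(np.sum(np.log(np.maximum(1.0 / dinv, 1e-300))))
            Huu = H[self.p:, self.p:]
            sign, logdet = np.linalg.slogdet(Huu)
            if sign <= 0:
                return -np.inf, theta, H
            ll -= 0.5 * logdet
        return ll, theta, H

    # -- fitting ------------------------------------------------------------

    def fit(self, fix_variances=None, start_tau: float = 0.5) -> GLMMFit:
        """Fit the model.

        ``fix_variances`` maps group name -> fixed SD (e.g. 0.0 to force the
        reduction to an ordinary GLM); remaining variances are estimated.
        """
        fix = dict(fix_variances or {})
        free = [g for g in self.group_names if g not in fix]
        scale0 = np.std(self.y) + 1e-6 if self.family == "gaussian" else None
        warm = {"theta": None}

        def unpack(params):
            taus = []
            it = iter(params[:len(free)])
            for g in self.group_names:
                taus.append(fix[g] if g in fix else float(np.exp(next(it))))
            scale = (float(np.exp(params[-1]))
                     if self.family == "gaussian" else None)
            return taus, scale

        def negloglik(params):
            taus, scale = unpack(params)
            ll, theta, _ = self._laplace(taus, scale, warm["theta"])
            if np.isfinite(ll):
                warm["theta"] = theta
            return -ll

        x0 = np.full(len(free), np.log(start_tau))
        if self.family == "gaussian":
            x0 = np.append(x0, np.log(scale0))
        converged, message = True, "ok"
        if x0.size:
            bounds = [( _TAU_FLOOR_LOG, 5.0)] * len(free)
            if self.family == "gaussian":
                bounds.append((np.log(scale0) - 10, np.log(scale0) + 5))
            res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": 200, "ftol": 1e-10})
            converged, message = bool(res.success), str(res.message)
            xopt = res.x
        else:
            xopt = x0
        taus, scale = unpack(xopt)
        ll, theta, H = self._laplace(taus, scale)
        beta = theta[:self.p]
        try:
            cov = np.linalg.inv(H)[:self.p, :self.p]
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)[:self.p, :self.p]
            converged = False
            message += "; singular Hessian"
        se = np.sqrt(np.maximum(np.diag(cov), 0))
        if not converged:
            warnings.warn(f"mixed model did not converge: {message}",
                          ConvergenceWarning)
        re = {}
        off = self.p
        for gname, levels, qk in zip(self.group_names, self.block_levels,
                                     self.q_per):
            re[gname] = pd.Series(theta[off:off + qk], index=levels)
            off += qk
        return GLMMFit(
            params=pd.Series(beta, index=self.names),
            se=pd.Series(se, index=self.names),
            re_sd={g: t for g, t in zip(self.group_names, taus)},
            scale=scale,
            loglik=float(ll),
            converged=converged,
            message=message,
            family=self.family,
            cov_params=pd.DataFrame(cov, index=self.names,
                                    columns=self.names),
            random_effects=re,
            n_obs=self.n,
        )
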