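"""Generalized linear mixed models with crossed random intercepts.

Maximum-likelihood fitting by the Laplace approximation, for binomial
(logit) and Poisson (log) responses with one or two crossed
random-intercept factors — the structure needed for trial-level analyses
with participants and levels as crossed grouping factors.

For fixed effects beta and variance parameters theta (one log standard
deviation per factor), the random-effect modes u solve the penalized
score equations by damped Newton steps, and the Laplace log-likelihood is

    l(y | beta, u)  -  (1/2) u' D^-1 u  -  (1/2) log det(I + D Z'WZ)

with D the random-effect covariance and W the IRLS weights at the mode.
(beta, theta) are optimized jointly in the outer problem — the same
objective as lme4's glmer with nAGQ = 1 — using BFGS with numerical
gradients and a deterministic start, so fits are bit-for-bit
reproducible.  The random-effects cross-products are assembled from the
factor codes directly (never a dense indicator matrix), so an evaluation
costs O(n + q^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_MAX_ETA = 30.0  # logit link: |eta| beyond this flags quasi-separation


class Binomial:
    name = "binomial"

    @staticmethod
    def loglik(y, eta):
        # -log(1 + exp(-(2y-1) eta)), stable form
        z = (2.0 * y - 1.0) * eta
        return float(-np.logaddexp(0.0, -z).sum())

    @staticmethod
    def mean(eta):
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -_MAX_ETA, _MAX_ETA)))

    @staticmethod
    def weights(eta):
        mu = Binomial.mean(eta)
        return np.maximum(mu * (1.0 - mu), 1e-10)

    @staticmethod
    def residual(y, eta):
        return y - Binomial.mean(eta)


class Poisson:
    name = "poisson"

    @staticmethod
    def loglik(y, eta):
        from scipy.special import gammaln

        eta = np.clip(eta, -_MAX_ETA, _MAX_ETA)
        return float((y * eta - np.exp(eta) - gammaln(y + 1.0)).sum())

    @staticmethod
    def mean(eta):
        return np.exp(np.clip(eta, -_MAX_ETA, _MAX_ETA))

    @staticmethod
    def weights(eta):
        return np.maximum(Poisson.mean(eta), 1e-10)

    @staticmethod
    def residual(y, eta):
        return y - Poisson.mean(eta)


_FAMILIES = {"binomial": Binomial, "poisson": Poisson}


@dataclass
class MixedGLMResults:
    """ML fit of a GLMM with crossed random intercepts."""

    params: pd.Series
    bse: pd.Series
    llf: float
    re_sd: dict[str, float]
    n_obs: int
    converged: bool
    separation: bool
    model: "MixedGLM"
    random_effects: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def fitted_mean(self) -> np.ndarray:
        """Conditional mean per observation at the fitted modes."""
        m = self.model
        eta = m.exog @ self.params.to_numpy() + m._zu(self._u)
        return m.family.mean(eta)

    @property
    def _u(self) -> np.ndarray:
        return np.concatenate([self.random_effects[g]
                               for g in self.model.group_names])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [f"Mixed {self.model.family.name} model "
                 f"(Laplace ML), n = {self.n_obs}",
                 f"  log-likelihood: {self.llf:.3f}"]
        for name in self.params.index:
            lines.append(
                f"  {name}: {self.params[name]: .4f} "
                f"[{ci.loc[name, 'lower']: .4f}, {ci.loc[name, 'upper']: .4f}]")
        for fac, sd in self.re_sd.items():
            lines.append(f"  random intercept sd ({fac}): {sd:.4f}")
        if self.separation:
            lines.append("  warning: quasi-separation detected")
        if not self.converged:
            lines.append("  warning: optimizer did not converge")
        return "\n".join(lines)


class MixedGLM:
    """GLMM with fixed effects X and crossed random intercepts.

    Parameters
    ----------
    endog : (n,) array
        Response (0/1 for binomial, counts for Poisson).
    exog : (n, p) array or DataFrame
        Fixed-effects design matrix (include the intercept column).
    groups : mapping name -> (n,) array
        Codes of each crossed random-intercept factor (at most two).
    family : {"binomial", "poisson"}
    """

    def __init__(self, endog, exog, groups, family: str = "binomial"):
        self.endog = np.asarray(endog, dtype=float).ravel()
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=float)
        else:
            self.exog = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{j}" for j in range(self.exog.shape[1])]
        n = len(self.endog)
        if self.exog.shape[0] != n:
            raise ValueError("endog and exog length mismatch")
        if family not in _FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if not 1 <= len(groups) <= 2:
            raise ValueError("one or two random-intercept factors supported")
        self.family = _FAMILIES[family]
        self.group_names = list(groups)
        self._codes: list[np.ndarray] = []
        self._nlev: list[int] = []
        for name in self.group_names:
            codes, _ = pd.factorize(np.asarray(groups[name]), sort=True)
            self._codes.append(codes)
            self._nlev.append(int(codes.max()) + 1)
        self._q = sum(self._nlev)
        self._offsets = np.cumsum([0] + self._nlev[:-1])
        self._slices = [slice(o, o + nl)
                        for o, nl in zip(self._offsets, self._nlev)]

    # -- factor-indexed linear algebra ------------------------------------

    def _zu(self, u: np.ndarray) -> np.ndarray:
        out = u[self._offsets[0] + self._codes[0]].copy()
        if len(self._codes) > 1:
            out += u[self._offsets[1] + self._codes[1]]
        return out

    def _zt(self, v: np.ndarray) -> np.ndarray:
        """Z' v via per-factor bincounts."""
        parts = [np.bincount(c, weights=v, minlength=nl)
                 for c, nl in zip(self._codes, self._nlev)]
        return np.concatenate(parts)

    def _ztwz(self, w: np.ndarray) -> np.ndarray:
        """Assemble the q x q matrix Z'WZ from the factor codes."""
        q = self._q
        A = np.zeros((q, q))
        d0 = np.bincount(self._codes[0], weights=w, minlength=self._nlev[0])
        sl0 = self._slices[0]
        A[sl0, sl0] = np.diag(d0)
        if len(self._codes) > 1:
            d1 = np.bincount(self._codes[1], weights=w, minlength=self._nlev[1])
            sl1 = self._slices[1]
            A[sl1, sl1] = np.diag(d1)
            cross = np.zeros((self._nlev[0], self._nlev[1]))
            np.add.at(cross, (self._codes[0], self._codes[1]), w)
            A[sl0, sl1] = cross
            A[sl1, sl0] = cross.T
        return A

    def _dinv(self, theta: np.ndarray) -> np.ndarray:
        dinv = np.empty(self._q)
        for sl, th in zip(self._slices, theta):
            dinv[sl] = math.exp(-2.0 * min(th, 15.0))
        return dinv

    # -- inner problem: modes of u given (beta, theta) --------------------

    def _solve_u(self, eta_fix: np.ndarray, dinv: np.ndarray,
                 u0: np.ndarray, max_iter: int = 50,
                 tol: float = 1e-10) -> tuple[np.ndarray, float]:
        y = self.endog
        u = u0.copy()
        obj_old = -np.inf
        for _ in range(max_iter):
            eta = eta_fix + self._zu(u)
            grad = self._zt(self.family.residual(y, eta)) - dinv * u
            H = self._ztwz(self.family.weights(eta))
            H[np.arange(self._q), np.arange(self._q)] += dinv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                cand = u + t * step
                obj = (self.family.loglik(y, eta_fix + self._zu(cand))
                       - 0.5 * float((dinv * cand * cand).sum()))
                if obj >= obj_old - 1e-12:
                    break
                t *= 0.5
            u = cand
            if abs(obj - obj_old) < tol * (1.0 + abs(obj)):
                obj_old = obj
                break
            obj_old = obj
        return u, obj_old

    def _laplace_llf(self, beta: np.ndarray, theta: np.ndarray,
                     u0: np.ndarray) -> tuple[float, np.ndarray]:
        dinv = self._dinv(theta)
        eta_fix = self.exog @ beta
        u, pen_ll = self._solve_u(eta_fix, dinv, u0)
        w = self.family.weights(eta_fix + self._zu(u))
        A = self._ztwz(w)
        A[np.arange(self._q), np.arange(self._q)] += dinv
        sign, ld = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf, u
        llf = pen_ll - 0.5 * (ld - float(np.log(dinv).sum()))
        return llf, u

    # -- API --------------------------------------------------------------

    def fit(self, start_logsd: float = 0.0) -> MixedGLMResults:
        p = self.exog.shape[1]
        k = len(self.group_names)
        warm = {"u": np.zeros(self._q)}

        def neg(x):
            llf, u = self._laplace_llf(x[:p], x[p:], warm["u"])
            warm["u"] = u
            return -llf

        x0 = np.concatenate([np.zeros(p), np.full(k, start_logsd)])
        res = optimize.minimize(neg, x0, method="BFGS",
                                options={"gtol": 1e-5, "maxiter": 500})
        if not res.success:
            res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                                     options={"xatol": 1e-6, "fatol": 1e-8,
                                              "maxiter": 4000})
            if res2.fun <= res.fun:
                res2.success = res.success or res2.success
                res = res2
        beta, theta = res.x[:p], res.x[p:]
        llf, u = self._laplace_llf(beta, theta, warm["u"])
        eta = self.exog @ beta + self._zu(u)
        separation = bool(np.max(np.abs(eta)) > _MAX_ETA)
        # Wald covariance of beta: Schur complement of the joint Hessian
        w = self.family.weights(eta)
        dinv = self._dinv(theta)
        Xw = self.exog * w[:, None]
        Hbb = self.exog.T @ Xw
        Hbu = np.column_stack([self._zt(Xw[:, j]) for j in range(p)]).T
        Huu = self._ztwz(w)
        Huu[np.arange(self._q), np.arange(self._q)] += dinv
        try:
            cov = np.linalg.inv(Hbb - Hbu @ np.linalg.solve(Huu, Hbu.T))
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
        re = {name: u[sl] for name, sl in zip(self.group_names, self._slices)}
        return MixedGLMResults(
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            llf=float(llf),
            re_sd={name: float(math.exp(t))
                   for name, t in zip(self.group_names, theta)},
            n_obs=len(self.endog), converged=bool(res.success),
            separation=separation, model=self, random_effects=re)


def lr_test(full: MixedGLMResults, reduced: MixedGLMResults,
            df: int | None = None) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square between nested ML fits.

    Returns (chi2, df, p).  Small negative statistics from approximation
    noise are clipped to zero.
    """
    if df is None:
        df = len(full.params) - len(reduced.params)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    return chi2, df, float(stats.chi2.sf(chi2, df)) if df > 0 else math.nan
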