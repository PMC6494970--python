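"""Linear mixed models with independent Gaussian grouping random effects.

This is the small variance-component engine the rest of the package is built
on.  It fits models of the form

    y = X beta + sum_f Z_f u_f + e,
    u_f ~ N(0, sigma_f^2 I),   e ~ N(0, sigma_E^2 I),

where every random factor f is a *grouping* factor: each observation belongs
to at most one level of f, so Z_f is a 0/1 indicator matrix.  Crossed factors
(e.g. line, bloc, line x year) are supported; statsmodels' MixedLM grouped API
cannot express these designs directly, which is why the engine exists.

Estimation profiles out sigma_E^2 and the fixed effects and optimises the
restricted (REML) or full (ML) log-likelihood over the log variance ratios
gamma_f = sigma_f^2 / sigma_E^2.  All linear algebra runs through the q x q
system A = Z'Z + diag(1/gamma), which is sparse for crossed designs and
diagonal when there is a single random factor (the per-marker scan model),
making thousands of fits per genome scan affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

__all__ = ["MixedLMM", "MixedLMMResults", "ConvergenceError", "RandomFactor"]

_LOG_GAMMA_MIN = -15.0
_LOG_GAMMA_MAX = 15.0
# below this ratio a component sits on the zero boundary and is reported as 0
_BOUNDARY_RATIO = 1e-5
_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """REML/ML optimisation failed to converge; carries optimiser diagnostics."""


@dataclass
class RandomFactor:
    """A grouping random factor: integer level codes per row, -1 = no membership."""

    name: str
    codes: np.ndarray
    levels: list

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.max(initial=-1) >= len(self.levels):
            raise ValueError(f"factor {self.name!r}: code exceeds level count")

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomFactor":
        arr = pd.Series(labels)
        mask = arr.notna()
        cats = pd.Categorical(arr[mask])
        codes = np.full(len(arr), -1, dtype=np.int64)
        codes[mask.to_numpy()] = cats.codes
        return cls(name, codes, list(cats.categories))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def indicator(self, n_rows: int) -> sparse.csc_matrix:
        rows = np.nonzero(self.codes >= 0)[0]
        cols = self.codes[rows]
        data = np.ones(len(rows))
        return sparse.csc_matrix(
            (data, (rows, cols)), shape=(n_rows, self.n_levels)
        )


class MixedLMM:
    """Mixed linear model with fixed effects X and grouping random factors.

    Parameters
    ----------
    endog : (n,) response vector; must be finite.
    exog : (n, p) fixed-effects design matrix of full column rank.
    factors : ordered list of RandomFactor (codes aligned with rows).
    exog_names : optional fixed-effect column names.
    """

    def __init__(self, endog, exog, factors, exog_names=None):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("endog and exog row counts differ")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("endog contains non-finite values")
        self.factors = list(factors)
        if not self.factors:
            raise ValueError("at least one random factor is required")
        for f in self.factors:
            if len(f.codes) != len(self.y):
                raise ValueError(f"factor {f.name!r} not aligned with endog")
        self.n, self.p = self.X.shape
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.p)
        ]
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.p:
            raise ValueError(
                f"fixed-effects design is rank deficient (rank {rank} < {self.p})"
            )
        self._prepare()

    # ------------------------------------------------------------------
    def _prepare(self) -> None:
        n = self.n
        self.q_sizes = [f.n_levels for f in self.factors]
        self.q = int(sum(self.q_sizes))
        self._single = len(self.factors) == 1
        Zs = [f.indicator(n) for f in self.factors]
        Z = sparse.hstack(Zs, format="csc")
        self.ZtX = np.asarray(Z.T @ self.X)
        self.XtX = self.X.T @ self.X
        # optimise on mean-centred y when the constant lies in span(X): the
        # REML/ML criterion is identical but the search path becomes exactly
        # location invariant
        coef, res_ss, *_ = np.linalg.lstsq(self.X, np.ones(n), rcond=None)
        fitted = self.X @ coef
        self._has_const = bool(np.max(np.abs(fitted - 1.0)) < 1e-8)
        self._y_opt = self.y - self.y.mean() if self._has_const else self.y
        self._Zty_opt = np.asarray(Z.T @ self._y_opt).ravel()
        self._Xty_opt = self.X.T @ self._y_opt
        self.Zty = np.asarray(Z.T @ self.y).ravel()
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        if self._single:
            # one grouping factor: Z'Z is the diagonal of level counts
            self._zz_diag = np.asarray(Z.multiply(Z).sum(axis=0)).ravel()
        else:
            self.ZtZ = (Z.T @ Z).tocsc()
        self._block_ix = np.concatenate(
            [np.full(qf, i) for i, qf in enumerate(self.q_sizes)]
        )

    # ------------------------------------------------------------------
    def _profiled(self, log_gamma: np.ndarray, centred: bool = False):
        """Return (S, logdet_A, logdet_XtHX, beta, u_hat, log_H) at given ratios."""
        y = self._y_opt if centred else self.y
        Zty = self._Zty_opt if centred else self.Zty
        Xty = self._Xty_opt if centred else self.Xty
        gamma = np.exp(np.clip(log_gamma, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
        d = (1.0 / gamma)[self._block_ix]
        if self._single:
            a = self._zz_diag + d
            Ainv_ZtX = self.ZtX / a[:, None]
            Ainv_Zty = Zty / a
            logdet_A = float(np.sum(np.log(a)))
        else:
            A = self.ZtZ + sparse.diags(d)
            # A is SPD: symmetric-mode ordering avoids the fill-in COLAMD
            # produces on crossed designs (bloc factor coupling all lines)
            lu = splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A",
                      diag_pivot_thresh=0.0,
                      options={"SymmetricMode": True})
            rhs = np.column_stack([self.ZtX, Zty])
            sol = lu.solve(rhs)
            Ainv_ZtX, Ainv_Zty = sol[:, :-1], sol[:, -1]
            logdet_A = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        XtHX = self.XtX - self.ZtX.T @ Ainv_ZtX
        XtHy = Xty - self.ZtX.T @ Ainv_Zty
        sign, logdet_XtHX = np.linalg.slogdet(XtHX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'H^-1X not positive definite")
        beta = np.linalg.solve(XtHX, XtHy)
        resid_proj = Zty - self.ZtX @ beta
        if self._single:
            u_hat = resid_proj / a
        else:
            u_hat = lu.solve(resid_proj)
        # offset-stable form of (y - Xb)' H^-1 (y - Xb)
        r = y - self.X @ beta
        S = max(float(r @ r) - float(resid_proj @ u_hat), 1e-300)
        log_H = float(np.sum(np.array(self.q_sizes) * log_gamma)) + logdet_A
        return S, logdet_A, logdet_XtHX, beta, u_hat, log_H, XtHX

    def _neg2ll(self, log_gamma: np.ndarray, reml: bool) -> float:
        try:
            S, _, logdet_XtHX, _, _, log_H, _ = self._profiled(log_gamma,
                                                               centred=True)
        except np.linalg.LinAlgError:
            return 1e12
        n, p = self.n, self.p
        if reml:
            df = n - p
            return df * np.log(S / df) + log_H + logdet_XtHX + df * (1 + _LOG2PI)
        return n * np.log(S / n) + log_H + n * (1 + _LOG2PI)

    # ------------------------------------------------------------------
    def fit(self, reml: bool = True, start=None, maxiter: int = 200,
            tol: float = 1e-8) -> "MixedLMMResults":
        """Estimate variance components by REML (default) or ML.

        Raises ConvergenceError if the optimiser does not converge within
        ``maxiter`` iterations.
        """
        k = len(self.factors)
        if np.var(self.y) == 0.0:
            # degenerate: a constant response carries no variance to split
            return self._degenerate_results(reml)
        x0 = np.log(np.full(k, 0.2)) if start is None else np.log(np.asarray(start))
        if k == 1:
            res = optimize.minimize_scalar(
                lambda lg: self._neg2ll(np.array([lg]), reml),
                bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX),
                method="bounded",
                options={"xatol": 1e-6, "maxiter": maxiter},
            )
            if not res.success:
                raise ConvergenceError(f"scalar REML/ML search failed: {res.message}")
            log_gamma = np.array([res.x])
            nit = res.nfev
        else:
            res = optimize.minimize(
                self._neg2ll, x0, args=(reml,), method="L-BFGS-B",
                bounds=[(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX)] * k,
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-6,
                         "eps": 1e-6},
            )
            if not res.success and "ABNORMAL" in str(res.message).upper():
                raise ConvergenceError(
                    f"L-BFGS-B failed after {res.nit} iterations: {res.message}"
                )
            if res.nit >= maxiter:
                raise ConvergenceError(f"no convergence in {maxiter} iterations")
            log_gamma = res.x
            nit = res.nit
        return self._results_at(log_gamma, reml, nit)

    # ------------------------------------------------------------------
    def _results_at(self, log_gamma, reml, nit) -> "MixedLMMResults":
        S, _, logdet_XtHX, beta, u_hat, log_H, XtHX = self._profiled(log_gamma)
        df = self.n - self.p if reml else self.n
        sigma2_e = S / df
        gamma = np.exp(log_gamma)
        # boundary truncation: ratios pinned at the lower bound are zeros
        on_boundary = gamma <= np.exp(_LOG_GAMMA_MIN) * 10 + 0.0
        gamma_rep = np.where(gamma < _BOUNDARY_RATIO, 0.0, gamma)
        vcomp = {f.name: float(g * sigma2_e) for f, g in zip(self.factors, gamma_rep)}
        blups = {}
        off = 0
        for f, g in zip(self.factors, gamma_rep):
            vals = u_hat[off: off + f.n_levels] if g > 0 else np.zeros(f.n_levels)
            blups[f.name] = pd.Series(vals, index=f.levels, name=f.name)
            off += f.n_levels
        neg2ll = self._neg2ll(log_gamma, reml)
        cov_beta = sigma2_e * np.linalg.inv(XtHX)
        return MixedLMMResults(
            model=self,
            fe_params=pd.Series(beta, index=self.exog_names),
            cov_fe=cov_beta,
            vcomp=vcomp,
            sigma2_resid=float(sigma2_e),
            blups=blups,
            reml=reml,
            neg2_loglike=float(neg2ll),
            n_iter=int(nit),
            converged=True,
            boundary={f.name: bool(b) for f, b in zip(self.factors, on_boundary)},
        )

    def _degenerate_results(self, reml) -> "MixedLMMResults":
        beta = np.zeros(self.p)
        # intercept-only solution reproduces the constant exactly
        beta_ls, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        return MixedLMMResults(
            model=self,
            fe_params=pd.Series(beta_ls, index=self.exog_names),
            cov_fe=np.zeros((self.p, self.p)),
            vcomp={f.name: 0.0 for f in self.factors},
            sigma2_resid=0.0,
            blups={
                f.name: pd.Series(np.zeros(f.n_levels), index=f.levels, name=f.name)
                for f in self.factors
            },
            reml=reml,
            neg2_loglike=float("-inf"),
            n_iter=0,
            converged=True,
            boundary={f.name: True for f in self.factors},
        )


@dataclass
class MixedLMMResults:
    """Fitted mixed model: variance components, fixed effects, BLUPs."""

    model: MixedLMM
    fe_params: pd.Series
    cov_fe: np.ndarray
    vcomp: dict
    sigma2_resid: float
    blups: dict
    reml: bool
    neg2_loglike: float
    n_iter: int
    converged: bool
    boundary: dict = field(default_factory=dict)

    @property
    def loglike(self) -> float:
        return -0.5 * self.neg2_loglike

    def fe_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_fe)), index=self.fe_params.index)

    def summary(self) -> str:
        meth = "REML" if self.reml else "ML"
        lines = [
            f"Mixed linear model ({meth}), n = {self.model.n}, "
            f"p = {self.model.p}, converged in {self.n_iter} iterations",
            "",
            "Variance components:",
        ]
        for name, v in self.vcomp.items():
            tag = "  (boundary)" if self.boundary.get(name) else ""
            lines.append(f"  {name:<16s} {v:12.6g}{tag}")
        lines.append(f"  {'residual':<16s} {self.sigma2_resid:12.6g}")
        lines.append("")
        lines.append("Fixed effects (estimate, SE):")
        se = self.fe_se()
        for name in self.fe_params.index:
            lines.append(f"  {name:<24s} {self.fe_params[name]:12.5g} {se[name]:12.5g}")
        return "\n".join(lines)
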