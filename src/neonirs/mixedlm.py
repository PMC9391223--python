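"""REML estimation for crossed variance-components mixed models.

The trial-level models here have crossed random factors (participant and
channel, or participant and channel pair), each contributing several
uncorrelated random slopes: V = sigma^2 (I + sum_k lambda_k Z_k Z_k') with
one variance ratio lambda_k per random term.  The fitter profiles the fixed
effects and the residual variance out of the REML criterion and optimises
the variance ratios with an analytic gradient, using the Woodbury/Henderson
normal-equation algebra so each evaluation costs O(q^3) in the number of
random effects q regardless of the number of observations.

Satterthwaite denominator degrees of freedom follow the classical recipe:
df = 2 f^2 / Var(f) with f = c' Cov(beta-hat) c, the variance of f obtained
by the delta method from the observed information of the variance
parameters (numerically differentiated analytic gradient).

Conditional modes (BLUPs) of every random term are available from the same
factorisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import t as t_dist

__all__ = ["RandomBlock", "VarCompMixedLM", "VarCompResults", "blocks_from_table"]

_BOUNDARY = 1e-7


@dataclass
class RandomBlock:
    """One random term: a grouping factor x a (possibly constant) covariate,
    with a single shared variance across levels."""

    name: str
    codes: np.ndarray        # (n,) integer level codes
    covariate: np.ndarray    # (n,) slope variable (ones for intercepts)
    levels: list             # level labels, len = n_levels

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def matrix(self) -> sparse.csr_matrix:
        n = len(self.codes)
        return sparse.csr_matrix(
            (self.covariate.astype(float), (np.arange(n), self.codes)),
            shape=(n, self.n_levels))


def blocks_from_table(table: pd.DataFrame, design: pd.DataFrame,
                      factor_col: str, terms: list[str],
                      prefix: str) -> list[RandomBlock]:
    """Build one RandomBlock per random term for a grouping column."""
    fac = table[factor_col].astype("category")
    codes = fac.cat.codes.to_numpy()
    levels = list(fac.cat.categories)
    out = []
    for t in terms:
        cov = np.ones(len(table)) if t == "1" else design[t].to_numpy()
        out.append(RandomBlock(f"{prefix}:{t}", codes, cov, levels))
    return out


class VarCompMixedLM:
    """Linear mixed model with uncorrelated, crossed variance components.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effects design.
    blocks : random terms (may be empty, giving OLS).
    term_names : fixed-term labels, len p.
    """

    def __init__(self, y, X, blocks: list[RandomBlock],
                 term_names: list[str] | None = None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, p) matching y")
        self.n, self.p = self.X.shape
        self.term_names = list(term_names) if term_names is not None \
            else [f"x{i}" for i in range(self.p)]
        self._check_rank()
        self.blocks = list(blocks)
        cols = []
        self.slices: list[slice] = []
        start = 0
        for b in self.blocks:
            cols.append(b.matrix())
            self.slices.append(slice(start, start + b.n_levels))
            start += b.n_levels
        self.q = start
        if self.q:
            Z = sparse.hstack(cols, format="csc")
            self.S = np.asarray((Z.T @ Z).todense())
            self.U = np.asarray(Z.T @ self.X)
            self.w = Z.T @ self.y
        else:
            self.S = np.zeros((0, 0))
            self.U = np.zeros((0, self.p))
            self.w = np.zeros(0)
        self.G = self.X.T @ self.X
        self.gx = self.X.T @ self.y
        self.yy = float(self.y @ self.y)

    def _check_rank(self) -> None:
        from numpy.linalg import matrix_rank
        r = matrix_rank(self.X)
        if r < self.p:
            # identify offending columns by greedy rank growth
            bad, kept = [], np.zeros((self.n, 0))
            for j in range(self.p):
                cand = np.column_stack([kept, self.X[:, j]])
                if matrix_rank(cand) > kept.shape[1]:
                    kept = cand
                else:
                    bad.append(self.term_names[j])
            raise ValueError(f"fixed design is rank deficient; collinear "
                             f"columns: {bad}")

    # -- core linear algebra ------------------------------------------------

    def _expand(self, lam: np.ndarray) -> np.ndarray:
        full = np.empty(self.q)
        for k, sl in enumerate(self.slices):
            full[sl] = lam[k]
        return full

    def _solve(self, lam: np.ndarray) -> dict:
        """Factorise the profiled system at variance ratios ``lam``.

        Returns the quantities needed for the criterion, its gradient, the
        GLS estimates and the BLUPs.
        """
        lam = np.maximum(np.asarray(lam, dtype=float), 0.0)
        lfull = self._expand(lam)
        l = np.sqrt(lfull)
        if self.q:
            A = (l[:, None] * self.S) * l[None, :]
            A[np.diag_indices_from(A)] += 1.0
            cf = cho_factor(A, lower=True)
            logdetA = 2.0 * np.log(np.diag(cf[0])).sum()
            K = cho_solve(cf, np.eye(self.q))
            LU = l[:, None] * self.U                 # Lambda Z'X
            Lw = l * self.w
            KLU = K @ LU
            KLw = K @ Lw
            Cxx = self.G - LU.T @ KLU
            cxy = self.gx - LU.T @ KLw
            yVy = self.yy - Lw @ KLw
        else:
            K = np.zeros((0, 0))
            logdetA = 0.0
            Cxx, cxy, yVy = self.G.copy(), self.gx.copy(), self.yy
        cfx = cho_factor(Cxx, lower=True)
        logdetC = 2.0 * np.log(np.diag(cfx[0])).sum()
        beta = cho_solve(cfx, cxy)
        Q = yVy - cxy @ beta
        Q = max(Q, 1e-300)
        sigma2 = Q / (self.n - self.p)
        out = {"lam": lam, "lfull": lfull, "l": l, "K": K,
               "logdetA": logdetA, "logdetC": logdetC, "cfx": cfx,
               "beta": beta, "Q": Q, "sigma2": sigma2}
        if self.q:
            m = self.w - self.U @ beta               # Z'(y - X beta)
            zp = m - self.S @ (l * (K @ (l * m)))    # Z' V0^-1 (y - X beta)
            out["zpy"] = zp
            out["LU"] = LU
        else:
            out["zpy"] = np.zeros(0)
        return out

    def _dev_grad(self, lam: np.ndarray) -> tuple[float, np.ndarray, dict]:
        """Profiled REML criterion and its gradient w.r.t. the ratios."""
        sol = self._solve(lam)
        npp = self.n - self.p
        dev = npp * (1.0 + np.log(2 * np.pi * sol["sigma2"])) \
            + sol["logdetA"] + sol["logdetC"]
        grad = np.zeros(len(self.blocks))
        if self.q:
            l, K, S = sol["l"], sol["K"], self.S
            B = l[:, None] * S                       # Lambda S
            KB = K @ B
            d_logA = np.diag(S) - np.einsum("ij,ij->j", B, KB)
            F = self.U.T - (sol["LU"].T @ K) @ B     # X' V0^-1 Z  (p x q)
            CinvF = cho_solve(sol["cfx"], F)
            d_logC = -np.einsum("ij,ij->j", F, CinvF)
            dQ = -sol["zpy"] ** 2
            percol = d_logA + d_logC + dQ / sol["sigma2"]
            for k, sl in enumerate(self.slices):
                grad[k] = percol[sl].sum()
        return dev, grad, sol

    # -- public API ---------------------------------------------------------

    def fit(self, start: np.ndarray | None = None, maxiter: int = 500,
            fixed_lam: np.ndarray | None = None) -> "VarCompResults":
        """Optimise the REML criterion (or evaluate at ``fixed_lam``)."""
        nb = len(self.blocks)
        if fixed_lam is not None or nb == 0:
            lam = np.zeros(nb) if fixed_lam is None else np.asarray(fixed_lam, float)
            dev, _, sol = self._dev_grad(lam)
            return VarCompResults(self, lam, sol, dev, converged=True,
                                  n_iter=0)
        x0 = np.full(nb, 0.5) if start is None else np.asarray(start, float)

        def obj(lam):
            dev, grad, _ = self._dev_grad(lam)
            return dev, grad

        res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0.0, None)] * nb,
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-7})
        lam = np.maximum(res.x, 0.0)
        dev, grad, sol = self._dev_grad(lam)
        # at a boundary optimum (lambda_k = 0) a positive gradient component
        # is expected; only the projected gradient matters
        proj = np.where((lam <= 0) & (grad > 0), 0.0, grad)
        converged = bool(res.success) or float(np.abs(proj).max()) < 1e-2
        if not converged:
            warnings.warn(f"REML optimiser did not converge: {res.message}")
        return VarCompResults(self, lam, sol, dev, converged=converged,
                              n_iter=int(res.nit))

    # unprofiled criterion in variance units, for the Satterthwaite Hessian
    def _dev_v_grad(self, v: np.ndarray, active: list[int],
                    base_lam: np.ndarray) -> tuple[float, np.ndarray]:
        sigma2 = v[-1]
        lam = base_lam.copy()
        lam[active] = v[:-1] / sigma2
        sol = self._solve(lam)
        npp = self.n - self.p
        dev = npp * np.log(2 * np.pi * sigma2) + sol["logdetA"] \
            + sol["logdetC"] + sol["Q"] / sigma2
        # gradient pieces w.r.t. lambda
        l, K, S = sol["l"], sol["K"], self.S
        if self.q:
            B = l[:, None] * S
            KB = K @ B
            d_logA = np.diag(S) - np.einsum("ij,ij->j", B, KB)
            F = self.U.T - (sol["LU"].T @ K) @ B
            CinvF = cho_solve(sol["cfx"], F)
            d_logC = -np.einsum("ij,ij->j", F, CinvF)
            dQ = -sol["zpy"] ** 2
            dlam_col = d_logA + d_logC + dQ / sigma2
            dlam = np.array([dlam_col[self.slices[k]].sum()
                             for k in range(len(self.blocks))])
        else:
            dlam = np.zeros(0)
        g = np.empty(len(v))
        g[:-1] = dlam[active] / sigma2
        dsig = npp / sigma2 - sol["Q"] / sigma2 ** 2
        if len(active):
            dsig += float(np.sum(dlam[active] * (-v[:-1] / sigma2 ** 2)))
        g[-1] = dsig
        return dev, g


class VarCompResults:
    """REML fit: fixed estimates, variance components, BLUPs, Satterthwaite
    tests and a summary table."""

    def __init__(self, model: VarCompMixedLM, lam: np.ndarray, sol: dict,
                 deviance: float, converged: bool, n_iter: int):
        self.model = model
        self.lam = lam
        self._sol = sol
        self.deviance = deviance
        self.converged = converged
        self.n_iter = n_iter
        self.scale = sol["sigma2"]                      # residual variance
        self.fe_params = pd.Series(sol["beta"], index=model.term_names)
        cov = self.scale * cho_solve(sol["cfx"], np.eye(model.p))
        self.cov_params = pd.DataFrame(cov, index=model.term_names,
                                       columns=model.term_names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=model.term_names)
        self.vcomp = pd.Series(
            {b.name: lam[k] * self.scale
             for k, b in enumerate(model.blocks)})
        self.singular = bool(np.any(lam <= _BOUNDARY)) if len(lam) else False
        self._hess_cov = None

    # -- random effects -----------------------------------------------------

    def blups(self, block_name: str) -> pd.Series:
        """Conditional modes of one random term, indexed by level label."""
        m = self.model
        for k, b in enumerate(m.blocks):
            if b.name == block_name:
                vals = self.lam[k] * self._sol["zpy"][m.slices[k]]
                return pd.Series(vals, index=b.levels, name=block_name)
        raise KeyError(f"no random term named {block_name!r}; have "
                       f"{[b.name for b in m.blocks]}")

    # -- Satterthwaite machinery ---------------------------------------------

    def _active(self) -> list[int]:
        return [k for k in range(len(self.lam)) if self.lam[k] > _BOUNDARY]

    def _vcov_varpar(self):
        """Asymptotic covariance of the active variance parameters
        (sigma_k^2 ..., sigma^2): twice the inverse observed information of
        the REML criterion, Hessian from central differences of the
        analytic gradient."""
        if self._hess_cov is not None:
            return self._hess_cov
        m = self.model
        active = self._active()
        v0 = np.append(self.lam[active] * self.scale, self.scale)
        K = len(v0)
        H = np.zeros((K, K))
        for i in range(K):
            h = 1e-4 * max(abs(v0[i]), 1e-3 * self.scale)
            vp, vm = v0.copy(), v0.copy()
            vp[i] += h
            vm[i] = max(vm[i] - h, 1e-12)
            _, gp = m._dev_v_grad(vp, active, self.lam)
            _, gm = m._dev_v_grad(vm, active, self.lam)
            H[i] = (gp - gm) / (vp[i] - vm[i])
        H = (H + H.T) / 2.0
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
        self._hess_cov = (active, v0, cov)
        return self._hess_cov

    def _contrast_var_grad(self, c: np.ndarray, active: list[int]):
        """f = c' Cov(beta) c and its analytic gradient w.r.t. the active
        variance parameters and sigma^2."""
        m = self.model
        sol = self._sol
        uc = cho_solve(sol["cfx"], c)
        f = self.scale * float(c @ uc)
        if m.q:
            l, K = sol["l"], sol["K"]
            B = l[:, None] * m.S
            F = m.U.T - (sol["LU"].T @ K) @ B
            Fu = F.T @ uc                        # (q,)
            percol = Fu ** 2
            dlam = np.array([percol[m.slices[k]].sum()
                             for k in range(len(m.blocks))])
        else:
            dlam = np.zeros(0)
        g = np.empty(len(active) + 1)
        g[:-1] = dlam[active]                    # d f / d sigma_k^2
        g[-1] = f / self.scale - float(
            np.sum(dlam[active] * self.lam[active])) if len(active) \
            else f / self.scale
        return f, g

    def satterthwaite_df(self, term: str | np.ndarray) -> float:
        """Satterthwaite denominator df for one fixed term (or an arbitrary
        contrast vector).  Falls back to +inf (normal approximation) with a
        warning when the information matrix is unusable."""
        c = self._contrast(term)
        active, _, cov = self._vcov_varpar()
        f, g = self._contrast_var_grad(c, active)
        if cov is None:
            warnings.warn("variance-parameter information singular; "
                          "using normal approximation (df = inf)")
            return np.inf
        denom = float(g @ cov @ g)
        if not np.isfinite(denom) or denom <= 0:
            warnings.warn("nonpositive variance of the contrast variance; "
                          "using normal approximation (df = inf)")
            return np.inf
        df = 2.0 * f ** 2 / denom
        return float(df) if df > 0 else np.inf

    def _contrast(self, term) -> np.ndarray:
        if isinstance(term, str):
            c = np.zeros(self.model.p)
            c[self.model.term_names.index(term)] = 1.0
            return c
        return np.asarray(term, dtype=float)

    def test_term(self, term: str) -> dict:
        """Estimate, s.e.m., Satterthwaite df, t and two-tailed p for one
        fixed term."""
        beta = float(self.fe_params[term])
        se = float(self.bse[term])
        df = self.satterthwaite_df(term)
        tval = beta / se
        if np.isfinite(df):
            p = 2.0 * t_dist.sf(abs(tval), df)
        else:
            from scipy.stats import norm
            p = 2.0 * norm.sf(abs(tval))
        return {"term": term, "beta": beta, "sem": se, "df": df,
                "t": tval, "p": float(p)}

    def summary(self, terms: list[str] | None = None) -> pd.DataFrame:
        """Fixed-effects table (beta, sem, df, t, p) plus variance
        components attached as DataFrame attrs."""
        terms = terms or self.model.term_names
        rows = [self.test_term(t) for t in terms]
        out = pd.DataFrame(rows).set_index("term")
        out.attrs["vcomp"] = self.vcomp.to_dict()
        out.attrs["sigma2"] = self.scale
        out.attrs["converged"] = self.converged
        out.attrs["singular"] = self.singular
        return out

    def conf_int(self, term: str, alpha: float = 0.05) -> tuple[float, float]:
        r = self.test_term(term)
        df = r["df"] if np.isfinite(r["df"]) else 1e9
        half = t_dist.ppf(1 - alpha / 2, df) * r["sem"]
        return r["beta"] - half, r["beta"] + half
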