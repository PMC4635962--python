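"""Repeated-measures multi-GRM mixed model fit by average-information REML.

Model
-----
    y = X b + Z a_1 + ... + Z a_C + Z p + e

with y the m-vector of replicate-level phenotypes for n strains, Z the m x n
incidence matrix mapping measures to strains, a_c ~ N(0, s2_c K_c) genetic
effects for each supplied GRM K_c (e.g. the additive GRM A and its Hadamard
square A o A), p ~ N(0, s2_p I_n) the residual strain-repeatability effect and
e ~ N(0, s2_e I_m) measurement error, so that

    V = sum_c s2_c Z K_c Z^T + s2_p Z Z^T + s2_e I_m.

The restricted likelihood is maximised by average-information (AI) updates
with an expectation-maximisation first step and step-halving fallback, which
keeps accepted iterations monotone in the restricted log-likelihood.
Components are clamped at a small positive floor when updates go negative and
re-enter the AI system when their score turns positive. Standard errors come
from the inverse of the AI matrix at convergence (the average-information
approximation to the Fisher information).

With equal replicate counts and strain-constant fixed effects the fit is
reduced exactly to strain means plus a within-strain sum of squares, which
turns the m-dimensional problem into an n-dimensional one; unbalanced designs
use the full m-dimensional form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["ModelSpec", "VarCompFit", "fit_aireml", "blup_effects", "variance_fractions"]

_FLOOR_FRAC = 1e-6  # boundary clamp, as a fraction of var(y)


@dataclass
class ModelSpec:
    """Inputs of one variance-component fit.

    Parameters
    ----------
    y : (m,) replicate-level phenotype vector.
    strain : (m,) integer strain codes in 0..n_strains-1 (the incidence Z).
    n_strains : number of strains n.
    K : ordered mapping component name -> (n, n) GRM.
    X : optional (m, p) fixed-effect design; defaults to an intercept column.
    include_strain_term : add the strain-repeatability component Z I_n Z^T.
    """

    y: np.ndarray
    strain: np.ndarray
    n_strains: int
    K: dict[str, np.ndarray]
    X: np.ndarray | None = None
    include_strain_term: bool = True

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        self.strain = np.asarray(self.strain, dtype=np.int64)
        m = self.y.size
        if self.strain.shape != (m,):
            raise ValueError("y and strain must have the same length")
        if self.X is None:
            self.X = np.ones((m, 1))
        else:
            self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
            if self.X.shape[0] != m:
                raise ValueError("X must have one row per observation")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")
        for name, Kc in self.K.items():
            if Kc.shape != (self.n_strains, self.n_strains):
                raise ValueError(f"GRM {name!r} is not n x n")

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def component_names(self) -> list[str]:
        names = list(self.K)
        if self.include_strain_term:
            names.append("strain")
        names.append("error")
        return names

    def replicate_counts(self) -> np.ndarray:
        return np.bincount(self.strain, minlength=self.n_strains)


@dataclass
class VarCompFit:
    """Result of an AI-REML fit."""

    sigma2: dict[str, float]
    se: dict[str, float]
    beta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    fractions: dict[str, float] = field(default_factory=dict)
    fractions_se: dict[str, float] = field(default_factory=dict)
    ai_cov: np.ndarray | None = None
    loglik_trace: list = field(default_factory=list)
    # strain-level projected residual Z^T V^{-1} (y - X beta), used for BLUPs
    _zt_vinv_resid: np.ndarray | None = None
    _K: dict | None = None

    def to_dict(self) -> dict:
        return {
            "sigma2": self.sigma2,
            "se": self.se,
            "beta": self.beta.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "fractions": self.fractions,
            "fractions_se": self.fractions_se,
            "loglik_trace": [float(v) for v in self.loglik_trace],
        }


class _RemlProblem:
    """Gaussian working data u ~ N(Xd b, sum_c s2_c B_c), plus an optional
    independent chi-square block (df, SS) attached to the error component
    (the within-strain part of the balanced-design reduction)."""

    def __init__(self, u, Xd, comps, df_extra=0.0, ss_extra=0.0):
        self.u = u
        self.Xd = Xd
        self.comps = comps  # list of (name, B) with B=None meaning identity
        self.names = [name for name, _ in comps]
        self.df_extra = float(df_extra)
        self.ss_extra = float(ss_extra)
        self.N = u.size

    def _build_V(self, sig):
        V = np.zeros((self.N, self.N))
        for s2, (name, B) in zip(sig, self.comps):
            if B is None:
                V[np.diag_indices_from(V)] += s2
            else:
                V += s2 * B
        return V

    def loglik(self, sig):
        return self._core(sig, derivs=False)[0]

    def _core(self, sig, derivs=True):
        V = self._build_V(sig)
        s2e = sig[self.names.index("error")]
        try:
            cf = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf, None
        ldV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi_X = cho_solve(cf, self.Xd, check_finite=False)
        XtViX = self.Xd.T @ Vi_X
        cfx = cho_factor(XtViX, lower=True, check_finite=False)
        ld_XtViX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        Vi_u = cho_solve(cf, self.u, check_finite=False)
        beta = cho_solve(cfx, self.Xd.T @ Vi_u, check_finite=False)
        Pu = Vi_u - Vi_X @ beta
        uPu = self.u @ Pu
        ll = -0.5 * (ldV + ld_XtViX + uPu)
        if self.df_extra > 0:
            ll -= 0.5 * (self.df_extra * np.log(s2e) + self.ss_extra / s2e)
        if not derivs:
            return ll, None

        Vi = cho_solve(cf, np.eye(self.N), check_finite=False)
        nC = len(self.comps)
        T = np.empty((self.N, nC))  # B_c P u
        trPB = np.empty(nC)
        for c, (name, B) in enumerate(self.comps):
            if B is None:
                T[:, c] = Pu
                trVB = np.trace(Vi)
                W = Vi_X
            else:
                T[:, c] = B @ Pu
                trVB = float(np.sum(Vi * B))
                W = B @ Vi_X
            corr = cho_solve(cfx, Vi_X.T @ W, check_finite=False)
            trPB[c] = trVB - np.trace(corr)
        # P applied to each T column
        PT = Vi @ T - Vi_X @ cho_solve(cfx, Vi_X.T @ T, check_finite=False)
        AI = 0.5 * (T.T @ PT)
        score = -0.5 * (trPB - T.T @ Pu)
        e_idx = self.names.index("error")
        if self.df_extra > 0:
            score[e_idx] += -0.5 * (self.df_extra / s2e - self.ss_extra / s2e**2)
            AI[e_idx, e_idx] += 0.5 * self.ss_extra / s2e**3
        return ll, {"score": score, "AI": AI, "beta": beta, "Pu": Pu, "trPB": trPB, "T": T}


def _prepare_problem(spec: ModelSpec):
    """Build the working REML problem, reducing balanced designs exactly."""
    m, n = spec.n_obs, spec.n_strains
    counts = spec.replicate_counts()
    balanced = counts.min() == counts.max() and counts.min() >= 1
    Xs = None
    if balanced:
        # fixed effects must be constant within strain for the reduction
        r = int(counts[0])
        order = np.argsort(spec.strain, kind="stable")
        Xs = np.empty((n, spec.X.shape[1]))
        ok = True
        for j in range(spec.X.shape[1]):
            col_sum = np.bincount(spec.strain, weights=spec.X[:, j], minlength=n)
            Xs[:, j] = col_sum / r
            ok = ok and np.allclose(spec.X[:, j], Xs[spec.strain, j])
        balanced = ok
    if balanced:
        r = int(counts[0])
        ybar = np.bincount(spec.strain, weights=spec.y, minlength=n) / r
        ssw = float(np.sum((spec.y - ybar[spec.strain]) ** 2))
        u = np.sqrt(r) * ybar
        Xd = np.sqrt(r) * Xs
        comps = [(name, r * Kc) for name, Kc in spec.K.items()]
        if spec.include_strain_term:
            comps.append(("strain", r * np.eye(n)))
        comps.append(("error", None))
        prob = _RemlProblem(u, Xd, comps, df_extra=m - n, ss_extra=ssw)
        meta = {"reduced": True, "r": r}
    else:
        Zidx = spec.strain
        comps = []
        for name, Kc in spec.K.items():
            comps.append((name, Kc[np.ix_(Zidx, Zidx)]))
        if spec.include_strain_term:
            comps.append(("strain", (Zidx[:, None] == Zidx[None, :]).astype(float)))
        comps.append(("error", None))
        prob = _RemlProblem(spec.y, spec.X, comps)
        meta = {"reduced": False}
    return prob, meta


def fit_aireml(spec: ModelSpec, tol: float = 1e-4, max_iter: int = 100) -> VarCompFit:
    """Fit the multi-GRM repeated-measures model by AI-REML.

    Convergence is declared when the restricted log-likelihood changes by
    less than ``tol`` between accepted iterations. Non-convergence within
    ``max_iter`` is flagged on the result, not raised.
    """
    prob, meta = _prepare_problem(spec)
    names = prob.names
    nC = len(names)
    var_y = float(np.var(spec.y))
    scale = max(var_y, 1e-12)
    floor = _FLOOR_FRAC * scale

    sig = np.full(nC, max(var_y / nC, floor))
    ll, info = prob._core(sig)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if info is None:
            break
        score, AI = info["score"], info["AI"]
        weights = np.full(nC, float(prob.N))
        e_idx = names.index("error")
        weights[e_idx] += prob.df_extra
        em_step = sig**2 * (2.0 * score) / weights  # = sig^2 (uPBPu - trPB)/N
        if it == 1:
            cand_steps = [em_step]
        else:
            # AI direction on the free (non-clamped or positive-score) set
            free = (sig > floor * 1.0001) | (score > 0)
            delta = np.zeros(nC)
            if free.any():
                Af = AI[np.ix_(free, free)]
                try:
                    delta[free] = np.linalg.solve(
                        Af + 1e-8 * np.eye(free.sum()) * np.trace(Af), score[free]
                    )
                except np.linalg.LinAlgError:
                    delta[free] = score[free] / np.maximum(np.diag(Af), 1e-12)
            cand_steps = [delta, 0.5 * delta, 0.25 * delta, 0.1 * delta, em_step, 0.5 * em_step]
        accepted = False
        for step in cand_steps:
            cand = np.maximum(sig + step, floor)
            ll_new, info_new = prob._core(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                sig, info = cand, info_new
                accepted = True
                break
        if not accepted:
            converged = True
            break
        trace.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        warnings.warn("AI-REML did not converge within max_iter", stacklevel=2)

    ll, info = prob._core(sig)
    if info is None:  # degenerate input (e.g. constant y): report floor fit
        beta = np.linalg.lstsq(spec.X, spec.y, rcond=None)[0]
        sigma2 = dict(zip(names, sig))
        return VarCompFit(sigma2, {k: np.nan for k in names}, beta, -np.inf, it, True)

    AI = info["AI"]
    try:
        ai_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        ai_cov = np.linalg.pinv(AI)
    se = np.sqrt(np.maximum(np.diag(ai_cov), 0.0))

    # delta-method SEs for variance fractions f_c = s2_c / sum(s2)
    total = float(sig.sum())
    frac = sig / total
    frac_se = np.empty(nC)
    for c in range(nC):
        grad = -sig[c] / total**2 * np.ones(nC)
        grad[c] += 1.0 / total
        frac_se[c] = np.sqrt(max(grad @ ai_cov @ grad, 0.0))

    fit = VarCompFit(
        sigma2=dict(zip(names, sig.tolist())),
        se=dict(zip(names, se.tolist())),
        beta=info["beta"],
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        fractions=dict(zip(names, frac.tolist())),
        fractions_se=dict(zip(names, frac_se.tolist())),
        ai_cov=ai_cov,
        loglik_trace=trace,
    )
    # strain-level projected residual for BLUPs
    Pu = info["Pu"]
    if meta["reduced"]:
        fit._zt_vinv_resid = np.sqrt(meta["r"]) * Pu
    else:
        fit._zt_vinv_resid = np.bincount(spec.strain, weights=Pu, minlength=spec.n_strains)
    fit._K = dict(spec.K)
    return fit


def blup_effects(fit: VarCompFit, spec: ModelSpec, component: str) -> np.ndarray:
    """Best linear unbiased predictor of one random effect, per strain.

    u_hat_c = s2_c K_c Z^T V^{-1} (y - X beta_hat); for the strain term
    K_c = I_n.
    """
    if fit._zt_vinv_resid is None:
        raise ValueError("fit does not carry BLUP information")
    if component == "strain":
        if not spec.include_strain_term:
            raise KeyError("model has no strain term")
        return fit.sigma2["strain"] * fit._zt_vinv_resid
    if component not in spec.K:
        raise KeyError(f"unknown component {component!r}")
    return fit.sigma2[component] * (spec.K[component] @ fit._zt_vinv_resid)


def variance_fractions(fit: VarCompFit) -> "pd.DataFrame":
    """Per-component variance fractions with delta-method standard errors."""
    import pandas as pd

    total = sum(fit.sigma2.values())
    if total <= 0:
        raise ValueError("total variance is zero")
    return pd.DataFrame(
        {
            "component": list(fit.sigma2),
            "sigma2": list(fit.sigma2.values()),
            "sigma2_se": [fit.se[k] for k in fit.sigma2],
            "fraction": [fit.fractions[k] for k in fit.sigma2],
            "fraction_se": [fit.fractions_se[k] for k in fit.sigma2],
        }
    )
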