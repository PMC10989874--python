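"""Logistic mixed-model association for dichotomized traits (GMMAT-style).

Recalcitrance (zero vs nonzero regeneration) is modeled as a binary outcome
with a logit link and a polygenic random effect whose covariance is the same
kinship matrix the Gaussian mixed model uses. Fitting is by penalized
quasi-likelihood (PQL): iterate a logistic working response and a linear
mixed-model solve until the fixed effects stabilize. Per-SNP inference uses
the efficient score test under the null fit; Wald p-values come from a full
refit with the SNP in the fixed effects and are intended for the small set
of SNPs that a score scan (or ART windows over it) flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from .core import GenotypeMatrix
from .lmm import NullModelFit, _align_inputs, _check_design
from .popstruct import Kinship

_LATENT_VAR = np.pi ** 2 / 3.0  # logistic latent-scale residual variance


def _normalize_K(K, n):
    Kmat = K.K if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    if Kmat.shape != (n, n):
        raise ValueError("kinship dimension does not match samples")
    return Kmat / (np.trace(Kmat) / n)


def _working_reml_sigma(z, X, Kn, w, bounds=(-8.0, 4.0)):
    """REML estimate of sigma_g^2 for z = Xb + u + e, e ~ N(0, diag(1/w))."""
    n, p = X.shape

    def neg_ll(log_s2):
        s2 = np.exp(log_s2)
        Sigma = s2 * Kn + np.diag(1.0 / w)
        c, low = cho_factor(Sigma, lower=True)
        Si_z = cho_solve((c, low), z)
        Si_X = cho_solve((c, low), X)
        XtSiX = X.T @ Si_X
        beta = np.linalg.solve(XtSiX, X.T @ Si_z)
        r = z - X @ beta
        Si_r = cho_solve((c, low), r)
        ld_sigma = 2.0 * np.sum(np.log(np.diag(c)))
        _, ld_xsx = np.linalg.slogdet(XtSiX)
        return 0.5 * (ld_sigma + ld_xsx + float(r @ Si_r))

    res = minimize_scalar(neg_ll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    s2 = float(np.exp(res.x))
    if neg_ll(bounds[0]) < res.fun:  # boundary: effectively zero
        s2 = float(np.exp(bounds[0]))
    return s2


def fit_glmm_null(y, X, K, sigma_g2: float | None = None, max_iter: int = 50,
                  tol: float = 1e-6, trait: str = "") -> NullModelFit:
    """PQL fit of the binomial (logit) null mixed model.

    ``sigma_g2=None`` estimates the polygenic variance by REML on the
    working response at each outer iteration; a fixed value (e.g. 0) skips
    estimation. Raises on separation (fitted probabilities pinned at 0/1).
    The reported h2_SNP is on the latent logistic scale,
    ``sigma_g^2 / (sigma_g^2 + pi^2/3)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial trait must be 0/1")
    if y.min() == y.max():
        raise ValueError("dichotomized trait has no variation")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _check_design(X, names)
    n, p = X.shape
    Kn = _normalize_K(K, n)

    beta = np.zeros(p)
    beta[0] = np.log(y.mean() / (1.0 - y.mean()))  # intercept at observed odds
    b = np.zeros(n)
    s2 = 0.5 if sigma_g2 is None else float(sigma_g2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + b
        mu = expit(eta)
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
            raise ValueError(
                "separation detected (fitted probabilities pinned at 0/1); "
                "reduce covariates")
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        if sigma_g2 is None:
            s2 = _working_reml_sigma(z, X, Kn, w)
        Sigma = s2 * Kn + np.diag(1.0 / w)
        c, low = cho_factor(Sigma, lower=True)
        Si_z = cho_solve((c, low), z)
        Si_X = cho_solve((c, low), X)
        XtSiX = X.T @ Si_X
        beta_new = np.linalg.solve(XtSiX, X.T @ Si_z)
        b = s2 * (Kn @ cho_solve((c, low), z - X @ beta_new))
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    eta = X @ beta + b
    mu = expit(eta)
    w = mu * (1.0 - mu)
    Sigma = s2 * Kn + np.diag(1.0 / w)
    Si = np.linalg.inv(Sigma)
    XtSiX_inv = np.linalg.inv(X.T @ Si @ X)
    P = Si - Si @ X @ XtSiX_inv @ X.T @ Si
    h2 = s2 / (s2 + _LATENT_VAR)
    return NullModelFit(
        sigma_g2=s2, sigma_e2=_LATENT_VAR, beta=beta, loglik=np.nan,
        h2_snp=h2, family="binomial", trait=trait, converged=converged,
        _ctx={"P": P, "mu": mu, "resid": y - mu, "y": y, "X": X, "Kn": Kn,
              "XtSiX_inv": XtSiX_inv, "w": w},
    )


def glmm_score_tests(null: NullModelFit, dosages: np.ndarray) -> pd.DataFrame:
    """Efficient score tests: U = g'(y - mu), Var(U) = g' P g, p from chi2_1."""
    if null.family != "binomial":
        raise ValueError("score test requires a binomial null fit")
    ctx = null._ctx
    D = np.array(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    miss = D < 0
    if miss.any():
        mu = np.nanmean(np.where(miss, np.nan, D), axis=0)
        D = np.where(miss, mu[None, :], D)
    mono = D.std(axis=0) == 0
    U = D.T @ ctx["resid"]
    PG = ctx["P"] @ D
    V = np.einsum("ij,ij->j", D, PG)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = U ** 2 / V
    stat = np.where(V <= 0, 0.0, stat)
    p = chi2.sf(stat, df=1)
    p = np.where(stat == 0.0, 1.0, p)
    out = pd.DataFrame({"beta": np.nan, "se": np.nan, "stat": stat, "p": p,
                        "test": "glmm_score"})
    out.loc[mono, ["stat", "p"]] = np.nan
    out["skip"] = np.where(mono, "monomorphic", "")
    return out


def glmm_score_test(null: NullModelFit, g) -> dict:
    return glmm_score_tests(null, np.asarray(g, dtype=float)).iloc[0].to_dict()


def glmm_wald_refit(y, X, K, g, **kwargs) -> dict:
    """Refit the PQL model with the SNP in the fixed effects; Wald p for it.

    Pass ``sigma_g2`` (e.g. the null-model estimate) to hold the polygenic
    variance fixed during the refit; re-estimating it per SNP is noisier and
    occasionally collapses the variance component for strong signals.
    """
    g = np.asarray(g, dtype=float).ravel()
    if g.std() == 0:
        return {"beta": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
                "test": "glmm_wald", "skip": "monomorphic"}
    Xg = np.column_stack([np.asarray(X, dtype=float), g])
    fit = fit_glmm_null(y, Xg, K, **kwargs)
    se = float(np.sqrt(fit._ctx["XtSiX_inv"][-1, -1]))
    beta = float(fit.beta[-1])
    z = beta / se
    return {"beta": beta, "se": se, "stat": z,
            "p": float(2.0 * norm.sf(abs(z))), "test": "glmm_wald", "skip": ""}


class LogisticMixedGWAS(BaseEstimator):
    """Genome scan for a dichotomized trait with the logistic mixed model.

    ``fit`` estimates the null PQL model and runs score tests for every SNP
    passing the MAF/missingness filters. ``wald_refit(positions)`` computes
    Wald p-values for a chosen subset (the two-round protocol used with ART).
    """

    def __init__(self, maf_min: float = 0.05, max_missing: float = 0.10):
        self.maf_min = maf_min
        self.max_missing = max_missing

    def fit(self, G: GenotypeMatrix, y, covariates=None, kinship=None,
            trait: str = ""):
        y_arr, X, Gs, K = _align_inputs(G, y, covariates, kinship, self.maf_min)
        Gs = Gs.filtered(maf_min=self.maf_min, max_missing=self.max_missing)
        self.null_ = fit_glmm_null(y_arr, X, K, trait=trait)
        self._y, self._X, self._K, self._G = y_arr, X, K, Gs
        res = glmm_score_tests(self.null_, Gs.dosages)
        res.insert(0, "chrom", Gs.chrom.astype(str))
        res.insert(1, "pos", Gs.pos)
        res.insert(2, "maf", Gs.maf())
        self.results_ = res[res["skip"] == ""].drop(columns="skip").reset_index(drop=True)
        return self

    def wald_refit(self, positions) -> pd.DataFrame:
        """Wald refits for SNPs at the given (chrom, pos) pairs.

        The polygenic variance is held at the null-model estimate.
        """
        want = set(map(tuple, positions))
        rows = []
        D = self._G.imputed()
        for j in range(self._G.n_snps):
            key = (str(self._G.chrom[j]), int(self._G.pos[j]))
            if key not in want:
                continue
            r = glmm_wald_refit(self._y, self._X, self._K, D[:, j],
                                sigma_g2=self.null_.sigma_g2)
            r.update({"chrom": key[0], "pos": key[1]})
            rows.append(r)
        return pd.DataFrame(rows)
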