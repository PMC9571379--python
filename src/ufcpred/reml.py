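"""REML estimation for variance-component models with independent random
effects.

The model is ``y = X b + sum_i Z_i u_i + e`` with ``u_i ~ N(0, s2_i I)`` and
``e ~ N(0, s2_e I)``.  Writing ``g_i = s2_i / s2_e``, the scaled covariance
``V* = V / s2_e = I + W G W'`` involves only the variance ratios, so the
restricted likelihood is maximised over the (log) ratios with the residual
variance and fixed effects profiled out analytically.  All linear algebra
runs through the Woodbury identity at the size of the total number of random
levels M, never n x n, which keeps fits with thousands of records cheap.

The optimiser is derivative-free (Nelder-Mead over log-ratios; golden-section
for a single ratio), which is robust for the small component counts used
here (at most four).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, sparse

__all__ = ["RandomTerm", "MixedModelFit", "fit_mixed", "factor_codes"]

_LOG_RATIO_BOUNDS = (-23.0, 16.0)
_VAR_FLOOR = 1e-10


def factor_codes(values) -> tuple[np.ndarray, list]:
    """Integer codes and level list for a categorical vector."""
    levels, codes = np.unique(np.asarray(values, dtype=object), return_inverse=True)
    return codes.astype(np.int64), levels.tolist()


@dataclass
class RandomTerm:
    """One i.i.d. random factor: a name and an integer level code per record.

    A code of -1 marks a record that does not load on this term (used for
    family-specific genetic terms, where only the family's own records carry
    the effect).
    """

    name: str
    codes: np.ndarray
    levels: list | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.levels is None:
            self.levels = [str(i) for i in range(int(self.codes.max()) + 1)]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def from_values(cls, name: str, values) -> "RandomTerm":
        levels, codes = np.unique(np.asarray(values, dtype=object),
                                  return_inverse=True)
        return cls(name, codes.astype(np.int64), levels.tolist())


@dataclass
class MixedModelFit:
    """Result of a REML fit."""

    beta: np.ndarray
    varcomps: dict  # term name -> variance (trait units^2)
    sigma2_e: float
    loglik: float  # restricted log-likelihood (constant terms dropped)
    converged: bool
    n_obs: int
    blups: dict = field(default_factory=dict)  # term name -> level effects
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None  # conditional residuals
    message: str = ""

    def varcomp(self, name: str) -> float:
        return self.varcomps[name]


class _WorkSpace:
    """Precomputed cross-products for repeated likelihood evaluations."""

    def __init__(self, y, X, terms):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = y.size
        if X.shape[0] != n:
            raise ValueError("X rows must match y")
        self.y, self.X, self.terms, self.n = y, X, terms, n
        self.p = X.shape[1]
        blocks = []
        offsets = [0]
        for t in terms:
            if t.codes.size != n:
                raise ValueError(f"term {t.name!r} codes length mismatch")
            active = t.codes >= 0
            Z = sparse.csr_matrix(
                (np.ones(int(active.sum())),
                 (np.flatnonzero(active), t.codes[active])),
                shape=(n, t.n_levels),
            )
            blocks.append(Z)
            offsets.append(offsets[-1] + t.n_levels)
        self.W = sparse.hstack(blocks, format="csr") if blocks else None
        self.offsets = offsets
        self.M = offsets[-1]
        if self.W is not None:
            self.WtW = np.asarray((self.W.T @ self.W).todense())
            self.WtX = np.asarray(self.W.T @ X)
            self.Wty = np.asarray(self.W.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

        # fast path: absorb the largest all-records random factor, whose
        # scaled covariance I + g Z Z' is block-diagonal by level
        self.absorb = None
        cand = [i for i, t in enumerate(terms) if t.codes.min(initial=1) >= 0]
        if cand:
            self.absorb = max(cand, key=lambda i: terms[i].n_levels)
            t = terms[self.absorb]
            Za = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), t.codes)), shape=(n, t.n_levels)
            )
            self.a_counts = np.bincount(t.codes, minlength=t.n_levels).astype(float)
            rest = [j for j in range(len(terms)) if j != self.absorb]
            self.rest_idx = rest
            cols = np.concatenate(
                [np.arange(self.offsets[j], self.offsets[j + 1]) for j in rest]
            ) if rest else np.array([], dtype=int)
            self.rest_cols = cols
            Wr = self.W[:, cols] if cols.size else None
            self.ZaW = np.asarray((Za.T @ Wr).todense()) if Wr is not None else None
            self.ZaX = np.asarray(Za.T @ X)
            self.Zay = np.asarray(Za.T @ y).ravel()
            self.WrtW = self.WtW[np.ix_(cols, cols)] if cols.size else None
            self.WrtX = self.WtX[cols] if cols.size else None
            self.Wrty = self.Wty[cols] if cols.size else None

    def expand(self, gammas: np.ndarray) -> np.ndarray:
        """Per-level ratio vector from per-term ratios."""
        s = np.empty(self.M)
        for i, t in enumerate(self.terms):
            s[self.offsets[i]:self.offsets[i + 1]] = gammas[i]
        return s

    def core(self, gammas: np.ndarray):
        """Return (XtVinvX, XtVinvy, ytVinvy, logdetK) for V* = I + W G W'."""
        if self.W is None or self.M == 0:
            return self.XtX, self.Xty, self.yty, 0.0
        s = np.sqrt(self.expand(gammas))
        K = np.eye(self.M) + (s[:, None] * s[None, :]) * self.WtW
        cf = linalg.cho_factor(K, lower=True, check_finite=False)
        logdetK = 2.0 * np.log(np.diag(cf[0])).sum()
        A = s[:, None] * self.WtX  # M x p
        a = s * self.Wty
        KiA = linalg.cho_solve(cf, A, check_finite=False)
        Kia = linalg.cho_solve(cf, a, check_finite=False)
        XtVinvX = self.XtX - A.T @ KiA
        XtVinvy = self.Xty - A.T @ Kia
        ytVinvy = self.yty - a @ Kia
        return XtVinvX, XtVinvy, ytVinvy, logdetK

    def core_absorbed(self, gammas: np.ndarray):
        """Same quantities as :meth:`core`, exploiting the block-diagonal
        structure of the absorbed factor: O(n + M'^3) per evaluation."""
        ga = gammas[self.absorb]
        d = ga / (1.0 + self.a_counts * ga)  # Sherman-Morrison weight per level
        logdetB = float(np.log1p(self.a_counts * ga).sum())
        # B-inverse cross-products via the absorbed group sums
        XtBX = self.XtX - self.ZaX.T @ (d[:, None] * self.ZaX)
        XtBy = self.Xty - self.ZaX.T @ (d * self.Zay)
        ytBy = self.yty - float(self.Zay @ (d * self.Zay))
        if self.ZaW is None or self.rest_cols.size == 0:
            return XtBX, XtBy, ytBy, logdetB
        WtBW = self.WrtW - self.ZaW.T @ (d[:, None] * self.ZaW)
        WtBX = self.WrtX - self.ZaW.T @ (d[:, None] * self.ZaX)
        WtBy = self.Wrty - self.ZaW.T @ (d * self.Zay)
        g_rest = np.concatenate([
            np.full(self.terms[j].n_levels, gammas[j]) for j in self.rest_idx
        ])
        s = np.sqrt(g_rest)
        K = np.eye(s.size) + (s[:, None] * s[None, :]) * WtBW
        cf = linalg.cho_factor(K, lower=True, check_finite=False)
        logdetK = 2.0 * np.log(np.diag(cf[0])).sum() + logdetB
        A = s[:, None] * WtBX
        a = s * WtBy
        KiA = linalg.cho_solve(cf, A, check_finite=False)
        Kia = linalg.cho_solve(cf, a, check_finite=False)
        return (XtBX - A.T @ KiA, XtBy - A.T @ Kia,
                ytBy - a @ Kia, logdetK)

    def reml_nll(self, gammas: np.ndarray, sigma2_e: float | None = None) -> float:
        """Negative restricted log-likelihood (constants dropped).

        If ``sigma2_e`` is None it is profiled out analytically.
        """
        try:
            if self.absorb is not None:
                XtVinvX, XtVinvy, ytVinvy, logdetK = self.core_absorbed(gammas)
            else:
                XtVinvX, XtVinvy, ytVinvy, logdetK = self.core(gammas)
        except linalg.LinAlgError:
            return np.inf
        try:
            cX = linalg.cho_factor(XtVinvX, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(cX, XtVinvy, check_finite=False)
        rss = max(ytVinvy - XtVinvy @ beta, 1e-300)
        logdetX = 2.0 * np.log(np.diag(cX[0])).sum()
        df = self.n - self.p
        if sigma2_e is None:
            s2 = max(rss / df, _VAR_FLOOR)
            nll = 0.5 * (df * np.log(s2) + logdetK + logdetX + df)
        else:
            nll = 0.5 * (df * np.log(sigma2_e) + logdetK + logdetX
                         + rss / sigma2_e)
        return float(nll)

    def solve(self, gammas: np.ndarray, sigma2_e: float | None = None):
        """Full solution (beta, sigma2, blups, fitted, residuals) at gammas."""
        XtVinvX, XtVinvy, ytVinvy, logdetK = self.core(gammas)
        beta, *_ = linalg.lstsq(XtVinvX, XtVinvy, check_finite=False)
        rss = max(ytVinvy - XtVinvy @ beta, 0.0)
        df = max(self.n - self.p, 1)
        s2 = max(rss / df, _VAR_FLOOR) if sigma2_e is None else sigma2_e
        blups = {}
        resid = self.y - self.X @ beta
        if self.W is not None and self.M > 0:
            w_r = self.Wty - self.WtX @ beta  # W'(y - Xb)
            s = np.sqrt(self.expand(gammas))
            K = np.eye(self.M) + (s[:, None] * s[None, :]) * self.WtW
            cf = linalg.cho_factor(K, lower=True, check_finite=False)
            t = linalg.cho_solve(cf, s * w_r, check_finite=False)
            u_all = self.expand(gammas) * (w_r - self.WtW @ (s * t))
            for i, term in enumerate(self.terms):
                u = u_all[self.offsets[i]:self.offsets[i + 1]]
                blups[term.name] = u
                active = term.codes >= 0
                resid = resid.copy()
                resid[active] -= u[term.codes[active]]
        fitted = self.y - resid
        return beta, s2, blups, fitted, resid, XtVinvX


def fit_mixed(
    y,
    X,
    terms: list[RandomTerm],
    *,
    fixed_gammas: dict | None = None,
    sigma2_e: float | None = None,
    ftol: float = 1e-8,
    max_iter: int = 500,
) -> MixedModelFit:
    """Fit the mixed model by REML over variance ratios.

    Parameters
    ----------
    y, X
        Response and fixed-effect design matrix (full column rank).
    terms
        Random terms; each gets one variance component.
    fixed_gammas
        Map term name -> fixed variance *ratio* (s2_term / s2_e); these terms
        are held at the given ratio and not optimised.
    sigma2_e
        If given, the residual variance is held fixed at this value instead
        of being profiled (used when sharing nuisance components across
        sub-models).
    """
    ws = _WorkSpace(y, X, terms)
    fixed_gammas = dict(fixed_gammas or {})
    free_idx = [i for i, t in enumerate(terms) if t.name not in fixed_gammas]
    gam = np.array(
        [fixed_gammas.get(t.name, 0.5) for t in terms], dtype=float
    )

    def nll_theta(theta):
        g = gam.copy()
        g[free_idx] = np.exp(np.clip(theta, *_LOG_RATIO_BOUNDS))
        return ws.reml_nll(g, sigma2_e)

    converged = True
    message = ""
    if free_idx:
        x0 = np.zeros(len(free_idx))  # start at ratio 1
        if len(free_idx) == 1:
            res = optimize.minimize_scalar(
                lambda t: nll_theta(np.array([t])),
                bounds=_LOG_RATIO_BOUNDS, method="bounded",
                options={"xatol": 1e-8},
            )
            theta_opt = np.array([res.x])
            converged = bool(res.success)
            message = getattr(res, "message", "")
        else:
            res = optimize.minimize(
                nll_theta, x0, method="Nelder-Mead",
                options={"fatol": ftol, "xatol": 1e-5,
                         "maxiter": max_iter * len(free_idx),
                         "maxfev": max_iter * len(free_idx)},
            )
            theta_opt = res.x
            converged = bool(res.success)
            message = res.message
        gam[free_idx] = np.exp(np.clip(theta_opt, *_LOG_RATIO_BOUNDS))
        if not converged:
            warnings.warn(f"REML did not converge: {message}", stacklevel=2)

    beta, s2, blups, fitted, resid, _ = ws.solve(gam, sigma2_e)
    varcomps = {t.name: float(g * s2) for t, g in zip(terms, gam)}
    # clip effective zeros produced by the log-ratio bounds
    for k, v in varcomps.items():
        if v < _VAR_FLOOR * s2:
            varcomps[k] = 0.0
    ll = -ws.reml_nll(gam, sigma2_e)
    return MixedModelFit(
        beta=beta, varcomps=varcomps, sigma2_e=float(s2), loglik=float(ll),
        converged=converged, n_obs=ws.n, blups={k: v * 1.0 for k, v in blups.items()},
        fitted=fitted, residuals=resid, message=str(message),
    )
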