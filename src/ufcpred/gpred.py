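"""Genomic prediction: marker QC, GBLUP, RRBLUP and cross-validation.

GBLUP models line effects through the VanRaden genomic relationship matrix
``G = (X - 2P)(X - 2P)' / (2 sum p(1-p))``; RRBLUP places a common ridge
penalty on per-marker effects.  The two are the same model in different
coordinates, and ``fit_rrblup`` is solved in the GBLUP parameterisation so
the fitted genetic values agree to numerical precision.  REML for the single
genetic variance runs on the eigendecomposition of G, which reduces every
likelihood evaluation to diagonal operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GenotypeMatrixQC",
    "GRM",
    "MarkerEffects",
    "marker_qc",
    "compute_grm",
    "fit_gblup",
    "fit_rrblup",
    "cross_validate_5fold",
    "leave_one_cycle_out",
]


@dataclass
class GenotypeMatrixQC:
    """Dosage matrix after marker quality control (no missing values)."""

    X: pd.DataFrame  # genotypes x kept markers
    freq: pd.Series  # counted-allele frequency per kept marker
    kept: list
    dropped_maf: list
    dropped_missing: list


@dataclass
class GRM:
    """VanRaden genomic relationship matrix and its scaling constant."""

    G: np.ndarray
    ids: list
    denom: float  # 2 * sum p(1-p)
    freq: np.ndarray


@dataclass
class MarkerEffects:
    """RRBLUP solution: intercept, per-marker additive effects, variances."""

    mu: float
    alpha: pd.Series  # trait units per dosage unit
    sigma2_alpha: float
    sigma2_e: float
    freq: pd.Series  # allele frequencies used for centering
    converged: bool = True

    def gebv(self, dosage: pd.DataFrame) -> pd.Series:
        """Genomic estimated breeding values for a dosage matrix (deviation
        from the population intercept; centered with the stored frequencies)."""
        Xc = dosage[self.alpha.index].to_numpy(float) - 2.0 * self.freq.to_numpy()
        return pd.Series(Xc @ self.alpha.to_numpy(), index=dosage.index)


def marker_qc(
    dosage: pd.DataFrame,
    maf_threshold: float = 0.05,
    max_missing: float = 0.05,
) -> GenotypeMatrixQC:
    """Drop low-MAF and high-missingness markers; mean-impute the rest.

    Markers with minor allele frequency <= ``maf_threshold`` (computed on
    observed calls) or missing rate >= ``max_missing`` are removed; remaining
    missing dosages are imputed with twice the allele frequency.
    """
    X = dosage.astype(float)
    obs = X.notna()
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("markers with no observed calls")
    freq = X.sum(axis=0, skipna=True) / (2.0 * n_obs)
    maf = np.minimum(freq, 1.0 - freq)
    miss_rate = 1.0 - n_obs / len(X)
    drop_maf = X.columns[maf <= maf_threshold].tolist()
    drop_miss = X.columns[(miss_rate >= max_missing) & (maf > maf_threshold)].tolist()
    kept = [c for c in X.columns if c not in set(drop_maf) | set(drop_miss)]
    if not kept:
        raise ValueError("no markers survive quality control")
    Xk = X[kept]
    fk = freq[kept]
    Xk = Xk.fillna(2.0 * fk)
    return GenotypeMatrixQC(Xk, fk, kept, drop_maf, drop_miss)


def compute_grm(X: pd.DataFrame, freq: pd.Series | None = None) -> GRM:
    """VanRaden relationship matrix from a complete dosage matrix."""
    ids = list(X.index)
    if len(ids) < 2:
        raise ValueError("need >= 2 genotypes")
    Xv = X.to_numpy(dtype=float)
    p = (Xv.mean(axis=0) / 2.0) if freq is None else freq[X.columns].to_numpy(float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero GRM denominator")
    Xc = Xv - 2.0 * p
    G = (Xc @ Xc.T) / denom
    return GRM(G, ids, denom, p)


def _reml_eigen(y: np.ndarray, G: np.ndarray):
    """Single-component REML (V = s2_g G + s2_e I) via eigendecomposition.

    Returns (mu, sigma2_g, sigma2_e, converged) with the intercept as the
    only fixed effect.
    """
    n = y.size
    d, U = np.linalg.eigh(G)
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    xs = U.T @ np.ones(n)

    def nll(log_lam):
        lam = np.exp(log_lam)
        w = lam * d + 1.0
        xwx = np.sum(xs * xs / w)
        xwy = np.sum(xs * ys / w)
        beta = xwy / xwx
        rss = np.sum((ys - beta * xs) ** 2 / w)
        s2 = max(rss / (n - 1), 1e-300)
        return 0.5 * ((n - 1) * np.log(s2) + np.sum(np.log(w)) + np.log(xwx))

    res = optimize.minimize_scalar(nll, bounds=(-23.0, 16.0), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    w = lam * d + 1.0
    xwx = np.sum(xs * xs / w)
    mu = float(np.sum(xs * ys / w) / xwx)
    rss = float(np.sum((ys - mu * xs) ** 2 / w))
    s2e = max(rss / (n - 1), 1e-12)
    return mu, lam * s2e, s2e, bool(res.success), (d, U)


def fit_gblup(
    y: pd.Series,
    grm: GRM,
    train: list | None = None,
) -> tuple[float, float, float, pd.Series]:
    """Fit GBLUP ``y = mu + g + e`` and return (mu, s2_g, s2_e, GEBVs).

    ``y`` must be indexed by genotype id; ``train`` (default: the ids of
    ``y``) selects the phenotyped training lines.  GEBVs are returned for
    every genotype in the GRM, with unphenotyped lines predicted through
    their genomic covariance with the training set.
    """
    idx = {g: i for i, g in enumerate(grm.ids)}
    train = list(y.index) if train is None else list(train)
    if len(train) < 10:
        raise ValueError("need >= 10 training genotypes")
    ti = np.array([idx[g] for g in train])
    yt = y.loc[train].to_numpy(float)
    Gtt = grm.G[np.ix_(ti, ti)]
    mu, s2g, s2e, conv, (d, U) = _reml_eigen(yt, Gtt)
    if not conv:
        warnings.warn("GBLUP REML did not converge")
    lam = s2g / s2e
    # Vinv (y - mu) in the eigenbasis of Gtt
    resid_rot = U.T @ (yt - mu)
    vinv_r = U @ (resid_rot / (lam * d + 1.0)) / s2e
    gebv_all = s2g * (grm.G[:, ti] @ vinv_r)
    return mu, s2g, s2e, pd.Series(gebv_all, index=grm.ids, name="gebv")


def fit_rrblup(
    y: pd.Series,
    X: pd.DataFrame,
    freq: pd.Series | None = None,
    train: list | None = None,
    grm: GRM | None = None,
) -> MarkerEffects:
    """Ridge-regression BLUP of marker effects, solved in the GBLUP
    parameterisation.

    The ridge parameter ``lambda = s2_e / s2_alpha`` comes from REML on the
    equivalent GBLUP model; effects are recovered through the dual solution
    ``alpha = s2_alpha Xc' Vinv (y - mu)``, which equals
    ``(Xc'Xc + lambda I)^-1 Xc'(y - mu)``.  A precomputed GRM over the rows
    of ``X`` can be passed to avoid rebuilding it across training subsets.
    """
    if X.shape[1] == 0:
        raise ValueError("no markers")
    train = list(y.index) if train is None else list(train)
    p = (X.mean(axis=0) / 2.0) if freq is None else freq[X.columns]
    if grm is None:
        grm = compute_grm(X, freq=p)
    else:
        p = pd.Series(grm.freq, index=X.columns)
    idx = {g: i for i, g in enumerate(grm.ids)}
    ti = np.array([idx[g] for g in train])
    yt = y.loc[train].to_numpy(float)
    Gtt = grm.G[np.ix_(ti, ti)]
    mu, s2g, s2e, conv, (d, U) = _reml_eigen(yt, Gtt)
    lam = s2g / s2e
    resid_rot = U.T @ (yt - mu)
    vinv_r = U @ (resid_rot / (lam * d + 1.0)) / s2e
    s2_alpha = s2g / grm.denom
    Xc_t = X.to_numpy(float)[ti] - 2.0 * np.asarray(p, float)
    alpha = s2_alpha * (Xc_t.T @ vinv_r)
    return MarkerEffects(
        mu=mu, alpha=pd.Series(alpha, index=X.columns, name="alpha"),
        sigma2_alpha=s2_alpha, sigma2_e=s2e,
        freq=pd.Series(np.asarray(p, float), index=X.columns), converged=conv,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate_5fold(
    y: pd.Series,
    grm: GRM,
    n_rep: int = 100,
    seed: int | np.random.Generator = 0,
    n_folds: int = 5,
) -> float:
    """Mean genotype-level prediction ability over repeated 5-fold CV.

    Each repetition partitions the phenotyped genotypes into five folds;
    the model is refitted on each training split and the Pearson correlation
    between held-out phenotypes and predictions is averaged over folds and
    repetitions.  Folds with undefined correlation (constant vectors) are
    dropped with a warning.
    """
    if len(y) < 25:
        raise ValueError("need >= 25 genotypes for five-fold cross-validation")
    rng = np.random.default_rng(seed)
    ids = np.array(y.index)
    rs = []
    for _ in range(n_rep):
        perm = rng.permutation(len(ids))
        folds = np.array_split(perm, n_folds)
        for fold in folds:
            test = ids[fold]
            trainset = np.setdiff1d(ids, test)
            _, _, _, gebv = fit_gblup(y.loc[trainset], grm, train=list(trainset))
            r = _safe_corr(y.loc[test].to_numpy(float),
                           gebv.loc[test].to_numpy(float))
            if np.isnan(r):
                warnings.warn("fold with undefined correlation dropped")
            else:
                rs.append(r)
    return float(np.mean(rs)) if rs else np.nan


def leave_one_cycle_out(
    y: pd.Series,
    grm: GRM,
    cycles: pd.Series,
    min_cycle_size: int = 3,
) -> pd.Series:
    """Per-cycle prediction ability: train on all other cycles, predict the
    held-out cycle.  Cycles with fewer than ``min_cycle_size`` phenotyped
    genotypes are skipped with a warning."""
    cyc = cycles.reindex(y.index)
    labels = sorted(cyc.dropna().unique().tolist())
    if len(labels) < 2:
        raise ValueError("need >= 2 breeding cycles")
    out = {}
    for c in labels:
        test = y.index[cyc == c]
        trainset = y.index[cyc != c]
        if len(test) < min_cycle_size:
            warnings.warn(f"cycle {c!r} has < {min_cycle_size} genotypes; skipped")
            continue
        _, _, _, gebv = fit_gblup(y.loc[trainset], grm, train=list(trainset))
        out[c] = _safe_corr(y.loc[test].to_numpy(float),
                            gebv.loc[test].to_numpy(float))
    return pd.Series(out, name="r_gp")
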