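"""Two-stage phenotypic analysis of multi-environment trials.

Stage 1 fits, per environment, ``y = mu + g + b + r + e`` with genotype,
incomplete block and replication random, yielding variance components and the
per-environment repeatability; genotype BLUEs are then computed by
generalised least squares with genotype fixed at the stage-1 variance
components.  Stage 2 combines the per-environment BLUEs across environments
(``y = mu + g + u_env + e``), giving the broad-sense heritability and
across-environment BLUEs.  Family-specific genetic variances come from the
plot-level model with environment, block- and replication-within-environment
effects and one genetic variance per family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reml import MixedModelFit, RandomTerm, fit_mixed

__all__ = [
    "StageFit",
    "remove_outliers",
    "fit_env_model",
    "repeatability",
    "fit_across_env_model",
    "heritability",
    "fit_family_variance_model",
    "observed_family_summary",
]

REQUIRED_COLS = ("genotype", "environment", "replication", "block", "value")


@dataclass
class StageFit:
    """Variance components and (optionally) BLUEs from one model fit."""

    model: str
    varcomps: dict  # component name -> variance, incl. "residual"
    mu: float
    blues: pd.Series | None
    converged: bool
    loglik: float
    n_obs: int
    extras: dict = field(default_factory=dict)  # nR / nE / flags

    def varcomp(self, name: str) -> float:
        return self.varcomps[name]


def _check_records(records: pd.DataFrame, cols=REQUIRED_COLS) -> None:
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"trial records missing columns {missing}")


def _env_terms(records: pd.DataFrame) -> list[RandomTerm]:
    terms = []
    if records["replication"].nunique() > 1:
        terms.append(RandomTerm.from_values("replication", records["replication"]))
    blk = records["replication"].astype(str) + ":" + records["block"].astype(str)
    if blk.nunique() > 1:
        terms.append(RandomTerm.from_values("block", blk))
    return terms


def fit_env_model(
    records: pd.DataFrame,
    genotype_fixed: bool = False,
    _vc_fit: "StageFit | None" = None,
) -> StageFit:
    """Single-environment model ``y = mu + g + b + r + e``.

    With ``genotype_fixed`` False the genotype effect is random and REML
    variance components are returned.  With ``genotype_fixed`` True the
    genotype BLUEs are computed by GLS holding block/replication variance
    ratios at their REML estimates from the genotype-random fit.
    """
    _check_records(records)
    if records["environment"].nunique() != 1:
        raise ValueError("fit_env_model expects records from a single environment")
    geno = records["genotype"].to_numpy()
    if len(np.unique(geno)) < 2:
        raise ValueError("need >= 2 genotypes")
    y = records["value"].to_numpy(dtype=float)
    nR = records.groupby("genotype").size().mean()

    nuisance = _env_terms(records)
    vc = _vc_fit
    if vc is None:
        gterm = RandomTerm.from_values("genotype", geno)
        fit = fit_mixed(y, np.ones((len(y), 1)), [gterm] + nuisance)
        vc = StageFit(
            model="within-env", varcomps={**fit.varcomps, "residual": fit.sigma2_e},
            mu=float(fit.beta[0]), blues=None, converged=fit.converged,
            loglik=fit.loglik, n_obs=fit.n_obs,
            extras={"nR": float(nR), "fit": fit},
        )
    if not genotype_fixed:
        return vc

    # GLS with genotype fixed at the stage-1 variance ratios
    se2 = max(vc.varcomps["residual"], 1e-12)
    ratios = {t.name: vc.varcomps.get(t.name, 0.0) / se2 for t in nuisance}
    levels, codes = np.unique(geno, return_inverse=True)
    X = np.zeros((len(y), len(levels)))
    X[np.arange(len(y)), codes] = 1.0
    fit = fit_mixed(y, X, nuisance, fixed_gammas=ratios, sigma2_e=se2)
    blues = pd.Series(fit.beta, index=levels, name="blue")
    return StageFit(
        model="within-env-blue", varcomps=dict(vc.varcomps), mu=float(blues.mean()),
        blues=blues, converged=vc.converged and fit.converged,
        loglik=fit.loglik, n_obs=fit.n_obs, extras={"nR": float(nR)},
    )


def remove_outliers(
    records: pd.DataFrame, threshold: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-pass outlier removal per environment (and trait, if present).

    A preliminary genotype-random fit of the single-environment model is made
    and records whose conditional residual exceeds ``threshold`` residual
    standard deviations are dropped.  Returns (kept, removed).
    """
    _check_records(records)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not np.isfinite(threshold):
        return records, records.iloc[0:0]
    keys = ["environment"] + (["trait"] if "trait" in records.columns else [])
    drop_idx = []
    for _, grp in records.groupby(keys, sort=False):
        if grp["genotype"].nunique() < 2:
            continue
        gterm = RandomTerm.from_values("genotype", grp["genotype"])
        fit = fit_mixed(grp["value"].to_numpy(float), np.ones((len(grp), 1)),
                        [gterm] + _env_terms(grp))
        sd = np.sqrt(max(fit.sigma2_e, 1e-300))
        std_resid = fit.residuals / sd
        bad = grp.index[np.abs(std_resid) > threshold]
        if len(bad) == len(grp):
            raise ValueError("outlier removal would discard every record")
        drop_idx.extend(bad.tolist())
    removed = records.loc[drop_idx]
    kept = records.drop(index=drop_idx)
    if kept.empty:
        raise ValueError("outlier removal would discard every record")
    return kept, removed


def repeatability(sigma2_g: float, sigma2_e: float, n_r: float) -> float:
    """Within-environment repeatability s2_g / (s2_g + s2_e / nR)."""
    if sigma2_g < 0 or sigma2_e < 0 or n_r <= 0:
        raise ValueError("variances must be >= 0 and nR > 0")
    denom = sigma2_g + sigma2_e / n_r
    if denom == 0:
        raise ValueError("repeatability undefined: both variances are zero")
    return sigma2_g / denom


def heritability(sigma2_g: float, sigma2_e: float, n_e: float) -> float:
    """Across-environment broad-sense heritability s2_G / (s2_G + s2_e / nE)."""
    if sigma2_g < 0 or sigma2_e < 0 or n_e <= 0:
        raise ValueError("variances must be >= 0 and nE > 0")
    denom = sigma2_g + sigma2_e / n_e
    if denom == 0:
        raise ValueError("heritability undefined: both variances are zero")
    return sigma2_g / denom


def fit_across_env_model(
    blues: pd.DataFrame,
    genotype_fixed: bool = False,
    _vc_fit: "StageFit | None" = None,
) -> StageFit:
    """Across-environment model on stage-1 BLUEs: ``y = mu + g + u_env + e``.

    ``blues`` needs columns genotype, environment, value.  When every
    genotype appears in a single environment the genetic and residual
    variances are not separable; the fit is flagged.
    """
    _check_records(blues, cols=("genotype", "environment", "value"))
    if blues["environment"].nunique() < 2:
        raise ValueError("need BLUEs from >= 2 environments")
    y = blues["value"].to_numpy(float)
    geno = blues["genotype"].to_numpy()
    env_counts = blues.groupby("genotype").size()
    nE = float(env_counts.mean())
    confounded = bool((env_counts <= 1).all())

    env_term = RandomTerm.from_values("environment", blues["environment"])
    vc = _vc_fit
    if vc is None:
        gterm = RandomTerm.from_values("genotype", geno)
        fit = fit_mixed(y, np.ones((len(y), 1)), [gterm, env_term])
        conv = fit.converged and not confounded
        if confounded:
            warnings.warn("each genotype seen in one environment only: "
                          "genetic and residual variance not separable")
        vc = StageFit(
            model="across-env",
            varcomps={**fit.varcomps, "residual": fit.sigma2_e},
            mu=float(fit.beta[0]), blues=None, converged=conv,
            loglik=fit.loglik, n_obs=fit.n_obs,
            extras={"nE": nE, "confounded": confounded, "fit": fit},
        )
    if not genotype_fixed:
        return vc

    se2 = max(vc.varcomps["residual"], 1e-12)
    ratio = {"environment": vc.varcomps.get("environment", 0.0) / se2}
    levels, codes = np.unique(geno, return_inverse=True)
    X = np.zeros((len(y), len(levels)))
    X[np.arange(len(y)), codes] = 1.0
    fit = fit_mixed(y, X, [env_term], fixed_gammas=ratio, sigma2_e=se2)
    blues_out = pd.Series(fit.beta, index=levels, name="blue")
    return StageFit(
        model="across-env-blue", varcomps=dict(vc.varcomps),
        mu=float(blues_out.mean()), blues=blues_out,
        converged=vc.converged and fit.converged, loglik=fit.loglik,
        n_obs=fit.n_obs, extras={"nE": nE, "confounded": vc.extras.get("confounded", False)},
    )


# ---------------------------------------------------------------------------
# family-specific genetic variance (plot-level model across environments)


def _family_table(records: pd.DataFrame, families) -> pd.Series:
    fam = pd.Series(families)
    geno = pd.Index(records["genotype"].unique())
    missing = geno.difference(fam.index)
    if len(missing):
        raise ValueError(f"genotypes without family assignment: {list(missing)[:5]}")
    return fam

def _shared_terms(records: pd.DataFrame) -> list[RandomTerm]:
    terms = [RandomTerm.from_values("environment", records["environment"])]
    er = records["environment"].astype(str) + ":" + records["replication"].astype(str)
    if er.nunique() > records["environment"].nunique():
        terms.append(RandomTerm.from_values("env_rep", er))
    eb = er + ":" + records["block"].astype(str)
    if eb.nunique() > er.nunique():
        terms.append(RandomTerm.from_values("env_block", eb))
    return terms


def fit_family_variance_model(
    records: pd.DataFrame,
    families,
    shared: dict | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Family-specific genetic variances from the plot-level model
    ``y = mu + g + u_env + b(env) + r(env) + e`` with ``g ~ N(0, (+)_k I s2_Gk)``.

    For a handful of families the variances are estimated jointly; beyond
    that, environment / block / replication / residual variances are held at
    shared estimates (from a pooled fit, or from ``shared`` if provided with
    keys ``environment, env_block, env_rep, residual``) and each family's
    genetic variance is profiled on its own records — mirroring the fallback
    one needs when the joint model will not converge on unbalanced data.

    Returns a table with columns family, var_g, n_members, n_records,
    converged; shared components are stored in ``.attrs["shared"]``.
    """
    _check_records(records)
    fam_of = _family_table(records, families)
    rec = records.copy()
    rec["family"] = fam_of.loc[rec["genotype"]].to_numpy()
    fams = sorted(pd.unique(rec["family"]))
    n_members = rec.groupby("family")["genotype"].nunique()
    y = rec["value"].to_numpy(float)
    joint = method == "joint" or (method == "auto" and len(fams) <= 4
                                  and shared is None)

    if joint:
        terms = []
        for f in fams:
            in_f = rec["family"].to_numpy() == f
            geno = rec["genotype"].to_numpy()
            levels = np.unique(geno[in_f])
            lut = {g: i for i, g in enumerate(levels)}
            codes = np.array([lut.get(g, -1) for g in geno], dtype=np.int64)
            terms.append(RandomTerm(f"g:{f}", codes, levels.tolist()))
        sh_terms = _shared_terms(rec)
        fit = fit_mixed(y, np.ones((len(y), 1)), terms + sh_terms)
        rows = []
        for f in fams:
            nm = int(n_members[f])
            var_g = fit.varcomps[f"g:{f}"] if nm > 1 else np.nan
            rows.append((f, var_g, nm,
                         int((rec["family"] == f).sum()),
                         fit.converged and nm > 1))
        out = pd.DataFrame(rows, columns=["family", "var_g", "n_members",
                                          "n_records", "converged"])
        out.attrs["shared"] = {
            **{t.name: fit.varcomps[t.name] for t in sh_terms},
            "residual": fit.sigma2_e,
        }
        out.attrs["method"] = "joint"
        return out

    if shared is None:
        gterm = RandomTerm.from_values("genotype", rec["genotype"])
        sh_terms = _shared_terms(rec)
        pooled = fit_mixed(y, np.ones((len(y), 1)), [gterm] + sh_terms)
        shared = {t.name: pooled.varcomps[t.name] for t in sh_terms}
        shared["residual"] = pooled.sigma2_e
    se2 = max(shared.get("residual", 1.0), 1e-12)

    rows = []
    for f in fams:
        sub = rec[rec["family"] == f]
        nm = int(n_members[f])
        if nm < 2:
            rows.append((f, np.nan, nm, len(sub), False))
            continue
        terms = [RandomTerm.from_values("genotype", sub["genotype"])]
        fixed = {}
        for t in _shared_terms(sub):
            terms.append(t)
            fixed[t.name] = shared.get(t.name, 0.0) / se2
        fit = fit_mixed(sub["value"].to_numpy(float), np.ones((len(sub), 1)),
                        terms, fixed_gammas=fixed, sigma2_e=se2)
        rows.append((f, fit.varcomps["genotype"], nm, len(sub), fit.converged))
    out = pd.DataFrame(rows, columns=["family", "var_g", "n_members",
                                      "n_records", "converged"])
    out.attrs["shared"] = dict(shared)
    out.attrs["method"] = "profiled"
    return out


def observed_family_summary(
    blues: pd.Series,
    families,
    family_variances: pd.DataFrame,
    i: float = 1.27,
    h: float = 1.0,
) -> pd.DataFrame:
    """Observed per-family mean, genetic SD and usefulness criterion.

    The family mean is the arithmetic mean of the members' across-environment
    BLUEs; UFC = mean + i * h * sd with the family SD from the family-variance
    table.  Families absent from the table are skipped with a warning.
    """
    if i < 0 or not 0 <= h <= 1:
        raise ValueError("need i >= 0 and 0 <= h <= 1")
    fam_of = pd.Series(families)
    var_tbl = family_variances.set_index("family")["var_g"]
    rows = []
    df = pd.DataFrame({"blue": blues})
    df["family"] = fam_of.reindex(df.index).to_numpy()
    for f, grp in df.dropna(subset=["family"]).groupby("family"):
        if f not in var_tbl.index or not np.isfinite(var_tbl[f]):
            warnings.warn(f"family {f!r} missing from variance table; skipped")
            continue
        mean = float(grp["blue"].mean())
        sd = float(np.sqrt(max(var_tbl[f], 0.0)))
        rows.append((f, len(grp), mean, sd, mean + i * h * sd))
    return pd.DataFrame(rows, columns=["family", "n", "mean", "sd", "ufc"])
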