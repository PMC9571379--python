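"""Validation of cross-level predictions against observed family summaries.

Three scenarios mirror how a breeder would deploy the method: training on
everything (training set = prediction set), leaving out the final breeding
cycle, and training on random subsets of increasing size from the earlier
cycles.  Families enter validation only if they come from two-way crosses,
have at least a minimum number of phenotyped members and a non-degenerate
estimated genetic variance.  Prediction ability is the Pearson correlation
between predicted and observed family statistics; a selection-intensity
sweep compares the variance-aware and mean-only usefulness criteria across
hypothetical selection regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import crosspred, gpred, phenostat
from .simdata import ProgramDataset

__all__ = [
    "ScenarioConfig",
    "PhenoAnalysis",
    "analyze_phenotypes",
    "filter_families",
    "prediction_ability",
    "selection_intensity",
    "c_sweep",
    "run_scenario_full",
    "run_scenario_holdout_cycle",
    "run_scenario_training_size",
]

STATISTICS = ("mean", "variance", "ufc_u", "ufc_mu")


@dataclass
class ScenarioConfig:
    """Family filters, sizes and constants shared by the scenarios."""

    traits: tuple | None = None  # default: every trait in the dataset
    min_family_size: int = 10
    min_variance: float = 0.01
    cross_types: tuple = ("2-way",)
    training_sizes: tuple = (50, 100, 200, 400, 1000)
    n_samples: int = 5
    i: float = 1.27
    h_predicted: float = 1.0  # sqrt(h2) assumed for the predicted UFC
    outlier_threshold: float = 4.0
    seed: int = 0


@dataclass
class PhenoAnalysis:
    """Per-trait observed quantities from the two-stage phenotypic analysis."""

    trait: str
    repeatabilities: pd.Series  # per environment
    h2: float
    n_e: float
    blues_stage1: pd.DataFrame  # genotype, environment, value
    blues_across: pd.Series  # genotype -> across-environment BLUE
    family_variances: pd.DataFrame
    observed: pd.DataFrame  # family, n, mean, sd, ufc
    stage2_varcomps: dict
    n_outliers_removed: int = 0


def analyze_phenotypes(
    dataset: ProgramDataset,
    traits: tuple | None = None,
    outlier_threshold: float = 4.0,
    i: float = 1.27,
) -> dict[str, PhenoAnalysis]:
    """Run the full two-stage analysis for each trait of a programme.

    Returns observed family means, genetic SDs and UFCs (with the trait's
    own sqrt(h2) inside the observed UFC, per-trait selection intensity
    ``i``), plus repeatabilities, heritability and the family-variance table.
    """
    fam_of = dataset.lines.set_index("id")["family"]
    out: dict[str, PhenoAnalysis] = {}
    for trait in traits or dataset.traits:
        rec = dataset.trials[dataset.trials["trait"] == trait]
        reps, blues_parts, kept_parts = {}, [], []
        n_removed = 0
        stage1_block, stage1_rep, stage1_resid = [], [], []
        for env, grp in rec.groupby("environment", sort=True):
            vc = phenostat.fit_env_model(grp)
            # outlier pass on the conditional residuals of this same fit
            if np.isfinite(outlier_threshold):
                sd = np.sqrt(max(vc.extras["fit"].sigma2_e, 1e-300))
                bad = np.abs(vc.extras["fit"].residuals / sd) > outlier_threshold
                if bad.all():
                    raise ValueError("outlier removal would discard every record")
                if bad.any():
                    n_removed += int(bad.sum())
                    grp = grp.loc[~bad]
                    vc = phenostat.fit_env_model(grp)
            kept_parts.append(grp)
            reps[env] = phenostat.repeatability(
                vc.varcomps["genotype"], vc.varcomps["residual"], vc.extras["nR"]
            )
            stage1_block.append(vc.varcomps.get("block", 0.0))
            stage1_rep.append(vc.varcomps.get("replication", 0.0))
            stage1_resid.append(vc.varcomps["residual"])
            blue = phenostat.fit_env_model(grp, genotype_fixed=True, _vc_fit=vc)
            blues_parts.append(pd.DataFrame({
                "genotype": blue.blues.index, "environment": env,
                "value": blue.blues.to_numpy(),
            }))
        kept = pd.concat(kept_parts, ignore_index=False)
        blues1 = pd.concat(blues_parts, ignore_index=True)
        s2 = phenostat.fit_across_env_model(blues1)
        h2 = phenostat.heritability(
            s2.varcomps["genotype"], s2.varcomps["residual"], s2.extras["nE"]
        )
        blue2 = phenostat.fit_across_env_model(blues1, genotype_fixed=True,
                                               _vc_fit=s2)
        # shared components for the plot-level family-variance model: the
        # stage-2 residual is approximately GxE + plot error / nR, so the
        # plot-level residual is the stage-1 residual plus the GxE part
        m_resid = float(np.mean(stage1_resid))
        n_r = kept.groupby(["environment", "genotype"]).size().mean()
        shared = {
            "environment": s2.varcomps.get("environment", 0.0),
            "env_block": float(np.mean(stage1_block)),
            "env_rep": float(np.mean(stage1_rep)),
            "residual": m_resid + max(
                s2.varcomps["residual"] - m_resid / n_r, 0.0),
        }
        dh = fam_of[fam_of != ""]
        fam_rec = kept[kept["genotype"].isin(dh.index)]
        fam_var = phenostat.fit_family_variance_model(
            fam_rec, dh, shared=shared, method="profiled"
        )
        observed = phenostat.observed_family_summary(
            blue2.blues, dh, fam_var, i=i, h=float(np.sqrt(h2))
        )
        out[trait] = PhenoAnalysis(
            trait=trait, repeatabilities=pd.Series(reps), h2=h2,
            n_e=s2.extras["nE"], blues_stage1=blues1, blues_across=blue2.blues,
            family_variances=fam_var, observed=observed,
            stage2_varcomps={**s2.varcomps}, n_outliers_removed=n_removed,
        )
    return out


def filter_families(
    families: pd.DataFrame,
    min_size: int | None = 10,
    min_variance: float | None = 0.01,
    cross_types: tuple | None = ("2-way",),
) -> pd.DataFrame:
    """Keep families meeting every eligibility filter.

    ``families`` needs columns family, cross_type, n, var_g.  Passing None
    for a filter disables it.  Idempotent; raises if nothing survives.
    """
    keep = pd.Series(True, index=families.index)
    if cross_types is not None:
        keep &= families["cross_type"].isin(cross_types)
    if min_size is not None:
        keep &= families["n"] >= min_size
    if min_variance is not None:
        keep &= families["var_g"] > min_variance
    out = families[keep]
    if out.empty:
        raise ValueError("no families pass the eligibility filters")
    return out


def prediction_ability(predicted, observed) -> float:
    """Pearson correlation between paired predicted and observed values."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size != o.size or p.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(p) == 0 or np.std(o) == 0:
        warnings.warn("constant vector: prediction ability undefined")
        return np.nan
    return float(np.corrcoef(p, o)[0, 1])


def selection_intensity(p: float) -> float:
    """Selection intensity under truncation of a normal trait.

    ``i = phi(z) / p`` with ``z`` the (1-p) standard-normal quantile; a
    selected fraction of 1 means no selection (i = 0).
    """
    if not 0 < p <= 1:
        raise ValueError("selected fraction must be in (0, 1]")
    if p == 1:
        return 0.0
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def c_sweep(
    pred_mean, pred_sd, obs_mean, obs_sd, c_grid=None
) -> pd.DataFrame:
    """Prediction ability of the UFC as the constant ``c = i * h`` varies.

    For each ``c``, observed UFC(c) = obs_mean + c * obs_sd is correlated
    with the variance-aware prediction ``pred_mean + c * pred_sd`` (UFC_u)
    and with the mean-only prediction (UFC_mu).  At c = 0 both collapse to
    the mean-prediction ability.
    """
    if c_grid is None:
        c_grid = np.linspace(0.0, 5.0, 51)
    pm, ps = np.asarray(pred_mean, float), np.asarray(pred_sd, float)
    om, os_ = np.asarray(obs_mean, float), np.asarray(obs_sd, float)
    rows = []
    for c in np.asarray(c_grid, float):
        obs_u = om + c * os_
        rows.append((c, prediction_ability(pm + c * ps, obs_u),
                     prediction_ability(pm, obs_u)))
    return pd.DataFrame(rows, columns=["c", "r_ufc_u", "r_ufc_mu"])


# ---------------------------------------------------------------------------
# scenario machinery


def _eligible_observed(
    dataset: ProgramDataset, pheno: PhenoAnalysis, config: ScenarioConfig,
    families: list | None = None,
) -> pd.DataFrame:
    """Observed summaries joined with eligibility data, filtered."""
    obs = pheno.observed.merge(
        dataset.pedigree[["family", "cross_type"]], on="family"
    )
    obs = obs.merge(
        pheno.family_variances[["family", "var_g"]], on="family"
    )
    if families is not None:
        obs = obs[obs["family"].isin(families)]
    return filter_families(
        obs, config.min_family_size, config.min_variance, config.cross_types
    )


class _PredictionContext:
    """Per-dataset cache of QC'd genotypes and the full-matrix GRM."""

    def __init__(self, dataset: ProgramDataset):
        self.dosage_df = dataset.dosage_df()
        self.qc = gpred.marker_qc(self.dosage_df)
        self.grm = gpred.compute_grm(self.qc.X)
        self.gmap = dataset.gmap


def _predict_and_score(
    dataset, pheno, config, train_ids, eligible, scenario, size=None, rep=0,
    include_baseline=False, ctx: _PredictionContext | None = None,
) -> list[tuple]:
    """Fit marker effects on the training BLUEs and score the eligible
    families; returns tidy result rows."""
    ctx = ctx or _PredictionContext(dataset)
    qc = ctx.qc
    y = pheno.blues_across.loc[[g for g in train_ids
                                if g in pheno.blues_across.index]]
    me = gpred.fit_rrblup(y, qc.X, grm=ctx.grm)
    gebv = me.gebv(qc.X)
    kept_markers = pd.Index(qc.kept)
    alpha_full = pd.Series(0.0, index=dataset.gmap.marker)
    alpha_full[kept_markers] = me.alpha
    crosses = [dataset.cross_spec(f) for f in eligible["family"]]
    pred = crosspred.predict_families(
        crosses, gebv, ctx.dosage_df, dataset.gmap, alpha_full,
        i=config.i, h=config.h_predicted,
    )
    merged = eligible.merge(pred, on="family")
    rows = []
    pairs = {
        "mean": ("pred_mean", "mean"),
        "variance": ("pred_var", "var_g"),
        "ufc_u": ("ufc_u", "ufc"),
        "ufc_mu": ("ufc_mu", "ufc"),
    }
    for stat, (pc, oc) in pairs.items():
        ok = merged[[pc, oc]].dropna()
        r = prediction_ability(ok[pc], ok[oc]) if len(ok) >= 3 else np.nan
        rows.append((scenario, pheno.trait, stat, size, rep, r, len(ok)))
    if include_baseline:
        base = []
        for cross in crosses:
            try:
                vals = [float(pheno.blues_across[p]) for p in cross.parents]
            except KeyError:
                continue
            base.append((cross.family,
                         crosspred.predict_family_mean(vals, cross.weights)))
        bdf = pd.DataFrame(base, columns=["family", "midparent"])
        mb = eligible.merge(bdf, on="family")
        if len(mb) >= 3:
            rows.append((scenario, pheno.trait, "mean_phenotypic_midparent",
                         size, rep, prediction_ability(mb["midparent"], mb["mean"]),
                         len(mb)))
    return rows


_RESULT_COLS = ["scenario", "trait", "statistic", "training_size",
                "repetition", "r", "n_families"]


def _select_traits(pheno: dict, config: ScenarioConfig) -> dict:
    if config.traits is None:
        return pheno
    return {t: ph for t, ph in pheno.items() if t in config.traits}


def run_scenario_full(
    dataset: ProgramDataset,
    config: ScenarioConfig | None = None,
    pheno: dict[str, PhenoAnalysis] | None = None,
) -> pd.DataFrame:
    """Training set identical to the prediction set: marker effects from all
    phenotyped genotypes, validated on every eligible family.  Includes the
    phenotypic-midparent baseline for the family mean."""
    config = config or ScenarioConfig()
    pheno = pheno or analyze_phenotypes(dataset, config.traits,
                                        config.outlier_threshold, config.i)
    rows = []
    ctx = _PredictionContext(dataset)
    train_ids = dataset.line_ids.tolist()
    for trait, ph in _select_traits(pheno, config).items():
        eligible = _eligible_observed(dataset, ph, config)
        rows += _predict_and_score(dataset, ph, config, train_ids, eligible,
                                   "full_data", include_baseline=True, ctx=ctx)
    return pd.DataFrame(rows, columns=_RESULT_COLS)


def _final_cycle(dataset: ProgramDataset) -> str:
    cycles = dataset.cycles
    if len(cycles) < 2:
        raise ValueError("need >= 2 breeding cycles")
    return cycles[-1]


def run_scenario_holdout_cycle(
    dataset: ProgramDataset,
    config: ScenarioConfig | None = None,
    pheno: dict[str, PhenoAnalysis] | None = None,
) -> pd.DataFrame:
    """Leave the final breeding cycle out: marker effects from all earlier
    cycles (and founders), validated on the final cycle's families."""
    config = config or ScenarioConfig()
    pheno = pheno or analyze_phenotypes(dataset, config.traits,
                                        config.outlier_threshold, config.i)
    final = _final_cycle(dataset)
    lines = dataset.lines
    train_ids = lines.loc[lines["cycle"] != final, "id"].tolist()
    final_fams = dataset.pedigree.loc[dataset.pedigree["cycle"] == final,
                                      "family"].tolist()
    rows = []
    ctx = _PredictionContext(dataset)
    for trait, ph in _select_traits(pheno, config).items():
        eligible = _eligible_observed(dataset, ph, config, families=final_fams)
        rows += _predict_and_score(dataset, ph, config, train_ids, eligible,
                                   "holdout_final_cycle", ctx=ctx)
    return pd.DataFrame(rows, columns=_RESULT_COLS)


def run_scenario_training_size(
    dataset: ProgramDataset,
    config: ScenarioConfig | None = None,
    pheno: dict[str, PhenoAnalysis] | None = None,
) -> pd.DataFrame:
    """Predict the final cycle from random training subsets of the earlier
    cycles, over a ladder of training population sizes."""
    config = config or ScenarioConfig()
    pheno = pheno or analyze_phenotypes(dataset, config.traits,
                                        config.outlier_threshold, config.i)
    final = _final_cycle(dataset)
    lines = dataset.lines
    pool = [g for g in lines.loc[lines["cycle"] != final, "id"]]
    final_fams = dataset.pedigree.loc[dataset.pedigree["cycle"] == final,
                                      "family"].tolist()
    rng = np.random.default_rng(config.seed)
    rows = []
    ctx = _PredictionContext(dataset)
    for trait, ph in _select_traits(pheno, config).items():
        phenotyped = [g for g in pool if g in ph.blues_across.index]
        eligible = _eligible_observed(dataset, ph, config, families=final_fams)
        for size in config.training_sizes:
            if size > len(phenotyped):
                raise ValueError(
                    f"training size {size} exceeds available {len(phenotyped)}")
            for rep in range(config.n_samples):
                sub = rng.choice(phenotyped, size=size, replace=False).tolist()
                rows += _predict_and_score(dataset, ph, config, sub, eligible,
                                           "training_size", size=size, rep=rep,
                                           ctx=ctx)
    return pd.DataFrame(rows, columns=_RESULT_COLS)
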