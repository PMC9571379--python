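"""Predicting cross progeny means, variances and the usefulness criterion.

For a biparental cross of inbred lines, a DH progeny receives at each locus
either the maternal or the paternal diplotype, each with probability one
half, and a locus pair stays in its parental configuration with probability
``q = 1 - r`` (one round of meiosis, no random mating).  Writing ``m_j`` and
``v_j`` for the diplotype effects — twice the additive marker effect times
the parental allele indicator — the genetic variance of the DH family is

    sigma2_G = sum_c sum_{j,k in c} (q_jk/2 - 1/4)
               (m_j m_k + v_j v_k - m_j v_k - v_j m_k),

including the diagonal (q = 1) and with unlinked pairs (q = 1/2)
contributing nothing.  Only loci where the parents differ contribute.  The
family mean is the contribution-weighted midparent value; the usefulness
criterion adds ``i * h * sigma_G`` to the mean.  A Monte-Carlo progeny
simulator provides an independent check on the analytic formula.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .crossing import CrossSpec, HeterozygousParentError, contribution_weights
from .genmap import GeneticMap
from .meiosis import haldane, simulate_gametes

__all__ = [
    "contribution_weights",
    "predict_family_mean",
    "recombination_fraction",
    "pair_q",
    "predict_family_variance",
    "mc_progeny",
    "predict_ufc",
    "predict_families",
]


def predict_family_mean(parent_values, weights=None) -> float:
    """Weighted midparent value: sum_i w_i value_i.

    ``parent_values`` are per-parent GEBVs (or phenotypic BLUEs for the
    non-genomic baseline); ``weights`` default to equal shares.
    """
    v = np.asarray(parent_values, dtype=float)
    if np.any(~np.isfinite(v)):
        raise ValueError("missing parent value")
    w = (np.full(v.size, 1.0 / v.size) if weights is None
         else np.asarray(weights, dtype=float))
    if w.size != v.size:
        raise ValueError("weights must match parents")
    return float(w @ v)


def recombination_fraction(gmap: GeneticMap, j, k) -> float:
    """Haldane recombination fraction between two markers (ids or indices);
    0.5 across chromosomes."""
    ji = gmap.index_of(j) if isinstance(j, str) else int(j)
    ki = gmap.index_of(k) if isinstance(k, str) else int(k)
    if gmap.chrom[ji] != gmap.chrom[ki]:
        return 0.5
    return float(haldane(abs(gmap.pos_cm[ji] - gmap.pos_cm[ki])))


def pair_q(r, generations: int = 0):
    """Probability that a locus pair remains in parental configuration.

    With zero generations of random mating between the cross and DH
    induction, ``q = 1 - r``.  Other generation counts are out of scope.
    """
    if generations != 0:
        raise NotImplementedError("only zero generations of random mating supported")
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("r must be in [0, 0.5]")
    return 1.0 - r


def _homozygous_indicator(dosage: np.ndarray, who: str) -> np.ndarray:
    d = np.asarray(dosage)
    if np.any((d != 0) & (d != 2)):
        raise HeterozygousParentError(f"{who} parent is not fully homozygous")
    return (d // 2).astype(float)


def predict_family_variance(
    parent1_dosage: np.ndarray,
    parent2_dosage: np.ndarray,
    gmap: GeneticMap,
    alpha: np.ndarray,
) -> float:
    """Analytic genetic variance of a DH family from marker effects.

    Parents must be homozygous over the mapped marker set; ``alpha`` holds
    one additive effect per marker in map order.
    """
    a1 = _homozygous_indicator(parent1_dosage, "maternal")
    a2 = _homozygous_indicator(parent2_dosage, "paternal")
    alpha = np.asarray(alpha, dtype=float)
    if not (a1.size == a2.size == alpha.size == gmap.n_markers):
        raise ValueError("parents, effects and map are not aligned")
    # delta_j = m_j - v_j with m, v the diplotype effects 2 alpha * allele
    delta = 2.0 * alpha * (a1 - a2)
    total = 0.0
    for c, sl in gmap.chrom_slices().items():
        d = delta[sl]
        seg = np.flatnonzero(d != 0.0)
        if seg.size == 0:
            continue
        pos = gmap.pos_cm[sl][seg]
        r = haldane(np.abs(pos[:, None] - pos[None, :]))
        factor = pair_q(r) / 2.0 - 0.25
        total += float(d[seg] @ factor @ d[seg])
    return total


def mc_progeny(
    parent1_dosage: np.ndarray,
    parent2_dosage: np.ndarray,
    gmap: GeneticMap,
    alpha: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
    freq: np.ndarray | None = None,
) -> tuple[float, float]:
    """Monte-Carlo oracle: mean and variance of scored DH progeny.

    Simulates ``n`` DH lines through one meiosis of the biparental F1 and
    scores each with the marker effects (dosages centered at ``2 * freq``
    when frequencies are given; centering shifts the mean only).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a1 = _homozygous_indicator(parent1_dosage, "maternal")
    a2 = _homozygous_indicator(parent2_dosage, "paternal")
    alpha = np.asarray(alpha, dtype=float)
    f1 = np.vstack([a1, a2]).astype(np.uint8)
    gametes = simulate_gametes(f1, gmap, n, seed)
    # score chromosome-wise to avoid materialising an n x p float matrix
    scores = np.zeros(n)
    for _, sl in gmap.chrom_slices().items():
        scores += gametes[:, sl].astype(np.float64, copy=False) @ (2.0 * alpha[sl])
    if freq is not None:
        scores -= float(2.0 * np.asarray(freq, dtype=float) @ alpha)
    var = float(scores.var(ddof=1)) if n > 1 else 0.0
    return float(scores.mean()), var


def predict_ufc(
    mean: float, var_g: float, i: float = 1.27, h: float = 1.0
) -> tuple[float, float]:
    """Usefulness criterion: (UFC_u, UFC_mu).

    ``UFC_u = mean + i * h * sqrt(var_g)`` (variance-aware); ``UFC_mu``
    ignores the variance and equals the predicted mean.  Negative variance
    estimates are clipped to zero with a warning.
    """
    if i < 0:
        raise ValueError("selection intensity must be >= 0")
    if var_g < 0:
        warnings.warn(f"negative predicted variance {var_g:.3g} clipped to 0")
        var_g = 0.0
    return float(mean + i * h * np.sqrt(var_g)), float(mean)


def predict_families(
    crosses: list[CrossSpec],
    gebv: pd.Series,
    dosage: pd.DataFrame,
    gmap: GeneticMap,
    alpha: pd.Series,
    i: float = 1.27,
    h: float = 1.0,
) -> pd.DataFrame:
    """Predicted mean, variance and UFC for a set of planned crosses.

    Means use contribution-weighted midparent GEBVs for 2-, 3- and 4-way
    crosses; the analytic variance (and hence UFC_u) is computed for two-way
    crosses only and reported as NaN otherwise.
    """
    a = alpha[gmap.marker].to_numpy(float)
    rows = []
    for cross in crosses:
        try:
            pv = [float(gebv[p]) for p in cross.parents]
        except KeyError as e:
            warnings.warn(f"family {cross.family}: parent {e.args[0]!r} has no "
                          "GEBV; skipped")
            continue
        mean = predict_family_mean(pv, cross.weights)
        if len(cross.parents) == 2:
            d1 = dosage.loc[cross.parents[0], gmap.marker].to_numpy()
            d2 = dosage.loc[cross.parents[1], gmap.marker].to_numpy()
            var = predict_family_variance(d1, d2, gmap, a)
            ufc_u, ufc_mu = predict_ufc(mean, max(var, 0.0), i, h)
        else:
            var, ufc_u, ufc_mu = np.nan, np.nan, mean
        rows.append((cross.family, cross.cross_type, mean, var, ufc_u, ufc_mu))
    return pd.DataFrame(
        rows, columns=["family", "cross_type", "pred_mean", "pred_var",
                       "ufc_u", "ufc_mu"],
    )
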