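"""Meiosis under the Haldane model (Poisson crossovers, no interference).

Two equivalent gamete samplers are provided:

* :func:`simulate_gamete` draws an explicit crossover process — a
  Poisson-distributed crossover count per chromosome with uniform breakpoint
  positions — and reads the recombinant haplotype off the marker grid.
* :func:`simulate_gametes` is a vectorised batch sampler that uses the Markov
  property of the no-interference crossover process: the gamete's source
  haplotype switches between adjacent markers independently with probability
  equal to the Haldane recombination fraction of the interval.  At the marker
  loci the two constructions have identical distributions; the batch form is
  used wherever many gametes are needed (DH families, Monte-Carlo progeny).
"""

from __future__ import annotations

import numpy as np

from .genmap import GeneticMap

__all__ = ["haldane", "haldane_inverse", "simulate_gamete", "simulate_gametes"]


def haldane(d_cm):
    """Recombination fraction for a map distance in cM: r = (1 - e^(-2d))/2."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def haldane_inverse(r):
    """Map distance in cM for a recombination fraction r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("r must be in [0, 0.5)")
    return -50.0 * np.log(1.0 - 2.0 * r)


def _check_haplotypes(haplotypes: np.ndarray, gmap: GeneticMap) -> np.ndarray:
    h = np.asarray(haplotypes)
    if h.shape != (2, gmap.n_markers):
        raise ValueError(
            f"expected haplotypes of shape (2, {gmap.n_markers}), got {h.shape}"
        )
    return h.astype(np.uint8, copy=False)

def simulate_gamete(
    haplotypes: np.ndarray,
    gmap: GeneticMap,
    rng: int | np.random.Generator = 0,
    return_crossovers: bool = False,
):
    """Draw one recombinant gamete from a pair of phased haplotypes.

    Crossover count per chromosome is Poisson(length in Morgans) and
    breakpoints are uniform on the chromosome.  Returns the gamete's allele
    per marker (and optionally the realised crossover count).
    """
    h = _check_haplotypes(haplotypes, gmap)
    rng = np.random.default_rng(rng)
    gamete = np.empty(gmap.n_markers, dtype=np.uint8)
    total_xo = 0
    for c, sl in gmap.chrom_slices().items():
        pos = gmap.pos_cm[sl]
        length_m = (pos[-1] - pos[0]) / 100.0 if pos.size > 1 else 0.0
        k = rng.poisson(length_m)
        total_xo += int(k)
        start = rng.integers(0, 2)
        if k == 0:
            source = np.full(pos.size, start)
        else:
            breaks = np.sort(rng.uniform(pos[0], pos[-1], size=k))
            n_below = np.searchsorted(breaks, pos, side="left")
            source = (start + n_below) % 2
        gamete[sl] = h[:, sl][source, np.arange(pos.size)]
    if return_crossovers:
        return gamete, total_xo
    return gamete


def simulate_gametes(
    haplotypes: np.ndarray,
    gmap: GeneticMap,
    n: int,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` gametes at once (shape ``(n, n_markers)``, dtype uint8).

    Uses the inter-marker Markov construction: the source haplotype switches
    between adjacent markers with probability ``haldane(d)``, which is exact
    for marker alleles under the no-interference model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h = _check_haplotypes(haplotypes, gmap)
    rng = np.random.default_rng(rng)
    out = np.empty((n, gmap.n_markers), dtype=np.uint8)
    for c, sl in gmap.chrom_slices().items():
        pos = gmap.pos_cm[sl]
        m = pos.size
        r = haldane(np.diff(pos)).astype(np.float32)
        start = rng.integers(0, 2, size=(n, 1), dtype=np.int32)
        source = np.empty((n, m), dtype=np.int32)
        source[:, :1] = start
        if m > 1:
            switch = rng.random((n, m - 1), dtype=np.float32) < r
            np.cumsum(switch, axis=1, dtype=np.int32, out=source[:, 1:])
            source[:, 1:] += start
            source[:, 1:] &= 1
        source[:, 0] &= 1
        hap_c = h[:, sl]
        out[:, sl] = hap_c[source, np.arange(m)[None, :]]
    return out
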