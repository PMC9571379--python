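"""Crosses, F1 construction and doubled-haploid (DH) families.

Parents in a DH programme are fully inbred, so a parent's phase is trivial
(both haplotypes identical).  Two-way crosses give an F1 carrying one
haplotype from each parent; three- and four-way crosses chain gametes drawn
from intermediate F1s.  A DH line is one gamete of the final F1, doubled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap
from .meiosis import simulate_gamete, simulate_gametes

__all__ = [
    "PhasedGenotype",
    "CrossSpec",
    "HeterozygousParentError",
    "contribution_weights",
    "make_cross",
    "produce_dh_family",
]


class HeterozygousParentError(ValueError):
    """Raised when an operation requiring inbred parents meets a het locus."""


@dataclass
class PhasedGenotype:
    """Two phased haplotypes over the marker set (alleles coded 0/1)."""

    id: str
    haplotypes: np.ndarray  # shape (2, n_markers), uint8

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2 or h.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_markers)")
        if h.max(initial=0) > 1:
            raise ValueError("alleles must be 0/1")
        self.haplotypes = h

    @property
    def dosage(self) -> np.ndarray:
        """Counted-allele dosage per marker, in {0, 1, 2}."""
        return self.haplotypes.sum(axis=0).astype(np.uint8)

    @property
    def is_homozygous(self) -> bool:
        return bool(np.all(self.haplotypes[0] == self.haplotypes[1]))

    @classmethod
    def from_dosage(cls, id: str, dosage: np.ndarray) -> "PhasedGenotype":
        """Build a fully homozygous genotype from a {0,2} dosage vector."""
        d = np.asarray(dosage)
        if np.any((d != 0) & (d != 2)):
            raise ValueError("homozygous dosages must be in {0, 2}")
        hap = (d // 2).astype(np.uint8)
        return cls(id, np.vstack([hap, hap]))


_WEIGHTS = {2: (0.5, 0.5), 3: (0.25, 0.25, 0.5), 4: (0.25, 0.25, 0.25, 0.25)}


def contribution_weights(n_parents_or_type) -> tuple:
    """Expected genome contribution per parent for 2-, 3- and 4-way crosses.

    Weights follow the expected proportion of contributed genome: (1/2, 1/2)
    for two-way, (1/4, 1/4, 1/2) for three-way — the last-crossed parent
    contributes half — and (1/4,)*4 for four-way crosses.
    """
    k = n_parents_or_type
    if isinstance(k, str):
        try:
            k = int(k.split("-")[0])
        except ValueError:
            raise ValueError(f"unsupported cross type {n_parents_or_type!r}") from None
    if k not in _WEIGHTS:
        raise ValueError(f"unsupported cross type: {k} parents")
    return _WEIGHTS[k]


@dataclass(frozen=True)
class CrossSpec:
    """A planned cross: ordered parents and the derived contribution weights.

    Parent order matters for three-way crosses ``(P1 x P2) x P3``: the final
    parent P3 contributes half the genome.  Four-way crosses are
    ``(P1 x P2) x (P3 x P4)``.
    """

    family: str
    parents: tuple
    weights: tuple = field(default=None)

    def __post_init__(self) -> None:
        parents = tuple(self.parents)
        object.__setattr__(self, "parents", parents)
        w = self.weights or contribution_weights(len(parents))
        if len(w) != len(parents) or abs(sum(w) - 1.0) > 1e-12:
            raise ValueError("weights must match parents and sum to 1")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def cross_type(self) -> str:
        return f"{len(self.parents)}-way"


def _parent_hap(g: PhasedGenotype) -> np.ndarray:
    if not g.is_homozygous:
        raise HeterozygousParentError(
            f"parent {g.id!r} is heterozygous; only inbred parents are supported"
        )
    return g.haplotypes[0]


def make_cross(
    cross: CrossSpec,
    genotypes: dict,
    gmap: GeneticMap,
    rng: int | np.random.Generator = 0,
) -> PhasedGenotype:
    """Produce the final F1 of a 2-, 3- or 4-way cross of inbred parents.

    ``genotypes`` maps parent id -> :class:`PhasedGenotype`.  Intermediate
    F1s are not returned; gametes from them are drawn by simulated meiosis.
    """
    rng = np.random.default_rng(rng)
    try:
        parents = [genotypes[p] for p in cross.parents]
    except KeyError as e:
        raise KeyError(f"parent {e.args[0]!r} not in genotype set") from None
    haps = [_parent_hap(p) for p in parents]
    k = len(haps)
    if k == 2:
        h1, h2 = haps
    elif k == 3:
        f1 = np.vstack([haps[0], haps[1]])
        h1 = simulate_gamete(f1, gmap, rng)
        h2 = haps[2]
    elif k == 4:
        h1 = simulate_gamete(np.vstack([haps[0], haps[1]]), gmap, rng)
        h2 = simulate_gamete(np.vstack([haps[2], haps[3]]), gmap, rng)
    else:
        raise ValueError(f"unsupported cross type: {k} parents")
    return PhasedGenotype(f"{cross.family}_F1", np.vstack([h1, h2]))


def produce_dh_family(
    f1: PhasedGenotype,
    n_lines: int,
    gmap: GeneticMap,
    rng: int | np.random.Generator = 0,
    id_prefix: str | None = None,
) -> list[PhasedGenotype]:
    """Derive ``n_lines`` doubled haploids from an F1.

    Each line is a single simulated gamete of the F1, doubled — hence fully
    homozygous with dosage in {0, 2} at every marker.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    prefix = id_prefix if id_prefix is not None else f1.id.removesuffix("_F1")
    gametes = simulate_gametes(f1.haplotypes, gmap, n_lines, rng)
    return [
        PhasedGenotype(f"{prefix}_{i + 1:03d}", np.vstack([g, g]))
        for i, g in enumerate(gametes)
    ]
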