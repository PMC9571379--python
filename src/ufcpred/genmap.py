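"""Genetic maps in centiMorgan coordinates.

A :class:`GeneticMap` stores the marker order the whole package relies on:
markers are grouped by chromosome and sorted by genetic position within each
chromosome.  All genotype matrices are column-aligned to this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "build_genetic_map"]


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions on one or more chromosomes.

    Parameters
    ----------
    marker
        Globally unique marker identifiers, grouped by chromosome.
    chrom
        Chromosome name per marker; markers of one chromosome must be
        contiguous.
    pos_cm
        Genetic position in centiMorgans, non-decreasing within chromosome.
    """

    marker: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        marker = np.asarray(self.marker, dtype=object)
        chrom = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos_cm, dtype=float)
        if not (marker.shape == chrom.shape == pos.shape) or marker.ndim != 1:
            raise ValueError("marker, chrom and pos_cm must be equal-length 1-d arrays")
        if len(set(marker)) != marker.size:
            raise ValueError("marker identifiers must be globally unique")
        if np.any(pos < 0) or not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite and >= 0")
        # chromosomes contiguous, positions sorted within each
        seen: dict = {}
        prev = None
        for i, c in enumerate(chrom):
            if c != prev:
                if c in seen:
                    raise ValueError(f"markers of chromosome {c!r} are not contiguous")
                seen[c] = i
                prev = c
            elif pos[i] < pos[i - 1]:
                raise ValueError(
                    f"positions not sorted on chromosome {c!r} (marker {marker[i]!r})"
                )
        object.__setattr__(self, "marker", marker)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_cm", pos)
        object.__setattr__(self, "_index", {m: i for i, m in enumerate(marker)})

    @property
    def n_markers(self) -> int:
        return self.marker.size

    @property
    def chromosomes(self) -> list:
        out, prev = [], None
        for c in self.chrom:
            if c != prev:
                out.append(c)
                prev = c
        return out

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of marker columns."""
        out: dict = {}
        start, prev = 0, None
        for i, c in enumerate(self.chrom):
            if c != prev:
                if prev is not None:
                    out[prev] = slice(start, i)
                start, prev = i, c
        if prev is not None:
            out[prev] = slice(start, self.n_markers)
        return out

    def index_of(self, marker_id) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker, "chrom": self.chrom, "pos_cm": self.pos_cm}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            df["marker"].to_numpy(dtype=object),
            df["chrom"].to_numpy(dtype=object),
            df["pos_cm"].to_numpy(dtype=float),
        )


def build_genetic_map(
    n_chrom: int,
    markers_per_chrom: int,
    chrom_length_cm: float,
    seed: int | np.random.Generator = 0,
) -> GeneticMap:
    """Place markers uniformly at random on equal-length chromosomes.

    Positions are sorted within each chromosome; marker names are
    ``C{c}M{j}``.  Deterministic given the seed.
    """
    if n_chrom < 1 or markers_per_chrom < 1:
        raise ValueError("n_chrom and markers_per_chrom must be >= 1")
    if chrom_length_cm < 0:
        raise ValueError("chrom_length_cm must be >= 0")
    rng = np.random.default_rng(seed)
    markers, chroms, pos = [], [], []
    width = len(str(markers_per_chrom))
    for c in range(1, n_chrom + 1):
        p = np.sort(rng.uniform(0.0, chrom_length_cm, size=markers_per_chrom))
        pos.append(p)
        chroms.extend([f"{c}H"] * markers_per_chrom)
        markers.extend(f"C{c}M{j + 1:0{width}d}" for j in range(markers_per_chrom))
    return GeneticMap(
        np.array(markers, dtype=object),
        np.array(chroms, dtype=object),
        np.concatenate(pos),
    )
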