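"""Per-animal pedigree-knowledge metrics.

Four standard measures of how much of an animal's ancestry is recorded:

* ``max_gen`` — generations to the farthest known ancestor (longest path).
* ``full_gen`` — deepest generation ``g`` such that *all* ``2**g`` ancestor
  slots up to ``g`` are filled by known (non-phantom) animals.
* ``cge`` — complete generations equivalent, the sum of ``(1/2)**g`` over all
  known ancestor slots at generation ``g``; a fully known pedigree of depth
  ``g`` gives exactly ``g``.
* ``pci`` — pedigree completeness index over ``d`` generations: the harmonic
  mean of the paternal- and maternal-side proportions of known ancestors,
  each side averaged over generations 1..d (the parent itself is
  generation 1, so founders score 0).

Phantom records count as unknown throughout: they encode absence of
information, not an extra ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree_io import Pedigree

__all__ = ["CompletenessMetrics", "generation_metrics", "pci", "pci_all",
           "completeness_metrics", "completeness_table"]


@dataclass(frozen=True)
class CompletenessMetrics:
    max_gen: int
    full_gen: int
    cge: float
    pci: float
    pci_depth: int

    def __post_init__(self):
        assert self.full_gen <= self.cge + 1e-12 <= self.max_gen + 1e-12


def _known_parent_indices(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Parent indices with phantoms demoted to unknown (-1)."""
    ped.require_ordered()
    phantom = ped.df["is_phantom"].to_numpy(dtype=bool)
    sire = ped.sire_idx.copy()
    dam = ped.dam_idx.copy()
    sire[(sire >= 0) & phantom[np.clip(sire, 0, None)]] = -1
    dam[(dam >= 0) & phantom[np.clip(dam, 0, None)]] = -1
    return sire, dam


def _all_generation_metrics(ped: Pedigree):
    sire, dam = _known_parent_indices(ped)
    n = len(ped)
    max_gen = np.zeros(n, dtype=np.int64)
    full_gen = np.zeros(n, dtype=np.int64)
    cge = np.zeros(n, dtype=np.float64)
    for i in range(n):
        s, d = sire[i], dam[i]
        mg = 0
        if s >= 0:
            mg = max(mg, 1 + max_gen[s])
            cge[i] += (1.0 + cge[s]) / 2.0
        if d >= 0:
            mg = max(mg, 1 + max_gen[d])
            cge[i] += (1.0 + cge[d]) / 2.0
        max_gen[i] = mg
        if s >= 0 and d >= 0:
            full_gen[i] = 1 + min(full_gen[s], full_gen[d])
    return max_gen, full_gen, cge


def generation_metrics(ped: Pedigree, animal) -> tuple[int, int, float]:
    """``(max_gen, full_gen, cge)`` for one animal."""
    i = ped.index_of(animal)
    mg, fg, t = _all_generation_metrics(ped)
    return int(mg[i]), int(fg[i]), float(t[i])


def _known_counts_per_generation(ped: Pedigree, depth: int) -> np.ndarray:
    """``k[i, g]`` = known ancestor slots of animal i at generation g+1.

    Slots are counted with multiplicity (an inbred ancestor occupying two
    slots counts twice), so ``k[i, g] <= 2**(g+1)``.
    """
    sire, dam = _known_parent_indices(ped)
    n = len(ped)
    k = np.zeros((n, depth), dtype=np.float64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                k[i, 0] += 1
                if depth > 1:
                    k[i, 1:] += k[p, :-1]
    return k


def pci(ped: Pedigree, animal, depth: int = 5) -> float:
    """Pedigree completeness index of one animal over ``depth`` generations."""
    if depth < 1:
        raise ValueError("pci depth must be >= 1")
    i = ped.index_of(animal)
    return float(pci_all(ped, depth)[i])


def pci_all(ped: Pedigree, depth: int = 5) -> np.ndarray:
    """Vector of PCI values for every animal (canonical order)."""
    if depth < 1:
        raise ValueError("pci depth must be >= 1")
    sire, dam = _known_parent_indices(ped)
    k = _known_counts_per_generation(ped, depth)
    n = len(ped)
    out = np.zeros(n, dtype=np.float64)
    denom = 2.0 ** np.arange(1, depth)  # per-side slots at generations 2..d
    for i in range(n):
        sides = []
        for p in (sire[i], dam[i]):
            if p < 0:
                sides.append(0.0)
                continue
            # generation 1 is the parent itself (always known here); deeper
            # generations reuse the parent's own per-generation counts.
            props = np.empty(depth)
            props[0] = 1.0
            if depth > 1:
                props[1:] = k[p, :depth - 1] / denom
            sides.append(props.mean())
        c_pat, c_mat = sides
        if c_pat + c_mat == 0.0:
            out[i] = 0.0
        else:
            out[i] = 2.0 * c_pat * c_mat / (c_pat + c_mat)
    return out


def completeness_metrics(ped: Pedigree, animal, depth: int = 5) -> CompletenessMetrics:
    """All four metrics for one animal, invariant-checked."""
    mg, fg, t = generation_metrics(ped, animal)
    return CompletenessMetrics(mg, fg, t, pci(ped, animal, depth), depth)


def completeness_table(ped: Pedigree, depth: int = 5) -> pd.DataFrame:
    """All completeness metrics for every animal as a DataFrame."""
    mg, fg, t = _all_generation_metrics(ped)
    return pd.DataFrame({
        "id": ped.ids,
        "max_gen": mg,
        "full_gen": fg,
        "cge": t,
        "pci": pci_all(ped, depth),
    })
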