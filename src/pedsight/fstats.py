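"""Wright's F-statistics for a pedigreed population split into subpopulations.

Following the coancestry formulation for pedigreed (rather than
marker-typed) populations: with ``f_S`` the weighted mean within-
subpopulation coancestry (self-pairs included), ``f_T`` the mean coancestry
over all pairs in the whole reference set, and ``F̄`` the mean inbreeding
coefficient,

    F_IS = (F̄ - f_S) / (1 - f_S)
    F_ST = (f_S - f_T) / (1 - f_T)
    F_IT = (F̄ - f_T) / (1 - f_T)

which makes ``(1 - F_IT) = (1 - F_IS)(1 - F_ST)`` an algebraic identity.
With a single subpopulation ``f_S = f_T`` and F_ST vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inbreeding import inbreeding_meuwissen_luo, relationship_matvec
from .pedigree_io import Pedigree, PedigreeError, ReferenceSet

__all__ = ["FStatSummary", "wright_f_statistics"]


@dataclass(frozen=True)
class FStatSummary:
    fis: float
    fst: float
    fit: float
    f_S: float
    f_T: float
    F_bar: float
    weights: str
    partition: dict = field(repr=False, default_factory=dict)

    def identity_residual(self) -> float:
        """|(1 - F_IT) - (1 - F_IS)(1 - F_ST)|, zero up to round-off."""
        return abs((1.0 - self.fit) - (1.0 - self.fis) * (1.0 - self.fst))


def wright_f_statistics(ped: Pedigree, ref, partition: dict,
                        *, weights: str = "size") -> FStatSummary:
    """F_IS / F_ST / F_IT over a labelled reference population.

    ``partition`` maps every reference id to a subpopulation label.
    ``weights='size'`` weights each subpopulation's mean coancestry by its
    share ``n_s/n`` of the reference set; ``weights='equal'`` averages
    subpopulations unweighted.  Mean coancestries are computed matrix-free
    (one relationship-matrix product per subpopulation), so studbook-scale
    reference sets are fine.
    """
    ped.require_ordered()
    ids = list(ref.ids if isinstance(ref, ReferenceSet) else ref)
    missing = [a for a in ids if a not in partition]
    if missing:
        raise PedigreeError(f"reference ids without subpopulation label: "
                            f"{sorted(map(str, missing))[:10]}")
    groups: dict[object, list] = {}
    for a in ids:
        groups.setdefault(partition[a], []).append(a)
    if any(len(g) == 0 for g in groups.values()):
        raise PedigreeError("empty subpopulation")

    F = inbreeding_meuwissen_luo(ped)
    n = len(ids)

    def group_mean_f(members) -> float:
        x = np.zeros(len(ped))
        for a in members:
            x[ped.index_of(a)] = 1.0
        m = len(members)
        return float(x @ relationship_matvec(ped, x, F)) / (2.0 * m * m)

    f_T = group_mean_f(ids)
    if weights == "size":
        f_S = sum(len(g) / n * group_mean_f(g) for g in groups.values())
    elif weights == "equal":
        f_S = float(np.mean([group_mean_f(g) for g in groups.values()]))
    else:
        raise ValueError(f"unknown weighting {weights!r}")

    ridx = [ped.index_of(a) for a in ids]
    F_bar = float(F[ridx].mean())
    fis = (F_bar - f_S) / (1.0 - f_S)
    fst = (f_S - f_T) / (1.0 - f_T)
    fit = (F_bar - f_T) / (1.0 - f_T)
    return FStatSummary(fis=fis, fst=fst, fit=fit, f_S=f_S, f_T=f_T,
                        F_bar=F_bar, weights=weights, partition=dict(partition))
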