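"""Probability-of-gene-origin statistics and the diversity-loss partition.

For a reference population the expected fraction ``p_i`` of its gene pool
contributed by each founder is obtained by recursive halving up the
pedigree.  From these:

* effective number of founders ``fe = 1 / sum(p_i^2)``;
* effective number of ancestors ``fa = 1 / sum(p_k^2)`` over *marginal*
  contributions of greedily selected ancestors (founders or not): at each
  round the ancestor explaining the largest share of the reference gene pool
  not yet explained is selected, its parent links are cut, and explained
  fractions are discounted — ``fa < fe`` signals a bottleneck;
* founder genome equivalents ``fge = 1 / (2 f̄)`` with ``f̄`` the mean
  coancestry of the reference set (self-coancestries included), which also
  folds in drift since the founder generation.

Genetic-diversity losses relative to the founders: total loss
``1 - GD = 1/(2 fge)``, loss from unequal founder contributions
``1 - GD* = 1/(2 fe)``, and drift loss as their difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inbreeding import mean_coancestry
from .pedigree_io import (Pedigree, PedigreeError, ReferenceSet,
                          complete_parents)

__all__ = [
    "GeneOriginSummary",
    "founder_contributions",
    "effective_ancestors",
    "gene_diversity_summary",
    "diversity_loss_partition",
    "gene_origin_summary",
]


def _ref_indices(ped: Pedigree, ref) -> np.ndarray:
    ids = ref.ids if isinstance(ref, ReferenceSet) else ref
    idx = np.array(sorted(ped.index_of(a) for a in ids), dtype=np.int64)
    if idx.size == 0:
        raise PedigreeError("empty reference population")
    return idx


def founder_contributions(ped: Pedigree, ref) -> tuple[dict, float]:
    """Expected founder genome shares ``p_i`` over the reference set, and fe.

    Shares are exact expectations (recursive halving), not gene-drop
    estimates; they sum to one because every lineage terminates in a founder
    (phantom parents, including those standing in for single unknown
    parental sides, count as founders).  Only founders with a positive share
    appear in the returned mapping.
    """
    ped = complete_parents(ped)
    ridx = _ref_indices(ped, ref)
    n = len(ped)
    nref = ridx.size
    # downward pass of reference mass: w[i] = expected fraction of the
    # reference gene pool that traces through animal i to i's own genome
    w = np.zeros(n)
    w[ridx] += 1.0 / nref
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n - 1, -1, -1):
        wi = w[i]
        if wi == 0.0:
            continue
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            w[s] += 0.5 * wi
            w[d] += 0.5 * wi
            w[i] = 0.0  # fully passed upward; mass rests only on founders
    founders = (sire < 0) & (dam < 0)
    contrib = {ped.ids[i]: float(w[i]) for i in range(n)
               if founders[i] and w[i] > 0.0}
    total = float(sum(contrib.values()))
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"founder shares sum to {total}, not 1")
    fe = 1.0 / float(sum(p * p for p in contrib.values()))
    return contrib, fe


def _absorbed_reach(ped: Pedigree, ridx: np.ndarray,
                    selected: np.ndarray) -> np.ndarray:
    """Reference gene-pool share reaching each animal, absorbing at selected.

    ``r[k]`` is the probability that a gene sampled from a random reference
    animal traces to k along a path whose intermediate animals are all
    unselected — the share of the reference pool k can still explain.
    """
    n = len(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    r = np.zeros(n)
    r[ridx] += 1.0 / ridx.size
    for i in range(n - 1, -1, -1):
        ri = r[i]
        if ri == 0.0 or selected[i]:
            continue
        for p in (sire[i], dam[i]):
            if p >= 0:
                r[p] += 0.5 * ri
    return r


def _explained_genome_fraction(ped: Pedigree, selected: np.ndarray) -> np.ndarray:
    """Fraction of each animal's genome deriving from selected ancestors.

    Selected ancestors act as founders (their parent links are cut), so
    genes they inherited are attributed to them, not beyond.
    """
    n = len(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    beta = np.zeros(n)
    for i in range(n):
        if selected[i]:
            beta[i] = 1.0
            continue
        b = 0.0
        if sire[i] >= 0:
            b += 0.5 * beta[sire[i]]
        if dam[i] >= 0:
            b += 0.5 * beta[dam[i]]
        beta[i] = b
    return beta


def effective_ancestors(ped: Pedigree, ref, *, tol: float = 1e-9,
                        max_ancestors: int | None = None
                        ) -> tuple[list[tuple], float, int]:
    """Greedy marginal-contribution ancestor selection.

    Returns ``(ancestors, fa, n50)`` where ``ancestors`` is the selection
    order as ``(id, marginal_contribution)`` pairs, ``fa`` the effective
    number of ancestors and ``n50`` the smallest count of ancestors jointly
    explaining at least half the reference gene pool.

    Candidates are proper ancestors of reference animals plus founders that
    are themselves in the reference set.  Ties are broken by earliest
    canonical (topological) position, then id.  Selection stops when the
    unexplained share drops below ``tol``.
    """
    ped = complete_parents(ped)
    ridx = _ref_indices(ped, ref)
    n = len(ped)
    sire, dam = ped.sire_idx, ped.dam_idx

    candidate = np.zeros(n, dtype=bool)
    stack = []
    for i in ridx:
        for p in (sire[i], dam[i]):
            if p >= 0:
                stack.append(p)
        if sire[i] < 0 and dam[i] < 0:
            candidate[i] = True  # a founder in the reference explains itself
    while stack:
        i = stack.pop()
        if candidate[i]:
            continue
        candidate[i] = True
        for p in (sire[i], dam[i]):
            if p >= 0:
                stack.append(p)

    selected = np.zeros(n, dtype=bool)
    picks: list[tuple] = []
    explained = 0.0
    limit = max_ancestors if max_ancestors is not None else int(candidate.sum())
    while len(picks) < limit and explained < 1.0 - tol:
        r = _absorbed_reach(ped, ridx, selected)
        beta = _explained_genome_fraction(ped, selected)
        marg = np.where(candidate & ~selected, r * (1.0 - beta), 0.0)
        best = float(marg.max(initial=0.0))
        if best <= tol:
            break
        # deterministic tie-break: earliest topological position, then id
        contenders = np.flatnonzero(marg >= best - 1e-15)
        k = int(min(contenders, key=lambda j: (j, str(ped.ids[j]))))
        picks.append((ped.ids[k], float(marg[k])))
        explained += float(marg[k])
        selected[k] = True

    ps = np.array([p for _, p in picks])
    fa = 1.0 / float((ps ** 2).sum())
    cum = np.cumsum(ps)
    n50 = int(np.searchsorted(cum, 0.5 - 1e-12) + 1) if cum.size else 0
    if cum.size and cum[-1] < 0.5:
        n50 = len(picks)
    return picks, fa, n50


@dataclass(frozen=True)
class GeneOriginSummary:
    contributions: dict
    fe: float
    ancestors: list = field(repr=False)
    fa: float = float("nan")
    n50: int = 0
    fge: float = float("nan")
    mean_coancestry: float = float("nan")
    loss_total: float = float("nan")
    loss_founder: float = float("nan")
    loss_drift: float = float("nan")
    n_founders_true: int = 0
    n_founders_phantom: int = 0


def diversity_loss_partition(fge: float, fe: float) -> tuple[float, float, float]:
    """``(loss_total, loss_founder, loss_drift)`` as fractions.

    ``loss_total = 1/(2 fge)`` (equals the mean coancestry of the reference
    set), ``loss_founder = 1/(2 fe)`` and drift loss is their difference, so
    the partition is exact by construction.
    """
    loss_total = 1.0 / (2.0 * fge)
    loss_founder = 1.0 / (2.0 * fe)
    return loss_total, loss_founder, loss_total - loss_founder


def gene_diversity_summary(ped: Pedigree, ref, fe: float,
                           f_mean: float | None = None):
    """Founder genome equivalents and the diversity-loss partition."""
    if f_mean is None:
        ridx = _ref_indices(ped, ref)
        f_mean = mean_coancestry(ped, [ped.ids[i] for i in ridx])
    if f_mean <= 0.0:
        return float("inf"), f_mean, (0.0, 1.0 / (2.0 * fe), -1.0 / (2.0 * fe))
    fge = 1.0 / (2.0 * f_mean)
    return fge, f_mean, diversity_loss_partition(fge, fe)


def gene_origin_summary(ped: Pedigree, ref) -> GeneOriginSummary:
    """Full probability-of-gene-origin analysis of a reference population."""
    ped = complete_parents(ped)
    contrib, fe = founder_contributions(ped, ref)
    ancestors, fa, n50 = effective_ancestors(ped, ref)
    fge, f_mean, losses = gene_diversity_summary(ped, ref, fe)
    phantom = set(ped.df.loc[ped.df["is_phantom"], "id"])
    n_true = sum(1 for a in contrib if a not in phantom)
    n_ph = len(contrib) - n_true
    return GeneOriginSummary(
        contributions=contrib, fe=fe, ancestors=ancestors, fa=fa, n50=n50,
        fge=fge, mean_coancestry=f_mean,
        loss_total=losses[0], loss_founder=losses[1], loss_drift=losses[2],
        n_founders_true=n_true, n_founders_phantom=n_ph,
    )
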