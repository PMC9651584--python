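"""Numerator-relationship machinery.

Inbreeding coefficients by the Meuwissen & Luo algorithm, the tabular
(recursive) relationship matrix as an independent cross-check and for small
submatrices, matrix-free products with the relationship matrix A (Colleau's
indirect method) for average relatedness and mean coancestries, individual
increase in inbreeding, and effective population size.

Notation: A is the additive (numerator) relationship matrix, ``a_ii = 1 +
F_i`` on the diagonal; coancestry (kinship) is ``f_ij = a_ij / 2``.  The
Meuwissen–Luo algorithm computes ``F_i`` one animal at a time by tracing its
ancestors with the within-family-variance vector D, never forming A, so it
scales to studbook-sized pedigrees (tens of thousands of animals).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree_io import Pedigree, PedigreeError, ReferenceSet

__all__ = [
    "inbreeding_meuwissen_luo",
    "tabular_relationship_matrix",
    "kinship_submatrix",
    "relationship_matvec",
    "average_relatedness",
    "mean_coancestry",
    "individual_delta_F",
    "NeEstimate",
    "ne_regression",
    "ne_from_delta_F",
    "ne_estimates",
    "inbreeding_table",
]


def _d_vector(sire: np.ndarray, dam: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Within-family segregation variances d_i given parental inbreeding."""
    n = len(sire)
    d = np.empty(n, dtype=np.float64)
    for i in range(n):
        s, dm = sire[i], dam[i]
        if s >= 0 and dm >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * F[s]
        elif dm >= 0:
            d[i] = 0.75 - 0.25 * F[dm]
        else:
            d[i] = 1.0
    return d


def inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F for every animal (canonical order).

    Per-animal upward trace: starting from the focal animal with coefficient
    1, ancestor contributions are halved along each parent link and the
    diagonal element accumulated as ``a_ii = sum_j L_ij^2 d_j``; then
    ``F_i = a_ii - 1``.  Animals with any unknown parent have F = 0 by
    definition (the unknown side is assumed unrelated).
    """
    ped.require_ordered()
    sire, dam = ped.sire_idx, ped.dam_idx
    n = len(ped)
    F = np.zeros(n, dtype=np.float64)
    # d for ancestors is consumed during later animals' traces; parents always
    # precede offspring so F of j's parents is final when d_j is needed.
    for i in range(n):
        s, dm = sire[i], dam[i]
        if s < 0 or dm < 0:
            continue
        L: dict[int, float] = {i: 1.0}
        a_ii = 0.0
        # process ancestors in decreasing index so every contribution to an
        # ancestor's L is complete before it is popped
        heap = [-i]
        inheap = {i}
        while heap:
            j = -heapq.heappop(heap)
            inheap.discard(j)
            lj = L.pop(j)
            sj, dj = sire[j], dam[j]
            if sj >= 0 and dj >= 0:
                dj_val = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0:
                dj_val = 0.75 - 0.25 * F[sj]
            elif dj >= 0:
                dj_val = 0.75 - 0.25 * F[dj]
            else:
                dj_val = 1.0
            a_ii += lj * lj * dj_val
            for p in (sj, dj):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in inheap:
                        heapq.heappush(heap, -p)
                        inheap.add(p)
        F[i] = a_ii - 1.0
    return F


def tabular_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Full additive relationship matrix A by the tabular method.

    Quadratic in pedigree size; intended as an independent oracle and for
    explicit submatrices, not for production-scale pedigrees.
    """
    ped.require_ordered()
    sire, dam = ped.sire_idx, ped.dam_idx
    n = len(ped)
    A = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        f_i = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + f_i
    return A


def kinship_submatrix(ped: Pedigree, ids, *, max_closure: int = 4000,
                      coancestry: bool = False) -> pd.DataFrame:
    """Relationship (or coancestry) submatrix for a subset of animals.

    The ancestor closure of ``ids`` is extracted, the tabular method run on
    that subpedigree only, and the requested block returned as a labelled
    DataFrame.  ``max_closure`` guards against accidentally materialising a
    near-full matrix; use :func:`relationship_matvec` for matrix-free work.
    """
    ped.require_ordered()
    want = [ped.index_of(a) for a in ids]
    closure: set[int] = set()
    stack = list(want)
    while stack:
        i = stack.pop()
        if i in closure:
            continue
        closure.add(i)
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                stack.append(p)
    if len(closure) > max_closure:
        raise PedigreeError(
            f"ancestor closure has {len(closure)} animals (cap {max_closure}); "
            "use relationship_matvec for matrix-free operations")
    sub = sorted(closure)  # canonical order is preserved under subsetting
    pos = {g: k for k, g in enumerate(sub)}
    sire = np.array([pos.get(ped.sire_idx[i], -1) if ped.sire_idx[i] >= 0 else -1
                     for i in sub])
    dam = np.array([pos.get(ped.dam_idx[i], -1) if ped.dam_idx[i] >= 0 else -1
                    for i in sub])
    n = len(sub)
    A = np.zeros((n, n))
    for k in range(n):
        s, d = sire[k], dam[k]
        if k > 0:
            row = np.zeros(k)
            if s >= 0:
                row += 0.5 * A[s, :k]
            if d >= 0:
                row += 0.5 * A[d, :k]
            A[k, :k] = row
            A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    sel = [pos[i] for i in want]
    block = A[np.ix_(sel, sel)]
    if coancestry:
        block = block / 2.0
    labels = [ped.ids[i] for i in want]
    return pd.DataFrame(block, index=labels, columns=labels)


def relationship_matvec(ped: Pedigree, x: np.ndarray,
                        F: np.ndarray | None = None) -> np.ndarray:
    """Product ``A @ x`` without forming A (Colleau's indirect method).

    Uses the decomposition ``A = (I-B)^{-1} D (I-B)^{-T}`` where B holds the
    one-half parent links: one backward sparse triangular solve, a diagonal
    scaling by D, and one forward solve — O(n) per product.
    """
    ped.require_ordered()
    sire, dam = ped.sire_idx, ped.dam_idx
    n = len(ped)
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != n:
        raise ValueError("x length must equal pedigree size")
    if F is None:
        F = inbreeding_meuwissen_luo(ped)
    d = _d_vector(sire, dam, F)
    # u = (I-B)^{-T} x  (reverse order: children push half their u to parents)
    u = x.copy()
    for i in range(n - 1, -1, -1):
        ui = u[i]
        if ui != 0.0:
            for p in (sire[i], dam[i]):
                if p >= 0:
                    u[p] += 0.5 * ui
    v = d * u
    # y = (I-B)^{-1} v  (forward order: each animal adds half of parents' y)
    y = v
    for i in range(n):
        s, dm = sire[i], dam[i]
        if s >= 0:
            y[i] += 0.5 * y[s]
        if dm >= 0:
            y[i] += 0.5 * y[dm]
    return y


def average_relatedness(ped: Pedigree, F: np.ndarray | None = None,
                        *, scope_ids=None) -> np.ndarray:
    """Average relatedness AR_i = mean_j a_ij for every animal.

    ``scope_ids`` restricts the averaging population j (default: the whole
    pedigree, the usual definition); the returned vector still covers every
    animal i.  Computed matrix-free via one product of A with an indicator
    vector.
    """
    ped.require_ordered()
    n = len(ped)
    if scope_ids is None:
        x = np.full(n, 1.0)
        m = n
    else:
        x = np.zeros(n)
        for a in scope_ids:
            x[ped.index_of(a)] = 1.0
        m = int(x.sum())
        if m == 0:
            raise PedigreeError("empty AR scope")
    return relationship_matvec(ped, x, F) / m


def mean_coancestry(ped: Pedigree, ids, F: np.ndarray | None = None) -> float:
    """Mean coancestry over all ordered pairs of ``ids``, self-pairs included.

    ``f̄ = 1' A 1 / (2 m^2)`` restricted to the subset; self-coancestries
    ``f_ii = (1+F_i)/2`` are part of the average.
    """
    ped.require_ordered()
    x = np.zeros(len(ped))
    for a in ids:
        x[ped.index_of(a)] = 1.0
    m = x.sum()
    if m == 0:
        raise PedigreeError("empty coancestry set")
    return float(x @ relationship_matvec(ped, x, F) / (2.0 * m * m))


# ---------------------------------------------------------------------------
# rate of inbreeding and effective population size


def individual_delta_F(F_i: float, t_i: float) -> float:
    """Individual increase in inbreeding ``ΔF_i = 1 - (1-F_i)^(1/(t_i-1))``.

    ``t_i`` is the animal's equivalent complete generations.  Defined only
    for ``t_i > 1`` (otherwise NaN): an animal with no traced generation
    carries no information on the rate.
    """
    if F_i >= 1.0:
        raise ValueError("F must be < 1")
    if t_i is None or not np.isfinite(t_i) or t_i <= 1.0:
        return float("nan")
    return 1.0 - (1.0 - F_i) ** (1.0 / (t_i - 1.0))


def delta_F_all(F: np.ndarray, t: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(F >= 1.0):
        raise ValueError("F must be < 1")
    out = np.full(F.shape, np.nan)
    ok = np.isfinite(t) & (t > 1.0)
    out[ok] = 1.0 - (1.0 - F[ok]) ** (1.0 / (t[ok] - 1.0))
    return out


@dataclass(frozen=True)
class NeEstimate:
    """Effective population size with its provenance.

    ``ne = 1/(2 b)`` for the regression methods (b = OLS slope of F on the
    generation measure) or ``ne = 1/(2 mean ΔF)`` for the individual-increase
    method; ``dispersion`` is a delta-method standard error, NaN when the
    slope/mean is non-positive and ne is undefined.
    """
    ne: float
    method: str
    b: float = float("nan")
    mean_delta_F: float = float("nan")
    dispersion: float = float("nan")
    n: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.ne) and self.ne > 0


def ne_regression(F: np.ndarray, predictor: np.ndarray,
                  method: str = "regression-on-cge") -> NeEstimate:
    """Ne from the OLS slope of individual F on a generation measure."""
    F = np.asarray(F, dtype=float)
    x = np.asarray(predictor, dtype=float)
    ok = np.isfinite(F) & np.isfinite(x)
    if ok.sum() < 3:
        raise PedigreeError("need at least 3 animals with defined predictors")
    res = stats.linregress(x[ok], F[ok])
    b = res.slope
    if b <= 0:
        return NeEstimate(float("nan"), method, b=b, n=int(ok.sum()))
    ne = 1.0 / (2.0 * b)
    se = res.stderr / (2.0 * b * b)  # delta method through 1/(2b)
    return NeEstimate(ne, method, b=b, dispersion=se, n=int(ok.sum()))


def ne_from_delta_F(delta_F: np.ndarray) -> NeEstimate:
    """Ne from the mean individual increase in inbreeding."""
    dF = np.asarray(delta_F, dtype=float)
    dF = dF[np.isfinite(dF)]
    if dF.size < 3:
        raise PedigreeError("need at least 3 defined delta-F values")
    mean = float(dF.mean())
    if mean <= 0:
        return NeEstimate(float("nan"), "individual-delta-F",
                          mean_delta_F=mean, n=dF.size)
    ne = 1.0 / (2.0 * mean)
    sem = dF.std(ddof=1) / np.sqrt(dF.size)
    se = sem / (2.0 * mean * mean)  # delta method through 1/(2 mean)
    return NeEstimate(ne, "individual-delta-F", mean_delta_F=mean,
                      dispersion=se, n=dF.size)


def ne_estimates(F: np.ndarray, cge: np.ndarray, max_gen: np.ndarray,
                 mask: np.ndarray | None = None) -> dict[str, NeEstimate]:
    """All three Ne estimators over a reference subset (boolean ``mask``)."""
    if mask is None:
        mask = np.ones(len(F), dtype=bool)
    F = np.asarray(F)[mask]
    cge = np.asarray(cge, dtype=float)[mask]
    mg = np.asarray(max_gen, dtype=float)[mask]
    return {
        "regression-on-cge": ne_regression(F, cge, "regression-on-cge"),
        "regression-on-maxgen": ne_regression(F, mg, "regression-on-maxgen"),
        "individual-delta-F": ne_from_delta_F(delta_F_all(F, cge)),
    }


def inbreeding_table(ped: Pedigree, cge: np.ndarray | None = None) -> pd.DataFrame:
    """Per-animal F, AR and ΔF as a DataFrame (canonical order)."""
    F = inbreeding_meuwissen_luo(ped)
    ar = average_relatedness(ped, F)
    if cge is None:
        from .completeness import _all_generation_metrics
        cge = _all_generation_metrics(ped)[2]
    return pd.DataFrame({
        "id": ped.ids,
        "F": F,
        "AR": ar,
        "delta_F": delta_F_all(F, cge),
    })
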