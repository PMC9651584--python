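"""Gene-dropping decomposition of inbreeding into new and ancestral parts.

Each founder carries two uniquely labelled alleles; every transmission down
the pedigree picks one parental allele with probability one half.  In a given
realisation an animal is *autozygous* when its two labels coincide.  An
allele copy is *exposed* when some strict ancestor on its transmission path
was itself autozygous in that realisation — the allele has already been
through an identical-by-descent event higher up the pedigree.

Per animal the following probabilities are estimated (or, in exhaustive
mode, enumerated exactly over all transmission patterns):

* ``F_hat``     — P(autozygous), the ordinary inbreeding coefficient;
* ``Fa_kal``    — P(autozygous and at least one allele exposed): ancestral
  inbreeding in Kalinowski's sense, IBD involving alleles already exposed to
  inbreeding in ancestors;
* ``F_new``     — P(autozygous and neither allele exposed): first-time IBD;
  by construction ``F_new + Fa_kal = F_hat`` within every run;
* ``Fa_ballou`` — P(a randomly chosen one of the two alleles is exposed):
  Ballou's ancestral inbreeding.

Exposure is defined over *strict* ancestors only (the focal animal's own
autozygosity does not expose its alleles to itself), which is what makes the
new/ancestral split an exact partition of F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree_io import Pedigree, PedigreeError

__all__ = ["GeneDropResult", "gene_drop"]

_BATCH = 1 << 14


@dataclass(frozen=True)
class GeneDropResult:
    """Per-animal gene-drop probabilities in pedigree (canonical) order."""
    ids: list
    F_hat: np.ndarray
    Fa_kal: np.ndarray
    F_new: np.ndarray
    Fa_ballou: np.ndarray
    replicates: int
    seed: int | None
    mode: str

    @property
    def se(self) -> np.ndarray:
        """Binomial Monte-Carlo standard error of F_hat (zero if exhaustive)."""
        if self.mode == "exhaustive":
            return np.zeros_like(self.F_hat)
        return np.sqrt(self.F_hat * (1.0 - self.F_hat) / self.replicates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "F_hat": self.F_hat, "Fa_kal": self.Fa_kal,
            "F_new": self.F_new, "Fa_ballou": self.Fa_ballou,
        })


def _drop_batch(ped: Pedigree, bits) -> tuple[np.ndarray, ...]:
    """Run one batch of realisations given per-transmission bit arrays.

    ``bits`` maps transmission slots (one per known-parent link, in animal
    order, sire side first) to uint8 arrays of length = batch size.  An
    unknown parental side contributes a fresh, never-exposed unique allele.
    Returns per-animal counts of (autozygous, autozygous-and-exposed,
    exposed allele halves) summed over the batch, plus the batch size.
    """
    sire, dam = ped.sire_idx, ped.dam_idx
    n = len(ped)
    nrep = len(next(iter(bits.values())))
    lab = [[None, None] for _ in range(n)]  # founder-allele labels, 2 copies
    exp = [[None, None] for _ in range(n)]  # exposure flags, 2 copies
    auto: list = [None] * n
    fresh_exp = np.zeros(nrep, dtype=bool)
    n_auto = np.zeros(n, dtype=np.int64)
    n_anc = np.zeros(n, dtype=np.int64)
    n_expose_half = np.zeros(n, dtype=np.int64)
    # free each animal's per-replicate arrays once its last child is done
    last_use = np.arange(n)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                last_use[p] = i
    free_at: dict[int, list[int]] = {}
    for j in range(n):
        free_at.setdefault(int(last_use[j]), []).append(j)
    t = 0
    for i in range(n):
        for side, p in enumerate((sire[i], dam[i])):
            if p >= 0:
                pick = bits[t].astype(bool)
                t += 1
                lab[i][side] = np.where(pick, lab[p][0], lab[p][1])
                exp[i][side] = np.where(pick, exp[p][0], exp[p][1]) | auto[p]
            else:
                lab[i][side] = np.full(nrep, 2 * i + side, dtype=np.int32)
                exp[i][side] = fresh_exp
        az = lab[i][0] == lab[i][1]
        auto[i] = az
        n_auto[i] = int(az.sum())
        n_anc[i] = int((az & (exp[i][0] | exp[i][1])).sum())
        n_expose_half[i] = int(exp[i][0].sum()) + int(exp[i][1].sum())
        for j in free_at.get(i, ()):
            lab[j] = exp[j] = auto[j] = None
    return n_auto, n_anc, n_expose_half, nrep


def _transmission_slots(ped: Pedigree) -> int:
    sire, dam = ped.sire_idx, ped.dam_idx
    return int((sire >= 0).sum() + (dam >= 0).sum())


def gene_drop(ped: Pedigree, replicates: int = 100_000,
              seed: int | None = None, mode: str = "monte-carlo",
              *, exhaustive_bound: int = 25) -> GeneDropResult:
    """Drop founder alleles through the pedigree and split F into new/old.

    ``mode='monte-carlo'`` samples ``replicates`` independent realisations
    (an explicit ``seed`` is mandatory).  ``mode='exhaustive'`` enumerates
    all ``2**T`` transmission patterns, where T is the number of
    transmission events (two per animal with both parents known), and
    returns exact probabilities; it refuses pedigrees with more than
    ``exhaustive_bound`` transmissions.
    """
    ped.require_ordered()
    n = len(ped)
    T = _transmission_slots(ped)
    counts = [np.zeros(n, dtype=np.int64) for _ in range(3)]
    total = 0
    if mode == "exhaustive":
        if T > exhaustive_bound:
            raise PedigreeError(
                f"{T} transmission events exceed the exhaustive bound "
                f"{exhaustive_bound}; use monte-carlo mode")
        npat = 1 << T
        for start in range(0, npat, _BATCH):
            stop = min(start + _BATCH, npat)
            pats = np.arange(start, stop, dtype=np.int64)
            bits = {k: ((pats >> k) & 1).astype(np.uint8) for k in range(T)}
            if T == 0:
                bits = {0: np.zeros(stop - start, dtype=np.uint8)}
            out = _drop_batch(ped, bits)
            for c, o in zip(counts, out[:3]):
                c += o
            total += out[3]
        reps = npat
    elif mode == "monte-carlo":
        if seed is None:
            raise PedigreeError("monte-carlo gene drop requires an explicit seed")
        rng = np.random.default_rng(seed)
        done = 0
        while done < replicates:
            b = min(_BATCH, replicates - done)
            bits = {k: rng.integers(0, 2, size=b, dtype=np.uint8)
                    for k in range(max(T, 1))}
            out = _drop_batch(ped, bits)
            for c, o in zip(counts, out[:3]):
                c += o
            done += b
        total = done
        reps = replicates
    else:
        raise PedigreeError(f"unknown gene-drop mode {mode!r}")

    n_auto, n_anc, n_half = counts
    F_hat = n_auto / total
    Fa_kal = n_anc / total
    F_new = (n_auto - n_anc) / total
    Fa_ballou = n_half / (2.0 * total)
    return GeneDropResult(ped.ids, F_hat, Fa_kal, F_new, Fa_ballou,
                          replicates=reps, seed=seed, mode=mode)
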