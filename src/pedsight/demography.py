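"""Generation intervals and reproductive-skew summaries.

Generation interval: mean parental age at the birth of offspring that
themselves reproduced, split over the four parent-offspring paths
(father-son, father-daughter, mother-son, mother-daughter).  The companion
metric counts parental age at the birth of *every* offspring, reproducing or
not.  Ages are measured in years of 365.25 days; year-only birth dates
were mapped to mid-year at parse time, so year-resolution pedigrees lose at
most half a year per endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree_io import FEMALE, MALE, Pedigree, PedigreeError

__all__ = ["IntervalSummary", "generation_intervals", "reproductive_summary"]

_PATHS = ("father-son", "father-daughter", "mother-son", "mother-daughter")

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class IntervalSummary:
    """Counts, means and SDs of parental ages per path and in total."""
    metric: str
    paths: dict = field(default_factory=dict)  # path -> (n, mean, sd)

    @property
    def total(self) -> tuple[int, float, float]:
        return self.paths["total"]

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, *v) for k, v in self.paths.items()]
        return pd.DataFrame(rows, columns=["path", "n", "mean_years", "sd_years"])


def _observations(ped: Pedigree, metric: str, restrict_ids=None):
    """Yield (path, age_years) for every qualifying parent-offspring pair."""
    df = ped.df
    birth = df["birth_date"]
    sex = df["sex"]
    sire, dam = ped.sire_idx, ped.dam_idx
    has_kids = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        for p in (sire[i], dam[i]):
            if p >= 0:
                has_kids[p] = True
    keep = None
    if restrict_ids is not None:
        keep = {ped.index_of(a) for a in restrict_ids}
    obs: list[tuple[str, float]] = []
    for i in range(len(df)):
        if metric == "interval-reproducing-offspring" and not has_kids[i]:
            continue
        child_sex = sex.iloc[i]
        if child_sex == MALE:
            child_part = "son"
        elif child_sex == FEMALE:
            child_part = "daughter"
        else:
            continue  # unknown-sex animals are outside the four paths
        b_child = birth.iloc[i]
        if pd.isna(b_child):
            continue
        for p, parent_part in ((sire[i], "father"), (dam[i], "mother")):
            if p < 0:
                continue
            if keep is not None and p not in keep:
                continue
            b_par = birth.iloc[p]
            if pd.isna(b_par):
                continue
            age = (b_child - b_par).days / _DAYS_PER_YEAR
            if age <= 0:
                raise PedigreeError(
                    f"non-positive parental age for {df['id'].iloc[p]!r} -> "
                    f"{df['id'].iloc[i]!r}")
            obs.append((f"{parent_part}-{child_part}", age))
    return obs


def generation_intervals(ped: Pedigree,
                         metric: str = "interval-reproducing-offspring",
                         *, restrict_parents=None) -> IntervalSummary:
    """Parental-age summary over the four sexed parent-offspring paths.

    ``metric='interval-reproducing-offspring'`` (the classical generation
    interval) counts only offspring that themselves have offspring;
    ``metric='age-at-any-offspring'`` counts every offspring.
    ``restrict_parents`` limits the parent side to a subset of ids (e.g. a
    reference population).
    """
    if metric not in ("interval-reproducing-offspring", "age-at-any-offspring"):
        raise ValueError(f"unknown metric {metric!r}")
    ped.require_ordered()
    obs = _observations(ped, metric, restrict_parents)
    paths: dict[str, tuple[int, float, float]] = {}
    for path in _PATHS:
        vals = np.array([a for p, a in obs if p == path])
        paths[path] = _nms(vals)
    allvals = np.array([a for _, a in obs])
    paths["total"] = _nms(allvals)
    return IntervalSummary(metric=metric, paths=paths)


def _nms(vals: np.ndarray) -> tuple[int, float, float]:
    if vals.size == 0:
        return (0, float("nan"), float("nan"))
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return (int(vals.size), float(vals.mean()), sd)


def reproductive_summary(ped: Pedigree) -> dict:
    """Per-sex counts of breeders, offspring-per-breeder and the histogram.

    The histogram maps offspring count -> number of parents of that sex with
    exactly that many recorded offspring (reproducing animals only), so the
    weighted histogram total equals the number of animals with that parent
    recorded.
    """
    ped.require_ordered()
    df = ped.df
    n = len(df)
    n_off = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                n_off[p] += 1
    out = {}
    for sex, label in ((MALE, "male"), (FEMALE, "female")):
        mask = (df["sex"] == sex).to_numpy()
        total = int(mask.sum())
        counts = n_off[mask]
        rep = counts[counts > 0]
        hist = {int(k): int(v) for k, v in
                zip(*np.unique(rep, return_counts=True))}
        out[label] = {
            "n_animals": total,
            "n_reproducing": int(rep.size),
            "pct_reproducing": 100.0 * rep.size / total if total else float("nan"),
            "mean_offspring": float(rep.mean()) if rep.size else float("nan"),
            "sd_offspring": float(rep.std(ddof=1)) if rep.size > 1 else 0.0,
            "offspring_histogram": hist,
            "total_offspring": int(rep.sum()),
        }
    return out
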