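"""Synthetic pedigrees with known ground truth.

The forward simulator emulates the statistical structure of a closed,
intensively managed large-herbivore studbook population: a small founder set
(default 17), two partially overlapping breeding lineages, overlapping
generations spanning ~140 years, heavy-tailed female offspring counts
(negative-binomial), strong male reproductive skew (a small fraction of
males sires most calves), and a fraction of records with censored parents or
sex.  Censoring is applied *after* simulation, so the complete pedigree is
always available as ground truth: per-animal founder genome shares (exact
recursive expectations) and exact inbreeding coefficients.

Deterministic fixtures with closed-form truth are also provided: the
full-sib chain (whose inbreeding obeys ``F_t = (1 + 2 F_{t-1} + F_{t-2})/4``)
and a constant-size discrete-generation random-mating population for
effective-size calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inbreeding import inbreeding_meuwissen_luo, tabular_relationship_matrix
from .pedigree_io import FEMALE, MALE, UNKNOWN, Pedigree, pedigree_from_frame

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimulationExtinct",
    "simulate_pedigree",
    "fullsib_chain_fixture",
    "fullsib_chain_F",
    "discrete_generations_pedigree",
    "random_pedigree",
]


class SimulationExtinct(RuntimeError):
    """Raised when no eligible breeding pairs remain."""

    def __init__(self, generation: int):
        super().__init__(f"population extinct at generation {generation}")
        self.generation = generation


@dataclass(frozen=True)
class SimConfig:
    """Forward-simulation parameters.

    Defaults emulate the study system: 17 founders, two lineages seeded
    unevenly, ~20 overlapping generations from 1881, mean parental age about
    9 years, negative-binomial litter sizes (mean ~4.7 per breeding female)
    and a male-skew concentration small enough that well under 30% of males
    ever reproduce.
    """
    n_founders: int = 17
    n_generations: int = 20
    offspring_mean: float = 4.7
    # negative-binomial size parameter; smaller = heavier tail.  None makes
    # litter counts deterministic (round(offspring_mean)), handy for minimal
    # constructions.
    offspring_dispersion: float | None = 1.5
    male_mating_skew: float = 0.03     # Dirichlet concentration over sires
    lineage_split: float = 12 / 17     # fraction of founders seeding lineage 2
    missing_parent_rate: float = 0.0
    missing_sex_rate: float = 0.0
    start_year: int = 1881
    mean_parental_age: float = 9.0
    max_cohort: int = 400
    seed: int | None = None

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        for r in (self.missing_parent_rate, self.missing_sex_rate,
                  self.lineage_split):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")


@dataclass(frozen=True)
class TruthTable:
    """Un-censored ground truth keyed by animal id.

    ``founder_shares`` rows sum to one; ``F`` is the exact inbreeding
    coefficient of the complete pedigree; ``generation`` is the birth cohort
    (founders are 0).
    """
    founder_shares: pd.DataFrame
    F: pd.Series
    generation: pd.Series
    uncensored: Pedigree = field(repr=False, default=None)


def _true_F(ped: Pedigree) -> np.ndarray:
    # exact tabular diagonal where affordable, Meuwissen-Luo beyond that
    if len(ped) <= 3000:
        return np.diag(tabular_relationship_matrix(ped)) - 1.0
    return inbreeding_meuwissen_luo(ped)


def _founder_shares(ped: Pedigree, founder_ids: list) -> pd.DataFrame:
    n = len(ped)
    fpos = {ped.index_of(a): k for k, a in enumerate(founder_ids)}
    shares = np.zeros((n, len(founder_ids)))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if i in fpos:
            shares[i, fpos[i]] = 1.0
            continue
        if s >= 0:
            shares[i] += 0.5 * shares[s]
        if d >= 0:
            shares[i] += 0.5 * shares[d]
    return pd.DataFrame(shares, index=ped.ids, columns=founder_ids)


def simulate_pedigree(config: SimConfig) -> tuple[Pedigree, TruthTable]:
    """Run the forward simulation; returns the censored pedigree and truth.

    Breeding is cohort-based with overlap: each step the females of the two
    most recent cohorts breed; every new female draws a lifetime offspring
    count from the negative-binomial spec, and each calf's sire is drawn
    from the eligible males with Dirichlet-distributed (skewed) weights.
    Identical config (including seed) gives an identical pedigree.
    """
    rng = np.random.default_rng(config.seed)
    records: list[dict] = []  # id, sire, dam, sex, birth_year, lineage, gen

    n2 = int(round(config.n_founders * config.lineage_split))
    per_lineage_rank = {"L1": 0, "L2": 0}
    for k in range(config.n_founders):
        lineage = "L2" if k < n2 else "L1"
        rank = per_lineage_rank[lineage]
        per_lineage_rank[lineage] += 1
        records.append({
            "id": f"F{k + 1}",
            "sire": None, "dam": None,
            # alternate sexes within each lineage, females first, so both
            # herds start with breeding females
            "sex": FEMALE if rank % 2 == 0 else MALE,
            "birth_year": config.start_year + int(rng.integers(0, 6)),
            "lineage": lineage,
            "gen": 0,
        })

    cohorts: list[list[int]] = [list(range(config.n_founders))]
    counter = 0
    for g in range(1, config.n_generations + 1):
        recent = cohorts[-1] + (cohorts[-2] if len(cohorts) > 1 else [])
        dams = [i for i in recent if records[i]["sex"] == FEMALE]
        sires = [i for i in recent if records[i]["sex"] == MALE]
        if not dams or not sires:
            raise SimulationExtinct(g)
        # reproductive skew: a few sires get nearly all the weight
        w = rng.dirichlet(np.full(len(sires), config.male_mating_skew)
                          if len(sires) > 1 else [1.0])
        new: list[int] = []
        disp = config.offspring_dispersion
        p_nb = disp / (disp + config.offspring_mean) if disp else None
        # breeding order shuffled so the cohort cap does not starve the
        # females listed last
        for dm in rng.permutation(cohorts[-1]):
            if records[dm]["sex"] != FEMALE:
                continue
            n_off = int(rng.negative_binomial(disp, p_nb)) if disp \
                else int(round(config.offspring_mean))
            for _ in range(n_off):
                if len(new) >= config.max_cohort:
                    break
                dam_rec = records[dm]
                s = _pick_sire(rng, sires, w, records, dam_rec["lineage"])
                counter += 1
                age_d = max(2.0, rng.normal(config.mean_parental_age, 3.0))
                # the calf must postdate both parents (sires can be younger
                # than the dam within the overlapping cohorts)
                birth = max(dam_rec["birth_year"] + int(round(age_d)),
                            records[s]["birth_year"] + 2)
                # herd membership follows the dam; occasional cross-lineage
                # sires keep the two gene pools partially overlapping
                records.append({
                    "id": f"X{counter}",
                    "sire": records[s]["id"], "dam": dam_rec["id"],
                    "sex": MALE if rng.random() < 0.5 else FEMALE,
                    "birth_year": birth,
                    "lineage": dam_rec["lineage"],
                    "gen": g,
                })
                new.append(len(records) - 1)
        if not new:
            raise SimulationExtinct(g)
        cohorts.append(new)

    full = pd.DataFrame.from_records(records)
    full["birth_date"] = pd.to_datetime(
        {"year": full["birth_year"], "month": 7, "day": 1})
    lifespan = np.maximum(2, rng.normal(18.0, 6.0, len(full))).round()
    full["death_date"] = pd.to_datetime(
        {"year": full["birth_year"] + lifespan.astype(int), "month": 7, "day": 1})

    uncensored = pedigree_from_frame(
        full[["id", "sire", "dam", "sex", "birth_date", "death_date",
              "lineage"]].copy())
    truth = TruthTable(
        founder_shares=_founder_shares(
            uncensored, [f"F{k + 1}" for k in range(config.n_founders)]),
        F=pd.Series(_true_F(uncensored), index=uncensored.ids),
        generation=pd.Series(full["gen"].to_numpy(), index=full["id"]),
        uncensored=uncensored,
    )

    censored = full.copy()
    nonf = censored["sire"].notna() | censored["dam"].notna()
    for col in ("sire", "dam"):
        drop = (rng.random(len(censored)) < config.missing_parent_rate) & nonf
        censored.loc[drop, col] = None
    drop_sex = rng.random(len(censored)) < config.missing_sex_rate
    censored.loc[drop_sex, "sex"] = UNKNOWN
    # animals still referenced as parents keep their sex so the censored
    # pedigree stays structurally valid
    used = set(censored["sire"].dropna()) | set(censored["dam"].dropna())
    mask = censored["id"].isin(used)
    censored.loc[mask, "sex"] = full.loc[mask, "sex"]
    ped = pedigree_from_frame(
        censored[["id", "sire", "dam", "sex", "birth_date", "death_date",
                  "lineage"]].copy())
    return ped, truth


def _pick_sire(rng, sires, w, records, dam_lineage):
    """Sire draw: within-lineage with probability 0.97, population-wide else."""
    if rng.random() < 0.97:
        mask = np.array([records[s]["lineage"] == dam_lineage for s in sires])
        wl = w * mask
        if wl.sum() > 0:
            return sires[int(rng.choice(len(sires), p=wl / wl.sum()))]
    return sires[int(rng.choice(len(sires), p=w))]


# ---------------------------------------------------------------------------
# deterministic fixtures


def fullsib_chain_F(depth: int) -> list[float]:
    """Closed-form inbreeding along repeated full-sib mating.

    ``F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4`` with ``F_0 = F_{-1} = 0``;
    generation 1 (offspring of the founder pair) has F = 1/4 and the
    sequence increases monotonically to 1.
    """
    Fm1, F0 = 0.0, 0.0
    out = []
    for _ in range(depth):
        Ft = (1.0 + 2.0 * F0 + Fm1) / 4.0
        out.append(Ft)
        Fm1, F0 = F0, Ft
    return out


def fullsib_chain_fixture(depth: int) -> Pedigree:
    """Repeated full-sib mating: one sib pair per generation.

    Founders A and B produce the generation-0 sib pair ``S0a``/``S0b``
    (non-inbred); thereafter the pair of generation ``t`` are full sibs whose
    parents are the generation ``t-1`` pair, so ``S{t}a``/``S{t}b`` carry the
    closed-form coefficient ``fullsib_chain_F(depth)[t-1]`` for t >= 1.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rows = [("A", None, None, "M"), ("B", None, None, "F")]
    sire, dam = "A", "B"
    for t in range(0, depth + 1):
        a, b = f"S{t}a", f"S{t}b"
        rows.append((a, sire, dam, "M"))
        rows.append((b, sire, dam, "F"))
        sire, dam = a, b
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])
    return pedigree_from_frame(df)


def discrete_generations_pedigree(N: int, n_generations: int,
                                  seed: int) -> Pedigree:
    """Constant-size random-mating population with discrete generations.

    Each generation has ``N`` animals (half males, half females); every
    offspring draws its sire and dam uniformly from the previous
    generation.  The idealised effective size of this design is close to the
    census size N, so it calibrates rate-of-inbreeding estimators.
    """
    rng = np.random.default_rng(seed)
    rows = []
    males = [f"G0M{j}" for j in range(N // 2)]
    females = [f"G0F{j}" for j in range(N - N // 2)]
    rows += [(m, None, None, "M", 2000) for m in males]
    rows += [(f, None, None, "F", 2000) for f in females]
    for g in range(1, n_generations + 1):
        nm = N // 2
        new_m = [f"G{g}M{j}" for j in range(nm)]
        new_f = [f"G{g}F{j}" for j in range(N - nm)]
        year = 2000 + 5 * g
        for name, sex in [(x, "M") for x in new_m] + [(x, "F") for x in new_f]:
            s = males[int(rng.integers(len(males)))]
            d = females[int(rng.integers(len(females)))]
            rows.append((name, s, d, sex, year))
        males, females = new_m, new_f
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "year"])
    df["birth_date"] = pd.to_datetime({"year": df.pop("year"),
                                       "month": 7, "day": 1})
    return pedigree_from_frame(df)


def random_pedigree(n: int, seed: int, *, founder_fraction: float = 0.3,
                    missing_rate: float = 0.0) -> Pedigree:
    """Small random valid pedigree for property tests.

    Each non-founder picks a sire and dam uniformly among earlier animals of
    the right sex (falling back to founder status if none exists yet).
    """
    rng = np.random.default_rng(seed)
    rows = []
    males: list[str] = []
    females: list[str] = []
    for i in range(n):
        name = f"R{i}"
        sex = "M" if rng.random() < 0.5 else "F"
        founder = (i < 2) or (rng.random() < founder_fraction) or \
            not males or not females
        if founder:
            s = d = None
        else:
            s = males[int(rng.integers(len(males)))]
            d = females[int(rng.integers(len(females)))]
            if missing_rate:
                if rng.random() < missing_rate:
                    s = None
                if rng.random() < missing_rate:
                    d = None
        rows.append((name, s, d, sex))
        (males if sex == "M" else females).append(name)
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])
    return pedigree_from_frame(df)
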