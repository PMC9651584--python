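"""Reading, validation and canonical ordering of pedigree tables.

A pedigree is a table with one row per animal: identifier, sire, dam, sex,
birth/death dates and an optional lineage label.  Parents referenced but never
defined are materialised as *phantom* founder records so that every edge of
the ancestor graph points at a real row.  Canonical order is topological
(every parent precedes every offspring) with input order as tie-break, which
is the order all downstream recursions assume.
"""

from __future__ import annotations

import heapq
import io
import json
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "Pedigree",
    "ReferenceSet",
    "PedigreeError",
    "parse_pedigree",
    "validate_and_order",
    "select_reference",
    "write_pedigree",
]

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_TOKENS = {
    "m": MALE, "male": MALE, "1": MALE, "s": MALE, "sire": MALE, "bull": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE, "d": FEMALE, "dam": FEMALE,
    "cow": FEMALE,
    "u": UNKNOWN, "unknown": UNKNOWN, "?": UNKNOWN, "3": UNKNOWN, "0": UNKNOWN,
}


class PedigreeError(ValueError):
    """Raised for structural defects that make a pedigree unusable."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping and missing-value conventions of a pedigree file.

    ``columns`` maps the logical field names (``id``, ``sire``, ``dam``,
    ``sex``, ``birth``, ``death``, ``lineage``) to header names in the file;
    only ``id``, ``sire`` and ``dam`` are mandatory.  Any token in
    ``missing_codes`` (case-sensitive, compared after stripping) is treated
    as MISSING.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "id": "id", "sire": "sire", "dam": "dam", "sex": "sex",
            "birth": "birth", "death": "death", "lineage": "lineage",
        }
    )
    missing_codes: tuple[str, ...] = ("", "0", "NA", "na", ".")
    sep: str = ","

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "Dialect":
        kwargs = {}
        if "columns" in cfg:
            kwargs["columns"] = dict(cfg["columns"])
        if "missing_codes" in cfg:
            kwargs["missing_codes"] = tuple(str(c) for c in cfg["missing_codes"])
        if "sep" in cfg:
            kwargs["sep"] = cfg["sep"]
        return cls(**kwargs)


@dataclass(frozen=True)
class ReferenceSet:
    """A reference population: ids considered alive (able to breed) at a date."""

    ids: frozenset
    as_of: date | None = None

    def __post_init__(self):
        if not self.ids:
            raise PedigreeError("reference set is empty")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


class Pedigree:
    """A validated, canonically ordered collection of animal records.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per animal with columns ``id``, ``sire``, ``dam`` (object,
        ``None`` for missing), ``sex`` (``male``/``female``/``unknown``),
        ``birth_date``/``death_date`` (``pandas.Timestamp`` or ``NaT``),
        ``lineage`` (object or ``None``), ``is_phantom`` (bool).

    Attributes
    ----------
    sire_idx, dam_idx : ndarray of int
        Positional parent indices in canonical order, ``-1`` for missing.
        Only available after :func:`validate_and_order`.
    """

    REQUIRED = ("id", "sire", "dam", "sex", "birth_date", "death_date",
                "lineage", "is_phantom")

    def __init__(self, df: pd.DataFrame, *, ordered: bool = False):
        for c in self.REQUIRED:
            if c not in df.columns:
                raise PedigreeError(f"pedigree frame lacks column {c!r}")
        ids = df["id"].tolist()
        dup = pd.Series(ids).duplicated()
        if dup.any():
            offenders = sorted(set(pd.Series(ids)[dup]))
            raise PedigreeError(f"duplicate animal ids: {offenders}")
        self._df = df.reset_index(drop=True)
        self._idx = {a: i for i, a in enumerate(ids)}
        self.ordered = ordered
        self.sire_idx: np.ndarray | None = None
        self.dam_idx: np.ndarray | None = None
        if ordered:
            self._build_parent_indices()

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, animal) -> bool:
        return animal in self._idx

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def ids(self) -> list:
        return self._df["id"].tolist()

    def index_of(self, animal) -> int:
        try:
            return self._idx[animal]
        except KeyError:
            raise PedigreeError(f"unknown animal id: {animal!r}") from None

    @property
    def founder_ids(self) -> list:
        """Ids with both parents missing (phantom records included)."""
        m = self._df["sire"].isna() & self._df["dam"].isna()
        return self._df.loc[m, "id"].tolist()

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def _build_parent_indices(self) -> None:
        n = len(self._df)
        sire = np.full(n, -1, dtype=np.int64)
        dam = np.full(n, -1, dtype=np.int64)
        for i, (s, d) in enumerate(zip(self._df["sire"], self._df["dam"])):
            if s is not None and not pd.isna(s):
                sire[i] = self._idx[s]
            if d is not None and not pd.isna(d):
                dam[i] = self._idx[d]
        if ((sire >= np.arange(n)) & (sire >= 0)).any() or \
           ((dam >= np.arange(n)) & (dam >= 0)).any():
            raise PedigreeError("pedigree is not in parents-first order")
        self.sire_idx = sire
        self.dam_idx = dam

    def require_ordered(self) -> None:
        if not self.ordered or self.sire_idx is None:
            raise PedigreeError(
                "pedigree must be canonically ordered first "
                "(call validate_and_order)")

    def canonical_equals(self, other: "Pedigree") -> bool:
        """Field-wise equality after canonical ordering of both operands."""
        a = validate_and_order(self).df.sort_values("id").reset_index(drop=True)
        b = validate_and_order(other).df.sort_values("id").reset_index(drop=True)
        return a.equals(b)


# ---------------------------------------------------------------------------
# parsing


def _parse_date(token, warnings_out: list, animal, field_name: str):
    """Calendar date or bare year; year-only maps to 1 July (mid-year)."""
    if token is None:
        return pd.NaT
    tok = str(token).strip()
    if not tok:
        return pd.NaT
    if tok.isdigit() and len(tok) == 4:
        return pd.Timestamp(int(tok), 7, 1)
    try:
        ts = pd.Timestamp(tok)
    except (ValueError, TypeError):
        warnings_out.append({
            "level": "warning", "animal": animal, "field": field_name,
            "message": f"unparseable date {tok!r} treated as missing"})
        return pd.NaT
    return ts


def _parse_sex(token, warnings_out: list, animal):
    if token is None:
        return UNKNOWN
    tok = str(token).strip().lower()
    if not tok:
        return UNKNOWN
    if tok in _SEX_TOKENS:
        return _SEX_TOKENS[tok]
    warnings_out.append({
        "level": "warning", "animal": animal, "field": "sex",
        "message": f"unmappable sex token {token!r} treated as unknown"})
    return UNKNOWN


def parse_pedigree(
    source,
    dialect: Dialect | Mapping | None = None,
    *,
    warnings_out: list | None = None,
) -> Pedigree:
    """Read a delimited pedigree table into an (unordered) :class:`Pedigree`.

    ``source`` is a path or text stream with a header row.  Parents that are
    referenced but have no row of their own are appended as phantom founder
    records (sex inferred from the slot they were referenced in).  Input row
    order is preserved; call :func:`validate_and_order` to canonicalise.

    ``warnings_out``, if given, collects one dict per non-fatal issue
    (unparseable date or sex token), suitable for JSON-lines reporting.
    """
    if dialect is None:
        dialect = Dialect()
    elif not isinstance(dialect, Dialect):
        dialect = Dialect.from_mapping(dialect)
    warns = warnings_out if warnings_out is not None else []

    raw = pd.read_csv(source, sep=dialect.sep, dtype=str,
                      keep_default_na=False, skipinitialspace=True)
    cols = dialect.columns
    for req in ("id", "sire", "dam"):
        if cols.get(req) not in raw.columns:
            raise PedigreeError(
                f"dialect maps {req!r} to column {cols.get(req)!r}, "
                f"not present in header {list(raw.columns)}")

    missing = set(dialect.missing_codes)

    def clean(tok):
        tok = str(tok).strip()
        return None if tok in missing else tok

    records = []
    for _, row in raw.iterrows():
        animal = str(row[cols["id"]]).strip()
        if animal in missing or not animal:
            raise PedigreeError("empty animal id in input row")
        rec = {
            "id": animal,
            "sire": clean(row[cols["sire"]]),
            "dam": clean(row[cols["dam"]]),
            "sex": UNKNOWN,
            "birth_date": pd.NaT,
            "death_date": pd.NaT,
            "lineage": None,
            "is_phantom": False,
        }
        if cols.get("sex") in raw.columns:
            rec["sex"] = _parse_sex(clean(row[cols["sex"]]), warns, animal)
        if cols.get("birth") in raw.columns:
            rec["birth_date"] = _parse_date(
                clean(row[cols["birth"]]), warns, animal, "birth")
        if cols.get("death") in raw.columns:
            rec["death_date"] = _parse_date(
                clean(row[cols["death"]]), warns, animal, "death")
        if cols.get("lineage") in raw.columns:
            rec["lineage"] = clean(row[cols["lineage"]])
        if rec["sire"] == animal or rec["dam"] == animal:
            raise PedigreeError(f"animal {animal!r} is its own parent")
        if (not pd.isna(rec["birth_date"]) and not pd.isna(rec["death_date"])
                and rec["death_date"] < rec["birth_date"]):
            raise PedigreeError(
                f"animal {animal!r} has death date before birth date")
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    dup = df["id"].duplicated()
    if dup.any():
        raise PedigreeError(
            f"duplicate animal ids: {sorted(set(df.loc[dup, 'id']))}")

    df = _insert_phantoms(df)
    return Pedigree(df, ordered=False)


def _insert_phantoms(df: pd.DataFrame) -> pd.DataFrame:
    known = set(df["id"])
    phantoms = []
    seen = set()
    for parent_col, sex in (("sire", MALE), ("dam", FEMALE)):
        for p in df[parent_col]:
            if p is not None and p not in known and p not in seen:
                seen.add(p)
                phantoms.append({
                    "id": p, "sire": None, "dam": None, "sex": sex,
                    "birth_date": pd.NaT, "death_date": pd.NaT,
                    "lineage": None, "is_phantom": True,
                })
    if phantoms:
        df = pd.concat([df, pd.DataFrame.from_records(phantoms)],
                       ignore_index=True)
    return df


def write_pedigree(ped: Pedigree, dest, dialect: Dialect | None = None) -> None:
    """Write a pedigree back to delimited text in the given dialect."""
    if dialect is None:
        dialect = Dialect()
    cols = dialect.columns
    na = dialect.missing_codes[0] if dialect.missing_codes else ""
    out = pd.DataFrame()
    out[cols["id"]] = ped.df["id"]
    out[cols["sire"]] = ped.df["sire"]
    out[cols["dam"]] = ped.df["dam"]
    if "sex" in cols:
        out[cols["sex"]] = ped.df["sex"].map(
            {MALE: "M", FEMALE: "F", UNKNOWN: na})
    if "birth" in cols:
        out[cols["birth"]] = ped.df["birth_date"].dt.strftime("%Y-%m-%d")
    if "death" in cols:
        out[cols["death"]] = ped.df["death_date"].dt.strftime("%Y-%m-%d")
    if "lineage" in cols:
        out[cols["lineage"]] = ped.df["lineage"]
    out.to_csv(dest, sep=dialect.sep, index=False, na_rep=na)


# ---------------------------------------------------------------------------
# validation / ordering


def validate_and_order(
    ped: Pedigree, *, warnings_out: list | None = None
) -> Pedigree:
    """Return the pedigree in canonical (parents-first) order.

    Topological order with input position as tie-break, so the result is a
    deterministic function of the input and the operation is idempotent.
    Structural errors — a cycle, an id used both as sire and as dam, a sex
    contradicting parental use — are raised as :class:`PedigreeError`.
    """
    warns = warnings_out if warnings_out is not None else []
    df = ped.df
    n = len(df)
    idx = {a: i for i, a in enumerate(df["id"])}

    as_sire = {s for s in df["sire"] if s is not None}
    as_dam = {d for d in df["dam"] if d is not None}
    both = as_sire & as_dam
    if both:
        raise PedigreeError(
            f"ids used as both sire and dam: {sorted(both)}")
    for animal, sex in zip(df["id"], df["sex"]):
        if animal in as_sire and sex == FEMALE:
            raise PedigreeError(f"female {animal!r} used as a sire")
        if animal in as_dam and sex == MALE:
            raise PedigreeError(f"male {animal!r} used as a dam")
        if (animal in (as_sire | as_dam)) and sex == UNKNOWN:
            warns.append({
                "level": "warning", "animal": animal, "field": "sex",
                "message": "parent of unknown sex"})

    # Kahn's algorithm; the heap keyed on input position makes ties stable.
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p is not None:
                children[idx[p]].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) < n:
        resolved = set(order)
        cyclic = [df["id"].iloc[i] for i in range(n) if i not in resolved]
        raise PedigreeError(
            f"pedigree contains a cycle through: {_name_one_cycle(df, idx, cyclic)}")

    out = df.iloc[order].reset_index(drop=True)
    return Pedigree(out, ordered=True)


def _name_one_cycle(df: pd.DataFrame, idx: Mapping, cyclic: Sequence) -> list:
    """Walk parent links inside the unresolved set until a repeat closes a cycle."""
    in_cycle = set(cyclic)
    start = cyclic[0]
    path, seen = [start], {start}
    cur = start
    while True:
        row = df.iloc[idx[cur]]
        nxt = next((p for p in (row["sire"], row["dam"])
                    if p is not None and p in in_cycle), None)
        if nxt is None:
            return path
        if nxt in seen:
            return path[path.index(nxt):]
        path.append(nxt)
        seen.add(nxt)
        cur = nxt


# ---------------------------------------------------------------------------
# reference population


def select_reference(
    ped: Pedigree,
    as_of: date | str | None = None,
    mode: str = "birth-death-window",
    *,
    id_list: Iterable | None = None,
    status_column: str | None = None,
) -> ReferenceSet:
    """Define the reference population (potential parents of future generations).

    Modes
    -----
    ``birth-death-window``
        Alive at ``as_of``: born on or before it and (no recorded death or
        death after it).  Animals without a birth date are excluded.
    ``id-list``
        Exactly the given ids; unknown ids are an error.
    ``status-column``
        Rows where the named extra column of ``ped.df`` is truthy.
    """
    if mode == "id-list":
        if id_list is None:
            raise PedigreeError("id-list mode requires id_list")
        wanted = list(id_list)
        absent = [a for a in wanted if a not in ped]
        if absent:
            raise PedigreeError(f"reference ids not in pedigree: {absent}")
        return ReferenceSet(frozenset(wanted), _coerce_date(as_of))
    if mode == "status-column":
        if status_column is None or status_column not in ped.df.columns:
            raise PedigreeError("status-column mode requires an existing column")
        ids = ped.df.loc[ped.df[status_column].astype(bool), "id"]
        return ReferenceSet(frozenset(ids), _coerce_date(as_of))
    if mode == "birth-death-window":
        ts = pd.Timestamp(_coerce_date(as_of))
        born = ped.df["birth_date"].notna() & (ped.df["birth_date"] <= ts)
        alive = ped.df["death_date"].isna() | (ped.df["death_date"] > ts)
        ids = ped.df.loc[born & alive, "id"]
        return ReferenceSet(frozenset(ids), ts.date())
    raise PedigreeError(f"unknown reference mode {mode!r}")


def _coerce_date(as_of) -> date | None:
    if as_of is None:
        return None
    if isinstance(as_of, date):
        return as_of
    return pd.Timestamp(as_of).date()


def validation_report_json(warnings: list) -> str:
    """Render collected warnings/errors as JSON lines."""
    return "\n".join(json.dumps(w) for w in warnings)


def complete_parents(ped: Pedigree) -> Pedigree:
    """Fill every single missing parental side with a phantom founder.

    Gene-origin bookkeeping needs each gene lineage to terminate in an
    identifiable founder record; an animal with one recorded parent has its
    unknown side materialised as a phantom (named ``~U<n>``), mirroring how
    studbook software treats unknown ancestors as additional founders.
    Pedigrees without half-known parentage are returned unchanged.  All
    relationship and inbreeding values among the original animals are
    unaffected (a phantom founder is unrelated to everything).
    """
    df = ped.df
    half = pd.Series(
        [bool(pd.isna(s)) != bool(pd.isna(d))
         for s, d in zip(df["sire"], df["dam"])],
        index=df.index)
    if not half.any():
        return ped if ped.ordered else validate_and_order(ped)
    df = df.copy()
    phantoms = []
    counter = 0
    existing = set(df["id"])
    for i in df.index[half]:
        counter += 1
        pid = f"~U{counter}"
        while pid in existing:
            counter += 1
            pid = f"~U{counter}"
        existing.add(pid)
        if pd.isna(df.at[i, "sire"]):
            df.at[i, "sire"] = pid
            sex = MALE
        else:
            df.at[i, "dam"] = pid
            sex = FEMALE
        phantoms.append({
            "id": pid, "sire": None, "dam": None, "sex": sex,
            "birth_date": pd.NaT, "death_date": pd.NaT,
            "lineage": None, "is_phantom": True,
        })
    df = pd.concat([df, pd.DataFrame.from_records(phantoms)],
                   ignore_index=True)
    return validate_and_order(Pedigree(df))


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Build an ordered pedigree from a minimal frame (id/sire/dam[/...]).

    Convenience for programmatic construction: missing optional columns are
    filled with defaults, phantoms inserted, and the result canonically
    ordered.
    """
    df = df.copy()
    df["id"] = df["id"].astype(str)
    for col in ("sire", "dam"):
        df[col] = [None if pd.isna(v) or str(v).strip() in ("", "0", "NA")
                   else str(v) for v in df.get(col, [None] * len(df))]
    if "sex" not in df.columns:
        df["sex"] = UNKNOWN
    else:
        df["sex"] = [
            _SEX_TOKENS.get(str(v).strip().lower(), UNKNOWN)
            if not pd.isna(v) else UNKNOWN
            for v in df["sex"]
        ]
    for col in ("birth_date", "death_date"):
        if col not in df.columns:
            df[col] = pd.NaT
        df[col] = pd.to_datetime(df[col])
    if "lineage" not in df.columns:
        df["lineage"] = None
    if "is_phantom" not in df.columns:
        df["is_phantom"] = False
    df = _insert_phantoms(df[list(Pedigree.REQUIRED)])
    return validate_and_order(Pedigree(df))
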