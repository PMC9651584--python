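import io

import numpy as np
import pandas as pd
import pytest

import pedsight as ps
from pedsight.pedigree_io import Dialect, PedigreeError


def parse(text, **kw):
    return ps.parse_pedigree(io.StringIO(text), **kw)


class TestParse:
    def test_minimal_trio(self, trio_csv):
        ped = ps.validate_and_order(ps.parse_pedigree(trio_csv))
        assert set(ped.founder_ids) == {"A", "B"}
        assert len(ped) == 3
        assert ped.df["sex"].tolist()[:2] == ["male", "female"]

    def test_missing_codes_and_year_dates(self, trio_csv):
        ped = ps.validate_and_order(ps.parse_pedigree(trio_csv))
        b = ped.df.set_index("id")["birth_date"]
        # year-only dates land mid-year; full dates are kept exactly
        assert b["A"] == pd.Timestamp(1990, 7, 1)
        assert b["X"] == pd.Timestamp(1999, 5, 20)

    def test_undefined_parent_becomes_phantom(self):
        ped = parse("id,sire,dam\nX,S9,\n")
        ped = ps.validate_and_order(ped)
        row = ped.df.set_index("id").loc["S9"]
        assert bool(row["is_phantom"])
        assert row["sire"] is None and row["dam"] is None
        # phantom insertion leaves the real record untouched
        assert ped.df.set_index("id").loc["X", "sire"] == "S9"

    def test_parse_is_row_order_insensitive(self):
        child_first = parse("id,sire,dam\nX,A,B\nA,,\nB,,\n")
        parent_first = parse("id,sire,dam\nA,,\nB,,\nX,A,B\n")
        assert child_first.canonical_equals(parent_first)

    def test_duplicate_id_is_hard_error(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            parse("id,sire,dam\nA,,\nA,,\n")

    def test_self_parent_rejected(self):
        with pytest.raises(PedigreeError, match="own parent"):
            parse("id,sire,dam\nA,A,\n")

    def test_bad_sex_token_warns_to_missing(self):
        warns = []
        ped = parse("id,sire,dam,sex\nA,,,xx\n", warnings_out=warns)
        assert ped.df["sex"].iloc[0] == "unknown"
        assert any(w["field"] == "sex" for w in warns)

    def test_round_trip(self, trio_csv):
        ped = ps.validate_and_order(ps.parse_pedigree(trio_csv))
        buf = io.StringIO()
        ps.write_pedigree(ped, buf)
        buf.seek(0)
        again = ps.parse_pedigree(buf)
        assert ped.canonical_equals(again)

    def test_custom_dialect(self):
        d = Dialect(columns={"id": "animal", "sire": "father", "dam": "mother"},
                    sep=";", missing_codes=("-",))
        ped = parse("animal;father;mother\nA;-;-\nX;A;-\n", dialect=d)
        assert "A" in ped and "X" in ped


class TestValidateAndOrder:
    def test_parents_precede_offspring(self):
        ped, _ = ps.simulate_pedigree(
            ps.SimConfig(seed=3, n_founders=10, n_generations=10,
                         max_cohort=120))
        idx = np.arange(len(ped))
        assert (ped.sire_idx < idx)[ped.sire_idx >= 0].all()
        assert (ped.dam_idx < idx)[ped.dam_idx >= 0].all()

    def test_idempotent(self, trio):
        again = ps.validate_and_order(trio)
        assert again.df.equals(trio.df)

    def test_cycle_detected(self):
        ped = parse("id,sire,dam\nX,Y,\nY,X,\n")
        with pytest.raises(PedigreeError, match="cycle"):
            ps.validate_and_order(ped)

    def test_sire_and_dam_conflict(self):
        ped = parse("id,sire,dam\nC,,\nX,C,\nY,,C\n")
        with pytest.raises(PedigreeError, match="both sire and dam"):
            ps.validate_and_order(ped)

    def test_female_sire_rejected(self):
        ped = parse("id,sire,dam,sex\nA,,,F\nX,A,,F\n")
        with pytest.raises(PedigreeError, match="used as a sire"):
            ps.validate_and_order(ped)


class TestReference:
    def test_window_mode(self, trio_csv):
        ped = ps.validate_and_order(ps.parse_pedigree(trio_csv))
        ref = ps.select_reference(ped, "2020-12-31")
        assert ref.ids == frozenset({"B", "X"})  # A died in 2010
        ref2 = ps.select_reference(ped, "2005-06-30")
        assert ref2.ids == frozenset({"A", "B", "X"})

    def test_id_list_mode(self, study_sim):
        ped, _ = study_sim
        wanted = ped.ids[-50:]
        ref = ps.select_reference(ped, None, "id-list", id_list=wanted)
        assert ref.ids == frozenset(wanted)

    def test_id_list_unknown_ids_error(self, trio):
        with pytest.raises(PedigreeError, match="not in pedigree"):
            ps.select_reference(trio, None, "id-list", id_list=["A", "ZZ"])


class TestCompleteParents:
    def test_half_known_gets_phantom(self):
        ped = parse("id,sire,dam\nA,,\nX,A,\n")
        ped = ps.validate_and_order(ped)
        full = ps.complete_parents(ped)
        assert len(full) == 3
        x = full.df.set_index("id").loc["X"]
        assert x["dam"].startswith("~U")
        assert bool(full.df.set_index("id").loc[x["dam"], "is_phantom"])

    def test_no_op_on_complete_pedigree(self, trio):
        assert ps.complete_parents(trio) is trio
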