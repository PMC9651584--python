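import io

import pandas as pd
import pytest

import pedsight as ps


@pytest.fixture
def trio() -> ps.Pedigree:
    """Founders A (sire) and B (dam) with one offspring X."""
    return ps.pedigree_from_frame(pd.DataFrame({
        "id": ["X", "A", "B"],
        "sire": ["A", None, None],
        "dam": ["B", None, None],
        "sex": ["F", "M", "F"],
    }))


@pytest.fixture
def fullsib_offspring() -> ps.Pedigree:
    """Founders A,B; full sibs C,D; E = C x D (F_E = 1/4)."""
    return ps.pedigree_from_frame(pd.DataFrame({
        "id": ["A", "B", "C", "D", "E"],
        "sire": [None, None, "A", "A", "C"],
        "dam": [None, None, "B", "B", "D"],
        "sex": ["M", "F", "M", "F", "F"],
    }))


@pytest.fixture
def looped_chain() -> ps.Pedigree:
    """A x B -> C; A x C -> D; D x C -> E: F_E = 3/8 with old exposure."""
    return ps.pedigree_from_frame(pd.DataFrame({
        "id": ["A", "B", "C", "D", "E"],
        "sire": [None, None, "A", "A", "D"],
        "dam": [None, None, "B", "C", "C"],
        "sex": ["M", "F", "F", "M", "F"],
    }))


@pytest.fixture
def trio_csv() -> io.StringIO:
    return io.StringIO(
        "id,sire,dam,sex,birth,death,lineage\n"
        "A,,,M,1990,2010,L1\n"
        "B,0,0,F,1991,,L1\n"
        "X,A,B,F,1999-05-20,,L1\n")


@pytest.fixture(scope="session")
def study_sim():
    """One study-scale simulated pedigree shared across the session."""
    cfg = ps.SimConfig(seed=11, missing_parent_rate=0.03,
                       missing_sex_rate=0.01)
    return ps.simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """A quick, fully recorded simulation with truth."""
    cfg = ps.SimConfig(seed=5, n_founders=8, n_generations=8, max_cohort=80)
    return ps.simulate_pedigree(cfg)
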