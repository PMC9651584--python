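import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pedsight as ps
from pedsight.completeness import _all_generation_metrics
from pedsight.inbreeding import delta_F_all


def build(rows):
    return ps.pedigree_from_frame(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))


class TestMeuwissenLuo:
    def test_outbred_offspring(self, trio):
        F = ps.inbreeding_meuwissen_luo(trio)
        assert np.allclose(F, 0.0)

    def test_classic_matings(self, fullsib_offspring):
        F = ps.inbreeding_meuwissen_luo(fullsib_offspring)
        assert F[fullsib_offspring.index_of("E")] == pytest.approx(0.25)

        parent_offspring = build([
            ("A", None, None, "M"), ("B", None, None, "F"),
            ("C", "A", "B", "F"), ("X", "A", "C", "F")])
        F = ps.inbreeding_meuwissen_luo(parent_offspring)
        assert F[parent_offspring.index_of("X")] == pytest.approx(0.25)

        half_sibs = build([
            ("A", None, None, "M"), ("B", None, None, "F"),
            ("C", None, None, "F"), ("S", "A", "B", "M"),
            ("D", "A", "C", "F"), ("X", "S", "D", "F")])
        F = ps.inbreeding_meuwissen_luo(half_sibs)
        assert F[half_sibs.index_of("X")] == pytest.approx(0.125)

    def test_unknown_parent_means_zero(self):
        ped = build([("A", None, None, "M"), ("X", "A", None, "F")])
        assert ps.inbreeding_meuwissen_luo(ped)[ped.index_of("X")] == 0.0

    def test_fullsib_chain_recurrence_exact(self):
        depth = 20
        ped = ps.fullsib_chain_fixture(depth)
        F = ps.inbreeding_meuwissen_luo(ped)
        expect = ps.fullsib_chain_F(depth)
        got = [F[ped.index_of(f"S{t}a")] for t in range(1, depth + 1)]
        assert got == expect  # dyadic rationals: equality to the bit

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_tabular_method(self, seed):
        n = 10 + 5 * seed
        ped = ps.random_pedigree(n, seed, missing_rate=0.1)
        F = ps.inbreeding_meuwissen_luo(ped)
        A = ps.tabular_relationship_matrix(ped)
        assert np.max(np.abs(F - (np.diag(A) - 1.0))) < 1e-12

    def test_requires_ordered_pedigree(self, trio_csv):
        raw = ps.parse_pedigree(trio_csv)
        with pytest.raises(ps.PedigreeError, match="ordered"):
            ps.inbreeding_meuwissen_luo(raw)


class TestKinshipSubmatrix:
    def test_trio_block(self, trio):
        K = ps.kinship_submatrix(trio, ["A", "B", "X"])
        assert K.loc["A", "X"] == 0.5
        assert K.loc["B", "X"] == 0.5
        assert K.loc["A", "B"] == 0.0
        assert np.allclose(np.diag(K), 1.0)

    def test_fullsib_pair(self, fullsib_offspring):
        K = ps.kinship_submatrix(fullsib_offspring, ["C", "D"])
        assert K.loc["C", "D"] == pytest.approx(0.5)

    def test_coancestry_view(self, trio):
        f = ps.kinship_submatrix(trio, ["A", "X"], coancestry=True)
        assert f.loc["A", "X"] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_symmetric_positive_semidefinite(self, seed):
        ped = ps.random_pedigree(80, seed)
        rng = np.random.default_rng(seed)
        ids = list(rng.choice(ped.ids, size=15, replace=False))
        K = ps.kinship_submatrix(ped, ids).to_numpy()
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_closure_cap(self, study_sim):
        ped, _ = study_sim
        with pytest.raises(ps.PedigreeError, match="matrix-free"):
            ps.kinship_submatrix(ped, ped.ids[-5:], max_closure=10)


class TestAverageRelatedness:
    def test_trio_values(self, trio):
        ar = ps.average_relatedness(trio)
        by_id = dict(zip(trio.ids, ar))
        assert by_id["A"] == pytest.approx(0.5)
        assert by_id["B"] == pytest.approx(0.5)
        assert by_id["X"] == pytest.approx(2 / 3)

    def test_isolated_founder(self):
        ped = build([("A", None, None, "M"), ("B", None, None, "F"),
                     ("X", "A", "B", "F"), ("Z", None, None, "F")])
        ar = ps.average_relatedness(ped)
        assert ar[ped.index_of("Z")] == pytest.approx(1 / 4)

    @pytest.mark.parametrize("n,seed", [(300, 0), (800, 1)])
    def test_matrix_free_equals_explicit(self, n, seed):
        ped = ps.random_pedigree(n, seed, founder_fraction=0.1)
        ar = ps.average_relatedness(ped)
        A = ps.tabular_relationship_matrix(ped)
        assert np.max(np.abs(ar - A.mean(axis=1))) < 1e-10

    def test_mean_coancestry_matches_explicit(self, fullsib_offspring):
        ids = ["C", "D", "E"]
        f = ps.kinship_submatrix(fullsib_offspring, ids, coancestry=True)
        assert ps.mean_coancestry(fullsib_offspring, ids) == \
            pytest.approx(f.to_numpy().mean())


class TestDeltaF:
    def test_zero_F(self):
        assert ps.individual_delta_F(0.0, 5.0) == 0.0

    def test_unit_exponent(self):
        assert ps.individual_delta_F(0.25, 2.0) == pytest.approx(0.25)

    def test_direct_evaluation(self):
        assert ps.individual_delta_F(0.25, 3.0) == \
            pytest.approx(1 - 0.75 ** 0.5)

    def test_undefined_below_one_generation(self):
        assert np.isnan(ps.individual_delta_F(0.2, 1.0))

    def test_invalid_F(self):
        with pytest.raises(ValueError):
            ps.individual_delta_F(1.0, 3.0)

    @given(F=st.floats(0, 0.999), t=st.floats(1.001, 40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_range_property(self, F, t):
        dF = ps.individual_delta_F(F, t)
        # strict upper bound holds mathematically; 1 - (1-F)^(1/(t-1)) can
        # round to 1.0 in floats for extreme (F, t)
        assert 0.0 <= dF <= 1.0


class TestNe:
    def test_delta_F_method_scale(self):
        est = ps.ne_from_delta_F(np.full(10, 0.01))
        assert est.ne == pytest.approx(50.0)
        assert est.mean_delta_F == pytest.approx(0.01)

    def test_regression_method_scale(self):
        x = np.arange(10.0)
        F = 0.005 * x  # exact slope b = 0.005
        est = ps.ne_regression(F, x)
        assert est.ne == pytest.approx(100.0)

    def test_negative_slope_is_undefined(self):
        est = ps.ne_regression(np.linspace(0.5, 0.0, 8), np.arange(8.0))
        assert not est.defined

    def test_constant_population_calibration(self):
        # one quick replicate; the multi-replicate calibration runs in the
        # acceptance suite
        ped = ps.discrete_generations_pedigree(50, 20, seed=77)
        F = ps.inbreeding_meuwissen_luo(ped)
        cge = _all_generation_metrics(ped)[2]
        mask = np.array([str(a).startswith("G20") for a in ped.ids])
        est = ps.ne_from_delta_F(delta_F_all(F[mask], cge[mask]))
        assert 30 < est.ne < 75
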