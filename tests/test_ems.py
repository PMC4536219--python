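import numpy as np
import pandas as pd
import pytest

from conftest import random_incidence
from riverems.ems import (
    STRUCTURE_LABELS,
    ClumpingResult,
    EMSTestResult,
    MetacommunityStructure,
    boundary_counts,
    classify_structure,
    count_embedded_absences,
    count_replacements,
    enumerate_structure_labels,
    evaluate_axis,
    fill_ranges,
    morisita_clumping,
    z_test,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def gaps_oracle(A):
    """Exhaustive scan: zeros strictly between first and last 1 of every
    column and every row."""
    total = 0
    for M in (A, A.T):
        for col in M.T:
            ones = np.flatnonzero(col)
            if ones.size:
                total += int((col[ones[0] : ones[-1] + 1] == 0).sum())
    return total


def replacements_oracle(A):
    """Quadruple loop over (site, site, taxon, taxon) pairs."""
    S, T = A.shape
    total = 0
    for i in range(T):
        for j in range(i + 1, T):
            n_i_only = sum(A[s, i] == 1 and A[s, j] == 0 for s in range(S))
            n_j_only = sum(A[s, j] == 1 and A[s, i] == 0 for s in range(S))
            total += n_i_only * n_j_only
    return total


def boundary_oracle(A):
    counts = np.zeros(A.shape[0], dtype=int)
    for col in A.T:
        ones = np.flatnonzero(col)
        if ones.size:
            counts[ones[0]] += 1
            counts[ones[-1]] += 1
    return counts


class TestEmbeddedAbsences:
    def test_single_gap_column(self):
        A = np.array([[1], [0], [1]])
        assert count_embedded_absences(A, mode="columns") == 1

    def test_banded_matrix_has_none(self, banded_incidence):
        assert count_embedded_absences(banded_incidence) == 0

    def test_all_ones_has_none(self):
        assert count_embedded_absences(np.ones((4, 5), int)) == 0

    def test_matches_scan_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            A = (rng.random((10, 8)) < rng.uniform(0.2, 0.7)).astype(int)
            assert count_embedded_absences(A, mode="both") == gaps_oracle(A)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            count_embedded_absences(np.empty((0, 0), int))


class TestFillRanges:
    def test_gap_filled(self):
        A = np.array([[1], [0], [1]])
        assert fill_ranges(A).ravel().tolist() == [1, 1, 1]

    def test_coherent_matrix_unchanged(self, banded_incidence):
        out = fill_ranges(banded_incidence)
        assert (out.to_numpy() == banded_incidence.to_numpy()).all()

    def test_idempotent_and_column_gap_free(self, rng):
        for _ in range(20):
            A = (rng.random((8, 6)) < 0.4).astype(int)
            f = fill_ranges(A)
            assert (fill_ranges(f) == f).all()
            assert count_embedded_absences(f, mode="columns") == 0
            assert ((f - A) >= 0).all()  # presences never removed


class TestReplacements:
    def test_nested_matrix_zero(self):
        A = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert count_replacements(A) == 0

    def test_two_by_two_checkerboard(self):
        A = np.array([[1, 0], [0, 1]])
        assert count_replacements(A) == 1

    def test_matches_quadruple_loop_oracle(self, rng):
        for _ in range(30):
            A = (rng.random((8, 6)) < 0.45).astype(int)
            assert count_replacements(A) == replacements_oracle(A)


class TestBoundaryCounts:
    def test_single_spanning_taxon(self):
        A = np.ones((5, 1), int)
        assert boundary_counts(A).tolist() == [1, 0, 0, 0, 1]

    def test_identical_ranges_concentrate(self):
        A = np.zeros((6, 4), int)
        A[1:4, :] = 1
        counts = boundary_counts(A)
        assert counts[1] == 4 and counts[3] == 4 and counts.sum() == 8

    def test_matches_index_scan_oracle(self, rng):
        for _ in range(30):
            A = (rng.random((9, 7)) < 0.4).astype(int)
            assert (boundary_counts(A) == boundary_oracle(A)).all()


class TestMorisita:
    def test_maximal_clumping_equals_T(self):
        counts = np.array([6, 0, 0])
        assert morisita_clumping(counts).morisita == pytest.approx(3.0)

    def test_one_boundary_per_position_is_zero(self):
        counts = np.ones(5, dtype=int)
        assert morisita_clumping(counts).morisita == 0.0

    def test_matches_formula_and_pearson_oracle(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 6, size=8)
            if counts.sum() < 2:
                continue
            res = morisita_clumping(counts)
            N, T = counts.sum(), len(counts)
            mi = T * (counts * (counts - 1)).sum() / (N * (N - 1))
            chi = ((counts - N / T) ** 2 / (N / T)).sum()
            assert res.morisita == pytest.approx(mi)
            assert res.chi2 == pytest.approx(chi)
            assert res.df == T - 1
            assert 0 <= res.p <= 1

    def test_too_few_boundaries_rejected(self):
        with pytest.raises(ValueError):
            morisita_clumping(np.array([1, 0, 0]))


class TestZTest:
    @pytest.mark.parametrize(
        "obs,mean,sd,expected_z",
        [
            (24774, 29843.7, 769.4, 6.59),
            (247479, 153040.5, 54087.9, -1.75),
        ],
    )
    def test_sign_convention(self, obs, mean, sd, expected_z):
        res = z_test(obs, null_mean=mean, null_sd=sd)
        assert res.z == pytest.approx(expected_z, abs=0.01)

    def test_observed_at_mean_gives_p_one(self):
        res = z_test(10.0, null_mean=10.0, null_sd=2.0)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_from_raw_null_values(self, rng):
        nulls = rng.normal(50, 5, size=200)
        res = z_test(40.0, nulls)
        assert res.z == pytest.approx((nulls.mean() - 40) / nulls.std(ddof=1))

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            z_test(1.0, null_mean=1.0, null_sd=0.0)


def _res(z, p):
    return EMSTestResult("stat", 0.0, 0.0, 1.0, z=z, p=p)


def _clump(mi, p):
    return ClumpingResult(morisita=mi, chi2=0.0, df=10, p=p)


class TestClassifyStructure:
    def test_nonsignificant_coherence_is_random(self):
        label = classify_structure(_res(1.5, 0.2), _res(-9, 1e-6), _clump(5, 1e-6))
        assert label == "Random"

    def test_negative_coherence_is_checkerboard(self):
        assert classify_structure(_res(-3, 1e-3), None, None) == "Checkerboard"

    def test_nested_clumped_species_loss(self):
        label = classify_structure(_res(4, 1e-4), _res(3, 1e-3), _clump(4, 1e-3))
        assert label == "Nested - clumped species loss"

    def test_quasi_family_from_deviation_direction(self):
        # non-significant turnover, observed above the null mean (z < 0)
        label = classify_structure(_res(4, 1e-4), _res(-0.7, 0.48), _clump(1.5, 0.004))
        assert label == "Quasi-Clementsian"
        # non-significant turnover, observed below the null mean
        label = classify_structure(_res(4, 1e-4), _res(0.7, 0.48), _clump(1.5, 0.004))
        assert label == "Quasi-nested - clumped species loss"

    def test_exhaustive_enumeration_yields_14_labels(self):
        labels = enumerate_structure_labels()
        assert labels == set(STRUCTURE_LABELS)
        assert len(labels) == 14


class TestEvaluateAxis:
    def test_banded_matrix_coherent(self, banded_incidence):
        cls = evaluate_axis(banded_incidence, axis=1, n_sim=100, seed=0)
        assert cls.coherence.z > 0
        assert cls.label not in ("Checkerboard",)

    def test_reversal_invariance_of_counts(self, rng):
        """Reversing site and taxon order cannot change Abs or Re."""
        A = random_incidence(rng, 10, 8)
        assert count_embedded_absences(A) == count_embedded_absences(A[::-1, ::-1])
        fa = fill_ranges(A)
        assert count_replacements(fa) == count_replacements(fa[::-1, ::-1])

    def test_deterministic_under_seed(self, rng):
        A = random_incidence(rng, 12, 10)
        c1 = evaluate_axis(A, axis=1, n_sim=60, seed=5)
        c2 = evaluate_axis(A, axis=1, n_sim=60, seed=5)
        assert c1.label == c2.label
        assert c1.coherence.z == c2.coherence.z
        assert c1.turnover.null_mean == c2.turnover.null_mean

    def test_estimator_attributes_and_summary(self, rng):
        A = random_incidence(rng, 12, 10)
        est = MetacommunityStructure(axis=1, n_sim=60, random_state=1).fit(A)
        row = est.summary_row()
        assert set(row) >= {"Abs", "Abs_z", "Re", "Re_z", "MI", "MI_p", "structure"}
        assert est.label_ in STRUCTURE_LABELS
        assert est.n_nulls_used_ >= 2

    def test_nulls_scored_on_empirical_order_switch(self, rng):
        A = random_incidence(rng, 10, 8)
        est = MetacommunityStructure(
            axis=1, n_sim=40, reordinate_nulls=False, random_state=2
        ).fit(A)
        assert est.label_ in STRUCTURE_LABELS
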