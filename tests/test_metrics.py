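import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoturnover import (
    AbundanceMatrix,
    berger_parker_dominance,
    bray_curtis,
    diversity_series,
    hill_n0,
    hill_n1,
    hill_n2,
    hill_ninf,
    mean_rank_shift,
    turnover_series,
)

abundance_vectors = st.lists(
    st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=12
).filter(lambda v: sum(v) > 0)


def brute_force_mrs(x, y):
    """Independent oracle: explicit rank assignment by enumeration.

    Ranks each pooled species by counting strictly-more-abundant species
    and averaging over its tied block, then averages absolute shifts.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pool = [i for i in range(len(x)) if x[i] > 0 or y[i] > 0]

    def rank(v, i):
        higher = sum(1 for j in pool if v[j] > v[i])
        tied = sum(1 for j in pool if v[j] == v[i])
        return higher + (1 + tied) / 2

    return float(np.mean([abs(rank(y, i) - rank(x, i)) for i in pool]))


class TestHillNumbers:
    @pytest.mark.parametrize(
        "fn,vec,expected",
        [
            (hill_n0, [10, 10, 10, 10], 4),
            (hill_n0, [1, 0, 0], 1),
            (hill_n0, [4, 2, 1, 1, 0], 4),
            (hill_n1, [10, 10, 10, 10], 4.0),
            (hill_n1, [1, 0, 0], 1.0),
            (hill_n1, [4, 2, 1, 1], 2**1.75),  # exp(1.75 ln 2) from p=(1/2,1/4,1/8,1/8)
            (hill_n2, [10, 10, 10, 10], 4.0),
            (hill_n2, [1, 0, 0], 1.0),
            (hill_n2, [4, 2, 1, 1], 1 / 0.34375),
            (hill_ninf, [50, 25, 25], 2.0),
            (hill_ninf, [7], 1.0),
            (hill_ninf, [10, 10, 10, 10], 4.0),
        ],
    )
    def test_reference_values(self, fn, vec, expected):
        assert fn(vec) == pytest.approx(expected)

    def test_all_zero_vector_is_an_error(self):
        for fn in (hill_n0, hill_n1, hill_n2, hill_ninf):
            with pytest.raises(ValueError):
                fn([0.0, 0.0])

    def test_dominance_is_reciprocal_of_ninf(self):
        v = [40, 30, 20, 10]
        assert berger_parker_dominance(v) == pytest.approx(1 / hill_ninf(v))

    @given(vec=abundance_vectors)
    @settings(max_examples=200, deadline=None)
    def test_hill_ordering_property(self, vec):
        n0, n1, n2, ninf = hill_n0(vec), hill_n1(vec), hill_n2(vec), hill_ninf(vec)
        eps = 1e-9 * max(1.0, n0)
        assert n0 + eps >= n1 >= n2 - eps and n2 + eps >= ninf

    @given(vec=abundance_vectors, c=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, vec, c):
        scaled = [c * v for v in vec]
        assert hill_n1(scaled) == pytest.approx(hill_n1(vec), rel=1e-9)
        assert hill_n2(scaled) == pytest.approx(hill_n2(vec), rel=1e-9)
        assert hill_ninf(scaled) == pytest.approx(hill_ninf(vec), rel=1e-9)


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([5, 1, 2], [5, 1, 2], 0.0),
            ([3, 0], [0, 7], 1.0),
            ([1, 2, 0], [0, 2, 4], 5 / 9),
        ],
    )
    def test_reference_values(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_both_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @given(x=abundance_vectors, y=abundance_vectors)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_bounds(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert 0 <= d <= 1
        assert d == pytest.approx(bray_curtis(y, x))


class TestMeanRankShift:
    def test_identical_years_have_zero_shift(self):
        assert mean_rank_shift([9, 5, 2, 1], [9, 5, 2, 1]) == 0.0

    def test_top_two_swap(self):
        # 4 distinct species, top two swap, bottom two fixed
        assert mean_rank_shift([10, 8, 3, 1], [8, 10, 3, 1]) == pytest.approx(0.5)

    def test_absence_ranked_last(self):
        # x ranks (1,2,3); y ranks (1,3,2) with absent species at the bottom
        assert mean_rank_shift([5, 3, 0], [5, 0, 3]) == pytest.approx(2 / 3)

    def test_intersection_pool_option(self):
        # only the species present in both years are ranked
        assert mean_rank_shift([5, 3, 0], [5, 0, 3], species_pool="intersection") == 0.0

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            mean_rank_shift([0, 0], [0, 0])

    @given(
        x=st.lists(st.integers(0, 8), min_size=1, max_size=6),
        y=st.lists(st.integers(0, 8), min_size=1, max_size=6),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle_with_ties_and_absences(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        assert mean_rank_shift(x, y) == pytest.approx(brute_force_mrs(x, y))

    @given(x=abundance_vectors, y=abundance_vectors, seed=st.integers(0, 2**16))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_permutation_invariance(self, x, y, seed):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if x.sum() + y.sum() == 0:
            return
        d = mean_rank_shift(x, y)
        assert d == pytest.approx(mean_rank_shift(y, x))
        perm = np.random.default_rng(seed).permutation(n)
        assert d == pytest.approx(mean_rank_shift(x[perm], y[perm]))
        u = ((x > 0) | (y > 0)).sum()
        assert 0 <= d <= u / 2 + 1e-12


class TestSeries:
    def test_constant_matrix_constant_profiles(self):
        m = AbundanceMatrix(["a", "b"], [1, 2, 3], [[4.0, 4, 4], [1.0, 1, 1]])
        for name in ("N0", "N1", "N2", "Ninf"):
            prof = diversity_series(m, name)
            assert np.allclose(prof.values, prof.values[0])
        for name in ("MRS", "BrayCurtis"):
            assert np.allclose(turnover_series(m, name).values, 0.0)

    def test_series_match_scalar_ops(self, small_matrix):
        prof = diversity_series(small_matrix, "N1")
        assert prof.values[0] == pytest.approx(hill_n1(small_matrix.values[:, 0]))
        turn = turnover_series(small_matrix, "BrayCurtis")
        assert len(turn.values) == small_matrix.n_years - 1
        assert turn.values[0] == pytest.approx(
            bray_curtis(small_matrix.values[:, 0], small_matrix.values[:, 1])
        )

    def test_all_zero_year_error_names_the_year(self):
        m = AbundanceMatrix(["a", "b"], [1, 2, 3], [[1.0, 0, 1], [2.0, 0, 2]])
        with pytest.raises(ValueError, match="2"):
            diversity_series(m, "N1")

    def test_synthetic_series_lengths(self, default_synthetic):
        m, _ = default_synthetic
        assert len(diversity_series(m, "N2").values) == 30
        assert len(turnover_series(m, "MRS").values) == 29
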