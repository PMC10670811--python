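"""Unit and property tests for the single-scale entropy measures."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from mcrde.entropy import (
    DegenerateSeriesError,
    DispersionConfig,
    PatternDistribution,
    SeriesTooShortError,
    crde,
    crde_of_series,
    cumulative_residual_entropy_sample,
    de_of_series,
    dispersion_entropy,
    extract_patterns,
    map_to_classes,
    ncdf_map,
    pattern_distribution,
)

CFG22 = DispersionConfig(m=2, c=3, d=1)


class TestNcdfMap:
    def test_worked_example_values(self, printed_series):
        y = ncdf_map(printed_series)
        assert y[3] == pytest.approx(0.34075, abs=5e-5)
        assert y[8] == pytest.approx(0.97701, abs=5e-5)
        assert np.all((y > 0) & (y < 1))

    def test_symmetric_pair_maps_to_phi_of_unit_deviates(self):
        y = ncdf_map([-3.0, 3.0])
        # sample sd of {-t, t} is t*sqrt(2), so the standardized pair is
        # (-1/sqrt(2), 1/sqrt(2)) and the NCDF values are symmetric about 1/2
        assert y[0] + y[1] == pytest.approx(1.0, abs=1e-15)
        assert y[1] == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=1e-15)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            ncdf_map([5.0, 5.0, 5.0])

    def test_single_sample_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            ncdf_map([1.0])

    def test_preserves_order_and_ties(self):
        x = np.array([3.0, 1.0, 3.0, 2.0, -1.0])
        y = ncdf_map(x)
        assert y[0] == y[2]
        assert np.array_equal(np.argsort(y, kind="stable"), np.argsort(x, kind="stable"))


class TestMapToClasses:
    def test_worked_example_class_series(self, printed_series):
        z = map_to_classes(ncdf_map(printed_series), 3)
        assert z.tolist() == [1, 1, 2, 2, 2, 3, 2, 2, 3, 1]

    @pytest.mark.parametrize(
        "y, c, expected",
        [
            ([0.01, 0.5, 0.99], 3, [1, 2, 3]),
            ([1 - 1e-12], 3, [3]),  # clamp at the upper boundary
            ([1e-12], 3, [1]),
        ],
    )
    def test_boundary_arithmetic(self, y, c, expected):
        assert map_to_classes(np.array(y), c).tolist() == expected

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValueError):
            map_to_classes(np.array([0.5, 1.0]), 3)

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1 - 1e-9), min_size=2, max_size=30),
        st.integers(min_value=2, max_value=9),
    )
    def test_monotone_in_y(self, ys, c):
        y = np.array(ys)
        labels = map_to_classes(y, c)
        order = np.argsort(y)
        assert np.all(np.diff(labels[order]) >= 0)
        assert np.all((labels >= 1) & (labels <= c))


class TestExtractPatterns:
    def test_worked_example_pattern_sequence(self, table1_patterns):
        z = [1, 1, 2, 2, 2, 3, 2, 2, 3, 1]
        pats = extract_patterns(z, CFG22)
        assert [tuple(p) for p in pats] == table1_patterns

    def test_single_window(self):
        pats = extract_patterns([1, 2, 3, 1], DispersionConfig(m=3, c=3, d=1))
        assert [tuple(p) for p in pats] == [(1, 2, 3), (2, 3, 1)]

    def test_delay_two_indexing(self):
        pats = extract_patterns([1, 2, 3, 1], DispersionConfig(m=2, c=3, d=2))
        assert [tuple(p) for p in pats] == [(1, 3), (2, 1)]

    def test_too_short_raises(self):
        with pytest.raises(SeriesTooShortError):
            extract_patterns([1, 2], DispersionConfig(m=3, c=3, d=1))

    @given(st.data())
    def test_matches_bruteforce_enumeration(self, data):
        """Window extraction equals direct index-by-index enumeration."""
        c = data.draw(st.integers(2, 4))
        m = data.draw(st.integers(2, 3))
        d = data.draw(st.integers(1, 3))
        n = data.draw(st.integers((m - 1) * d + 2, 50))
        z = data.draw(st.lists(st.integers(1, c), min_size=n, max_size=n))
        cfg = DispersionConfig(m=m, c=c, d=d)
        got = [tuple(p) for p in extract_patterns(z, cfg)]
        expected = [
            tuple(z[i + k * d] for k in range(m)) for i in range(len(z) - (m - 1) * d)
        ]
        assert got == expected


class TestPatternDistribution:
    def test_worked_example_frequencies(self, table1_patterns):
        dist = pattern_distribution(table1_patterns, CFG22)
        frame = dist.to_frame().set_index("pattern")["probability"]
        assert frame["11"] == pytest.approx(1 / 9, abs=0)
        assert frame["12"] == pytest.approx(1 / 9, abs=0)
        assert frame["22"] == pytest.approx(3 / 9, abs=0)
        assert frame["23"] == pytest.approx(2 / 9, abs=0)
        assert frame["32"] == pytest.approx(1 / 9, abs=0)
        assert frame["31"] == pytest.approx(1 / 9, abs=0)
        assert frame.drop(["11", "12", "22", "23", "32", "31"]).eq(0).all()
        assert dist.window_count == 9

    def test_single_pattern_mass(self):
        dist = pattern_distribution([(1, 1)] * 9, CFG22)
        assert dist.probabilities[0] == 1.0
        assert dist.probabilities[1:].sum() == 0.0

    def test_uniform_over_all_patterns(self):
        dist = pattern_distribution(_all_patterns(3, 2), CFG22)
        assert np.allclose(dist.probabilities, 1 / 9)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pattern_distribution(np.empty((0, 2), dtype=int), CFG22)

    @given(st.data())
    def test_normalization_and_rationality(self, data):
        """Probabilities sum to 1 and are multiples of 1/window_count."""
        c = data.draw(st.integers(2, 4))
        m = data.draw(st.integers(2, 3))
        n_pat = data.draw(st.integers(1, 40))
        pats = data.draw(
            st.lists(
                st.tuples(*[st.integers(1, c)] * m), min_size=n_pat, max_size=n_pat
            )
        )
        dist = pattern_distribution(pats, DispersionConfig(m=m, c=c, d=1))
        assert abs(dist.probabilities.sum() - 1.0) <= 1e-12
        counts = dist.probabilities * dist.window_count
        assert np.allclose(counts, np.round(counts), atol=1e-9)


def _all_patterns(c, m):
    import itertools

    return list(itertools.product(range(1, c + 1), repeat=m))


def _dist(probs, c=3, m=2):
    probs = np.asarray(probs, dtype=float)
    full = np.zeros(c**m)
    full[: probs.size] = probs
    return PatternDistribution(full, 1, DispersionConfig(m=m, c=c, d=1))


class TestDispersionEntropy:
    def test_worked_example_value(self, table1_patterns):
        """Shannon sum over the worked example's printed fractions.

        The source text prints 1.0297 for this example, but the Shannon sum
        over its own printed probabilities (four patterns at 1/9, one at 3/9,
        one at 2/9) is 1.6770 nats; the printed value corresponds to a
        distribution {0.5, 0.3, 0.2} appearing nowhere in the example and is
        treated as an erratum.
        """
        dist = pattern_distribution(table1_patterns, CFG22)
        oracle = 4 * (1 / 9) * math.log(9) + (1 / 3) * math.log(3) + (2 / 9) * math.log(9 / 2)
        assert dispersion_entropy(dist) == pytest.approx(oracle, abs=1e-12)
        assert dispersion_entropy(dist) == pytest.approx(1.6770, abs=5e-5)

    def test_uniform_is_maximal(self):
        assert dispersion_entropy(_dist([1 / 9] * 9)) == pytest.approx(
            math.log(9), abs=1e-12
        )

    def test_deterministic_is_zero(self):
        assert dispersion_entropy(_dist([1.0])) == 0.0

    @given(st.lists(st.floats(0.01, 1.0), min_size=9, max_size=9), st.randoms())
    def test_invariant_under_permutation(self, weights, rng):
        p = np.array(weights) / np.sum(weights)
        perm = list(range(9))
        rng.shuffle(perm)
        assert dispersion_entropy(_dist(p)) == pytest.approx(
            dispersion_entropy(_dist(p[perm])), abs=1e-12
        )


class TestCrde:
    def test_order_sensitive_motivating_pair(self):
        """Reversed distributions share DE but not CRDE."""
        p1 = _dist([0.4, 0.3, 0.2, 0.1], c=2, m=2)
        p2 = _dist([0.1, 0.2, 0.3, 0.4], c=2, m=2)
        oracle1 = -(0.6 * math.log(0.6) + 0.3 * math.log(0.3) + 0.1 * math.log(0.1))
        oracle2 = -(0.9 * math.log(0.9) + 0.7 * math.log(0.7) + 0.4 * math.log(0.4))
        assert crde(p1) == pytest.approx(oracle1, abs=1e-12)
        assert crde(p2) == pytest.approx(oracle2, abs=1e-12)
        assert crde(p1) == pytest.approx(0.8979, abs=5e-5)
        assert crde(p2) == pytest.approx(0.7110, abs=5e-5)
        assert dispersion_entropy(p1) == pytest.approx(dispersion_entropy(p2), abs=1e-12)
        assert crde(p1) != crde(p2)

    def test_mass_on_first_pattern_is_zero(self):
        assert crde(_dist([1.0])) == 0.0

    def test_worked_example_embedded_in_lexicographic_slots(self, table1_patterns):
        dist = pattern_distribution(table1_patterns, CFG22)
        survival = 1 - np.cumsum(dist.probabilities)
        oracle = -sum(t * math.log(t) for t in survival if t > 0)
        assert crde(dist) == pytest.approx(oracle, abs=1e-12)
        assert crde(dist) == pytest.approx(1.6299, abs=5e-5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=9, max_size=9))
    def test_bounds(self, weights):
        total = np.sum(weights)
        if total == 0:
            weights = [1.0] * 9
            total = 9.0
        p = _dist(np.array(weights) / total)
        value = crde(p)
        assert 0.0 <= value <= (9 - 1) / math.e + 1e-12
        de = dispersion_entropy(p)
        assert 0.0 <= de <= math.log(9) + 1e-12


class TestCumulativeResidualEntropySample:
    def test_two_point_closed_form(self):
        assert cumulative_residual_entropy_sample([0.0, 1.0]) == pytest.approx(
            0.5 * math.log(2), abs=1e-15
        )

    def test_constant_series_is_zero(self):
        assert cumulative_residual_entropy_sample([2.0, 2.0, 2.0]) == 0.0

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=40),
        st.floats(-100, 100),
        st.floats(0.1, 10),
    )
    def test_shift_invariant_and_positively_homogeneous(self, xs, shift, scale):
        x = np.array(xs)
        base = cumulative_residual_entropy_sample(x)
        assert base >= 0.0
        assert cumulative_residual_entropy_sample(x + shift) == pytest.approx(
            base, abs=1e-9
        )
        assert cumulative_residual_entropy_sample(scale * x) == pytest.approx(
            scale * base, rel=1e-9, abs=1e-9
        )

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            cumulative_residual_entropy_sample([1.0])


class TestSeriesCompositions:
    def test_worked_example_end_to_end(self, printed_series):
        assert de_of_series(printed_series, CFG22) == pytest.approx(1.6770, abs=5e-5)
        assert crde_of_series(printed_series, CFG22) == pytest.approx(1.6299, abs=5e-5)

    def test_crde_nonnegative_on_random_series(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=rng.integers(10, 60))
            assert crde_of_series(x, CFG22) >= 0.0

    def test_de_depends_only_on_pattern_multiset(self):
        """A reversal that preserves the pattern multiset preserves DE."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=30)
            z = map_to_classes(ncdf_map(x), 3)
            fwd = [tuple(p) for p in extract_patterns(z, CFG22)]
            rev = [tuple(p) for p in extract_patterns(z[::-1], CFG22)]
            if sorted(fwd) == sorted(rev):
                assert de_of_series(x, CFG22) == pytest.approx(
                    de_of_series(x[::-1], CFG22), abs=1e-12
                )


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [dict(m=1), dict(c=1), dict(c=10), dict(d=0)])
    def test_rejects_out_of_range_parameters(self, kwargs):
        with pytest.raises(ValueError):
            DispersionConfig(**{**dict(m=3, c=3, d=1), **kwargs})

    def test_rejects_oversized_pattern_space(self):
        with pytest.raises(ValueError):
            DispersionConfig(m=7, c=9, d=1)
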