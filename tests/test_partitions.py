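"""Divergence-model combinatorics and partition priors."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from codivabc.partitions import (DivergenceModel, ModelPriorSpec,
                                 bell_number, canonicalize,
                                 dpp_coclustering_prob, dpp_ncat_pmf,
                                 integer_partitions, msbayes_ordered_pmf,
                                 partition_signature, sample_partition_dpp,
                                 sample_partition_identity,
                                 sample_partition_msbayes,
                                 sample_partition_uniform,
                                 stirling1_unsigned, stirling2)


def enumerate_set_partitions(items):
    """Brute-force enumeration of all set partitions of a list."""
    if len(items) == 1:
        yield [[items[0]]]
        return
    first, rest = items[0], items[1:]
    for smaller in enumerate_set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


class TestExactCounts:
    @pytest.mark.parametrize("n,k,expected", [
        (3, 2, 3), (5, 1, 1), (5, 5, 1), (4, 2, 7)])
    def test_stirling2_known_values(self, n, k, expected):
        assert stirling2(n, k) == expected

    @pytest.mark.parametrize("n,k,expected", [
        (3, 1, 2), (4, 4, 1), (8, 1, math.factorial(7))])
    def test_stirling1_known_values(self, n, k, expected):
        assert stirling1_unsigned(n, k) == expected

    def test_stirling1_sums_to_factorial(self):
        assert sum(stirling1_unsigned(8, k)
                   for k in range(1, 9)) == math.factorial(8)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_stirling2_matches_enumeration(self, n):
        by_k = {}
        for part in enumerate_set_partitions(list(range(n))):
            by_k[len(part)] = by_k.get(len(part), 0) + 1
        for k in range(1, n + 1):
            assert stirling2(n, k) == by_k.get(k, 0)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_against_sympy_oracle(self, n):
        from sympy.functions.combinatorial.numbers import (bell,
                                                           stirling)
        assert bell_number(n) == int(bell(n))
        for k in (1, n // 2, n):
            assert stirling2(n, k) == stirling(n, k, kind=2)
            assert stirling1_unsigned(n, k) == stirling(n, k, kind=1,
                                                        signed=False)

    def test_model_counts_for_eight_and_twentytwo_pairs(self):
        # eight pairs: 4140 ordered vs 22 unordered divergence models
        assert bell_number(8) == 4140
        assert len(integer_partitions(8)) == 22
        # twenty-two pairs: 1002 unordered models
        assert len(integer_partitions(22)) == 1002

    def test_integer_partitions_basic(self):
        assert integer_partitions(1) == [(1,)]
        parts = integer_partitions(8)
        assert len(set(parts)) == len(parts)
        for p in parts:
            assert sum(p) == 8
            assert list(p) == sorted(p, reverse=True)
        # reverse-lexicographic: (8,) first, all-ones last
        assert parts[0] == (8,)
        assert parts[-1] == (1,) * 8

    def test_argument_errors(self):
        for bad in ((0, 1), (3, 0), (3, 4)):
            with pytest.raises(ValueError):
                stirling2(*bad)
            with pytest.raises(ValueError):
                stirling1_unsigned(*bad)
        with pytest.raises(ValueError):
            bell_number(0)
        with pytest.raises(ValueError):
            integer_partitions(0)


class TestDppLaw:
    def test_ncat_pmf_value_at_chi_one(self):
        # chi = 1: denominator is Y!, c(8,8) = 1, c(8,1) = 7!
        assert dpp_ncat_pmf(8, 1.0, 8) == pytest.approx(
            1 / math.factorial(8))
        assert dpp_ncat_pmf(8, 1.0, 1) == pytest.approx(0.125)

    @given(st.integers(1, 12), st.floats(0.01, 50.0))
    @settings(derandomize=True, max_examples=40)
    def test_ncat_pmf_normalizes(self, Y, chi):
        total = sum(dpp_ncat_pmf(Y, chi, k) for k in range(1, Y + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_coclustering_values(self):
        assert dpp_coclustering_prob(1.0) == 0.5
        assert dpp_coclustering_prob(1e-12) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            dpp_coclustering_prob(0.0)

    @pytest.mark.parametrize("chi", [0.5, 2.0])
    def test_crp_ncat_matches_pmf(self, rng, chi):
        """Empirical |tau| distribution from 1e5 CRP draws matches the
        closed-form pmf (goodness of fit at alpha = 0.001)."""
        Y, n = 8, 100_000
        counts = np.zeros(Y, dtype=int)
        for _ in range(n):
            t = sample_partition_dpp(Y, chi, rng)
            counts[max(t) - 1] += 1
        expected = n * np.array([dpp_ncat_pmf(Y, chi, k)
                                 for k in range(1, Y + 1)])
        # pool the sparse upper tail for chi-square validity
        keep = expected >= 5
        obs, exp = counts[keep], expected[keep]
        if (~keep).any():
            obs = np.append(obs, counts[~keep].sum())
            exp = np.append(exp, expected[~keep].sum())
        stat, p = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.001

    def test_crp_coclustering_frequency(self, rng):
        chi, n = 2.0, 100_000
        hits = sum(sample_partition_dpp(8, chi, rng)[1] == 1
                   for _ in range(n))
        p_hat = hits / n
        expect = dpp_coclustering_prob(chi)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(p_hat - expect) < 3 * se

    def test_tiny_chi_collapses_to_one_class(self, rng):
        for _ in range(200):
            assert max(sample_partition_dpp(8, 1e-12, rng)) == 1


class TestUniformPartitionPrior:
    def test_uniform_over_unordered_models(self, rng):
        Y, n = 8, 100_000
        models = integer_partitions(Y)
        index = {m: i for i, m in enumerate(models)}
        counts = np.zeros(len(models), dtype=int)
        for _ in range(n):
            t = sample_partition_uniform(Y, rng)
            counts[index[partition_signature(t)]] += 1
        stat, p = stats.chisquare(counts)
        assert p > 0.001

    def test_degenerate_cases(self, rng):
        assert sample_partition_uniform(1, rng) == (1,)
        two = [partition_signature(sample_partition_uniform(2, rng))
               for _ in range(4000)]
        frac = sum(s == (2,) for s in two) / len(two)
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / len(two))


class TestMsbayesPrior:
    def test_ncat_marginal_uniform(self, rng):
        Y, n = 8, 20_000
        counts = np.zeros(Y, dtype=int)
        for _ in range(n):
            counts[max(sample_partition_msbayes(Y, rng)) - 1] += 1
        stat, p = stats.chisquare(counts)
        assert p > 0.001

    def test_all_classes_occupied(self, rng):
        for _ in range(500):
            t = sample_partition_msbayes(8, rng)
            assert set(t) == set(range(1, max(t) + 1))

    def test_two_pair_split(self, rng):
        n = 20_000
        frac = sum(partition_signature(
            sample_partition_msbayes(2, rng)) == (2,)
            for _ in range(n)) / n
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_u_shape_exact_ordered_probabilities(self):
        """The induced prior puts more mass on the single-event model
        than on any individual model with an intermediate number of
        events (the U shape), exactly: p(t) = (1/Y) / S(Y, k)."""
        Y = 8
        p_one = msbayes_ordered_pmf((1,) * Y, Y)
        p_four = msbayes_ordered_pmf((1, 1, 2, 2, 3, 3, 4, 4), Y)
        assert p_one == pytest.approx(1 / 8)
        assert p_four == pytest.approx(1 / (8 * stirling2(8, 4)))
        assert p_one > p_four
        # and summed over all ordered models it is a proper pmf
        total = sum(stirling2(Y, k) * (1 / (Y * stirling2(Y, k)))
                    for k in range(1, Y + 1))
        assert total == pytest.approx(1.0)

    def test_conditional_law_uniform_over_set_partitions(self, rng):
        """Given k classes, every set partition with k blocks is equally
        likely (Y = 4, k inferred per draw)."""
        Y, n = 4, 40_000
        seen: dict[tuple, int] = {}
        for _ in range(n):
            t = sample_partition_msbayes(Y, rng)
            seen[t] = seen.get(t, 0) + 1
        by_k: dict[int, list[int]] = {}
        for t, c in seen.items():
            by_k.setdefault(max(t), []).append(c)
        for k, counts in by_k.items():
            assert len(counts) == stirling2(Y, k)
            if len(counts) >= 2 and min(counts) >= 20:
                stat, p = stats.chisquare(counts)
                assert p > 0.001, f"k={k}"


class TestModelPlumbing:
    def test_signature_examples(self):
        assert partition_signature((1, 1, 2, 3)) == (2, 1, 1)
        assert partition_signature((3, 3, 1, 2)) == \
            partition_signature((1, 1, 2, 3))
        assert partition_signature((1, 1, 1)) == (3,)
        with pytest.raises(ValueError):
            partition_signature(())

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=60)
    def test_signature_invariant_under_relabeling(self, t):
        t = canonicalize(t)
        relabeled = tuple(max(t) + 1 - c for c in t)
        assert partition_signature(t) == partition_signature(relabeled)

    @given(st.lists(st.integers(1, 6), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=60)
    def test_canonicalize_idempotent_and_first_appearance(self, t):
        c = canonicalize(t)
        assert canonicalize(c) == c
        assert c[0] == 1
        assert max(c) == len(set(t))
        seen_max = 0
        for v in c:
            assert v <= seen_max + 1
            seen_max = max(seen_max, v)

    def test_samplers_emit_canonical_labels(self, rng):
        for _ in range(200):
            for t in (sample_partition_dpp(6, 1.3, rng),
                      sample_partition_uniform(6, rng),
                      sample_partition_msbayes(6, rng)):
                assert t == canonicalize(t)

    def test_divergence_model_validation(self):
        m = DivergenceModel((1, 1, 2), (0.5, 1.5))
        assert m.ntau == 2 and m.Y == 3
        assert np.allclose(m.times, [0.5, 0.5, 1.5])
        with pytest.raises(ValueError):
            DivergenceModel((2, 1, 1), (0.5, 1.5))  # not canonical
        with pytest.raises(ValueError):
            DivergenceModel((1, 1, 2), (0.5,))  # wrong |tau|
        with pytest.raises(ValueError):
            DivergenceModel((1, 2), (0.5, -1.0))  # non-positive time

    def test_model_prior_spec_validation(self):
        with pytest.raises(ValueError):
            ModelPriorSpec("dpp")  # missing chi
        with pytest.raises(ValueError):
            ModelPriorSpec("dpp", -1.0)
        with pytest.raises(ValueError):
            ModelPriorSpec("uniform", 2.0)  # chi is DPP-only
        with pytest.raises(ValueError):
            ModelPriorSpec("pitman-yor", 1.0)
        spec = ModelPriorSpec("dpp", (2.0, 2.0))
        chi = spec.draw_chi(np.random.default_rng(0))
        assert chi > 0

    def test_identity_partition(self):
        assert sample_partition_identity(4) == (1, 2, 3, 4)
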