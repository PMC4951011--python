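"""Random-set null model, permutation FDR arithmetic and candidate filter."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedpath.network_io import ValidationError
from seedpath.path_core import BetweennessTable
from seedpath.permutation import (
    FdrTable,
    PermutationConfig,
    filter_candidates,
    permutation_fdr,
    sample_random_sets,
    sampling_universe,
)

from conftest import make_network


def chain_network(n: int):
    return make_network([(f"N{i}", f"N{i+1}", 500) for i in range(n - 1)])


def tables(values: dict[str, list[int]], mode: str = "all-paths"):
    """Build one BetweennessTable per permutation from per-gene count lists."""
    n = len(next(iter(values.values())))
    return [
        BetweennessTable({g: v[i] for g, v in values.items() if v[i] > 0}, mode)
        for i in range(n)
    ]


class TestSampleRandomSets:
    def test_full_universe_forces_identity(self):
        net = chain_network(10)
        config = PermutationConfig(n_permutations=5, set_size=10, rng_seed=0)
        for s in sample_random_sets(net, config):
            assert s == frozenset(net.nodes)

    def test_same_seed_reproduces_sequence(self):
        net = chain_network(30)
        config = PermutationConfig(n_permutations=20, set_size=4, rng_seed=17)
        assert sample_random_sets(net, config) == sample_random_sets(net, config)

    def test_different_seed_changes_sequence(self):
        net = chain_network(30)
        a = sample_random_sets(net, PermutationConfig(10, 4, rng_seed=1))
        b = sample_random_sets(net, PermutationConfig(10, 4, rng_seed=2))
        assert a != b

    def test_inclusion_frequency_is_uniform(self):
        # 10,000 sets of size 3 from 30 nodes: per-node inclusion is
        # Binomial(10000, 0.1); check within 3 standard errors.
        net = chain_network(30)
        config = PermutationConfig(n_permutations=10_000, set_size=3, rng_seed=5)
        sets = sample_random_sets(net, config)
        p = 3 / 30
        se = np.sqrt(p * (1 - p) / len(sets))
        for node in net.nodes:
            freq = sum(node in s for s in sets) / len(sets)
            assert abs(freq - p) < 3 * se

    def test_universe_smaller_than_set_size_is_error(self):
        net = chain_network(5)
        with pytest.raises(ValidationError):
            sample_random_sets(net, PermutationConfig(5, set_size=6))

    def test_non_seed_universe_excludes_seeds(self):
        net = chain_network(10)
        universe = sampling_universe(net, ["N0", "N1"], "non-seed-nodes")
        assert "N0" not in universe and "N1" not in universe
        assert len(universe) == 8


class TestPermutationFdr:
    def test_exceedance_ratio(self):
        observed = BetweennessTable({"g": 10}, "all-paths")
        runs = tables({"g": [11] * 37 + [10] * 100 + [0] * 863})
        result = permutation_fdr(observed, runs, PermutationConfig(1000))
        assert result.fdr["g"] == pytest.approx(0.037)
        assert result.exceed_count["g"] == 37

    def test_gene_absent_from_all_runs_gets_zero(self):
        observed = BetweennessTable({"g": 1}, "all-paths")
        runs = tables({"other": [5] * 100})
        result = permutation_fdr(observed, runs, PermutationConfig(100))
        assert result.fdr["g"] == 0.0

    def test_ge_comparison_at_zero_boundary_gives_one(self):
        observed = BetweennessTable({"g": 0}, "all-paths")
        runs = tables({"other": [1] * 50})  # g is 0 in every run, 0 >= 0
        result = permutation_fdr(
            observed, runs, PermutationConfig(50, comparison="ge")
        )
        assert result.fdr["g"] == 1.0

    def test_strict_comparison_ignores_ties(self):
        observed = BetweennessTable({"g": 5}, "all-paths")
        runs = tables({"g": [5] * 10 + [6] * 2 + [0] * 8})
        gt = permutation_fdr(observed, runs, PermutationConfig(20, comparison="gt"))
        ge = permutation_fdr(observed, runs, PermutationConfig(20, comparison="ge"))
        assert gt.exceed_count["g"] == 2
        assert ge.exceed_count["g"] == 12
        assert gt.fdr["g"] <= ge.fdr["g"]

    def test_smoothing_applies_pseudocount(self):
        observed = BetweennessTable({"g": 10}, "all-paths")
        runs = tables({"g": [0] * 99})
        plain = permutation_fdr(observed, runs, PermutationConfig(99))
        smooth = permutation_fdr(
            observed, runs, PermutationConfig(99, smoothing=True)
        )
        assert plain.fdr["g"] == 0.0
        assert smooth.fdr["g"] == pytest.approx(1 / 100)

    def test_empty_permutation_sequence_is_error(self):
        observed = BetweennessTable({"g": 1}, "all-paths")
        with pytest.raises(ValidationError):
            permutation_fdr(observed, [], PermutationConfig(10))

    def test_mode_mismatch_is_error(self):
        observed = BetweennessTable({"g": 1}, "all-paths")
        runs = [BetweennessTable({"g": 1}, "per-pair")]
        with pytest.raises(ValidationError):
            permutation_fdr(observed, runs, PermutationConfig(10))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        obs=st.integers(0, 20),
        counts=st.lists(st.integers(0, 20), min_size=1, max_size=60),
        comparison=st.sampled_from(["gt", "ge"]),
    )
    def test_fdr_times_n_is_exact_integer_exceed_count(self, obs, counts, comparison):
        observed = BetweennessTable({"g": obs}, "all-paths")
        runs = tables({"g": counts})
        result = permutation_fdr(
            observed, runs, PermutationConfig(len(counts), comparison=comparison)
        )
        assert result.fdr["g"] * result.n_permutations == result.exceed_count["g"]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        obs=st.integers(0, 10),
        counts=st.lists(st.integers(0, 10), min_size=1, max_size=40),
    )
    def test_fdr_is_monotone_in_observed_evidence(self, obs, counts):
        runs = tables({"g": counts})
        config = PermutationConfig(len(counts))
        lo = permutation_fdr(BetweennessTable({"g": obs}, "all-paths"), runs, config)
        hi = permutation_fdr(
            BetweennessTable({"g": obs + 1}, "all-paths"), runs, config
        )
        assert hi.fdr["g"] <= lo.fdr["g"]


class TestFilterCandidates:
    def test_threshold_boundary_is_exclusive(self):
        table = FdrTable(
            fdr={"a": 0.049, "b": 0.05, "c": 0.2},
            exceed_count={"a": 49, "b": 50, "c": 200},
            n_permutations=1000,
        )
        report = filter_candidates(table, 0.05, ["b"])
        assert report.candidates == ("a",)
        assert report.novel == ("a",)
        assert report.validated == ()

    def test_near_vacuous_threshold_keeps_all_below_one(self):
        table = FdrTable(
            fdr={"a": 0.0, "b": 0.999, "c": 1.0},
            exceed_count={"a": 0, "b": 999, "c": 1000},
            n_permutations=1000,
        )
        report = filter_candidates(table, 1.0, [])
        assert set(report.candidates) == {"a", "b"}

    def test_nested_thresholds_give_nested_candidate_sets(self):
        table = FdrTable(
            fdr={"a": 0.005, "b": 0.03, "c": 0.2},
            exceed_count={"a": 5, "b": 30, "c": 200},
            n_permutations=1000,
        )
        tight = set(filter_candidates(table, 0.01, []).candidates)
        loose = set(filter_candidates(table, 0.05, []).candidates)
        assert tight <= loose

    def test_partition_into_validated_and_novel(self):
        table = FdrTable(
            fdr={"a": 0.0, "b": 0.01, "c": 0.9},
            exceed_count={"a": 0, "b": 1, "c": 90},
            n_permutations=100,
        )
        report = filter_candidates(table, 0.05, ["a", "c"])
        assert report.validated == ("a",)
        assert report.novel == ("b",)
        assert report.n_candidates == 2

    @pytest.mark.parametrize("threshold", [0.0, 1.5, -1])
    def test_invalid_threshold_is_error(self, threshold):
        table = FdrTable(fdr={}, exceed_count={}, n_permutations=10)
        with pytest.raises(ValidationError):
            filter_candidates(table, threshold, [])
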