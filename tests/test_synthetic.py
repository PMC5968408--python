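"""Synthetic corpus generation, marginal fixtures and simulations."""

import dataclasses
import itertools

import numpy as np
import pytest

from claimcite.corpus import validate_corpus
from claimcite.datasets import study_profile
from claimcite.graph import build_graph
from claimcite.metrics import bipartite_density, contingency_table, utilization_distribution
from claimcite.synthetic import (
    ClassMarginals,
    ConfigError,
    FeasibilityError,
    MarginalProfile,
    PrimarySpec,
    SyntheticConfig,
    build_fixture_from_marginals,
    estimate_citation_probs,
    gale_ryser_feasible,
    generate_corpus,
    power_simulation,
)

STANCES = ("supportive", "neutral", "unsupportive")


def config(pi, *, reviews=10, primaries=None, min_cit=1, seed=0):
    primaries = primaries or {"supportive": 1, "unsupportive": 3}
    if isinstance(pi, float):
        pi = {rc: {pc: pi for pc in primaries} for rc in STANCES}
    return SyntheticConfig(
        primaries_per_class=primaries,
        reviews_per_class={c: reviews for c in STANCES},
        citation_prob=pi,
        min_citations_per_review=min_cit,
        seed=seed,
    )


class TestGenerateCorpus:
    def test_equal_seeds_bit_identical_different_seeds_differ(self):
        a = generate_corpus(config(0.5, seed=3))
        b = generate_corpus(config(0.5, seed=3))
        c = generate_corpus(config(0.5, seed=4))
        assert a == b
        assert a != c

    def test_generated_corpus_passes_validation(self):
        papers, records = generate_corpus(config(0.4, seed=9))
        assert validate_corpus(papers, records).is_valid

    def test_saturated_probabilities_give_complete_bipartite_density_one(self):
        papers, records = generate_corpus(config(1.0, seed=1))
        graph = build_graph(papers, records)
        for scope in ("all", *STANCES):
            assert bipartite_density(graph, scope).D == 1.0

    def test_zero_probability_floor_gives_out_degree_exactly_one(self):
        papers, records = generate_corpus(config(0.0, min_cit=1, seed=5))
        graph = build_graph(papers, records)
        assert utilization_distribution(graph).histogram == {1: len(graph.reviews)}

    def test_infeasible_floor_is_a_config_error(self):
        with pytest.raises(ConfigError, match="exceeds"):
            config(0.5, min_cit=5).validate()

    @pytest.mark.parametrize(
        "bad",
        [
            {"citation_prob": {c: {"supportive": 1.5, "unsupportive": 0.5} for c in STANCES}},
            {"reviews_per_class": {c: 0 for c in STANCES}},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        base = config(0.5)
        with pytest.raises(ConfigError):
            dataclasses.replace(base, **bad).validate()

    def test_mean_density_matches_exact_floor_adjusted_expectation(self):
        """Mean density over replicates vs enumeration of one review's
        2^4 citation patterns with the minimum-citation floor applied."""
        p, n_prim, min_cit = 0.5, 4, 1
        exact_mean_degree = sum(
            (p ** sum(s)) * ((1 - p) ** (n_prim - sum(s))) * max(sum(s), min_cit)
            for s in itertools.product((0, 1), repeat=n_prim)
        )
        cfg = config(p, reviews=17, primaries={"supportive": 2, "unsupportive": 2},
                     min_cit=min_cit)
        densities = []
        for s in range(300):
            papers, records = generate_corpus(dataclasses.replace(cfg, seed=s))
            densities.append(bipartite_density(build_graph(papers, records)).D)
        densities = np.array(densities)
        se = densities.std(ddof=1) / np.sqrt(len(densities))
        assert abs(densities.mean() - exact_mean_degree / n_prim) < 3 * se

    def test_class_pair_edge_counts_are_binomial_without_floor(self):
        """With the floor off the class-pair edge count is
        Binomial(n_r x n_p, pi); the replicate mean stays within 4 SE."""
        pi, n_rev, n_prim, reps = 0.3, 10, 2, 500
        cfg = SyntheticConfig(
            primaries_per_class={"unsupportive": n_prim},
            reviews_per_class={"neutral": n_rev},
            citation_prob={"neutral": {"unsupportive": pi}},
            min_citations_per_review=0,
        )
        counts = [
            len(generate_corpus(dataclasses.replace(cfg, seed=s))[1])
            for s in range(reps)
        ]
        n_pairs = n_rev * n_prim
        se = np.sqrt(n_pairs * pi * (1 - pi) / reps)
        assert abs(np.mean(counts) - n_pairs * pi) < 4 * se


class TestEstimateCitationProbs:
    def test_recovery_improves_with_sample_size(self):
        pi = {
            "supportive": {"supportive": 0.8, "unsupportive": 0.2},
            "neutral": {"supportive": 0.5, "unsupportive": 0.5},
            "unsupportive": {"supportive": 0.3, "unsupportive": 0.6},
        }
        maes = {}
        for n in (25, 400):
            cfg = SyntheticConfig(
                primaries_per_class={"supportive": 2, "unsupportive": 2},
                reviews_per_class={c: n for c in STANCES},
                citation_prob=pi,
                min_citations_per_review=0,
                seed=42,
            )
            papers, records = generate_corpus(cfg)
            est = estimate_citation_probs(papers, records)
            errors = []
            for rc, row in pi.items():
                for pc, true in row.items():
                    cell = est[rc][pc]
                    errors.append(abs(cell["estimate"] - true))
                    # each cell within its binomial 99% CI around the truth
                    half = 2.576 * np.sqrt(true * (1 - true) / cell["pairs"])
                    assert abs(cell["estimate"] - true) <= half
            maes[n] = np.mean(errors)
        assert maes[400] < maes[25]

    def test_empty_class_reported_as_undefined(self):
        papers, records = generate_corpus(
            SyntheticConfig(
                primaries_per_class={"supportive": 1, "unsupportive": 0},
                reviews_per_class={"neutral": 3},
                citation_prob={"neutral": {"supportive": 1.0, "unsupportive": 0.5}},
            )
        )
        est = estimate_citation_probs(papers, records)
        assert est["neutral"]["supportive"]["estimate"] == 1.0
        assert "unsupportive" not in est["neutral"]  # no such primary exists


class TestGaleRyser:
    def test_known_feasible_and_infeasible_sequences(self):
        assert gale_ryser_feasible([2, 2, 2], [3, 3, 0])
        assert gale_ryser_feasible([1, 2, 3], [3, 2, 1])
        # two full columns force every review to cite twice
        assert not gale_ryser_feasible([3, 3, 1, 1], [4, 4, 0])
        assert not gale_ryser_feasible([1, 1], [1])  # unequal totals


class TestFixtureFromMarginals:
    def test_study_profile_reproduces_published_marginals(self):
        profile = study_profile()
        papers, records = build_fixture_from_marginals(profile, seed=7)
        graph = build_graph(papers, records)
        table = contingency_table(graph)
        for cls, marg in profile.classes.items():
            row = dict(zip(table.col_labels, table.row(cls)))
            assert row == dict(marg.column_counts)
            hist = utilization_distribution(graph, cls).histogram
            assert hist == dict(marg.out_degree_hist)

    def test_closure_on_marginals_derived_from_a_random_corpus(self):
        papers, records = generate_corpus(config(0.5, reviews=8, seed=13))
        graph = build_graph(papers, records)
        table = contingency_table(graph)
        profile = MarginalProfile(
            primaries=tuple(
                PrimarySpec(p.id, p.classification, p.year) for p in graph.primaries
            ),
            classes={
                cls: ClassMarginals(
                    out_degree_hist=utilization_distribution(graph, cls).histogram,
                    column_counts=dict(zip(table.col_labels, (int(x) for x in table.row(cls)))),
                )
                for cls in table.row_labels
            },
        )
        rebuilt_papers, rebuilt_records = build_fixture_from_marginals(profile, seed=99)
        rebuilt = build_graph(rebuilt_papers, rebuilt_records)
        rebuilt_table = contingency_table(rebuilt)
        assert rebuilt_table.observed.tolist() == table.observed.tolist()
        for cls in table.row_labels:
            assert (
                utilization_distribution(rebuilt, cls).histogram
                == utilization_distribution(graph, cls).histogram
            )

    def test_fixture_is_seed_deterministic(self):
        a = build_fixture_from_marginals(study_profile(), seed=3)
        b = build_fixture_from_marginals(study_profile(), seed=3)
        assert a == b

    def test_column_exceeding_class_size_is_infeasible(self):
        profile = MarginalProfile(
            primaries=(PrimarySpec("p1", "supportive", 1966),),
            classes={
                "neutral": ClassMarginals(
                    out_degree_hist={1: 2}, column_counts={"p1": 3}
                )
            },
        )
        with pytest.raises(FeasibilityError, match="neutral"):
            build_fixture_from_marginals(profile, seed=0)

    def test_gale_ryser_violation_names_the_class(self):
        primaries = tuple(
            PrimarySpec(f"p{j}", "unsupportive", 1966) for j in range(3)
        )
        profile = MarginalProfile(
            primaries=primaries,
            classes={
                "supportive": ClassMarginals(
                    out_degree_hist={3: 2, 1: 2},
                    column_counts={"p0": 4, "p1": 4, "p2": 0},
                )
            },
        )
        with pytest.raises(FeasibilityError, match="supportive"):
            build_fixture_from_marginals(profile, seed=0)

    def test_inconsistent_singleton_allocation_rejected(self):
        profile = MarginalProfile(
            primaries=(
                PrimarySpec("p1", "supportive", 1966),
                PrimarySpec("p2", "unsupportive", 1966),
            ),
            classes={
                "neutral": ClassMarginals(
                    out_degree_hist={1: 2},
                    column_counts={"p1": 1, "p2": 1},
                    singleton_allocation={"p1": 1},  # covers 1 of 2 singles
                )
            },
        )
        with pytest.raises(FeasibilityError, match="singleton allocation"):
            build_fixture_from_marginals(profile, seed=0)

    def test_profile_dict_round_trip(self):
        profile = study_profile()
        assert MarginalProfile.from_dict(profile.to_dict()) == profile


class TestPowerSimulation:
    def test_identical_configs_give_identical_rates(self):
        cfg = config(0.5, reviews=8, seed=21)
        result = power_simulation(cfg, cfg, replicates=40)
        assert result["type1_rate"] == result["power"]

    def test_homophily_raises_rejection_rate_above_null(self):
        null = config(0.5, reviews=20, seed=6)
        alt = dataclasses.replace(
            null,
            citation_prob={
                "supportive": {"supportive": 1.0, "unsupportive": 0.1},
                "neutral": {"supportive": 1.0, "unsupportive": 0.6},
                "unsupportive": {"supportive": 0.7, "unsupportive": 0.5},
            },
        )
        result = power_simulation(null, alt, replicates=120)
        assert result["power"] > result["type1_rate"]
        assert result["power"] > 0.5

    def test_mismatched_class_structure_rejected(self):
        null = config(0.5)
        alt = dataclasses.replace(null, primaries_per_class={"supportive": 1})
        with pytest.raises(ConfigError, match="class structure"):
            power_simulation(null, alt, replicates=2)
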