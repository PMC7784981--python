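"""Enrichment scoring: chi-square statistic, p/q-values, group assignment.

The score anchor points are the published per-group presence fractions of
the study's top-ranked functions (three groups of 10/3/10 genomes), whose
printed enrichment scores the statistic must reproduce to printed
precision.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epirange.enrichment import (
    associated_groups,
    bh_fdr,
    enrichment_pvalue,
    enrichment_score,
    enrichment_score_vector,
    function_presence,
    run_enrichment,
)
from epirange.pangenome import GeneClusterMatrix, PhenotypeMap
from epirange.simulate import PangenomeSimConfig, simulate_pangenome

from oracles import bh_by_hand, chi_square_by_loop

R, NP, P = "resistant", "nonpermissive", "permissive"

# published fractions (n present out of 10/3/10) and their printed scores
PUBLISHED_SCORES = [
    ((10, 0, 0), 23.0),   # e.g. Mur ligase family / ArcA, resistant block
    ((0, 3, 10), 23.0),   # susceptible block (perfect complement pattern)
    ((2, 1, 10), 13.78),
    ((0, 1, 8), 13.48),
    ((0, 0, 7), 13.08),
    ((1, 3, 0), 16.74),
    ((0, 2, 0), 14.6),
    ((1, 3, 1), 12.42),
    ((1, 3, 2), 10.03),
    ((0, 2, 1), 9.19),
    ((9, 3, 1), 15.68),
    ((5, 3, 0), 11.98),
    ((10, 3, 4), 10.55),
]


def table_counts(k_r, k_np, k_p):
    return {R: (k_r, 10), NP: (k_np, 3), P: (k_p, 10)}


class TestScore:
    @pytest.mark.parametrize("fractions,expected", PUBLISHED_SCORES)
    def test_published_scores_to_printed_precision(self, fractions, expected):
        score = enrichment_score(table_counts(*fractions))
        assert score == pytest.approx(expected, abs=0.005)

    def test_no_variation_scores_zero(self):
        assert enrichment_score(table_counts(10, 3, 10)) == 0.0
        assert enrichment_score(table_counts(0, 0, 0)) == 0.0

    def test_perfect_association_scores_total_genomes(self):
        # presence coinciding exactly with a group boundary maximizes the
        # statistic at N, the number of labeled genomes
        assert enrichment_score(table_counts(10, 0, 0)) == pytest.approx(23.0)
        assert enrichment_score(table_counts(0, 3, 0)) == pytest.approx(23.0)
        assert enrichment_score(table_counts(10, 3, 0)) == pytest.approx(23.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_textbook_chi_square_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(300):
            sizes = rng.integers(1, 12, size=rng.integers(2, 5))
            counts = {f"g{i}": (int(rng.integers(0, n + 1)), int(n)) for i, n in enumerate(sizes)}
            assert enrichment_score(counts) == pytest.approx(
                chi_square_by_loop(counts), abs=1e-9)

    def test_invariant_under_group_relabeling(self):
        a = enrichment_score({R: (2, 10), NP: (1, 3), P: (10, 10)})
        b = enrichment_score({P: (2, 10), R: (1, 3), NP: (10, 10)})
        assert a == pytest.approx(b)

    def test_group_of_size_zero_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score({R: (0, 0), P: (1, 5)})

    def test_vectorized_scores_match_scalar(self):
        rng = np.random.default_rng(11)
        n = np.array([10, 3, 10])
        k = np.column_stack([rng.integers(0, s + 1, size=50) for s in n])
        vec = enrichment_score_vector(k, n)
        for row, v in zip(k, vec):
            counts = {g: (int(c), int(s)) for g, c, s in zip((R, NP, P), row, n)}
            assert v == pytest.approx(enrichment_score(counts), abs=1e-9)


class TestPValue:
    def test_zero_score_gives_one(self):
        assert enrichment_pvalue(0.0, 3) == 1.0

    def test_df2_closed_form(self):
        # chi-square survival with 2 df is exp(-x/2)
        assert enrichment_pvalue(23.0, 3) == pytest.approx(math.exp(-11.5), rel=1e-12)
        assert enrichment_pvalue(13.78, 3) == pytest.approx(math.exp(-6.89), rel=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            enrichment_pvalue(1.0, 1)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == [0.03]

    def test_step_up_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_hand_rule_and_dominates_p(self, pvals):
        q = bh_fdr(pvals)
        assert q == pytest.approx(bh_by_hand(pvals), abs=1e-12)
        assert all(qq >= pp for qq, pp in zip(q, pvals))
        order = np.argsort(pvals)
        assert all(np.diff(np.array(q)[order]) >= -1e-12)


class TestAssociatedGroups:
    @pytest.mark.parametrize("fractions,expected", [
        ({R: 1.0, NP: 0.0, P: 0.0}, {R}),
        ({R: 0.9, NP: 1.0, P: 0.1}, {R, NP}),
        ({R: 0.5, NP: 1.0, P: 0.0}, {R, NP}),  # boundary: >= not >
        ({R: 0.4, NP: 0.3, P: 0.2}, set()),
    ])
    def test_majority_rule(self, fractions, expected):
        assert associated_groups(fractions) == expected


@pytest.fixture(scope="module")
def planted():
    cfg = PangenomeSimConfig(
        n_core=20,
        n_exclusive={"susceptible": 5, R: 5, NP: 3, P: 4},
        n_noise=300, seed=5,
    )
    return simulate_pangenome(cfg)


class TestRunEnrichment:
    def test_function_on_second_cluster_still_counts(self):
        counts = np.array([[1, 0], [0, 1]])
        m = GeneClusterMatrix(genomes=["A", "B"], clusters=["c1", "c2"], counts=counts,
                              functions={"c1": {("F1", "f")}, "c2": {("F1", "f")}})
        ph = PhenotypeMap(assignments={"A": R, "B": P})
        profiles = function_presence(m, ph)
        assert len(profiles) == 1
        assert profiles[0].presence == {"A": True, "B": True}

    def test_planted_profiles_match_design(self, planted):
        m, ph, truth = planted
        profiles = {p.function[0]: p for p in function_presence(m, ph)}
        for acc in truth["functions"]["exclusive"][R]:
            assert profiles[acc].per_group_counts == {R: (10, 10), NP: (0, 3), P: (0, 10)}
        for acc in truth["functions"]["exclusive"]["susceptible"]:
            assert profiles[acc].per_group_counts == {R: (0, 10), NP: (3, 3), P: (10, 10)}

    def test_planted_exclusive_functions_score_total_and_rank_first(self, planted):
        m, ph, truth = planted
        records = run_enrichment(m, ph)
        planted_accs = set()
        for group in truth["functions"]["exclusive"]:
            planted_accs.update(truth["functions"]["exclusive"][group])
        top = records[: len(planted_accs)]
        assert {r.function[0] for r in top} >= planted_accs - {
            r.function[0] for r in records if r.score < 23}
        for r in records:
            if r.function[0] in planted_accs:
                assert r.score == pytest.approx(23.0)
                assert r.q_value <= r.score  # sanity: q defined
                assert r.q_value >= r.p_value

    def test_invariant_to_relabeling_within_groups(self, planted):
        m, ph, _ = planted
        # swap two resistant genomes' rows: same group, so identical output
        i, j = m.genomes.index("R01"), m.genomes.index("R02")
        counts = m.counts.copy()
        counts[[i, j]] = counts[[j, i]]
        m2 = GeneClusterMatrix(genomes=m.genomes, clusters=m.clusters, counts=counts,
                               functions=m.functions)
        rec1 = run_enrichment(m, ph)
        rec2 = run_enrichment(m2, ph)
        assert [(r.function, r.score, r.q_value) for r in rec1] == \
               [(r.function, r.score, r.q_value) for r in rec2]

    def test_unannotated_matrix_warns_and_returns_empty(self):
        m = GeneClusterMatrix(genomes=["A", "B"], clusters=["c1"],
                              counts=np.ones((2, 1), int))
        ph = PhenotypeMap(assignments={"A": R, "B": P})
        with pytest.warns(UserWarning, match="no function annotations"):
            assert run_enrichment(m, ph) == []

    def test_score_n_iff_boundary_pattern(self):
        # across 1000 random tables, score == N exactly when presence
        # coincides with a nonempty proper union of whole groups
        rng = np.random.default_rng(3)
        n = np.array([10, 3, 10])
        N = n.sum()
        hits = 0
        for _ in range(1000):
            k = np.array([rng.integers(0, s + 1) for s in n])
            counts = {g: (int(c), int(s)) for g, c, s in zip((R, NP, P), k, n)}
            score = enrichment_score(counts)
            boundary = all(c == 0 or c == s for c, s in zip(k, n)) and 0 < k.sum() < N
            assert (abs(score - N) < 1e-9) == boundary
            hits += boundary
        assert hits > 0
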