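import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drwr import (
    ComplementarityVector,
    OccurrenceMatrix,
    ValidationError,
    exhaustive_optimum,
    random_rankings,
    ranking_from_scores,
    ranking_to_scores,
    rarity_scores,
    rwr,
    zonation_ranking,
)


class TestRarityScores:
    def test_single_cell_species_has_maximum_rarity(self):
        inc = np.zeros((30, 1), dtype=bool)
        inc[4, 0] = True
        occ = OccurrenceMatrix([f"s{i}" for i in range(30)], ["sp1"], inc)
        assert rarity_scores(occ).as_dict()["sp1"] == 1.0

    def test_twenty_cell_species_scores_one_twentieth(self):
        inc = np.zeros((30, 1), dtype=bool)
        inc[:20, 0] = True
        occ = OccurrenceMatrix([f"s{i}" for i in range(30)], ["sp1"], inc)
        assert rarity_scores(occ).as_dict()["sp1"] == 0.05

    def test_matches_inverse_column_sums(self, random_occ):
        occ = random_occ(seed=4, n_sites=50, n_species=30)
        rar = rarity_scores(occ)
        col_sums = occ.incidence.sum(axis=0)
        for sp, r in rar.as_dict().items():
            assert r == 1.0 / col_sums[occ.species.index(sp)]

    def test_zero_occurrence_species_listed_not_scored(self):
        occ = OccurrenceMatrix(
            ["A", "B"], ["sp1", "sp2"], np.array([[1, 0], [1, 0]])
        )
        rar = rarity_scores(occ)
        assert rar.zero_occurrence == ["sp2"]
        assert "sp2" not in rar.as_dict()

    def test_all_species_empty_is_an_error(self):
        occ = OccurrenceMatrix(["A"], ["sp1"], np.array([[0]]))
        with pytest.raises(ValidationError, match="no scorable species"):
            rarity_scores(occ)


class TestRWR:
    def test_worked_example(self, abc_occ):
        vec = rwr(abc_occ)
        assert dict(zip(vec.sites, vec.scores)) == {"A": 1.5, "B": 0.5, "C": 1.0}

    def test_empty_site_scores_zero(self):
        occ = OccurrenceMatrix(
            ["A", "B"], ["sp1"], np.array([[1], [0]])
        )
        assert dict(zip(*[rwr(occ).sites, rwr(occ).scores]))["B"] == 0.0

    def test_matches_double_loop_oracle(self, random_occ):
        occ = random_occ(seed=5, n_sites=40, n_species=25)
        vec = rwr(occ)
        counts = occ.incidence.sum(axis=0)
        for i, site in enumerate(occ.sites):
            expected = sum(
                1.0 / counts[j]
                for j in range(occ.n_species)
                if occ.incidence[i, j] and counts[j] > 0
            )
            assert vec.scores[i] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_total_mass_equals_number_of_occurring_species(self, seed):
        rng = np.random.default_rng(seed)
        n_sites, n_species = rng.integers(2, 40), rng.integers(1, 30)
        inc = rng.random((n_sites, n_species)) < 0.3
        if not inc.any():
            inc[0, 0] = True
        occ = OccurrenceMatrix(
            [f"s{i}" for i in range(n_sites)],
            [f"sp{j}" for j in range(n_species)],
            inc,
        )
        n_occurring = int((inc.sum(axis=0) > 0).sum())
        assert rwr(occ).scores.sum() == pytest.approx(n_occurring, abs=1e-12)


class TestZonationRanking:
    def test_worked_example_removal(self, abc_occ):
        # delta: A=1 (sp1 exclusive), B=0.5, C=1 -> B removed first; the
        # A/C delta tie resolves by rarity mass (A=2 > C=1), so C goes next
        ranking = zonation_ranking(abc_occ)
        assert ranking.order == ["A", "C", "B"]
        assert ranking.prefix_counts.tolist() == [0, 2, 3, 3]

    def test_diagonal_matrix_ranks_by_tie_break(self):
        n = 4
        occ = OccurrenceMatrix(
            [f"s{i}" for i in range(n)], [f"sp{i}" for i in range(n)], np.eye(n)
        )
        ranking = zonation_ranking(occ)
        # all deltas and masses equal: removal follows ascending site ID
        assert ranking.order == ["s3", "s2", "s1", "s0"]
        assert ranking.prefix_counts.tolist() == [0, 1, 2, 3, 4]

    def test_rank_scores_span_unit_interval(self, abc_occ):
        vec = ranking_to_scores(zonation_ranking(abc_occ))
        assert vec.scores.max() == 1.0
        assert vec.scores.min() == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(6, 11))
    def test_top_m_beats_worst_subset_and_nears_optimum(self, seed):
        rng = np.random.default_rng(seed)
        inc = rng.random((12, 6)) < 0.5
        if not inc.any():
            inc[0, 0] = True
        occ = OccurrenceMatrix(
            [f"s{i:02d}" for i in range(12)], [f"sp{j}" for j in range(6)], inc
        )
        ranking = zonation_ranking(occ)
        site_idx = occ.site_index()
        for m in (1, 2, 3):
            top = ranking.prefix_counts[m]
            subset_counts = [
                int(inc[list(combo)].any(axis=0).sum())
                for combo in itertools.combinations(range(12), m)
            ]
            assert top >= min(subset_counts)
            _, opt = exhaustive_optimum(occ, m)
            assert top >= opt - 1

    def test_nested_prefixes_by_construction(self, random_occ):
        occ = random_occ(seed=8, n_sites=15, n_species=6)
        ranking = zonation_ranking(occ)
        for m in range(1, 15):
            assert set(ranking.top(m)) <= set(ranking.top(m + 1))


class TestRankingFromScores:
    def test_descending_score_order(self, abc_occ):
        scores = ComplementarityVector(["A", "B", "C"], [1.5, 0.5, 1.0])
        assert ranking_from_scores(scores, abc_occ).order == ["A", "C", "B"]

    def test_equal_scores_fall_back_to_site_id(self, abc_occ):
        scores = ComplementarityVector(["A", "B", "C"], [1.0, 1.0, 1.0])
        assert ranking_from_scores(scores, abc_occ).order == ["A", "B", "C"]

    def test_agrees_with_reference_stable_sort(self, random_occ):
        occ = random_occ(seed=11, n_sites=30, n_species=5)
        rng = np.random.default_rng(11)
        vals = rng.random(30)
        scores = ComplementarityVector(occ.sites, vals)
        expected = [
            s for s, _ in sorted(zip(occ.sites, vals), key=lambda t: (-t[1], t[0]))
        ]
        assert ranking_from_scores(scores, occ).order == expected

    def test_site_set_mismatch_rejected(self, abc_occ):
        scores = ComplementarityVector(["A", "B"], [1.0, 2.0])
        with pytest.raises(ValidationError, match="different site sets"):
            ranking_from_scores(scores, abc_occ)


class TestRandomRankings:
    def test_single_site_single_rep(self):
        occ = OccurrenceMatrix(["A"], ["sp1"], np.array([[1]]))
        (ranking,) = random_rankings(occ, 1, seed=0)
        assert ranking.order == ["A"]

    def test_seed_determinism(self, random_occ):
        occ = random_occ(seed=12, n_sites=10, n_species=4)
        a = random_rankings(occ, 5, seed=42)
        b = random_rankings(occ, 5, seed=42)
        c = random_rankings(occ, 5, seed=43)
        assert [r.order for r in a] == [r.order for r in b]
        assert [r.order for r in a] != [r.order for r in c]

    def test_diagonal_matrix_mean_coverage_is_exactly_m(self):
        # each site holds one exclusive species, so any m sites give m species
        occ = OccurrenceMatrix(
            [f"s{i}" for i in range(5)], [f"sp{i}" for i in range(5)], np.eye(5)
        )
        reps = random_rankings(occ, 200, seed=12)
        mean = np.mean([r.prefix_counts for r in reps], axis=0)
        assert np.array_equal(mean, np.arange(6))


class TestExhaustiveOptimum:
    def test_worked_example(self, abc_occ):
        subset, count = exhaustive_optimum(abc_occ, 2)
        assert set(subset) == {"A", "C"} and count == 3

    def test_full_set_covers_all_occurring_species(self, random_occ):
        occ = random_occ(seed=9, n_sites=8, n_species=10)
        _, count = exhaustive_optimum(occ, 8)
        assert count == int((occ.incidence.sum(axis=0) > 0).sum())

    def test_matches_set_union_oracle(self, random_occ):
        occ = random_occ(seed=13, n_sites=10, n_species=8)
        subset, count = exhaustive_optimum(occ, 4)
        best = max(
            int(occ.incidence[list(combo)].any(axis=0).sum())
            for combo in itertools.combinations(range(10), 4)
        )
        assert count == best
        rows = [occ.sites.index(s) for s in subset]
        assert int(occ.incidence[rows].any(axis=0).sum()) == best

    def test_guard_refuses_huge_enumerations(self, random_occ):
        occ = random_occ(seed=1, n_sites=60, n_species=5)
        with pytest.raises(ValidationError, match="exceeds the enumeration guard"):
            exhaustive_optimum(occ, 20)
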