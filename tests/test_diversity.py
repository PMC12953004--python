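"""Alpha diversity, rarefaction, Bray-Curtis and taxon aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biocrustnet as bn
from tests.conftest import make_table


class TestShannon:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([10, 10, 10, 10], np.log(4)),
            ([100], 0.0),
            ([5, 3, 2], 1.0297),  # hand computation of -sum p ln p
        ],
    )
    def test_known_values(self, vec, expected):
        assert bn.shannon(vec) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(bn.BiocrustError):
            bn.shannon([0, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=2, max_size=30))
    def test_permutation_invariant_and_bounded_by_uniform(self, vec):
        h = bn.shannon(vec)
        assert h == pytest.approx(bn.shannon(sorted(vec)), abs=1e-12)
        assert -1e-12 <= h <= np.log(len(vec)) + 1e-12
        assert bn.shannon([1] * len(vec)) == pytest.approx(np.log(len(vec)), abs=1e-12)


class TestAce:
    def test_no_rare_taxa_gives_observed_richness(self):
        assert bn.ace([20, 30, 40]) == 3.0

    def test_all_singletons_falls_back_to_chao1(self):
        from skbio.diversity.alpha import chao1

        vec = [1] * 6
        assert bn.ace(vec) == pytest.approx(float(chao1(vec, bias_corrected=True)))

    def test_matches_straight_formula_transcription(self):
        # independent transcription of the classical ACE formula
        def oracle(vec, k=10):
            x = np.array([v for v in vec if v > 0])
            rare = x[x <= k]
            s_ab, s_r, n_r = (x > k).sum(), rare.size, rare.sum()
            f1 = (rare == 1).sum()
            c = 1 - f1 / n_r
            g2 = max(
                (s_r / c)
                * sum(i * (i - 1) * (rare == i).sum() for i in range(1, k + 1))
                / (n_r * (n_r - 1))
                - 1,
                0,
            )
            return s_ab + s_r / c + f1 / c * g2

        for vec in ([1, 1, 2, 3, 11, 15], [1, 2, 2, 5, 9, 10, 40, 3], [2, 4, 6, 8, 12]):
            assert bn.ace(vec) == pytest.approx(oracle(vec), abs=1e-12)

    def test_agrees_with_skbio_on_random_vectors(self):
        from skbio.diversity.alpha import ace as sk_ace

        rng = np.random.default_rng(4)
        for _ in range(10):
            vec = rng.integers(1, 40, size=25)
            assert bn.ace(vec) == pytest.approx(float(sk_ace(vec)), rel=1e-10)


class TestRarefy:
    def test_exact_depth_column_sums(self):
        table = make_table({"a": [800, 700, 500], "b": [1000, 500, 400], "c": [900, 600, 200]})
        out = bn.rarefy(table, 1648, rng_seed=1)
        assert (out.counts.sum(axis=0) == 1648).all()

    def test_sample_at_exact_depth_unchanged(self):
        table = make_table({"a": [100, 48], "b": [200, 100]})
        out = bn.rarefy(table, 148, rng_seed=0)
        assert list(out.counts["a"]) == [100, 48]

    def test_never_increases_counts_and_is_deterministic(self):
        table = make_table({"a": [500, 300, 250], "b": [400, 400, 300]})
        out1 = bn.rarefy(table, 600, rng_seed=9)
        out2 = bn.rarefy(table, 600, rng_seed=9)
        assert out1.counts.equals(out2.counts)
        assert (out1.counts.values <= table.counts.values).all()

    def test_shallow_samples_dropped_or_error(self):
        table = make_table({"a": [10, 10], "b": [500, 500]})
        out = bn.rarefy(table, 100, rng_seed=0)
        assert list(out.samples) == ["b"]
        with pytest.raises(bn.DegenerateInputError):
            bn.rarefy(table, 5000)


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        table = make_table({"a": [1, 2, 0, 0], "b": [1, 2, 0, 0], "c": [0, 0, 3, 4]})
        d = bn.bray_curtis(table)
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        table = make_table({"a": [1, 2, 3], "b": [3, 2, 1]})
        assert bn.bray_curtis(table).loc["a", "b"] == pytest.approx(1 / 3, abs=1e-4)

    def test_symmetry_zero_diagonal_bounds(self):
        rng = np.random.default_rng(0)
        table = make_table({f"s{i}": rng.integers(0, 50, 8) + (1 if i == 0 else 0) for i in range(5)})
        d = bn.bray_curtis(table).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1)).all()


class TestSharedUnique:
    def test_cells_match_set_algebra_oracle(self):
        table = make_table(
            {"a": [5, 0, 1, 2], "b": [3, 4, 0, 2], "c": [0, 6, 0, 2]},
            stages={"a": "G1", "b": "G2", "c": "G3"},
        )
        cells = bn.shared_unique_partition(table)
        assert cells["G1&G2&G3"]["taxa"] == {"t4"}
        assert cells["G1&G2"]["taxa"] == {"t1"}
        assert cells["G2&G3"]["taxa"] == {"t2"}
        assert cells["G1"]["taxa"] == {"t3"}
        # per-group relative abundances over cells sum to 1
        for g in ("G1", "G2", "G3"):
            total = sum(c["rel_abundance"][g] for c in cells.values())
            assert total == pytest.approx(1.0)

    def test_single_group_rejected(self):
        table = make_table({"a": [1], "b": [2]}, stages={"a": "G1", "b": "G1"})
        with pytest.raises(bn.BiocrustError):
            bn.shared_unique_partition(table)


class TestAggregateByRank:
    def test_reads_conserved_and_group_sums(self):
        table = make_table({"a": [5, 3, 2, 1], "b": [1, 1, 1, 1]})
        table.taxon_meta["family"] = ["F1", "F1", "F2", "F2"]
        out = bn.aggregate_by_rank(table, "family")
        assert out.counts.sum(axis=0).equals(table.counts.sum(axis=0))
        assert list(out.counts.loc["F1"]) == [8, 2]
        assert list(out.counts.loc["F2"]) == [3, 2]

    def test_unclassified_pooled_under_parent(self):
        table = make_table({"a": [5, 3]})
        table.taxon_meta.loc["t2", "family"] = ""
        out = bn.aggregate_by_rank(table, "family")
        assert "unclassified O1" in out.counts.index

    def test_unknown_rank_rejected(self):
        with pytest.raises(bn.BiocrustError):
            bn.aggregate_by_rank(make_table({"a": [1]}), "genus")


def test_alpha_diversity_tidy_frame(community_fixture):
    res = bn.alpha_diversity(community_fixture)
    assert set(res.table.columns) == {"sample_id", "stage", "shannon", "ace", "richness"}
    assert len(res.table) == community_fixture.n_samples
    assert (res.table["shannon"] >= 0).all()
    assert (res.table["ace"] >= 1).all()
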