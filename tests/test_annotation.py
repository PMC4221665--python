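import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from morphovar.annotation import (
    GOSet,
    cluster_gos,
    interaction_counts,
    manova_go,
    manova_table,
    mann_whitney,
    read_gmt,
    select_gos,
)


class TestSelectGos:
    GOS = [
        GOSet("GO:1", frozenset({"g1", "g2", "g3", "g4"}), 50),
        GOSet("GO:2", frozenset({"g1", "g2"}), 40),
        GOSet("GO:3", frozenset({"g1", "g2", "g3"}), 150),
    ]

    def test_minimum_three_focal_hits(self):
        chosen = select_gos(self.GOS, {"g1", "g2", "g3"})
        assert [g.go_id for g in chosen] == ["GO:1"]

    def test_genome_annotation_cap(self):
        chosen = select_gos(self.GOS, {"g1", "g2", "g3"}, max_genome=200)
        assert {g.go_id for g in chosen} == {"GO:1", "GO:3"}

    def test_empty_annotation_list(self):
        assert select_gos([], {"g1"}) == []

    def test_invalid_go_sets_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GOSet("GO:X", frozenset(), 10)
        with pytest.raises(ValueError, match="count"):
            GOSet("GO:Y", frozenset({"a", "b"}), 1)

    def test_read_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("GO:1\theat response\tg1\tg2\nGO:2\tpolysome\tg3\tg4\tg5\n")
        gos = read_gmt(path, genome_counts={"GO:1": 30})
        assert gos[0].genome_annotation_count == 30
        assert gos[1].genes == frozenset({"g3", "g4", "g5"})


def _null_design(rng, n_natural=40, n_wt=4, n_member=12, p=3):
    """Natural strains + BY-background wild-type replicates + GO members.

    The membership dummy x marks deletion strains annotated to the GO; the
    background factor s separates natural strains from the BY background,
    which contains both the wild-type reference (x=0) and the deletion
    strains (x=1), so s and x are not collinear.
    """
    n = n_natural + n_wt + n_member
    scores = pd.DataFrame(
        rng.standard_normal((n, p)), columns=["PC1", "PC2", "PC4"][:p]
    )
    background = ["natural"] * n_natural + ["BY"] * (n_wt + n_member)
    x = np.r_[np.zeros(n_natural + n_wt), np.ones(n_member)]
    return scores, background, x


class TestManova:
    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(0)
        scores, background, x = _null_design(rng)
        res = manova_go(scores, background, x, "GO:1")
        df = scores.copy()
        df["s"] = background
        df["x"] = x
        mv = MANOVA.from_formula("PC1 + PC2 + PC4 ~ s + x", data=df).mv_test()
        table = mv.results["x"]["stat"]
        assert res.F_approx == pytest.approx(
            float(table.loc["Pillai's trace", "F Value"]), abs=1e-8
        )
        assert res.p_value == pytest.approx(
            float(table.loc["Pillai's trace", "Pr > F"]), abs=1e-10
        )

    def test_univariate_case_matches_nested_f_oracle(self):
        """Single response: multivariate test reduces to the partial F-test."""
        rng = np.random.default_rng(1)
        scores, background, x = _null_design(rng, p=1)
        res = manova_go(scores, background, x, "GO:1")
        y = scores.iloc[:, 0].to_numpy()
        X0 = np.column_stack([np.ones(len(y)), np.array(background) == "natural"])
        X1 = np.column_stack([X0, x])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return np.sum((y - X @ beta) ** 2)

        f_oracle = (rss(X0) - rss(X1)) / (rss(X1) / (len(y) - X1.shape[1]))
        assert res.F_approx == pytest.approx(f_oracle, abs=1e-8)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(2)
        scores, background, x = _null_design(rng)
        scores.loc[x == 1, "PC1"] += 5.0
        res = manova_go(scores, background, x, "GO:1")
        assert res.p_value < 1e-6

    def test_null_p_values_uniform(self):
        """Membership assigned at random under the null: p ~ Uniform(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(400):
            scores, background, x = _null_design(rng)
            pvals.append(manova_go(scores, background, x).p_value)
        assert kstest(pvals, "uniform").statistic < 0.07

    def test_invariant_to_strain_order(self):
        rng = np.random.default_rng(4)
        scores, background, x = _null_design(rng)
        res1 = manova_go(scores, background, x)
        perm = rng.permutation(len(scores))
        res2 = manova_go(
            scores.iloc[perm], [background[i] for i in perm], x[perm]
        )
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-10)

    def test_constant_membership_rejected(self):
        rng = np.random.default_rng(5)
        scores, background, x = _null_design(rng)
        with pytest.raises(ValueError, match="indistinguishable"):
            manova_go(scores, background, np.zeros(len(x)))

    def test_wilks_agrees_with_pillai_for_one_df_hypothesis(self):
        rng = np.random.default_rng(6)
        scores, background, x = _null_design(rng)
        p1 = manova_go(scores, background, x, statistic="pillai").p_value
        p2 = manova_go(scores, background, x, statistic="wilks").p_value
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_manova_table_bonferroni_over_tested_gos(self):
        rng = np.random.default_rng(7)
        scores, background, x = _null_design(rng)
        scores.index = [f"S{i}" for i in range(len(scores))]
        # deletion strains are the last 12; their deleted genes split 6 / 6
        genes = {f"S{i}": f"gene{i}" for i in range(44, 56)}
        gos = [
            GOSet("GO:A", frozenset(list(genes.values())[:6]), 50),
            GOSet("GO:B", frozenset(list(genes.values())[6:]), 50),
        ]
        out = manova_table(scores, background, genes, gos)
        assert list(out["go_id"]) == ["GO:A", "GO:B"]
        # 40 natural + 4 wild-type rows + the GO's own 6 deletion strains
        assert out["n_strains_used"].iloc[0] == 44 + 6


class TestClusterGos:
    def test_identical_gene_sets_merge_at_zero(self):
        gos = [
            GOSet("GO:1", frozenset({"a", "b"}), 10),
            GOSet("GO:2", frozenset({"a", "b"}), 12),
            GOSet("GO:3", frozenset({"c"}), 10),
        ]
        L = cluster_gos(gos)
        assert L[0, 2] == pytest.approx(0.0)

    def test_disjoint_sets_have_distance_one(self):
        gos = [
            GOSet("GO:1", frozenset({"a"}), 10),
            GOSet("GO:2", frozenset({"b"}), 10),
        ]
        L = cluster_gos(gos)
        assert L[0, 2] == pytest.approx(1.0)

    def test_matches_brute_force_complete_linkage(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(12)]
        gos = [
            GOSet(
                f"GO:{i}",
                frozenset(rng.choice(universe, size=rng.integers(2, 6), replace=False)),
                30,
            )
            for i in range(5)
        ]
        L = cluster_gos(gos)

        # brute-force: repeatedly merge the closest pair of clusters under
        # complete linkage (max pairwise distance), tracking merge heights
        def jacc(a, b):
            return 1 - len(a & b) / len(a | b)

        clusters = {i: {i} for i in range(5)}
        sets = {i: gos[i].genes for i in range(5)}
        heights = []
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(sorted(clusters), 2):
                d = max(
                    jacc(gos[a].genes, gos[b].genes)
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
            d, i, j = best
            heights.append(d)
            clusters[i] = clusters[i] | clusters[j]
            del clusters[j]
        assert np.allclose(sorted(L[:, 2]), sorted(heights))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(15)]
        gos = [
            GOSet(
                f"GO:{i}",
                frozenset(rng.choice(universe, size=4, replace=False)),
                30,
            )
            for i in range(8)
        ]
        L = cluster_gos(gos)
        assert np.all(np.diff(L[:, 2]) >= -1e-12)

    def test_duplicate_go_id_rejected(self):
        gos = [
            GOSet("GO:1", frozenset({"a"}), 10),
            GOSet("GO:1", frozenset({"b"}), 10),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            cluster_gos(gos)


class TestMannWhitney:
    def test_exact_enumeration_for_separated_triplets(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 2/20."""
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        # independent enumeration over all 20 labelings
        pooled = [1, 2, 3, 4, 5, 6]
        us = []
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            us.append(sum(1 for x in a for y in b if x > y))
        observed = 0
        extreme = sum(1 for u_ in us if min(u_, 9 - u_) <= min(observed, 9 - observed))
        assert extreme / len(us) == pytest.approx(p)

    def test_identical_groups_not_significant(self):
        _, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p >= 0.9

    def test_symmetry_of_two_sided_p(self):
        rng = np.random.default_rng(10)
        a, b = rng.standard_normal(15), rng.standard_normal(12) + 0.5
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(b, a)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_large_sample_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            _, p = mann_whitney(rng.standard_normal(30), rng.standard_normal(30))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    @given(
        st.lists(st.integers(0, 100), min_size=1, max_size=8),
        st.lists(st.integers(0, 100), min_size=1, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_p_in_unit_interval(self, a, b):
        _, p = mann_whitney(a, b)
        assert 0 < p <= 1


class TestInteractionCounts:
    RECORDS = pd.DataFrame(
        {
            "gene_a": ["a", "a", "b", "c"],
            "gene_b": ["b", "c", "c", "d"],
            "epsilon": [-0.15, 0.10, 0.20, -0.15],
            "p": [0.01, 0.001, 0.01, 0.20],
        }
    )

    def test_stringent_cutoffs(self):
        counts = interaction_counts(self.RECORDS, ["a", "b", "c", "d"])
        # a-b: negative significant; a-c: between cutoffs; b-c: positive
        # significant; c-d: not significant (p too large)
        assert counts.to_dict() == {"a": 1, "b": 2, "c": 1, "d": 0}

    def test_empty_records(self):
        counts = interaction_counts(self.RECORDS.iloc[:0], ["a", "b"])
        assert (counts == 0).all()
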