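from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from agetraj.enrich import (
    EnrichmentTable,
    fisher_2x2,
    hypergeom_enrich,
    intersect_term_lists,
    kappa_group,
)
from agetraj.io import GeneSetCollection


def _coll(**sets) -> GeneSetCollection:
    c = GeneSetCollection()
    for name, members in sets.items():
        c.add(name, members)
    return c


def enumeration_p(N, K, n, k) -> float:
    """Exhaustive oracle: fraction of n-draws from the urn with overlap >= k."""
    universe = list(range(N))
    special = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomEnrich:
    def test_exact_value_against_hand_count(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
        bg = [f"g{i}" for i in range(10)]
        sets = _coll(S=set(bg[:5]))
        res = hypergeom_enrich(bg[:4], sets, bg)
        assert res.table.loc["S", "p"] == pytest.approx(5 / 210, abs=1e-12)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 4), (12, 6, 5), (15, 7, 6)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        bg = [f"g{i}" for i in range(N)]
        sets = _coll(S=set(bg[:K]))
        query = bg[:n]  # maximal overlap k=min(K,n)... vary by shifting
        for shift in range(3):
            q = bg[shift : shift + n]
            k = len(set(q) & set(bg[:K]))
            res = hypergeom_enrich(q, sets, bg)
            assert res.table.loc["S", "p"] == pytest.approx(
                enumeration_p(N, K, n, k), abs=1e-12
            )

    def test_query_equals_background_is_null(self):
        bg = [f"g{i}" for i in range(12)]
        sets = _coll(A=set(bg[:4]), B=set(bg[4:9]))
        res = hypergeom_enrich(bg, sets, bg)
        assert (res.table["fold"] == 1.0).all()
        assert (res.table["p"] == 1.0).all()

    def test_fold_one_at_expected_overlap(self):
        bg = [f"g{i}" for i in range(20)]
        sets = _coll(S=set(bg[:10]))  # K/N = 1/2
        query = bg[:2] + bg[10:12]  # n=4, k=2 = n*K/N
        res = hypergeom_enrich(query, sets, bg)
        assert res.table.loc["S", "fold"] == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        from scipy.stats import hypergeom

        ps = [float(hypergeom.sf(k - 1, 30, 10, 8)) for k in range(0, 9)]
        assert all(p2 <= p1 + 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_set_outside_background_skipped_and_errors(self):
        bg = ["g1", "g2", "g3"]
        sets = _coll(IN={"g1"}, OUT={"x1", "x2"})
        res = hypergeom_enrich(["g1"], sets, bg)
        assert res.skipped == ["OUT"]
        with pytest.raises(ValueError):
            hypergeom_enrich([], sets, bg)
        with pytest.raises(ValueError, match="outside background"):
            hypergeom_enrich(["zz"], sets, bg)


class TestFisher:
    def test_hand_computed_two_sided(self):
        # ((4,0),(0,4)): 2 extreme tables of the C(8,4)=70 -> p = 2/70
        assert fisher_2x2([[4, 0], [0, 4]]) == pytest.approx(2 / 70, abs=1e-12)

    def test_identical_row_proportions_give_one(self):
        assert fisher_2x2([[5, 10], [10, 20]]) == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert fisher_2x2([[0, 0], [3, 4]]) == 1.0

    def test_upper_tail_equals_hypergeom_urn(self):
        from scipy.stats import fisher_exact, hypergeom

        # one-sided Fisher on ((k, n-k), (K-k, N-K-n+k)) is the same urn
        N, K, n, k = 12, 5, 4, 3
        table = [[k, n - k], [K - k, N - K - n + k]]
        p_one = fisher_exact(table, alternative="greater")[1]
        assert p_one == pytest.approx(float(hypergeom.sf(k - 1, N, K, n)), abs=1e-12)


class TestKappaGroup:
    def _enriched(self, sets, bg, query):
        return hypergeom_enrich(query, sets, bg)

    def test_identical_sets_form_one_group_with_kappa_one(self):
        bg = [f"g{i}" for i in range(30)]
        sets = _coll(A=set(bg[:6]), B=set(bg[:6]))
        res = self._enriched(sets, bg, bg[:6])
        groups, kmat = kappa_group(res, sets, bg, q_threshold=0.5)
        assert len(groups) == 1 and set(groups[0].members) == {"A", "B"}
        assert kmat.loc["A", "B"] == pytest.approx(1.0)

    def test_disjoint_small_sets_stay_separate(self):
        bg = [f"g{i}" for i in range(100)]
        sets = _coll(A=set(bg[:5]), B=set(bg[50:55]))
        res = self._enriched(sets, bg, bg[:5] + bg[50:55])
        groups, kmat = kappa_group(res, sets, bg, q_threshold=0.5)
        assert len(groups) == 2
        assert abs(kmat.loc["A", "B"]) < 0.1

    def test_single_linkage_chains_a_b_c(self):
        bg = [f"g{i}" for i in range(40)]
        # A~B and B~C overlap heavily; A and C share nothing
        sets = _coll(
            A=set(bg[0:10]),
            B=set(bg[5:15]),
            C=set(bg[10:20]),
        )
        res = self._enriched(sets, bg, bg[0:20])
        groups, kmat = kappa_group(res, sets, bg, q_threshold=1.1, kappa_threshold=0.3)
        assert kmat.loc["A", "B"] >= 0.3 and kmat.loc["B", "C"] >= 0.3
        assert kmat.loc["A", "C"] < 0.3
        assert len(groups) == 1 and set(groups[0].members) == {"A", "B", "C"}

    def test_group_output_invariant_to_input_order(self):
        bg = [f"g{i}" for i in range(40)]
        sets1 = _coll(A=set(bg[:8]), B=set(bg[4:12]), Z=set(bg[30:36]))
        sets2 = _coll(Z=set(bg[30:36]), B=set(bg[4:12]), A=set(bg[:8]))
        q = bg[:12] + bg[30:36]
        g1, _ = kappa_group(self._enriched(sets1, bg, q), sets1, bg, q_threshold=1.1)
        g2, _ = kappa_group(self._enriched(sets2, bg, q), sets2, bg, q_threshold=1.1)
        assert [(g.representative, tuple(g.members)) for g in g1] == [
            (g.representative, tuple(g.members)) for g in g2
        ]

    def test_representative_has_largest_overlap(self):
        bg = [f"g{i}" for i in range(30)]
        sets = _coll(BIG=set(bg[:10]), SMALL=set(bg[:4]))
        res = self._enriched(sets, bg, bg[:10])
        groups, _ = kappa_group(res, sets, bg, q_threshold=1.1, kappa_threshold=0.3)
        grp = next(g for g in groups if "BIG" in g.members)
        assert grp.representative == "BIG"


class TestRecoveryOnSimulatedSets:
    def test_archetype_sets_enriched_and_random_sets_quiet(self):
        from agetraj.simulate import SimConfig, simulate, simulate_gene_sets

        _, _, truth = simulate(SimConfig(seed=800))
        sets = simulate_gene_sets(truth, n_random_sets=50, seed=800)
        bg = truth.gene_ids
        archetypes = ("linear_up", "linear_down", "rapid_decay", "u_shape", "bell_shape")
        recovered, false_positives = 0, []
        for a in archetypes:
            res = hypergeom_enrich(truth.genes_of(a), sets, bg)
            sig = res.significant(0.05)
            recovered += f"SET_{a}" in sig
            false_positives.append(sum(1 for s in sig if s.startswith("RANDOM_")))
        assert recovered / len(archetypes) >= 0.9
        # BH at 0.05 over 50 null sets: expected false positives <= 2.5
        assert float(np.mean(false_positives)) <= 2.5


class TestIntersectTermLists:
    def _table(self, sig_names, all_names):
        rows = []
        for name in all_names:
            q = 0.01 if name in sig_names else 0.5
            rows.append({"set_name": name, "N": 10, "K": 2, "n": 2, "k": 1,
                         "p": q, "q": q, "fold": 1.0})
        return EnrichmentTable(table=pd.DataFrame(rows).set_index("set_name"), skipped=[])

    def test_identical_lists_give_100pct(self):
        names = [f"s{i}" for i in range(1, 6)]
        t = self._table(names[:3], names)
        out = intersect_term_lists(t, t)
        assert out.loc["all", "pct_of_b"] == pytest.approx(100.0)

    def test_disjoint_lists_give_0pct(self):
        names = [f"s{i}" for i in range(1, 9)]
        a = self._table(names[:3], names)
        b = self._table(names[3:6], names)
        assert intersect_term_lists(a, b).loc["all", "pct_of_b"] == 0.0

    def test_hand_counted_partial_overlap(self):
        names = [f"s{i}" for i in range(1, 9)]
        a = self._table(["s1", "s2", "s3", "s4"], names)
        b = self._table(["s3", "s4", "s5", "s6", "s7", "s8"], names)
        out = intersect_term_lists(a, b)
        assert out.loc["all", "n_intersection"] == 2
        assert out.loc["all", "pct_of_b"] == pytest.approx(100 * 2 / 6, abs=0.05)

    def test_disjoint_namespaces_are_an_error(self):
        a = self._table(["x1"], ["x1", "x2"])
        b = self._table(["y1"], ["y1", "y2"])
        with pytest.raises(ValueError):
            intersect_term_lists(a, b)
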