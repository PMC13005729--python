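import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enrichclust import (
    ClusterAssignment,
    ConsistencyError,
    DomainError,
    FormatError,
    PoolingSpec,
    apply_annotations,
    build_annotation_prompt,
    cap_pvalue,
    parse_annotation_reply,
    pool_pvalues,
    summarize_clusters,
    term_coherence,
)
from test_enrich import make_hit

# closed form for Fisher on two p = 0.5: chi2(4) survival = e^{-x/2}(1 + x/2)
X = -2.0 * math.log(0.25)
FISHER_HALF_HALF = math.exp(-X / 2) * (1 + X / 2)  # 0.596574...


class TestPoolPvalues:
    @pytest.mark.parametrize("p", [0.001, 0.05, 0.3, 0.9, 1.0])
    def test_singleton_identity_all_methods(self, p):
        for method in ("fisher", "stouffer", "weighted_z", "cauchy"):
            pooled = pool_pvalues([p], method, weights=[2.5])
            assert pooled == pytest.approx(p, rel=1e-9)

    def test_fisher_two_halves_closed_form(self):
        assert pool_pvalues([0.5, 0.5], "fisher") == pytest.approx(
            FISHER_HALF_HALF, abs=1e-9
        )
        assert FISHER_HALF_HALF == pytest.approx(0.596574, abs=1e-6)

    def test_stouffer_halves(self):
        assert pool_pvalues([0.5, 0.5], "stouffer") == pytest.approx(0.5, abs=1e-12)

    def test_cauchy_halves(self):
        assert pool_pvalues([0.5, 0.5, 0.5], "cauchy") == pytest.approx(
            0.5, abs=1e-12
        )

    def test_weighted_z_equal_weights_is_stouffer(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            ps = rng.uniform(1e-6, 1.0, size=int(rng.integers(2, 12)))
            w = np.full(ps.size, 3.7)
            assert pool_pvalues(ps, "weighted_z", weights=w) == pytest.approx(
                pool_pvalues(ps, "stouffer"), abs=1e-12
            )

    def test_cauchy_small_p_linear_regime(self):
        # with one tiny p among (k-1) halves, T ~ tan((0.5-p)pi)/k ~ 1/(pi p k)
        # and the pooled value approaches k * p_min
        p_min = 1e-12
        for k in (2, 5, 10):
            ps = [p_min] + [0.5] * (k - 1)
            pooled = pool_pvalues(ps, "cauchy")
            assert pooled == pytest.approx(k * p_min, rel=0.1)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=10),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_permutation_invariance(self, ps, rnd):
        w = [1.0 + i for i in range(len(ps))]
        paired = list(zip(ps, w))
        rnd.shuffle(paired)
        ps2, w2 = zip(*paired)
        for method in ("fisher", "stouffer", "weighted_z", "cauchy"):
            assert pool_pvalues(list(ps2), method, weights=list(w2)) == pytest.approx(
                pool_pvalues(ps, method, weights=w), abs=1e-12
            )

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            pool_pvalues([], "fisher")
        with pytest.raises(DomainError):
            pool_pvalues([0.0, 0.5], "fisher")
        with pytest.raises(DomainError):
            pool_pvalues([0.5], "median_of_means")


class TestCapPvalue:
    @pytest.mark.parametrize(
        "p,floor,expected",
        [(1e-40, 1e-30, 1e-30), (0.02, 1e-30, 0.02), (1e-10, 1e-10, 1e-10)],
    )
    def test_cap(self, p, floor, expected):
        assert cap_pvalue(p, floor) == expected

    def test_bad_floor(self):
        with pytest.raises(DomainError):
            cap_pvalue(0.5, 0.0)


def assignment_for(*term_groups):
    labels = {}
    for cid, terms in enumerate(term_groups, start=1):
        for t in terms:
            labels[t] = cid
    return ClusterAssignment(labels=labels, modularity_value=0.0)


class TestSummarizeClusters:
    def test_singleton_cluster_identity_under_fisher(self):
        hits = [make_hit(term="T", padj=0.03)]
        rows = summarize_clusters(
            hits, assignment_for(["T"]), PoolingSpec(method="fisher")
        )
        assert rows[0].pooled_p == pytest.approx(0.03, rel=1e-9)

    def test_two_halves_under_fisher(self):
        hits = [
            make_hit(term="T1", padj=0.5, p=0.4),
            make_hit(term="T2", padj=0.5, p=0.4),
        ]
        rows = summarize_clusters(
            hits, assignment_for(["T1", "T2"]), PoolingSpec(method="fisher")
        )
        assert rows[0].pooled_p == pytest.approx(FISHER_HALF_HALF, abs=1e-9)
        assert rows[0].n_terms_here == 2

    def test_absent_condition_has_no_row(self):
        hits = [make_hit(term="T1", cond="A"), make_hit(term="T2", cond="B")]
        rows = summarize_clusters(hits, assignment_for(["T1"], ["T2"]))
        keys = {(r.cluster_id, r.condition) for r in rows}
        assert keys == {(1, "A"), (2, "B")}

    def test_duplicate_term_across_databases_collapsed(self):
        h1 = make_hit(term="T", db="lib1", padj=0.01, k=2)
        h2 = make_hit(term="T", db="lib2", padj=0.04, k=3)
        rows = summarize_clusters(
            [h1, h2], assignment_for(["T"]), PoolingSpec(method="fisher")
        )
        # collapsed to one entry with the minimum adjusted p
        assert rows[0].n_terms_here == 1
        assert rows[0].pooled_p == pytest.approx(0.01, rel=1e-9)
        assert rows[0].n_genes == 3  # union of overlap genes

    def test_n_terms_total_vs_here(self):
        hits = [
            make_hit(term="T1", cond="A"),
            make_hit(term="T2", cond="A"),
            make_hit(term="T1", cond="B"),
        ]
        rows = summarize_clusters(hits, assignment_for(["T1", "T2"]))
        by_cond = {r.condition: r for r in rows}
        assert by_cond["A"].n_terms_total == 2
        assert by_cond["A"].n_terms_here == 2
        assert by_cond["B"].n_terms_here == 1
        assert by_cond["B"].n_terms_total == 2

    def test_pooled_p_within_floor_bounds(self):
        spec = PoolingSpec(method="fisher", floor=1e-4)
        hits = [make_hit(term=f"T{i}", padj=1e-6) for i in range(5)]
        rows = summarize_clusters(
            hits, assignment_for([f"T{i}" for i in range(5)]), spec
        )
        assert rows[0].pooled_p >= spec.floor

    def test_missing_term_in_assignment(self):
        with pytest.raises(ConsistencyError):
            summarize_clusters([make_hit(term="T")], assignment_for(["OTHER"]))


class TestAnnotationRoundTrip:
    def test_prompt_contains_each_cluster_and_term_once(self):
        hits = [make_hit(term="Alpha"), make_hit(term="Beta"), make_hit(term="Gamma")]
        a = assignment_for(["Alpha", "Beta"], ["Gamma"])
        prompt = build_annotation_prompt(a, hits)
        for needle in ("Cluster 1:", "Cluster 2:", "Alpha", "Beta", "Gamma"):
            assert prompt.count(needle) == 1

    def test_prompt_deterministic(self):
        hits = [make_hit(term=t) for t in ("A", "B", "C")]
        a = assignment_for(["A", "B", "C"])
        assert build_annotation_prompt(a, hits) == build_annotation_prompt(a, hits)

    def test_large_term_lists_chunked(self):
        terms = [f"Term{i:04d}" for i in range(450)]
        a = assignment_for(*[[t] for t in terms])
        prompt = build_annotation_prompt(a, [])
        assert "Part 1 of 3" in prompt and "Part 3 of 3" in prompt
        for part in prompt.split("=== Part")[1:]:
            assert part.count("- Term") <= 200

    def test_detailed_style_lists_databases(self):
        hits = [make_hit(term="Alpha", db="GO"), make_hit(term="Alpha", db="Reactome", cond="B")]
        prompt = build_annotation_prompt(assignment_for(["Alpha"]), hits, style="detailed")
        assert "[GO,Reactome]" in prompt

    def test_parse_reply(self):
        amap = parse_annotation_reply(
            "1\tECM organization\n\n2\tInterferon response\n"
        )
        assert amap.labels == {1: "ECM organization", 2: "Interferon response"}

    def test_parse_reports_unknown_ids(self):
        amap = parse_annotation_reply("1\tX\n99\tY\n", known_ids=[1, 2])
        assert amap.unknown_ids == (99,)

    def test_parse_no_lines_errors(self):
        with pytest.raises(FormatError):
            parse_annotation_reply("no tabs here\n")

    def test_apply_and_overwrite(self):
        hits = [make_hit(term="T1"), make_hit(term="T2", cond="B")]
        rows = summarize_clusters(hits, assignment_for(["T1"], ["T2"]))
        labeled = apply_annotations(rows, {1: "X"})
        by_cluster = {r.cluster_id: r.annotation for r in labeled}
        assert by_cluster == {1: "X", 2: "Cluster 2"}
        relabeled = apply_annotations(labeled, {1: "Y", 2: "Z"})
        assert {r.annotation for r in relabeled} == {"Y", "Z"}

    def test_empty_map_all_placeholders(self):
        rows = summarize_clusters([make_hit(term="T")], assignment_for(["T"]))
        assert apply_annotations(rows, {})[0].annotation == "Cluster 1"


class TestCoherence:
    def test_hand_example(self):
        m = {"A": frozenset({"g1", "g2"}), "B": frozenset({"g1", "g2", "g3"})}
        rep = term_coherence(m, assignment_for(["A", "B"]))
        vals = dict(zip(rep.per_term["term"], rep.per_term["jaccard_vs_rest"]))
        assert vals["A"] == pytest.approx(2 / 3)
        assert vals["B"] == pytest.approx(2 / 3)
        assert rep.mean_jaccard == pytest.approx(2 / 3)

    def test_all_singletons_mean_absent(self):
        m = {"A": frozenset({"g1"}), "B": frozenset({"g2"})}
        rep = term_coherence(m, assignment_for(["A"], ["B"]))
        assert rep.mean_jaccard is None
        assert rep.per_term["jaccard_vs_rest"].isna().all()

    def test_duplicate_gene_sets_give_one(self):
        m = {"A": frozenset({"g1", "g2"}), "B": frozenset({"g1", "g2"})}
        rep = term_coherence(m, assignment_for(["A", "B"]))
        assert (rep.per_term["jaccard_vs_rest"] == 1.0).all()

    def test_true_partition_beats_random_relabelings(self, planted):
        library, _, truth = planted
        m = dict(library.sets)
        true_labels = truth.term_labels()
        a_true = ClusterAssignment(labels=true_labels, modularity_value=0.0)
        true_mean = term_coherence(m, a_true).mean_jaccard
        sizes = [len(t) for t in truth.blocks.values()]
        terms = sorted(m)
        rng = np.random.default_rng(123)
        wins = 0
        for _ in range(100):
            perm = rng.permutation(terms)
            labels, i = {}, 0
            for cid, size in enumerate(sizes, start=1):
                for t in perm[i : i + size]:
                    labels[t] = cid
                i += size
            rand_mean = term_coherence(
                m, ClusterAssignment(labels=labels, modularity_value=0.0)
            ).mean_jaccard
            if true_mean > rand_mean:
                wins += 1
        assert wins >= 99
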