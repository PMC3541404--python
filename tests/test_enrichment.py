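import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    bh_oracle,
    empirical_p_bounds,
    empirical_p_oracle,
    es_oracle,
    sum_oracle,
    sumsq_oracle,
)
from asmpath.asm_weighting import pathway_weights
from asmpath.errors import ConfigError, ContractError
from asmpath.enrichment import (
    MODES,
    METHODS,
    MethodStat,
    PathwayResult,
    analyze_pathways,
    apply_weights,
    bh_adjust,
    enrichment_score,
    filter_pathways_by_size,
    permutation_pvalues,
    significant_pathways,
    sum_square_statistic,
    sum_statistic,
)
from asmpath.gene_scoring import GeneAssignment
from asmpath.io_formats import Pathway
from conftest import make_pathway


class TestFilterPathwaysBySize:
    def test_boundaries(self):
        mapped = [f"g{i}" for i in range(400)]
        sizes = {"P9": 9, "P10": 10, "P380": 380, "P381": 381}
        pathways = [make_pathway(n, [f"g{i}" for i in range(k)]) for n, k in sizes.items()]
        kept = filter_pathways_by_size(pathways, mapped, 10, 380)
        assert {p.name for p in kept} == {"P10", "P380"}

    def test_mapped_not_database_size(self):
        # 200 genes in the database but only 8 on the mapped list -> removed
        pw = make_pathway("P", [f"db{i}" for i in range(192)] + [f"g{i}" for i in range(8)])
        assert filter_pathways_by_size([pw], [f"g{i}" for i in range(8)], 10, 380) == []

    def test_empty_input(self):
        assert filter_pathways_by_size([], ["g1"], 10, 380) == []


class TestApplyWeights:
    def test_multiplication(self):
        w = pathway_weights(4, 4, 2, 1)  # weights 1.5 / 0.75
        out = apply_weights({"A": 4.0, "B": 2.0}, {"A": True, "B": False}, w)
        assert out == {"A": 6.0, "B": 1.5}

    def test_identity_weights(self):
        w = pathway_weights(5, 5, 1, 1)
        scores = {"A": 4.0, "B": 2.0}
        assert apply_weights(scores, {"A": True, "B": False}, w) == scores

    def test_zero_scores(self):
        w = pathway_weights(4, 4, 2, 1)
        out = apply_weights({"A": 0.0, "B": 0.0}, {"A": True, "B": False}, w)
        assert out == {"A": 0.0, "B": 0.0}

    def test_unlabeled_gene(self):
        w = pathway_weights(4, 4, 2, 1)
        with pytest.raises(ContractError):
            apply_weights({"A": 1.0}, {}, w)


class TestEnrichmentScore:
    def test_hand_running_sum(self):
        scores = {"a": 9.0, "b": 4.0, "c": 1.0, "d": 0.0}
        members = {"a", "c"}
        es = enrichment_score(members, scores, {g: scores[g] for g in members})
        assert es == pytest.approx(0.9)

    def test_single_nonzero_member(self):
        scores = {"a": 5.0, "b": 0.0, "c": 0.0}
        es = enrichment_score({"a"}, scores, {"a": 5.0})
        assert es == pytest.approx(1.0)

    def test_all_members_rejected(self):
        scores = {"a": 1.0, "b": 2.0}
        with pytest.raises(ContractError):
            enrichment_score({"a", "b"}, scores, scores)

    def test_degenerate_zero_mass(self):
        scores = {"a": 0.0, "b": 1.0}
        assert enrichment_score({"a"}, scores, {"a": 0.0}) == 0.0

    def test_range_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            scores = {f"g{i}": float(v) for i, v in enumerate(rng.random(n) * 10)}
            members = set(list(scores)[: int(rng.integers(1, n - 1))])
            mw = {g: scores[g] for g in members}
            es = enrichment_score(members, scores, mw)
            assert -1.0 < es <= 1.0
            scaled = {g: 3.7 * v for g, v in scores.items()}
            mw_scaled = {g: scaled[g] for g in members}
            assert enrichment_score(members, scaled, mw_scaled) == pytest.approx(es)


class TestSumStatistics:
    def test_sum(self):
        assert sum_statistic({"a": 6.0, "b": 1.5, "c": 0.0}) == pytest.approx(7.5)

    def test_sum_square(self):
        assert sum_square_statistic({"a": 6.0, "b": 1.5, "c": 0.0}) == pytest.approx(38.25)

    def test_single_member_relation(self):
        x = 3.3
        assert sum_square_statistic({"a": x}) == pytest.approx(sum_statistic({"a": x}) ** 2)

    def test_strictly_increasing_in_member_score(self):
        base = {"a": 1.0, "b": 2.0}
        bumped = {"a": 1.5, "b": 2.0}
        assert sum_statistic(bumped) > sum_statistic(base)
        assert sum_square_statistic(bumped) > sum_square_statistic(base)

    def test_empty_contract(self):
        with pytest.raises(ContractError):
            sum_statistic({})


class TestBhAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.005, 0.1, 0.9]) == pytest.approx([0.015, 0.15, 0.9])

    def test_equal_inputs_fixed_point(self):
        assert bh_adjust([0.04] * 4) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            ps = rng.random(int(rng.integers(1, 40))).clip(1e-9, 1.0)
            assert bh_adjust(ps) == pytest.approx(bh_oracle(list(ps)))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        ps = rng.random(50).clip(1e-9, 1.0)
        expected = multipletests(ps, method="fdr_bh")[1]
        assert bh_adjust(ps) == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_never_below_raw_and_rank_monotone(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_domain(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


def _fake_result(name, bh_by_key):
    r = PathwayResult(name, "GO", 10, 10, 0.0, pathway_weights(5, 5, 0, 0))
    for key, bh in bh_by_key.items():
        r.stats[key] = MethodStat(1.0, bh / 2 if bh < 1 else bh, bh)
    return r


class TestSignificantPathways:
    def test_trigger_recorded(self):
        r = _fake_result("P", {("sumst", "weighted"): 0.009, ("gsea", "weighted"): 0.5})
        selected = significant_pathways([r], 0.01)
        assert selected == [(r, [("sumst", "weighted")])]

    def test_none_selected(self):
        r = _fake_result("P", {("sumst", "weighted"): 0.011})
        assert significant_pathways([r], 0.01) == []

    def test_threshold_zero_rejected(self):
        with pytest.raises(ConfigError):
            significant_pathways([], 0.0)


def _make_assignments(scores, informative, is_asm):
    out = []
    for i, (s, f, a) in enumerate(zip(scores, informative, is_asm)):
        out.append(
            GeneAssignment(
                gene_id=f"g{i:03d}", snp_ids=["x"], asm_snp_ids=[], is_asm=bool(a),
                asm_route="asm_snp_in_gene" if a else "none", n_snps=1,
                n_significant_snps=int(f), prop_significant=float(f), min_p=0.5,
                min_p_all=0.5, representative_snp="x", adjusted_p=0.5,
                gene_score=float(s), is_informative=bool(f),
            )
        )
    return out


class TestAnalyzePathways:
    def _random_instance(self, rng, n_genes=None):
        n = n_genes or int(rng.integers(8, 20))
        scores = rng.random(n) * 8
        informative = rng.random(n) < 0.3
        is_asm = rng.random(n) < 0.4
        assigns = _make_assignments(scores, informative, is_asm)
        k = int(rng.integers(2, max(3, n // 2)))
        members = rng.choice(n, size=k, replace=False)
        pw = make_pathway("PW", [f"g{i:03d}" for i in members])
        return assigns, pw

    def test_observed_stats_match_straightline_oracles(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            assigns, pw = self._random_instance(rng)
            res = analyze_pathways(assigns, [pw], B=100, seed=0)[0]
            scores = {a.gene_id: a.gene_score for a in assigns}
            labels = {a.gene_id: a.is_asm for a in assigns}
            members = {g for g in pw.gene_ids}
            w = res.weights
            for mode in MODES:
                if mode == "weighted":
                    mw = apply_weights({g: scores[g] for g in members}, labels, w)
                else:
                    mw = {g: scores[g] for g in members}
                assert res.stats[("gsea", mode)].raw_stat == pytest.approx(
                    es_oracle(members, scores, mw), abs=1e-12)
                assert res.stats[("sumst", mode)].raw_stat == pytest.approx(
                    sum_oracle(mw), abs=1e-9)
                assert res.stats[("sumsq", mode)].raw_stat == pytest.approx(
                    sumsq_oracle(mw), abs=1e-9)

    def test_empirical_p_add_one(self):
        # observed 5 against permuted {1,2,3,10} -> (1+1)/(4+1)
        assert empirical_p_oracle(5, [1, 2, 3, 10]) == pytest.approx(0.4)

    def test_empirical_p_floor(self):
        rng = np.random.default_rng(5)
        assigns, pw = self._random_instance(rng, n_genes=15)
        # give members overwhelming scores so no permutation beats observed
        for a in assigns:
            a.gene_score = 1000.0 if a.gene_id in pw.gene_ids else 0.001
        res = analyze_pathways(assigns, [pw], B=200, seed=1)[0]
        assert res.stats[("sumst", "unweighted")].empirical_p == pytest.approx(1 / 201)

    def test_pvalue_invariants(self, small_null_bundle):
        from asmpath import gene_scoring, io_formats

        b = small_null_bundle
        pairs = io_formats.filter_asm_pairs(b.asm_pairs)
        assigns = gene_scoring.score_genes(b.snps, b.genes, pairs, score_perms=1000, seed=0)
        tested = filter_pathways_by_size(b.pathways, [a.gene_id for a in assigns], 10, 380)
        results = analyze_pathways(assigns, tested, B=200, seed=0)
        for r in results:
            assert 0 <= r.pct_asm <= 100
            assert r.genes_on_list <= r.total_genes
            for s in r.stats.values():
                assert s.empirical_p >= 1 / 201
                assert s.bh_p >= s.empirical_p - 1e-12

    def test_weighted_equals_unweighted_when_weights_unit(self):
        rng = np.random.default_rng(8)
        scores = rng.random(12) * 5
        informative = np.zeros(12, dtype=bool)  # k_n = k_m = 0 -> equal weights
        is_asm = rng.random(12) < 0.5
        assigns = _make_assignments(scores, informative, is_asm)
        pw = make_pathway("PW", [f"g{i:03d}" for i in range(4)])
        res = analyze_pathways(assigns, [pw], B=100, seed=2)[0]
        for method in METHODS:
            assert res.stats[(method, "weighted")].raw_stat == pytest.approx(
                res.stats[(method, "unweighted")].raw_stat)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        assigns, pw = self._random_instance(rng)
        r1 = analyze_pathways(assigns, [pw], B=150, seed=7)[0]
        r2 = analyze_pathways(assigns, [pw], B=150, seed=7)[0]
        for key in r1.stats:
            assert r1.stats[key].empirical_p == r2.stats[key].empirical_p

    def test_weighting_mode_off_and_on(self):
        rng = np.random.default_rng(10)
        assigns, pw = self._random_instance(rng)
        off = analyze_pathways(assigns, [pw], B=100, seed=0, weighting="off")[0]
        on = analyze_pathways(assigns, [pw], B=100, seed=0, weighting="on")[0]
        assert set(off.stats) == {(m, "unweighted") for m in METHODS}
        assert set(on.stats) == {(m, "weighted") for m in METHODS}

    def test_b_too_small_rejected(self):
        rng = np.random.default_rng(11)
        assigns, pw = self._random_instance(rng)
        with pytest.raises(ConfigError):
            analyze_pathways(assigns, [pw], B=50, seed=0)

    def test_permutation_pvalues_wrapper(self):
        rng = np.random.default_rng(12)
        assigns, pw = self._random_instance(rng)
        ps = permutation_pvalues(assigns, [pw], B=100, seed=3)
        assert set(ps) == {("PW", m, mode) for m in METHODS for mode in MODES}
        assert all(0 < v <= 1 for v in ps.values())


class TestPermutationOracle:
    """Full permutation-path equivalence against a straight-line oracle."""

    def test_small_instances_match(self):
        rng = np.random.default_rng(77)
        for trial in range(20):
            n = int(rng.integers(6, 12))
            scores = np.round(rng.random(n) * 5, 3)
            informative = rng.random(n) < 0.4
            is_asm = rng.random(n) < 0.5
            assigns = _make_assignments(scores, informative, is_asm)
            k = int(rng.integers(2, n - 1))
            member_ids = {f"g{i:03d}" for i in rng.choice(n, size=k, replace=False)}
            pw = make_pathway("PW", member_ids)
            B = 100
            res = analyze_pathways(assigns, [pw], B=B, seed=trial)[0]

            # oracle: replay the same permutation stream
            gene_ids = sorted(a.gene_id for a in assigns)
            s_map = {a.gene_id: a.gene_score for a in assigns}
            f_map = {a.gene_id: a.is_informative for a in assigns}
            a_map = {a.gene_id: a.is_asm for a in assigns}
            s_vec = np.array([s_map[g] for g in gene_ids])
            f_vec = np.array([f_map[g] for g in gene_ids])
            prng = np.random.default_rng([trial, 21])
            perm_stats = {key: [] for key in res.stats}

            def oracle_stats(ps_map, pf_map):
                n_a = sum(1 for g in member_ids if a_map[g])
                m_a = len(member_ids) - n_a
                k_n = sum(1 for g in member_ids if a_map[g] and pf_map[g])
                k_m = sum(1 for g in member_ids if not a_map[g] and pf_map[g])
                w = pathway_weights(n_a, m_a, k_n, k_m)
                out = {}
                for mode in MODES:
                    if mode == "weighted":
                        mw = {g: float(w.w_asm if a_map[g] else w.w_nonasm) * ps_map[g]
                              for g in member_ids}
                    else:
                        mw = {g: ps_map[g] for g in member_ids}
                    out[("gsea", mode)] = es_oracle(member_ids, ps_map, mw)
                    out[("sumst", mode)] = sum_oracle(mw)
                    out[("sumsq", mode)] = sumsq_oracle(mw)
                return out

            obs_oracle = oracle_stats(s_map, f_map)
            for _ in range(B):
                perm = prng.permutation(n)
                ps_map = {g: float(s_vec[perm[i]]) for i, g in enumerate(gene_ids)}
                pf_map = {g: bool(f_vec[perm[i]]) for i, g in enumerate(gene_ids)}
                for key, val in oracle_stats(ps_map, pf_map).items():
                    perm_stats[key].append(val)
            for key, stat in res.stats.items():
                assert stat.raw_stat == pytest.approx(obs_oracle[key], abs=1e-12)
                lo, hi = empirical_p_bounds(obs_oracle[key], perm_stats[key])
                assert lo - 1e-12 <= stat.empirical_p <= hi + 1e-12, (trial, key)
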