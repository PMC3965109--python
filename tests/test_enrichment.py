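"""The hypergeometric phenolog statistic against exact rational oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenolog_kit as pk
from phenolog_kit.enrichment import PhenologResult, log_hypergeom_tail
from phenolog_kit.genesets import GeneSetCatalog, PhenotypeTerm, _add
from phenolog_kit.orthology import OrthologPair


def exact_tail(N, n1, n2, k):
    """Upper tail P(X >= k) by big-integer rational arithmetic."""
    num = sum(math.comb(n1, i) * math.comb(N - n1, n2 - i) for i in range(k, min(n1, n2) + 1))
    return Fraction(num, math.comb(N, n2))


@st.composite
def hypergeom_params(draw, max_N=2000):
    N = draw(st.integers(min_value=1, max_value=max_N))
    n1 = draw(st.integers(min_value=0, max_value=N))
    n2 = draw(st.integers(min_value=0, max_value=N))
    k = draw(st.integers(min_value=0, max_value=min(n1, n2)))
    return N, n1, n2, k


class TestTail:
    def test_case1_worked_example(self):
        # 3 shared orthologues of 16 worm and 12 human genes on a 4649 background
        p = pk.hypergeom_tail(4649, 16, 12, 3)
        assert f"{p:.1e}" == "7.2e-06"

    def test_k_zero_is_whole_distribution(self):
        assert pk.hypergeom_tail(100, 30, 20, 0) == 1.0

    def test_small_exact_value(self):
        # C(2,2)*C(3,0)/C(5,2) = 1/10
        assert pk.hypergeom_tail(5, 2, 2, 2) == pytest.approx(0.1, rel=1e-12)

    def test_single_shared_group_tail(self):
        # k=1 of 1-and-1 on N=10: 1 - C(9,1)/C(10,1) = 1/10
        assert pk.hypergeom_tail(10, 1, 1, 1) == pytest.approx(0.1, rel=1e-12)

    def test_no_underflow_in_extreme_tail(self):
        logp = log_hypergeom_tail(10_000, 100, 100, 100)
        assert np.isfinite(logp)
        # p = 1/C(10000,100) ~ 1e-243: log-space value survives well past
        # the double-precision underflow threshold of direct evaluation
        assert logp / math.log(10) < -240
        exact = exact_tail(10_000, 100, 100, 100)
        assert logp == pytest.approx(
            math.log(exact.numerator) - math.log(exact.denominator), rel=1e-10
        )

    def test_invalid_parameters_rejected(self):
        for args in [(10, 11, 5, 0), (10, 5, 5, 6), (10, 5, -1, 0), (10, 5, 5, 5.5)]:
            with pytest.raises(ValueError):
                log_hypergeom_tail(*args)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(hypergeom_params(max_N=60))
    def test_matches_exact_rational_arithmetic(self, params):
        N, n1, n2, k = params
        got = math.exp(log_hypergeom_tail(N, n1, n2, k))
        want = float(exact_tail(N, n1, n2, k))
        assert got == pytest.approx(want, rel=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(hypergeom_params())
    def test_symmetry_in_n1_n2(self, params):
        N, n1, n2, k = params
        a, b = log_hypergeom_tail(N, n1, n2, k), log_hypergeom_tail(N, n2, n1, k)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(hypergeom_params())
    def test_monotone_decreasing_in_k(self, params):
        N, n1, n2, k = params
        if k + 1 <= min(n1, n2):
            assert log_hypergeom_tail(N, n1, n2, k + 1) <= log_hypergeom_tail(N, n1, n2, k) + 1e-10

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(hypergeom_params(), st.integers(min_value=1, max_value=100))
    def test_monotone_decreasing_in_N(self, params, extra):
        N, n1, n2, k = params
        if k >= 1:
            assert (
                log_hypergeom_tail(N + extra, n1, n2, k)
                <= log_hypergeom_tail(N, n1, n2, k) + 1e-10
            )

    def test_agrees_with_scipy_survival_function(self):
        from scipy.stats import hypergeom

        for N, n1, n2, k in [(4649, 16, 12, 3), (200, 40, 30, 10), (50, 25, 25, 20)]:
            assert pk.hypergeom_tail(N, n1, n2, k) == pytest.approx(
                hypergeom.sf(k - 1, N, n1, n2), rel=1e-9
            )


class TestPhenologTest:
    def test_case1_counts_with_background_override(self, scenario_data):
        planted = scenario_data["truth"]["planted"][0]
        worm_genes = pk.gene_set_for_term(scenario_data["worm_catalog"], planted["worm_term"])
        human_genes = pk.gene_set_for_term(scenario_data["human_catalog"], planted["human_term"])
        r = pk.phenolog_test(worm_genes, human_genes, scenario_data["ortho_map"], N_override=4649)
        assert (r.n1, r.n2, r.k, r.N) == (16, 12, 3, 4649)
        assert f"{r.p:.1e}" == "7.2e-06"

    def test_disjoint_projections_give_p_one(self, triangle_map):
        r = pk.phenolog_test({"wX"}, {"hY"}, triangle_map)
        assert r.k == 0 and r.p == 1.0

    def test_single_shared_group(self):
        pairs = [OrthologPair(f"w{i}", f"h{i}", 100.0) for i in range(10)]
        m = pk.build_groups(pairs)
        r = pk.phenolog_test({"w0"}, {"h0"}, m)
        assert (r.n1, r.n2, r.k, r.N) == (1, 1, 1, 10)
        assert r.p == pytest.approx(0.1, rel=1e-12)

    def test_n_override_below_set_size_rejected(self, scenario_data):
        planted = scenario_data["truth"]["planted"][0]
        worm_genes = pk.gene_set_for_term(scenario_data["worm_catalog"], planted["worm_term"])
        human_genes = pk.gene_set_for_term(scenario_data["human_catalog"], planted["human_term"])
        with pytest.raises(ValueError, match="N_override"):
            pk.phenolog_test(worm_genes, human_genes, scenario_data["ortho_map"], N_override=10)

    def test_result_invariants_enforced(self):
        t = PhenotypeTerm("OMIM", "d", "d")
        with pytest.raises(ValueError):
            PhenologResult(t, t, 5, 3, 4, 100, 0.5)  # k > min(n1,n2)
        with pytest.raises(ValueError):
            PhenologResult(t, t, 5, 3, 2, 100, 0.0)  # p out of range


class TestBH:
    def test_single_pvalue_unchanged(self):
        assert pk.bh_adjust([0.04], m=1) == [0.04]

    def test_hand_step_up(self):
        assert pk.bh_adjust([0.01, 0.02, 0.03], m=3) == pytest.approx([0.03, 0.03, 0.03])

    def test_capped_at_one(self):
        assert pk.bh_adjust([1.0, 1.0], m=2) == [1.0, 1.0]

    def test_external_test_count_dilutes(self):
        # 2 observed among m=4 tests: adjusted = min over j>=i of m*p_j/j
        assert pk.bh_adjust([0.01, 0.02], m=4) == pytest.approx([0.04, 0.04])

    def test_m_below_list_length_rejected(self):
        with pytest.raises(ValueError):
            pk.bh_adjust([0.1, 0.2], m=1)

    def test_matches_statsmodels_when_m_equals_length(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(1e-6, 1.0, size=50)
        ours = pk.bh_adjust(p.tolist())
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)


def _toy_catalogs():
    pairs = [OrthologPair(f"w{i}", f"h{i}", 100.0) for i in range(30)]
    m = pk.build_groups(pairs)
    worm = GeneSetCatalog("WORMBASE")
    human = GeneSetCatalog("OMIM")
    wt = PhenotypeTerm("WORMBASE", "ce-t1", "worm term")
    for g in ["w0", "w1", "w2", "w3"]:
        _add(worm, wt, g, None)
    strong = PhenotypeTerm("OMIM", "hs-strong", "matching disease")
    weak = PhenotypeTerm("OMIM", "hs-weak", "one shared gene")
    none_ = PhenotypeTerm("OMIM", "hs-none", "disjoint disease")
    for g in ["h0", "h1", "h2", "h3"]:
        _add(human, strong, g, None)
    for g in ["h3", "h10", "h11", "h12"]:
        _add(human, weak, g, None)
    for g in ["h20", "h21", "h22", "h23"]:
        _add(human, none_, g, None)
    return worm, human, m


class TestSweeps:
    def test_single_overlapping_pair(self):
        worm, human, m = _toy_catalogs()
        res = pk.broad_sweep(worm, human, m)
        assert [r.term2.term_id for r in res] == ["hs-strong", "hs-weak"]
        assert res[0].k == 4 and res[1].k == 1

    def test_bh_denominator_counts_zero_overlap_pairs(self):
        worm, human, m = _toy_catalogs()
        res = pk.broad_sweep(worm, human, m)
        # 1 worm term x 3 human terms tested; BH over m=3 including the k=0 pair
        assert res[0].p_adjusted == pytest.approx(min(3 * res[0].p, 1.0))

    def test_planted_pair_ranks_first_among_decoys(self, scenario_data):
        res = pk.broad_sweep(
            scenario_data["worm_catalog"], scenario_data["human_catalog"],
            scenario_data["ortho_map"], adjust=False,
        )
        planted = scenario_data["truth"]["planted"][0]
        assert res[0].term1.term_id == planted["worm_term"]
        assert res[0].term2.term_id == planted["human_term"]
        assert (res[0].n1, res[0].n2, res[0].k) == (16, 12, 3)

    def test_within_species_identical_term_ranks_first(self):
        cat = GeneSetCatalog("OMIM")
        a = PhenotypeTerm("OMIM", "d-a", "query")
        twin = PhenotypeTerm("OMIM", "d-twin", "identical twin")
        partial = PhenotypeTerm("OMIM", "d-partial", "partial overlap")
        other = PhenotypeTerm("OMIM", "d-other", "disjoint")
        for g in ["g1", "g2", "g3"]:
            _add(cat, a, g, None)
            _add(cat, twin, g, None)
        for g in ["g1", "g4", "g5"]:
            _add(cat, partial, g, None)
        for g in ["g6", "g7", "g8"]:
            _add(cat, other, g, None)
        res = pk.within_species_sweep(cat, a)
        assert [r.term2.term_id for r in res] == ["d-twin", "d-partial"]
        assert res[0].k == 3 and res[0].N == len(cat.all_genes())

    def test_within_species_disjoint_query_empty(self):
        cat = GeneSetCatalog("OMIM")
        a = PhenotypeTerm("OMIM", "d-a", "query")
        b = PhenotypeTerm("OMIM", "d-b", "other")
        _add(cat, a, "g1", None)
        _add(cat, b, "g2", None)
        assert pk.within_species_sweep(cat, a) == []

    def test_within_species_ranks_by_overlap_at_equal_sizes(self):
        cat = GeneSetCatalog("OMIM")
        q = PhenotypeTerm("OMIM", "d-q", "query")
        for g in ["g1", "g2", "g3"]:
            _add(cat, q, g, None)
        two = PhenotypeTerm("OMIM", "d-two", "k=2")
        one = PhenotypeTerm("OMIM", "d-one", "k=1")
        zero = PhenotypeTerm("OMIM", "d-zero", "k=0")
        for t, genes in [(two, ["g1", "g2", "x1"]), (one, ["g3", "x2", "x3"]),
                         (zero, ["x4", "x5", "x6"])]:
            for g in genes:
                _add(cat, t, g, None)
        res = pk.within_species_sweep(cat, q)
        assert [r.term2.term_id for r in res] == ["d-two", "d-one"]
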