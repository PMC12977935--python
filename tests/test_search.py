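import itertools
import random

import numpy as np
import pytest
from scipy import stats

from dmckit.seqio import QueryList, write_dmc_table
from dmckit.search import (
    DegenerateSearchError,
    NoBackgroundError,
    SearchParams,
    TaxonContext,
    consensus_dmc,
    exclusivity_score,
    find_dmcs,
    refine_dmc,
    sample_candidate,
    site_eligibility,
    site_weights,
    taxon_context,
)
from dmckit.synth import SynthSpec, generate_training_alignment
from conftest import make_alignment
from _oracles import brute_exclusivity, brute_min_qualifying_length


class TestSearchParams:
    def test_min_len_auto_adjusts_to_exclusive(self):
        assert SearchParams(min_len=2, exclusive=4).effective_min_len == 4
        assert SearchParams(min_len=10, exclusive=4).effective_min_len == 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ref_strength": 1.5},
            {"n_iter": 0},
            {"exclusive": 20, "max_len": 15},
            {"majority_threshold": 0.0},
            {"weight_method": "nope"},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SearchParams(**kwargs)


class TestEligibility:
    def test_policies(self):
        # col1 {A,A,N}: fixed; col2 {A,C}: polymorphic; col3 {A,-}: gap policy;
        # col4 {R,R}: ambiguous; col5 {N,N}: all missing
        aln = make_alignment(
            {
                "Q_1": "AAARN",
                "Q_2": "AC-RN",
                "Q_3": "NAARN",
                "B_1": "CCCCC",
            },
            queries=["Q"],
        )
        elig, states = site_eligibility(aln, "Q", gaps_new=False)
        assert list(elig) == [True, False, True, False, False]
        assert states[0] == "A" and states[2] == "A"
        elig_gn, _ = site_eligibility(aln, "Q", gaps_new=True)
        assert list(elig_gn) == [True, False, False, False, False]


class TestSiteWeights:
    def test_fraction_of_differing_background(self):
        # col0: query {A,A}, background {A,C,C,G} -> w = 3/4
        # col1: invariant everywhere -> 0; col2: all background differ -> 1
        aln = make_alignment(
            {
                "Q_1": "AGT",
                "Q_2": "AGT",
                "B_1": "AGC",
                "B_2": "CGC",
                "B_3": "CGA",
                "B_4": "GGG",
            },
            queries=["Q"],
        )
        w = site_weights(aln, "Q")
        assert w[0] == pytest.approx(0.75)
        assert w[1] == 0.0
        assert w[2] == 1.0

    def test_missing_background_shrinks_denominator(self):
        aln = make_alignment(
            {"Q_1": "A", "B_1": "C", "B_2": "N"}, queries=["Q"]
        )
        assert site_weights(aln, "Q")[0] == 1.0  # one informative, it differs

    def test_ambiguity_code_counts_as_differing(self):
        aln = make_alignment({"Q_1": "A", "B_1": "R"}, queries=["Q"])
        assert site_weights(aln, "Q")[0] == 1.0

    def test_state_jaccard_variant(self):
        aln = make_alignment(
            {"Q_1": "A", "B_1": "A", "B_2": "C"}, queries=["Q"]
        )
        # state sets {A} vs {A,C}: 1 - 1/2
        assert site_weights(aln, "Q", weight_method="state_jaccard")[0] == 0.5
        assert site_weights(aln, "Q")[0] == 0.5  # 1 of 2 sequences differs

    def test_weight_one_iff_every_informative_background_differs(self):
        spec = SynthSpec(n_species=5, seqs_per_species=3, n_sites=30,
                         missing_rate=0.05, seed=4)
        aln, _ = generate_training_alignment(spec)
        taxon = "Synthia_sp01"
        w = site_weights(aln, taxon)
        elig, states = site_eligibility(aln, taxon)
        bg = [i for i in aln.ids if aln.taxon_of[i] != taxon]
        for j in range(aln.n_sites):
            assert 0.0 <= w[j] <= 1.0
            if not elig[j]:
                assert w[j] == 0.0
                continue
            informative = [aln.seq_of(b)[j] for b in bg
                           if aln.seq_of(b)[j] not in "N?-"]
            all_differ = bool(informative) and all(c != states[j] for c in informative)
            assert (w[j] == 1.0) == all_differ


class TestExclusivity:
    def test_empty_sites_scores_zero(self, toy_aln):
        assert exclusivity_score([], toy_aln, "Qa") == 0

    def test_single_background_direct_count(self):
        aln = make_alignment({"Q_1": "AAA", "B_1": "ATT"}, queries=["Q"])
        assert exclusivity_score([(1, "A"), (2, "A"), (3, "A")], aln, "Q") == 2

    def test_minimum_over_background(self):
        # per-background difference counts {3,2,4,2,5} -> min 2
        dmc = [(1, "A"), (2, "A"), (3, "A"), (4, "A"), (5, "A")]
        aln = make_alignment(
            {
                "Q_1": "AAAAA",
                "B_1": "CCCAA",
                "B_2": "CCAAA",
                "B_3": "CCCCA",
                "B_4": "ACCAA",
                "B_5": "CCCCC",
            },
            queries=["Q"],
        )
        counts = [3, 2, 4, 2, 5]
        assert exclusivity_score(dmc, aln, "Q") == min(counts) == 2

    def test_missing_background_is_conservative(self):
        aln = make_alignment({"Q_1": "AA", "B_1": "NC"}, queries=["Q"])
        sites = [(1, "A"), (2, "A")]
        assert exclusivity_score(sites, aln, "Q") == 1
        assert exclusivity_score(sites, aln, "Q", missing_breaks=True) == 2

    def test_no_background_is_an_error(self):
        aln = make_alignment({"Q_1": "AA", "Q_2": "AA"}, queries=["Q"])
        with pytest.raises(NoBackgroundError):
            exclusivity_score([(1, "A")], aln, "Q")

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for seed in range(8):
            spec = SynthSpec(n_species=5, seqs_per_species=4, n_sites=30,
                             intraspecific_rate=0.02, missing_rate=0.03,
                             seed=int(seed))
            aln, _ = generate_training_alignment(spec)
            for taxon in ("Synthia_sp01", "Synthia_sp03"):
                cols = rng.choice(30, size=4, replace=False) + 1
                ref = aln.seq_of(aln.members[taxon][0])
                sites = sorted(
                    (int(c), ref[c - 1]) for c in cols if ref[c - 1] in "ACGT"
                )
                if not sites:
                    continue
                assert exclusivity_score(sites, aln, taxon) == brute_exclusivity(
                    sites, aln, taxon
                )

    def test_adding_a_site_never_decreases_exclusivity(self):
        spec = SynthSpec(n_species=4, seqs_per_species=3, n_sites=20, seed=9)
        aln, _ = generate_training_alignment(spec)
        taxon = "Synthia_sp02"
        ref = aln.seq_of(aln.members[taxon][0])
        base = [(3, ref[2]), (10, ref[9])]
        e0 = exclusivity_score(base, aln, taxon)
        for extra in range(11, 20):
            e1 = exclusivity_score(base + [(extra, ref[extra - 1])], aln, taxon)
            assert e1 >= e0


def _manual_ctx(weights, diff):
    """Hand-built context for distribution-level sampling tests."""
    weights = np.asarray(weights, dtype=float)
    diff = np.asarray(diff, dtype=np.int16)
    n = weights.size
    return TaxonContext(
        taxon="T",
        query_ids=["q"],
        background_ids=[f"b{i}" for i in range(diff.shape[0])],
        eligible=weights > 0,
        qstate=["A"] * n,
        weights=weights,
        diff=diff,
    )


class TestSampling:
    def test_degenerate_distribution(self):
        # only one positive-weight column; it always forms the candidate
        ctx = _manual_ctx([0, 0, 1.0, 0], [[0, 0, 1, 0]])
        params = SearchParams(min_len=1, exclusive=1)
        rng = random.Random(0)
        for _ in range(20):
            assert sample_candidate(ctx, params, rng) == ((2,), 1)

    def test_no_positive_weight_is_degenerate(self):
        ctx = _manual_ctx([0.0, 0.0], [[0, 0]])
        with pytest.raises(DegenerateSearchError):
            sample_candidate(ctx, SearchParams(), random.Random(0))

    def test_first_draw_proportional_to_weights(self):
        # equal weights -> uniform first draw (chi-square GoF, alpha 0.01)
        m = 8
        ctx = _manual_ctx([1.0] * m, np.ones((1, m)))
        params = SearchParams(min_len=1, exclusive=1)
        rng = random.Random(123)
        n_draws = 10_000
        counts = np.zeros(m)
        for _ in range(n_draws):
            (site,), _e = sample_candidate(ctx, params, rng)
            counts[site] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_rejects_when_nothing_qualifies(self):
        # single background differing at one column only: exclusivity caps at 1
        aln = make_alignment({"Q_1": "AAAA", "B_1": "CAAA"}, queries=["Q"])
        params = SearchParams(exclusive=2, max_len=4)
        ctx = taxon_context(aln, "Q", params)
        assert brute_min_qualifying_length(aln, "Q", exclusive=2, max_k=4) is None
        rng = random.Random(5)
        assert all(sample_candidate(ctx, params, rng) is None for _ in range(50))


class TestRefinement:
    def _ctx_with_redundant_site(self):
        # {0,1} qualifies alone; site 2 is redundant in {0,1,2}
        diff = np.array([[1, 1, 1], [1, 1, 0]])
        return _manual_ctx([1.0, 1.0, 0.5], diff)

    def test_zero_strength_returns_nothing(self):
        ctx = self._ctx_with_redundant_site()
        params = SearchParams(ref_strength=0.0)
        assert refine_dmc((0, 1, 2), ctx, params, random.Random(0)) == {}

    def test_finds_redundant_site_reduction(self):
        ctx = self._ctx_with_redundant_site()
        params = SearchParams(ref_strength=1.0, exclusive=2, min_len=2)
        found = refine_dmc((0, 1, 2), ctx, params, random.Random(0))
        assert (0, 1) in found and found[(0, 1)] == 2

    def test_no_qualifying_subset_gives_empty(self):
        # every 2-subset of {0,1,2} has exclusivity 1 < 2
        diff = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        ctx = _manual_ctx([1.0, 1.0, 1.0], diff)
        params = SearchParams(ref_strength=1.0, exclusive=2, min_len=2)
        for k in range(2, 3):
            for comb in itertools.combinations(range(3), k):
                assert ctx.exclusivity(comb) < 2  # brute-force confirmation
        assert refine_dmc((0, 1, 2), ctx, params, random.Random(0)) == {}

    def test_backward_elimination_path_on_large_candidate(self):
        # L=13 forces the randomized path (2^13 > 4096); all sites identical
        # so any subset of size >= 2 qualifies and passes must shrink it
        n = 13
        diff = np.ones((2, n), dtype=int)
        ctx = _manual_ctx([1.0] * n, diff)
        params = SearchParams(ref_strength=1.0, exclusive=2, min_len=2)
        found = refine_dmc(tuple(range(n)), ctx, params, random.Random(1))
        assert found
        assert all(len(sites) == 2 for sites in found)  # eliminates to the floor


class TestConsensus:
    def test_single_candidate_pool(self):
        ctx = _manual_ctx([1.0, 1.0], np.ones((1, 2)))
        params = SearchParams()
        cons, alt, n_opt, fb = consensus_dmc({(0, 1): 2}, ctx, params)
        assert cons == ((0, 1), 2) and alt == ((0, 1), 2)
        assert n_opt == 1 and not fb

    def test_empty_pool(self):
        ctx = _manual_ctx([1.0], np.ones((1, 1)))
        assert consensus_dmc({}, ctx, SearchParams()) is None

    def test_universal_sites_qualifying_alone_form_consensus(self):
        # sites 0,1,2 appear in every candidate and qualify by themselves
        diff = np.array([[1, 1, 1, 0, 0, 0], [1, 1, 1, 1, 0, 0]])
        ctx = _manual_ctx([1.0] * 6, diff)
        params = SearchParams(exclusive=3, min_len=3)
        pool = {
            (0, 1, 2, 3): 3,
            (0, 1, 2, 4): 3,
            (0, 1, 2, 5): 3,
        }
        cons, _alt, _n, fb = consensus_dmc(pool, ctx, params)
        assert cons == ((0, 1, 2), 3) and not fb

    def test_greedy_augmentation_when_majority_fails(self):
        # sites 0,1 are in every candidate but reach exclusivity 1 alone;
        # the minority sites 2,3,4 each repair it, tie broken to column 2
        diff = np.array([[1, 0, 1, 1, 1], [0, 1, 1, 1, 1]])
        ctx = _manual_ctx([1.0] * 5, diff)
        params = SearchParams(exclusive=2, min_len=2)
        pool = {(0, 1, 2): 2, (0, 1, 3): 2, (0, 1, 4): 2}
        assert ctx.exclusivity((0, 1)) == 1  # majority set alone fails
        cons, _alt, _n, fb = consensus_dmc(pool, ctx, params)
        assert not fb
        assert cons == ((0, 1, 2), 2)


class TestFindDmcs:
    def test_planted_library_soundness_and_recovery(self, planted_library, fast_params):
        aln, truth = planted_library
        qs = QueryList(tuple(truth.species()))
        table = find_dmcs(aln, qs, fast_params)
        for row in table:
            assert row.status == "ok"
            for dmc in (row.consensus, row.alternative):
                assert len(dmc) >= fast_params.effective_min_len
                assert dmc.exclusivity >= fast_params.exclusive
                assert brute_exclusivity(dmc.sites, aln, row.taxon) == dmc.exclusivity
            planted_positions = {p for p, _ in truth.planted[row.taxon]}
            assert planted_positions & set(row.consensus.positions)

    def test_no_query_sequences_status(self, planted_library, fast_params):
        aln, truth = planted_library
        qs = QueryList(tuple(truth.species()) + ("Synthia_sp99",))
        table = find_dmcs(aln, qs, fast_params)
        assert table.row("Synthia_sp99").status == "no_query_sequences"

    def test_exclusive_floors_reported_length(self):
        spec = SynthSpec(n_species=5, seqs_per_species=3, n_sites=80,
                         planted_sites_per_species=4, intraspecific_rate=0.0,
                         seed=21)
        aln, truth = generate_training_alignment(spec)
        qs = QueryList(tuple(truth.species()))
        params = SearchParams(n_iter=1500, min_len=2, exclusive=4, seed=3)
        table = find_dmcs(aln, qs, params)
        for row in table:
            assert row.status == "ok"
            assert len(row.consensus) >= 4 and len(row.alternative) >= 4

    def test_seeded_runs_are_byte_identical(self, planted_library, tmp_path):
        aln, truth = planted_library
        qs = QueryList(tuple(truth.species()))
        params = SearchParams(n_iter=800, seed=5)
        paths = []
        for k in range(2):
            t = find_dmcs(aln, qs, params)
            p = tmp_path / f"run{k}.csv"
            write_dmc_table(t, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_per_taxon_streams_are_independent(self, planted_library):
        aln, truth = planted_library
        species = truth.species()
        params = SearchParams(n_iter=600, seed=5)
        full = find_dmcs(aln, QueryList(tuple(species)), params)
        solo = find_dmcs(aln, QueryList((species[2],)), params)
        assert full.row(species[2]) == solo.row(species[2])
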