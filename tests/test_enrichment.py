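"""Resampling enrichment test, exact hypergeometric oracle, profiles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaborank.enrichment import (
    MolecularProfiler,
    _null_cdf,
    _sample_null_counts,
    _substream,
    build_profile,
    build_profiles_bulk,
    enrich_feature,
    hypergeometric_tail,
)
from metaborank.io import ChemicalGeneTable, GeneSet, GeneSetCollection


def enumerate_tail(overlap, query_size, feature_size, universe_size):
    """Brute-force oracle: fraction of all size-k subsets with >= `overlap`
    feature members, by exhaustive enumeration."""
    universe = range(universe_size)
    feature = set(range(feature_size))
    hits = total = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(feature.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


class TestHypergeometricTail:
    def test_tail_from_zero_is_one(self):
        assert hypergeometric_tail(0, 4, 5, 20) == 1.0

    def test_forced_full_overlap(self):
        # query = whole universe: the draw always contains the whole feature
        assert hypergeometric_tail(5, 20, 5, 20) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "overlap,query,feature,universe",
        [(3, 4, 5, 20), (1, 4, 5, 20), (2, 6, 8, 15), (4, 5, 4, 12)],
    )
    def test_matches_exhaustive_enumeration(self, overlap, query, feature, universe):
        exact = hypergeometric_tail(overlap, query, feature, universe)
        assert exact == pytest.approx(
            enumerate_tail(overlap, query, feature, universe), abs=1e-12
        )

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(5, 4, 5, 20)  # overlap > query
        with pytest.raises(ValueError):
            hypergeometric_tail(1, 30, 5, 20)  # query > universe

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_tail_monotone_in_overlap(self, data):
        n = data.draw(st.integers(5, 40))
        m = data.draw(st.integers(1, n))
        k = data.draw(st.integers(1, n))
        tails = [hypergeometric_tail(x, k, m, n) for x in range(min(m, k) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))


class TestNullSampler:
    def test_matches_materialized_gene_set_draws(self):
        """The fast hypergeometric null sampler must agree with literally
        drawing random gene sets and intersecting."""
        N, m, k, R = 30, 8, 6, 40_000
        universe = np.arange(N)
        feature = set(range(m))
        rng = np.random.default_rng(2024)
        brute = np.array(
            [len(feature.intersection(rng.choice(universe, k, replace=False)))
             for _ in range(R)]
        )
        fast = _sample_null_counts(np.random.default_rng(2024), R, N, m, k)
        exact_mean = k * m / N
        assert fast.mean() == pytest.approx(exact_mean, rel=0.02)
        assert brute.mean() == pytest.approx(exact_mean, rel=0.02)
        assert fast.std() == pytest.approx(brute.std(), rel=0.05)
        assert fast.min() >= 0 and fast.max() <= min(m, k)

    def test_cdf_support_bounds(self):
        lo, cdf = _null_cdf(10, 8, 7)
        assert lo == 5  # k + m - N
        assert cdf[-1] == 1.0


class TestEnrichFeature:
    def setup_method(self):
        self.universe = [f"G{i}" for i in range(20)]

    def test_saturated_feature_is_never_enriched(self):
        q = GeneSet("q", frozenset(self.universe[:4]))
        f = GeneSet("f", frozenset(self.universe))
        res = enrich_feature(q, f, self.universe, n_resamples=100, seed=0)
        assert res.observed_fraction == 1.0
        assert res.fold_enrichment == 1.0
        assert res.p_value == 1.0

    def test_zero_overlap_not_significant(self):
        q = GeneSet("q", frozenset(self.universe[:4]))
        f = GeneSet("f", frozenset(self.universe[10:13]))
        res = enrich_feature(q, f, self.universe, n_resamples=500, seed=0)
        assert res.overlap_count == 0
        assert res.fold_enrichment <= 1.0
        assert res.p_value > 0.05

    def test_decision_agrees_with_exact_oracle(self):
        # universe 20, feature 5, query 4 with overlap 3
        q = GeneSet("q", frozenset(["G0", "G1", "G2", "G10"]))
        f = GeneSet("f", frozenset(["G0", "G1", "G2", "G3", "G4"]))
        res = enrich_feature(q, f, self.universe, n_resamples=2000, seed=1)
        exact = enumerate_tail(3, 4, 5, 20)
        assert (res.p_value < 0.05) == (exact < 0.05)
        assert res.overlap_count == 3

    def test_genes_outside_universe_dropped(self):
        q = GeneSet("q", frozenset(["G0", "G1", "NOT_THERE"]))
        f = GeneSet("f", frozenset(["G0", "G5"]))
        res = enrich_feature(q, f, self.universe, n_resamples=100, seed=0)
        assert res.observed_fraction == pytest.approx(1 / 2)

    def test_errors(self):
        q = GeneSet("q", frozenset(["ABSENT"]))
        f = GeneSet("f", frozenset(["G0"]))
        with pytest.raises(ValueError, match="no genes"):
            enrich_feature(q, f, self.universe, n_resamples=100, seed=0)
        with pytest.raises(ValueError, match="n_resamples"):
            enrich_feature(
                GeneSet("q", frozenset(["G0"])), f, self.universe, n_resamples=1, seed=0
            )

    def test_determinism(self):
        q = GeneSet("q", frozenset(self.universe[:5]))
        f = GeneSet("f", frozenset(self.universe[3:9]))
        a = enrich_feature(q, f, self.universe, n_resamples=300, seed=9)
        b = enrich_feature(q, f, self.universe, n_resamples=300, seed=9)
        assert a == b


class TestBuildProfile:
    def test_universe_wide_feature_excluded(self):
        genes = [f"G{i}" for i in range(30)]
        coll = GeneSetCollection([GeneSet("ALL", frozenset(genes))])
        prof = build_profile("q", genes[:5], coll, n_resamples=100, seed=0)
        assert len(prof) == 0 and prof.status == "ok"

    def test_single_containing_feature_recovered(self):
        genes = [f"G{i}" for i in range(200)]
        sets = [GeneSet("HIT", frozenset(genes[:8]))]
        sets += [
            GeneSet(f"BG{j}", frozenset(genes[50 + 10 * j : 60 + 10 * j]))
            for j in range(10)
        ]
        coll = GeneSetCollection(sets)
        prof = build_profile("q", genes[:6], coll, n_resamples=1000, seed=3)
        assert [r.feature for r in prof] == ["HIT"]
        # exact oracle confirms only HIT rejects at alpha=0.05
        n = len(coll.universe)
        assert hypergeometric_tail(6, 6, 8, n) < 0.05
        assert all(hypergeometric_tail(0, 6, 10, n) > 0.05 for _ in [0])

    def test_no_universe_overlap_flagged_not_raised(self, tiny_collection):
        prof = build_profile("q", ["ZZZ1"], tiny_collection, n_resamples=50, seed=0)
        assert len(prof) == 0
        assert prof.status == "no-universe-overlap"

    def test_profile_ordering_and_invariants(self):
        genes = [f"G{i}" for i in range(100)]
        rng = np.random.default_rng(5)
        sets = [
            GeneSet(f"S{j}", frozenset(rng.choice(genes, 12, replace=False)))
            for j in range(30)
        ]
        coll = GeneSetCollection(sets)
        prof = build_profile("q", genes[:10], coll, n_resamples=500, seed=1)
        ps = [r.p_value for r in prof]
        assert ps == sorted(ps)
        for r in prof:
            assert r.p_value < prof.alpha and r.fold_enrichment > 1
            assert r.overlap_count <= 10

    def test_same_seed_identical_profiles(self, tiny_collection):
        a = build_profile("q", ["G1", "G2", "G3"], tiny_collection, n_resamples=200, seed=4)
        b = build_profile("q", ["G1", "G2", "G3"], tiny_collection, n_resamples=200, seed=4)
        assert a.features == b.features

    def test_bh_correction_never_adds_features(self, tiny_collection):
        genes = ["G1", "G2", "G3", "G4"]
        raw = build_profile("q", genes, tiny_collection, n_resamples=200, seed=0)
        bh = build_profile(
            "q", genes, tiny_collection, n_resamples=200, seed=0, correction="bh"
        )
        assert bh.feature_names <= raw.feature_names


class TestBulkAndProfiler:
    def _table(self):
        return ChemicalGeneTable(
            {
                "c1": frozenset({"G1", "G2"}),
                "c2": frozenset({"G7", "G8", "G9"}),
                "c3": frozenset({"ZZZ"}),  # misses the universe
            }
        )

    def test_bulk_matches_single_profile(self, tiny_collection):
        bulk = build_profiles_bulk(self._table(), tiny_collection, n_resamples=200, seed=2)
        assert len(bulk) == 3
        single = build_profile("c1", {"G1", "G2"}, tiny_collection, n_resamples=200, seed=2)
        assert bulk["c1"].features == single.features
        assert bulk["c3"].status == "no-universe-overlap"

    def test_empty_table_rejected(self, tiny_collection):
        with pytest.raises(ValueError):
            build_profiles_bulk(
                ChemicalGeneTable({}), tiny_collection, n_resamples=100, seed=0
            )

    def test_profiler_estimator_api(self, tiny_collection):
        from sklearn.base import clone

        est = MolecularProfiler(alpha=0.1, n_resamples=150, random_state=3)
        assert clone(est).get_params() == est.get_params()
        with pytest.raises(Exception):
            est.transform(self._table())  # not fitted
        profiles = est.fit(tiny_collection).transform(self._table())
        direct = build_profiles_bulk(
            self._table(), tiny_collection, alpha=0.1, n_resamples=150, seed=3
        )
        assert {c: p.features for c, p in profiles.items()} == {
            c: p.features for c, p in direct.items()
        }

    def test_substream_independent_of_evaluation_order(self):
        ss1 = _substream(7, "chemA", "P1")
        ss2 = _substream(7, "chemA", "P1")
        assert np.random.PCG64(ss1).state == np.random.PCG64(ss2).state
        assert (
            _substream(7, "chemA", "P2").entropy != ss1.entropy
        )
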