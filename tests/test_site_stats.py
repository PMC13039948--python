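import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6a_landscape.data_model_io import ReadLevelRecord, SiteRecord
from m6a_landscape.site_stats import (
    FILTER_PRESETS,
    IsoformClass,
    aggregate_condition,
    call_m6a_sites,
    classify_isoforms,
    differential_sites,
    filter_sites,
    metagene_histogram,
    restoration_analysis,
)


def rec(start, n_mod, cov, sample="r1", cond="A", strand="+"):
    return SiteRecord(
        chrom="chr1",
        start=start,
        end=start + 1,
        strand=strand,
        mod_code="a",
        valid_cov=cov,
        n_mod=n_mod,
        sample_id=sample,
        condition=cond,
    )


KEY = ("chr1", 0, "+")


class TestAggregate:
    def test_symmetric_mean(self):
        s = aggregate_condition([rec(0, 8, 20, "r1"), rec(0, 12, 20, "r2")])
        assert s[KEY].mean_level == pytest.approx(0.5)
        assert s[KEY].agg_cov == 40
        assert s[KEY].agg_level == pytest.approx(0.5)

    def test_zero_coverage_replicate_excluded_from_mean(self):
        s = aggregate_condition([rec(0, 5, 10, "r1"), rec(0, 0, 0, "r2")])
        assert s[KEY].mean_level == pytest.approx(0.5)
        assert s[KEY].agg_cov == 10
        assert s[KEY].n_replicates == 2

    def test_unweighted_mean_vs_aggregate(self):
        s = aggregate_condition([rec(0, 9, 30, "r1"), rec(0, 3, 10, "r2")])
        assert s[KEY].mean_level == pytest.approx(0.30)
        assert s[KEY].agg_level == pytest.approx(12 / 40)

    def test_absent_site_contributes_nothing(self):
        s = aggregate_condition([rec(0, 5, 10, "r1"), rec(1, 2, 10, "r2")])
        assert s[KEY].n_replicates == 1
        assert s[KEY].mean_level == pytest.approx(0.5)

    def test_duplicate_sample_site_is_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_condition([rec(0, 1, 10, "r1"), rec(0, 2, 10, "r1")])

    def test_mixed_conditions_is_error(self):
        with pytest.raises(ValueError, match="conditions"):
            aggregate_condition([rec(0, 1, 10, cond="A"), rec(1, 1, 10, cond="B")])


def summaries(pairs_a, pairs_b):
    """pairs: {start: (n_mod per rep, cov per rep)} lists"""
    ra = [rec(s, m, c, f"r{i+1}", "A") for s, reps in pairs_a.items() for i, (m, c) in enumerate(reps)]
    rb = [rec(s, m, c, f"r{i+1}", "B") for s, reps in pairs_b.items() for i, (m, c) in enumerate(reps)]
    return aggregate_condition(ra), aggregate_condition(rb)


class TestFilterSites:
    def test_level_in_one_condition_suffices(self):
        a, b = summaries({0: [(1, 25)]}, {0: [(3, 25)]})  # levels 0.04, 0.12
        assert filter_sites(a, b, 20, 0.10) == {KEY}

    def test_fails_level_in_both(self):
        a, b = summaries({0: [(1, 25)]}, {0: [(1, 25)]})
        assert filter_sites(a, b, 20, 0.10) == set()

    def test_coverage_boundary_strict(self):
        a, b = summaries({0: [(10, 20)]}, {0: [(20, 40)]})  # agg_cov 20 vs 40
        assert filter_sites(a, b, 20, 0.10) == set()

    def test_present_in_both_required(self):
        a, b = summaries({0: [(20, 40)]}, {1: [(20, 40)]})
        assert filter_sites(a, b, 10, 0.10) == set()

    def test_bad_min_level(self):
        a, b = summaries({0: [(20, 40)]}, {0: [(20, 40)]})
        with pytest.raises(ValueError):
            filter_sites(a, b, 20, 1.5)

    def test_presets(self):
        assert FILTER_PRESETS["methods"]["min_agg_cov"] == 20
        assert FILTER_PRESETS["figure"]["min_agg_cov"] == 10


class TestCallSites:
    def test_called(self):
        (s,) = summaries({0: [(6, 11)]}, {})[0:1]
        # level 6/11 = 0.545 > 0.5, cov 11 > 10
        assert call_m6a_sites(s) == {KEY}

    def test_level_boundary_strict(self):
        s = aggregate_condition([rec(0, 50, 100)])
        assert call_m6a_sites(s) == set()

    def test_reads_boundary_strict(self):
        s = aggregate_condition([rec(0, 9, 10)])
        assert call_m6a_sites(s) == set()


class TestDifferentialSites:
    def test_hand_counted_thresholds(self):
        # deltas +0.25, +0.15, -0.05
        a, b = summaries(
            {0: [(45, 100)], 1: [(40, 100)], 2: [(20, 100)]},
            {0: [(20, 100)], 1: [(25, 100)], 2: [(25, 100)]},
        )
        joint = filter_sites(a, b, 20, 0.10)
        sites, _, overall = differential_sites(joint, a, b)
        assert overall.n_up_10 == 2
        assert overall.n_up_20 == 1
        assert overall.n_dn_10 == 0

    def test_exact_boundary_counted_neither(self):
        a, b = summaries({0: [(30, 100)]}, {0: [(20, 100)]})  # delta exactly 0.10
        joint = filter_sites(a, b, 20, 0.10)
        _, _, overall = differential_sites(joint, a, b)
        assert overall.n_up_10 == 0 and overall.n_dn_10 == 0

    def test_identity_all_zero(self):
        a, _ = summaries({i: [(30, 100)] for i in range(5)}, {})
        joint = filter_sites(a, a, 20, 0.10)
        sites, _, overall = differential_sites(joint, a, a)
        assert all(s.delta == 0 for s in sites)
        assert (overall.n_up_10, overall.n_dn_10, overall.n_up_20, overall.n_dn_20) == (0, 0, 0, 0)


@st.composite
def paired_records(draw):
    n = draw(st.integers(1, 50))
    recs_a, recs_b = [], []
    for i in range(n):
        for rep in (1, 2):
            ca = draw(st.integers(0, 120))
            cb = draw(st.integers(0, 120))
            recs_a.append(rec(i, draw(st.integers(0, ca)), ca, f"r{rep}", "A"))
            recs_b.append(rec(i, draw(st.integers(0, cb)), cb, f"r{rep}", "B"))
    return recs_a, recs_b


class TestDifferentialProperties:
    @given(paired_records())
    @settings(max_examples=40, deadline=None)
    def test_nesting_and_antisymmetry(self, recs):
        recs_a, recs_b = recs
        a, b = aggregate_condition(recs_a), aggregate_condition(recs_b)
        joint = filter_sites(a, b, 10, 0.10)
        if not joint:
            return
        _, strata, overall = differential_sites(joint, a, b)
        for c in [overall, *strata.values()]:
            assert c.n_up_20 <= c.n_up_10
            assert c.n_dn_20 <= c.n_dn_10
        # swapping condition labels negates deltas and swaps up/down exactly
        sites_ab, _, fwd = differential_sites(joint, a, b)
        sites_ba, _, rev = differential_sites(joint, b, a)
        for x, y in zip(sites_ab, sites_ba):
            assert x.delta == pytest.approx(-y.delta)
        assert (fwd.n_up_10, fwd.n_dn_10, fwd.n_up_20, fwd.n_dn_20) == (
            rev.n_dn_10, rev.n_up_10, rev.n_dn_20, rev.n_up_20,
        )

    @given(paired_records())
    @settings(max_examples=25, deadline=None)
    def test_counts_match_brute_force_recount(self, recs):
        # independent oracle: recompute everything from the raw records
        recs_a, recs_b = recs
        a, b = aggregate_condition(recs_a), aggregate_condition(recs_b)
        joint = filter_sites(a, b, 10, 0.10)
        if not joint:
            return
        _, _, overall = differential_sites(joint, a, b)

        def brute_mean(recs, key):
            levels = [
                r.n_mod / r.valid_cov for r in recs if r.key == key and r.valid_cov > 0
            ]
            return sum(levels) / len(levels) if levels else None

        up10 = dn10 = up20 = dn20 = 0
        for key in joint:
            d = brute_mean(recs_a, key) - brute_mean(recs_b, key)
            up10 += d > 0.10
            dn10 += d < -0.10
            up20 += d > 0.20
            dn20 += d < -0.20
        assert (overall.n_up_10, overall.n_dn_10, overall.n_up_20, overall.n_dn_20) == (
            up10, dn10, up20, dn20,
        )


def read_rec(i, tid, n_called, n_mod):
    return ReadLevelRecord(f"r{i}", tid, n_called, n_mod)


class TestClassifyIsoforms:
    def test_high(self):
        reads = [read_rec(i, "t1", 3, 1 if i < 16 else 0) for i in range(20)]
        profiles, props, _ = classify_isoforms(reads)
        assert profiles[0].level == pytest.approx(0.80)
        assert profiles[0].iso_class is IsoformClass.HIGH

    def test_boundary_is_medium(self):
        reads = [read_rec(i, "t1", 3, 1 if i < 6 else 0) for i in range(20)]
        (p,), _, _ = classify_isoforms(reads)
        assert p.level == pytest.approx(0.30)
        assert p.iso_class is IsoformClass.MEDIUM

    def test_upper_boundary_is_medium(self):
        reads = [read_rec(i, "t1", 3, 1 if i < 14 else 0) for i in range(20)]
        (p,), _, _ = classify_isoforms(reads)
        assert p.level == pytest.approx(0.70)
        assert p.iso_class is IsoformClass.MEDIUM

    def test_all_unmodified_low(self):
        reads = [read_rec(i, "t1", 2, 0) for i in range(15)]
        (p,), props, _ = classify_isoforms(reads)
        assert p.iso_class is IsoformClass.LOW
        assert props[IsoformClass.LOW] == 1.0

    def test_below_min_reads_unclassified(self):
        reads = [read_rec(i, "t1", 2, 1) for i in range(9)]
        profiles, _, unclassified = classify_isoforms(reads)
        assert profiles == []
        assert unclassified == 1

    def test_uninformative_reads_excluded(self):
        reads = [read_rec(i, "t1", 1, 1) for i in range(10)]
        reads += [read_rec(100 + i, "t1", 0, 0) for i in range(10)]
        (p,), _, _ = classify_isoforms(reads)
        assert p.n_reads == 10
        assert p.level == 1.0

    def test_proportions_sum_to_one(self):
        reads = []
        for t, frac in (("a", 0.1), ("b", 0.5), ("c", 0.9)):
            n_mod_reads = int(frac * 20)
            reads += [read_rec(f"{t}{i}", t, 2, 1 if i < n_mod_reads else 0) for i in range(20)]
        _, props, _ = classify_isoforms(reads)
        assert sum(props.values()) == pytest.approx(1.0)


class TestRestoration:
    def _summaries(self, treated_levels, untreated_levels, cov=50):
        t = aggregate_condition(
            [rec(i, int(round(l * cov)), cov, "r1", "treated") for i, l in enumerate(treated_levels)]
        )
        u = aggregate_condition(
            [rec(i, int(round(l * cov)), cov, "r1", "untreated") for i, l in enumerate(untreated_levels)]
        )
        return t, u

    def test_restored_site(self):
        t, u = self._summaries([0.36], [0.20])
        res = restoration_analysis([("chr1", 0, "+")], t, u)
        assert res.n_restored == 1

    def test_below_threshold_not_restored(self):
        t, u = self._summaries([0.28], [0.20])
        res = restoration_analysis([("chr1", 0, "+")], t, u)
        assert res.n_restored == 0

    def test_fraction(self):
        treated = [0.40, 0.40, 0.20, 0.20, 0.20, 0.20, 0.20, 0.20]
        untreated = [0.20] * 8
        t, u = self._summaries(treated, untreated)
        res = restoration_analysis([("chr1", i, "+") for i in range(8)], t, u)
        assert res.n_eligible == 8
        assert res.fraction == pytest.approx(0.25)

    def test_empty_denominator_is_error(self):
        t, u = self._summaries([0.4], [0.2], cov=5)  # fails coverage filter
        with pytest.raises(ValueError):
            restoration_analysis([("chr1", 0, "+")], t, u, min_agg_cov=20)


def test_metagene_histogram_bins():
    xs = [0.0, 1.05, 2.0, 2.05, 2.95, 3.0, -0.1]
    hist = metagene_histogram(xs, n_bins=30)
    assert len(hist) == 30
    assert sum(c for _, _, c in hist) == 5  # 3.0 and -0.1 ignored
    assert hist[20][2] == 2  # bin [2.0, 2.1) holds 2.0 and 2.05
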