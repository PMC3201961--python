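from collections import Counter

import numpy as np
import pytest

from conftest import make_tetrad
from tetracomb.crossover_engine import (
    CrossOverConfig,
    classify_tetrad,
    event_position_and_length,
    find_crossovers,
    pair_double_co_chromatids,
)
from tetracomb.synthetic_data import SimTetradConfig, simulate_tetrad_batch


class TestFindCrossovers:
    def test_single_reciprocal_switch(self):
        tetrad = make_tetrad({5: [(1000, (0, 1, 1, 0)), (2000, (0, 1, 0, 1))]})
        (co,) = find_crossovers(tetrad)
        assert co.chromatids == (3, 4)
        assert (co.flank_left, co.flank_right) == (1000, 2000)
        assert co.position == 1500

    def test_four_strand_switch_is_double_candidate(self):
        tetrad = make_tetrad({1: [(1000, (0, 0, 1, 1)), (2000, (1, 1, 0, 0))]})
        (co,) = find_crossovers(tetrad)
        assert co.is_double

    def test_no_switch_no_co(self, small_parental_tetrad):
        assert find_crossovers(small_parental_tetrad) == []

    def test_non22_markers_do_not_define_cos(self):
        # 3:1 marker between two identical 2:2 markers: a conversion, not a CO
        tetrad = make_tetrad(
            {1: [(1000, (0, 1, 1, 0)), (1500, (1, 1, 1, 0)), (2000, (0, 1, 1, 0))]}
        )
        assert find_crossovers(tetrad) == []

    def test_matches_naive_scan_on_simulated_tetrads(self):
        tetrads, _ = simulate_tetrad_batch(2, seed=42)
        for tetrad in tetrads:
            found = find_crossovers(tetrad)
            expected = []
            for chrom in tetrad.chromosomes():
                pos, geno = tetrad.chromosome(chrom)
                rows = [
                    (int(p), tuple(int(x) for x in g))
                    for p, g in zip(pos, geno)
                    if sum(g) == 2
                ]
                for (p1, g1), (p2, g2) in zip(rows, rows[1:]):
                    diff = tuple(i + 1 for i in range(4) if g1[i] != g2[i])
                    if diff:
                        expected.append((chrom, p1, p2, diff))
            got = [
                (c.chromosome, c.flank_left, c.flank_right, c.chromatids)
                for c in found
            ]
            assert got == expected


class TestConnectedGcTyping:
    def test_co_without_tract_is_type0(self):
        tetrad = make_tetrad({1: [(1000, (0, 1, 1, 0)), (2000, (0, 1, 0, 1))]})
        report = classify_tetrad(tetrad)
        (co,) = report.crossovers
        assert co.co_type == 0
        assert co.linked_gc_ids == ()

    def test_tract_on_crossing_chromatid_type1(self):
        # crossing chromatids 3 and 4; two 1:3 markers between their switches
        tetrad = make_tetrad(
            {
                1: [
                    (1000, (0, 1, 1, 0)),
                    (1200, (0, 1, 1, 1)),
                    (1400, (0, 1, 1, 1)),
                    (2000, (0, 1, 0, 1)),
                ]
            }
        )
        report = classify_tetrad(tetrad)
        (co,) = report.crossovers
        assert co.co_type == 1
        (tract,) = report.tracts
        assert 1 in tract.gc_types
        assert tract.marker_count == 2
        assert (tract.est_start, tract.est_end) == (1100, 1700)
        assert tract.length_est == 600
        assert tract.length_min == 200
        assert tract.length_max == 1000
        # CO position: midpoint of the two per-chromatid switch midpoints
        assert co.position == pytest.approx((1100 + 1700) / 2)

    def test_tract_on_noncrossing_chromatid_type2_gc6(self):
        # CO between spores 2 and 3; 3:1 tract in spore 1
        tetrad = make_tetrad(
            {
                1: [
                    (1000, (1, 1, 0, 0)),
                    (1500, (0, 1, 0, 0)),
                    (2000, (1, 0, 1, 0)),
                ]
            }
        )
        report = classify_tetrad(tetrad)
        (co,) = report.crossovers
        assert co.co_type == 2
        assert co.chromatids == (2, 3)
        (tract,) = report.tracts
        assert 6 in tract.gc_types
        assert tract.chromatids == (1,)
        assert tract.segregation_class == "3:1"

    def test_intervening_40_tract_gives_type3(self):
        tetrad = make_tetrad(
            {
                1: [
                    (1000, (1, 1, 0, 0)),
                    (1500, (0, 0, 0, 0)),
                    (2000, (0, 1, 1, 0)),
                ]
            }
        )
        report = classify_tetrad(tetrad)
        (co,) = report.crossovers
        assert co.co_type == 3

    def test_plain_double_co_is_type5(self):
        tetrad = make_tetrad({1: [(1000, (0, 0, 1, 1)), (2000, (1, 1, 0, 0))]})
        report = classify_tetrad(tetrad)
        (co,) = report.crossovers
        assert co.co_type == 5
        assert co.is_double
        assert len(co.chromatid_pairs) == 2


class TestMergeCloseCos:
    SAME_PAIR = {
        1: [
            (1000, (0, 1, 1, 0)),
            (2000, (1, 0, 1, 0)),
            (4000, (1, 0, 1, 0)),
            (5000, (0, 1, 1, 0)),
        ]
    }
    THREE_CHROMATIDS = {
        1: [
            (1000, (0, 1, 1, 0)),
            (2000, (1, 0, 1, 0)),
            (4000, (1, 0, 1, 0)),
            (5000, (1, 1, 0, 0)),
        ]
    }

    def test_same_two_chromatids_become_gc_type5(self):
        report = classify_tetrad(make_tetrad(self.SAME_PAIR))
        assert report.crossovers == []
        (tract,) = report.tracts
        assert tract.gc_types == {5}
        assert tract.chromatids == (1, 2)
        assert tract.length_est == 3000  # between the two CO positions
        assert tract.length_min == 2000
        assert tract.length_max == 4000
        assert tract.marker_count == 2
        assert tract.is_nco

    def test_three_chromatids_become_co_type8(self):
        report = classify_tetrad(make_tetrad(self.THREE_CHROMATIDS))
        (co,) = report.crossovers
        assert co.co_type == 8
        # COs (1,2) then (2,3): the shared chromatid 2 carries the conversion
        assert co.chromatids == (1, 3)
        assert co.position == 3000
        (tract,) = report.tracts
        assert tract.gc_types == {6}
        assert tract.chromatids == (2,)

    def test_distant_pair_left_unmerged(self):
        data = {
            1: [
                (1000, (0, 1, 1, 0)),
                (2000, (1, 0, 1, 0)),
                (7000, (1, 0, 1, 0)),
                (8000, (0, 1, 1, 0)),
            ]
        }
        report = classify_tetrad(make_tetrad(data))
        assert len(report.crossovers) == 2
        assert all(c.co_type == 0 for c in report.crossovers)

    def test_merge_range_zero_disables_merging(self):
        report = classify_tetrad(
            make_tetrad(self.SAME_PAIR), CrossOverConfig(merge_range=0, gc_assoc_range=0)
        )
        assert len(report.crossovers) == 2

    def test_three_close_cos_flagged_not_merged(self):
        data = {
            1: [
                (1000, (0, 1, 1, 0)),
                (2000, (1, 0, 1, 0)),
                (3000, (0, 1, 1, 0)),
                (4000, (1, 0, 1, 0)),
            ]
        }
        report = classify_tetrad(make_tetrad(data))
        assert len(report.crossovers) == 3
        assert len(report.flags) == 1
        assert "inspect" in report.flags[0]

    def test_four_distinct_chromatids_kept_and_flagged(self):
        data = {
            1: [
                (1000, (0, 1, 1, 0)),
                (2000, (1, 0, 1, 0)),
                (4000, (1, 0, 1, 0)),
                (5000, (1, 0, 0, 1)),
            ]
        }
        report = classify_tetrad(make_tetrad(data))
        assert len(report.crossovers) == 2
        assert any("four distinct" in f for f in report.flags)

    def test_co_count_monotone_in_merge_range(self):
        tetrads, _ = simulate_tetrad_batch(5, seed=5)
        for ranges in [(0, 2500, 5000)]:
            counts = []
            for r in ranges:
                cfg = CrossOverConfig(merge_range=r, gc_assoc_range=r)
                counts.append(
                    sum(classify_tetrad(t, cfg).co_count for t in tetrads)
                )
            assert counts[0] >= counts[1] >= counts[2]


class TestDetachedTracts:
    def test_run_of_three_is_one_tract(self):
        rows = [(1000, (0, 1, 1, 0))]
        rows += [(1000 + 100 * i, (1, 1, 1, 0)) for i in range(1, 4)]
        rows += [(2000, (0, 1, 1, 0))]
        report = classify_tetrad(make_tetrad({1: rows}))
        (tract,) = report.tracts
        assert tract.marker_count == 3
        assert tract.chromatids == (1,)
        assert tract.gc_types == {0}
        assert tract.segregation_class == "1:3"

    def test_isolated_marker_is_its_own_tract(self):
        rows = [
            (1000, (0, 1, 1, 0)),
            (1500, (0, 0, 1, 0)),
            (2000, (0, 1, 1, 0)),
            (3000, (0, 1, 1, 1)),
            (4000, (0, 1, 1, 0)),
        ]
        report = classify_tetrad(make_tetrad({1: rows}))
        assert len(report.tracts) == 2
        assert all(t.marker_count == 1 for t in report.tracts)
        assert all(t.length_min == 0 for t in report.tracts)

    def test_adjacent_runs_on_different_chromatids_split(self):
        rows = [
            (1000, (0, 1, 1, 0)),
            (1100, (1, 1, 1, 0)),
            (1200, (0, 1, 1, 1)),
            (2000, (0, 1, 1, 0)),
        ]
        report = classify_tetrad(make_tetrad({1: rows}))
        assert len(report.tracts) == 2

    def test_chromosome_end_tracts_get_types_3_and_4(self):
        rows = [
            (1000, (1, 1, 1, 0)),   # first genotyped marker converted
            (2000, (0, 1, 1, 0)),
            (3000, (0, 1, 1, 0)),
            (4000, (0, 1, 0, 0)),   # last genotyped marker converted
        ]
        report = classify_tetrad(make_tetrad({1: rows}))
        types = sorted(frozenset(t.gc_types) for t in report.tracts)
        assert frozenset({0, 3}) in types
        assert frozenset({0, 4}) in types
        first = [t for t in report.tracts if 3 in t.gc_types][0]
        assert first.open_start
        assert first.first_marker_pos == 1000

    def test_detached_40_tract_is_type2(self):
        rows = [
            (1000, (0, 1, 1, 0)),
            (1500, (1, 1, 1, 1)),
            (2000, (0, 1, 1, 0)),
        ]
        report = classify_tetrad(make_tetrad({1: rows}))
        (tract,) = report.tracts
        assert tract.gc_types == {2}
        assert tract.segregation_class == "0:4"
        assert not tract.is_nco


class TestAssociation:
    @staticmethod
    def _seg_with_co_and_tract(gap, tract_spore, co_at=10_000):
        # CO on chromatids (1,2) at co_at; detached single-marker tract at
        # co_at + gap on the requested spore (0-based)
        left = [0, 1, 1, 0]
        right = [1, 0, 1, 0]
        conv = list(right)
        conv[tract_spore] = 1 - conv[tract_spore]
        rows = [
            (co_at - 500, tuple(left)),
            (co_at + 500, tuple(right)),
            (int(co_at + gap - 200), tuple(right)),
            (int(co_at + gap), tuple(conv)),
            (int(co_at + gap + 200), tuple(right)),
        ]
        return make_tetrad({1: rows})

    def test_nearby_tract_on_uninvolved_chromatid_is_type6(self):
        report = classify_tetrad(self._seg_with_co_and_tract(4000, tract_spore=3))
        tract = [t for t in report.tracts if t.marker_count == 1][0]
        assert tract.gc_types == {6}
        assert tract.is_nco

    def test_nearby_tract_on_involved_chromatid_is_type7(self):
        report = classify_tetrad(self._seg_with_co_and_tract(4000, tract_spore=0))
        tract = [t for t in report.tracts if t.marker_count == 1][0]
        assert tract.gc_types == {7}
        assert not tract.is_nco

    def test_distant_tract_stays_type0(self):
        report = classify_tetrad(self._seg_with_co_and_tract(10_000, tract_spore=3))
        tract = [t for t in report.tracts if t.marker_count == 1][0]
        assert tract.gc_types == {0}

    def test_partner_type1_tract_gains_type8(self):
        # CO with connected tract (Type 1) plus detached Type 6 tract nearby
        rows = [
            (9500, (0, 1, 1, 0)),
            (9800, (1, 1, 1, 0)),     # connected tract on crossing chromatid 1
            (10_500, (1, 0, 1, 0)),
            (13_800, (1, 0, 1, 0)),
            (14_000, (1, 0, 0, 0)),   # detached tract on uninvolved chromatid 3
            (14_200, (1, 0, 1, 0)),
        ]
        report = classify_tetrad(make_tetrad({1: rows}))
        (co,) = report.crossovers
        assert co.co_type == 1
        connected = [t for t in report.tracts if 1 in t.gc_types][0]
        detached = [t for t in report.tracts if 6 in t.gc_types][0]
        assert 8 in connected.gc_types
        assert 10 not in connected.gc_types
        assert detached.nearby_co is not None

    def test_lone_type1_tract_gets_type10(self):
        rows = [
            (1000, (0, 1, 1, 0)),
            (1200, (0, 1, 1, 1)),
            (2000, (0, 1, 0, 1)),
        ]
        report = classify_tetrad(make_tetrad({1: rows}))
        (tract,) = report.tracts
        assert {1, 10} <= tract.gc_types
        assert not (tract.gc_types & {8, 9})

    def test_tie_goes_to_leftmost_co(self):
        # two identical-distance COs flanking a central tract
        rows = [
            (5500, (0, 1, 1, 0)),
            (6500, (1, 0, 1, 0)),     # CO1 at 6000, chromatids (1,2)
            (9800, (1, 0, 1, 0)),
            (10_000, (1, 0, 0, 0)),   # tract on spore 3, equidistant to both COs
            (10_200, (1, 0, 1, 0)),
            (13_500, (1, 0, 1, 0)),
            (14_500, (1, 1, 0, 0)),   # CO2 at 14000, chromatids (2,3)
        ]
        report = classify_tetrad(
            make_tetrad({1: rows}), CrossOverConfig(gc_assoc_range=50_000)
        )
        tract = [t for t in report.tracts if t.marker_count == 1][0]
        assert tract.nearby_co is not None
        chosen = report.crossovers[tract.nearby_co]
        assert chosen.position == min(c.position for c in report.crossovers)
        # spore 3 is uninvolved in the left CO (1,2) -> Type 6
        assert tract.gc_types == {6}


class TestPositionsAndLengths:
    def test_simple_co_midpoint(self):
        metrics = event_position_and_length(1000, 2000)
        assert metrics["position"] == 1500

    def test_tract_metrics_from_fig_style_example(self):
        metrics = event_position_and_length(1000, 2000, [1200, 1400])
        assert metrics["est_start"] == 1100
        assert metrics["est_end"] == 1700
        assert metrics["length_est"] == 600
        assert metrics["length_min"] == 200
        assert metrics["length_max"] == 1000

    def test_single_marker_tract_has_degenerate_minimum(self):
        metrics = event_position_and_length(1000, 2000, [1500])
        assert metrics["length_min"] == 0
        assert metrics["length_max"] == 1000

    def test_open_end_uses_terminal_marker(self):
        metrics = event_position_and_length(1000, None, [1200, 1400])
        assert metrics["est_end"] == 1400
        assert metrics["open_end"]

    def test_half_integer_precision_is_kept(self):
        metrics = event_position_and_length(1000, 2001)
        assert metrics["position"] == 1500.5


class TestDoubleCoPairing:
    def test_deterministic_under_seed(self):
        first = pair_double_co_chromatids((0, 0, 1, 1), np.random.default_rng(17))
        again = pair_double_co_chromatids((0, 0, 1, 1), np.random.default_rng(17))
        assert first == again

    def test_both_pairings_equally_likely(self):
        rng = np.random.default_rng(0)
        seen = Counter(
            pair_double_co_chromatids((0, 1, 0, 1), rng) for _ in range(10_000)
        )
        assert len(seen) == 2
        for count in seen.values():
            assert abs(count - 5000) < 200  # ~4 sigma for a fair coin

    def test_different_seeds_eventually_differ(self):
        a = [pair_double_co_chromatids((0, 0, 1, 1), np.random.default_rng(s))
             for s in range(100)]
        b = [pair_double_co_chromatids((0, 0, 1, 1), np.random.default_rng(s + 1000))
             for s in range(100)]
        assert a != b

    def test_pairs_join_opposite_genotypes(self):
        pairs = pair_double_co_chromatids((1, 0, 1, 0), np.random.default_rng(3))
        genos = (1, 0, 1, 0)
        for i, j in pairs:
            assert genos[i - 1] != genos[j - 1]


class TestClassifyTetrad:
    def test_parental_seg_has_no_events_and_all_e0(self, small_parental_tetrad):
        report = classify_tetrad(small_parental_tetrad)
        assert report.co_count == 0
        assert report.tracts == []
        assert report.e0_chromosomes == [1, 2]

    def test_chromosome_with_co_co_gc_and_nco(self):
        # one chromosome carrying a plain CO, a CO with connected GC, and an NCO
        rows = [
            (1000, (0, 1, 1, 0)),
            (10_000, (0, 1, 1, 0)),
            (11_000, (1, 0, 1, 0)),     # CO type 0 on (1,2)
            (40_000, (1, 0, 1, 0)),
            (40_500, (1, 0, 1, 1)),     # connected tract
            (41_000, (1, 0, 0, 1)),     # CO type 1 on (3,4)
            (80_000, (1, 0, 0, 1)),
            (80_500, (0, 0, 0, 1)),     # detached NCO in spore 1
            (81_000, (1, 0, 0, 1)),
            (90_000, (1, 0, 0, 1)),
        ]
        report = classify_tetrad(make_tetrad({9: rows}))
        assert report.co_count == 2
        assert sorted(c.co_type for c in report.crossovers) == [0, 1]
        nco = [t for t in report.tracts if 0 in t.gc_types]
        assert len(nco) == 1
        assert report.nco_count == 1

    def test_spore_permutation_preserves_types_and_positions(self):
        tetrads, _ = simulate_tetrad_batch(
            1, SimTetradConfig(min_event_separation_bp=6000), seed=9
        )
        tetrad = tetrads[0]
        base = classify_tetrad(tetrad)
        permuted = classify_tetrad(tetrad.permute_spores([2, 0, 3, 1]))
        assert Counter(c.co_type for c in base.crossovers) == Counter(
            c.co_type for c in permuted.crossovers
        )
        assert sorted(c.position for c in base.crossovers) == sorted(
            c.position for c in permuted.crossovers
        )
        assert Counter(frozenset(t.gc_types) for t in base.tracts) == Counter(
            frozenset(t.gc_types) for t in permuted.tracts
        )

    def test_every_non22_marker_in_exactly_one_tract(self):
        tetrads, _ = simulate_tetrad_batch(3, seed=21)
        for tetrad in tetrads:
            report = classify_tetrad(tetrad)
            n_non22 = sum(
                int(np.sum(tetrad.chromosome(c)[1].sum(axis=1) != 2))
                for c in tetrad.chromosomes()
            )
            covered = sum(
                t.marker_count for t in report.tracts if t.segregation_class != "2:2"
            )
            assert covered == n_non22

    def test_tract_length_ordering_invariant(self):
        tetrads, _ = simulate_tetrad_batch(3, seed=33)
        for tetrad in tetrads:
            for t in classify_tetrad(tetrad).tracts:
                assert t.length_min <= t.length_est + 1e-9
                assert t.length_est <= t.length_max + 1e-9
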