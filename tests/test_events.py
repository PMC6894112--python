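"""Event calling: masking, segmentation, classification rules, invariances."""

import itertools

import numpy as np
import pytest

from meiomap import (
    AscusGenotypes,
    ChromosomeInfo,
    ChromosomeSet,
    LocusPair,
    MarkerMap,
    MISSING,
)
from meiomap import events as ev
from meiomap import simulate as sim

from conftest import clean_true_crossovers, make_ascus, roundtrip_stats


class TestMaskMarkers:
    def test_subtelomere_boundary(self, genome):
        pos = np.array([5_000, 8_000, 8_001, 100_000])
        markers = MarkerMap({"chr1": pos})
        m = np.tile([0, 0, 1, 1], (4, 1)).astype(np.int8)
        ascus = AscusGenotypes("t", ("a", "b", "c", "d"), {"chr1": m})
        masked, mmk = ev.mask_markers(ascus, markers, genome)
        # mask is [1, 8000]: 5,000 and 8,000 removed, 8,001 retained
        assert mmk.positions["chr1"].tolist() == [8_001, 100_000]

    def test_missing_rows_dropped(self, genome):
        pos = np.arange(10_000, 30_000, 1_000)
        markers = MarkerMap({"chr1": pos})
        m = np.tile([0, 0, 1, 1], (20, 1)).astype(np.int8)
        m[7, 2] = MISSING
        ascus = AscusGenotypes("t", ("a", "b", "c", "d"), {"chr1": m})
        masked, mmk = ev.mask_markers(ascus, markers, genome)
        assert len(mmk.positions["chr1"]) == 19
        assert 17_000 not in mmk.positions["chr1"]

    def test_drop_equals_keep_and_skip_oracle(self, genome):
        # events after dropping missing rows == events on the complete matrix
        pos = np.arange(100_000, 120_000, 1_000)
        complete = np.tile([0, 0, 1, 1], (20, 1)).astype(np.int8)
        complete[10:] = [0, 1, 0, 1]  # one reciprocal b/c switch
        with_missing = complete.copy()
        with_missing[4, 2] = MISSING  # inside a constant stretch
        markers = MarkerMap({"chr1": pos})
        a_complete = AscusGenotypes("t", ("a", "b", "c", "d"), {"chr1": complete})
        a_missing = AscusGenotypes("t", ("a", "b", "c", "d"), {"chr1": with_missing})
        es1 = ev.call_ascus(a_complete, markers, genome)
        es2 = ev.call_ascus(a_missing, markers, genome)
        assert [c.spores for c in es1.crossovers] == [c.spores for c in es2.crossovers]
        assert len(es1.crossovers) == len(es2.crossovers) == 1

    def test_unknown_chromosome_errors(self, small_genome):
        ascus, markers = make_ascus([[0, 0, 1, 1]] * 3, chrom="nope")
        with pytest.raises(ValueError, match="nope"):
            ev.mask_markers(ascus, markers, small_genome)


class TestSegmentation:
    def test_constant_vector_single_segment(self):
        ascus, markers = make_ascus([[0, 0, 1, 1]] * 7)
        segs = ev.segment_ascus(ascus, markers)["chrA"]
        assert len(segs) == 1
        assert (segs[0].first_marker_index, segs[0].last_marker_index) == (0, 6)

    def test_two_segment_boundary(self):
        vecs = [[0, 0, 1, 1]] * 5 + [[0, 1, 0, 1]] * 5
        ascus, markers = make_ascus(vecs)
        segs = ev.segment_ascus(ascus, markers)["chrA"]
        assert [(s.first_marker_index, s.last_marker_index) for s in segs] == [(0, 4), (5, 9)]
        assert segs[0].genotype_vector == (0, 0, 1, 1)
        assert segs[1].genotype_vector == (0, 1, 0, 1)

    def test_matches_direct_scan_oracle(self):
        rng = np.random.default_rng(42)
        m = rng.integers(0, 2, size=(200, 4)).astype(np.int8)
        ascus, markers = make_ascus(m)
        segs = ev.segment_ascus(ascus, markers)["chrA"]
        # oracle: naive linear scan
        oracle = []
        start = 0
        for i in range(1, len(m) + 1):
            if i == len(m) or tuple(m[i]) != tuple(m[start]):
                oracle.append((start, i - 1, tuple(int(v) for v in m[start])))
                start = i
        assert [(s.first_marker_index, s.last_marker_index, s.genotype_vector)
                for s in segs] == oracle
        # concatenation covers all markers exactly once
        covered = sum(s.support for s in segs)
        assert covered == len(m)


@pytest.fixture
def plain_genome():
    """One unmasked chromosome so fixtures need no mask bookkeeping."""
    return ChromosomeSet((ChromosomeInfo("chrA", 1_000_000, 500_000),))


def _call(vectors, plain_genome, labels=None, positions=None, **kw):
    ascus, markers = make_ascus(vectors, labels=labels, positions=positions)
    return ev.call_ascus(ascus, markers, plain_genome, **kw)


class TestCallingRules:
    def test_constant_matrix_no_events(self, plain_genome):
        es = _call([[0, 0, 1, 1]] * 12, plain_genome)
        assert not es.crossovers and not es.tracts and not es.complex_regions

    def test_crossover_and_bounded_tract(self, plain_genome):
        # 12 markers: reciprocal b/c switch at index 6, 2-marker flip in spore a
        vecs = ([[0, 0, 1, 1]] * 2 + [[1, 0, 1, 1]] * 2 + [[0, 0, 1, 1]] * 2
                + [[0, 1, 0, 1]] * 6)
        es = _call(vecs, plain_genome)
        assert len(es.crossovers) == 1
        assert set(es.crossovers[0].spores) == {"b", "c"}
        assert len(es.tracts) == 1
        tract = es.tracts[0]
        assert tract.ratio_class == "3:1"
        assert tract.recipient_spores == ("a",)
        assert tract.marker_support == 2

    def test_single_marker_tract_filtered(self, plain_genome):
        vecs = ([[0, 0, 1, 1]] * 3 + [[1, 0, 1, 1]] * 1 + [[0, 0, 1, 1]] * 2
                + [[0, 1, 0, 1]] * 6)
        es = _call(vecs, plain_genome)
        assert len(es.crossovers) == 1
        assert len(es.tracts) == 0
        assert es.filters_applied["n_single_marker_filtered"] == 1

    def test_filter_monotonicity(self, plain_genome):
        vecs = ([[0, 0, 1, 1]] * 3 + [[1, 0, 1, 1]] * 1 + [[0, 0, 1, 1]] * 2
                + [[0, 1, 0, 1]] * 6)
        with_filter = _call(vecs, plain_genome, single_marker_filter=True)
        without = _call(vecs, plain_genome, single_marker_filter=False)
        assert len(with_filter.crossovers) + len(with_filter.tracts) <= \
            len(without.crossovers) + len(without.tracts)

    def test_four_zero_tract(self, plain_genome):
        vecs = [[0, 0, 1, 1]] * 3 + [[1, 1, 1, 1]] * 3 + [[0, 0, 1, 1]] * 3
        es = _call(vecs, plain_genome)
        assert not es.crossovers
        assert len(es.tracts) == 1
        assert es.tracts[0].ratio_class == "4:0"

    def test_crossover_with_associated_conversion(self, plain_genome):
        # 0011 -> (spore a converted: 1011) -> 1010 = a/d reciprocal exchange
        vecs = [[0, 0, 1, 1]] * 3 + [[1, 0, 1, 1]] * 2 + [[1, 0, 1, 0]] * 3
        es = _call(vecs, plain_genome)
        assert len(es.crossovers) == 1
        co = es.crossovers[0]
        assert set(co.spores) == {"a", "d"}
        assert co.has_associated_conversion
        assert not es.tracts  # counted once, as a crossover

    def test_complex_three_spore_boundary_flagged(self, plain_genome):
        vecs = [[0, 0, 1, 1]] * 4 + [[1, 1, 0, 1]] * 4
        es = _call(vecs, plain_genome)
        assert not es.crossovers
        assert len(es.complex_regions) == 1

    def test_two_distinct_same_pair_crossovers(self, plain_genome):
        vecs = [[0, 0, 1, 1]] * 4 + [[1, 0, 0, 1]] * 4 + [[0, 0, 1, 1]] * 4
        es = _call(vecs, plain_genome)
        assert len(es.crossovers) == 2
        assert all(set(c.spores) == {"a", "c"} for c in es.crossovers)

    def test_crossover_positions_bracket_boundary(self, plain_genome):
        pos = 10_000 + 1_000 * np.arange(10)
        vecs = [[0, 0, 1, 1]] * 4 + [[0, 1, 0, 1]] * 6
        es = _call(vecs, plain_genome, positions=pos)
        co = es.crossovers[0]
        assert (co.left_pos, co.right_pos) == (13_000, 14_000)
        assert co.midpoint_bp == 13_500


class TestTrioRules:
    def test_persistent_single_switch_is_unsampled_crossover(self, plain_genome):
        vecs = [[0, 1, 1]] * 5 + [[1, 1, 1, ]] * 0 + [[0, 1, 0]] * 5
        es = _call(vecs, plain_genome, labels=("b", "c", "d"))
        assert len(es.crossovers) == 1
        assert es.crossovers[0].spores == ("d", "unsampled")

    def test_bounded_single_spore_tract(self, plain_genome):
        vecs = [[0, 1, 1]] * 4 + [[0, 0, 1]] * 3 + [[0, 1, 1]] * 4
        es = _call(vecs, plain_genome, labels=("b", "c", "d"))
        assert not es.crossovers
        assert len(es.tracts) == 1
        assert es.tracts[0].recipient_spores == ("c",)

    def test_distant_double_switch_stays_two_crossovers(self, plain_genome):
        # same bounded pattern but the deviant run spans 80 kb: far beyond
        # tract scale, so it reads as two exchanges with the unsampled spore
        pos = np.concatenate([
            10_000 + 1_000 * np.arange(4),
            200_000 + 40_000 * np.arange(3),
            400_000 + 1_000 * np.arange(4),
        ])
        vecs = [[0, 1, 1]] * 4 + [[0, 0, 1]] * 3 + [[0, 1, 1]] * 4
        es = _call(vecs, plain_genome, labels=("b", "c", "d"), positions=pos)
        assert len(es.crossovers) == 2
        assert not es.tracts

    def test_whole_chromosome_sweep(self, plain_genome):
        es = _call([[1, 1, 1]] * 20, plain_genome, labels=("b", "c", "d"))
        assert not es.crossovers
        assert len(es.tracts) == 1
        assert es.tracts[0].ratio_class == "trio-skew"
        assert es.tracts[0].marker_support == 20


class TestInvariances:
    @pytest.fixture
    def simulated(self, genome):
        params = sim.SimParams.calibrated(genome)
        markers = sim.simulate_marker_map(genome, 1.0, seed=5)
        ascus, _ = sim.simulate_meiosis(markers, genome, params,
                                        rng=np.random.default_rng(3))
        return ascus, markers

    def test_marker_order_reversal(self, simulated, genome):
        ascus, markers = simulated
        es = ev.call_ascus(ascus, markers, genome)
        flipped_matrix = {}
        flipped_pos = {}
        for chrom in genome:
            pos = markers.positions[chrom.name]
            flipped_pos[chrom.name] = np.sort(chrom.length_bp + 1 - pos)
            flipped_matrix[chrom.name] = ascus.matrix[chrom.name][::-1]
        # mirror the genome metadata as well
        mirrored = ChromosomeSet(tuple(
            ChromosomeInfo(
                c.name, c.length_bp, c.length_bp + 1 - c.centromere_midpoint_bp,
                tuple(sorted((c.length_bp + 1 - hi, c.length_bp + 1 - lo)
                             for lo, hi in c.subtelomere_masks)))
            for c in genome))
        flipped = AscusGenotypes(ascus.ascus_id, ascus.spore_labels, flipped_matrix)
        es_f = ev.call_ascus(flipped, MarkerMap(flipped_pos), mirrored)
        lens = {c.name: c.length_bp for c in genome}
        orig = sorted((c.chromosome, lens[c.chromosome] + 1 - c.right_pos,
                       lens[c.chromosome] + 1 - c.left_pos, frozenset(c.spores))
                      for c in es.crossovers)
        mirr = sorted((c.chromosome, c.left_pos, c.right_pos, frozenset(c.spores))
                      for c in es_f.crossovers)
        assert orig == mirr

    def test_spore_relabeling(self, simulated, genome):
        ascus, markers = simulated
        es = ev.call_ascus(ascus, markers, genome)
        perm = (2, 0, 3, 1)
        relabeled = AscusGenotypes(
            ascus.ascus_id, ascus.spore_labels,
            {c: m[:, list(perm)] for c, m in ascus.matrix.items()})
        es_p = ev.call_ascus(relabeled, markers, genome)
        # column k of the relabeled matrix, labeled spore_labels[k], holds
        # the original spore spore_labels[perm[k]]
        lab = {ascus.spore_labels[k]: ascus.spore_labels[perm[k]]
               for k in range(4)}
        orig = sorted((c.chromosome, c.left_pos, c.right_pos, frozenset(c.spores))
                      for c in es.crossovers)
        back = sorted((c.chromosome, c.left_pos, c.right_pos,
                       frozenset(lab.get(s, s) for s in c.spores))
                      for c in es_p.crossovers)
        assert orig == back

    def test_boundary_count_accounting(self, plain_genome):
        # boundaries = COs(no conv) + 2 x bounded tracts + 4:0 boundaries
        #              + 2 x CO-with-conversion
        vecs = ([[0, 0, 1, 1]] * 3          # anchor
                + [[1, 0, 1, 1]] * 2        # bounded 3:1 tract   (2 boundaries)
                + [[0, 0, 1, 1]] * 3        # anchor
                + [[0, 1, 0, 1]] * 3        # clean CO            (1 boundary)
                + [[1, 1, 1, 1]] * 2        # 4:0 tract           (2 boundaries)
                + [[0, 1, 0, 1]] * 3        # back
                + [[0, 1, 1, 1]] * 2        # conversion in c ... (2 boundaries)
                + [[0, 0, 1, 1]] * 3)       # ... resolving as CO b/c with conversion
        ascus, markers = make_ascus(vecs)
        es = ev.call_ascus(ascus, markers, plain_genome)
        segs = ev.segment_ascus(ascus, markers)["chrA"]
        n_boundaries = len(segs) - 1
        clean_cos = sum(1 for c in es.crossovers if not c.has_associated_conversion)
        conv_cos = sum(1 for c in es.crossovers if c.has_associated_conversion)
        bounded = sum(1 for t in es.tracts if t.ratio_class in ("3:1", "1:3"))
        four_zero_bounds = sum(2 for t in es.tracts if t.ratio_class in ("4:0", "0:4"))
        assert n_boundaries == clean_cos + 2 * bounded + four_zero_bounds + 2 * conv_cos
        assert clean_cos == 1 and conv_cos == 1 and bounded == 1


class TestRoundTrip:
    def test_simulator_detector_recovery(self, genome):
        n_clean, n_rec, n_called, n_brack = roundtrip_stats(10, seed=23, genome=genome)
        assert n_clean > 100
        assert n_rec / n_clean >= 0.99
        assert n_brack == n_called  # every call brackets a true crossover

    def test_called_positions_bracket_truth(self, genome):
        params = sim.SimParams.calibrated(genome)
        markers, pairs = sim.simulate_experiment(genome, params, 5, 0, seed=31)
        for ascus, truth in pairs:
            es = ev.call_ascus(ascus, markers, genome)
            for c in clean_true_crossovers(truth, markers, genome):
                hits = [e for e in es.crossovers
                        if e.chromosome == c.chromosome
                        and e.left_pos <= c.position_bp < e.right_pos]
                assert len(hits) == 1


class TestTwoLocus:
    def test_pd(self):
        vecs = [[0, 0, 1, 1], [0, 0, 1, 1]]
        ascus, markers = make_ascus(vecs, chrom="chr1")
        pair = LocusPair("chr1", 9_900, 11_500)
        assert ev.classify_two_locus(ascus, pair, markers) == "PD"

    def test_npd(self):
        vecs = [[0, 0, 1, 1], [1, 1, 0, 0]]
        ascus, markers = make_ascus(vecs, chrom="chr1")
        assert ev.classify_two_locus(ascus, LocusPair("chr1", 9_900, 11_500),
                                     markers) == "NPD"

    def test_tt(self):
        vecs = [[0, 0, 1, 1], [0, 1, 0, 1]]
        ascus, markers = make_ascus(vecs, chrom="chr1")
        assert ev.classify_two_locus(ascus, LocusPair("chr1", 9_900, 11_500),
                                     markers) == "TT"

    def test_non_mendelian_unclassifiable(self):
        vecs = [[0, 0, 0, 1], [0, 1, 0, 1]]
        ascus, markers = make_ascus(vecs, chrom="chr1")
        assert ev.classify_two_locus(ascus, LocusPair("chr1", 9_900, 11_500),
                                     markers) == "unclassifiable"

    def test_exhaustive_two_locus_enumeration(self):
        # all 36 two-locus assignments with 2:2 at both loci
        counts = {"PD": 0, "NPD": 0, "TT": 0}
        markers = MarkerMap({"chr1": np.array([100, 200])})
        pair = LocusPair("chr1", 90, 210)
        for za in itertools.combinations(range(4), 2):
            for zb in itertools.combinations(range(4), 2):
                m = np.zeros((2, 4), dtype=np.int8)
                m[0, list(za)] = 1
                m[1, list(zb)] = 1
                ascus = AscusGenotypes("x", ("a", "b", "c", "d"), {"chr1": m})
                counts[ev.classify_two_locus(ascus, pair, markers)] += 1
        assert counts == {"PD": 6, "NPD": 6, "TT": 24}

    def test_requires_tetrad(self):
        vecs = [[0, 1, 1], [0, 1, 1]]
        ascus, markers = make_ascus(vecs, chrom="chr1", labels=("b", "c", "d"))
        with pytest.raises(ValueError, match="tetrad"):
            ev.classify_two_locus(ascus, LocusPair("chr1", 90, 210), markers)


class TestObligatoryDesignation:
    def _events(self, midpoints, genome):
        cos = tuple(
            ev.CrossoverEvent("chr1", m - 500, m + 500, ("a", "b")) for m in midpoints
        )
        return ev.EventSet("t", cos, (), (), {}, 4)

    def test_single_crossover_flagged(self, genome):
        pair = LocusPair("chr1", 1_304_539, 1_725_539)
        es = self._events([1_600_000], genome)
        out = ev.designate_obligatory(es, pair, genome)
        assert out.crossovers[0].obligatory

    def test_more_distal_of_two_flagged(self, genome):
        # distances 100 kb and 300 kb from CEN1: the 300-kb one is obligatory
        pair = LocusPair("chr1", 1_304_539, 1_725_539)
        es = self._events([1_404_539 + 100_000, 1_404_539 + 300_000], genome)
        out = ev.designate_obligatory(es, pair, genome)
        flags = [c.obligatory for c in out.crossovers]
        assert flags == [False, True]

    def test_three_crossovers_only_most_distal(self, genome):
        pair = LocusPair("chr1", 1_304_539, 1_725_539)
        mids = [1_404_539 + d for d in (50_000 + 100_000, 120_000, 310_000)]
        es = self._events(mids, genome)
        out = ev.designate_obligatory(es, pair, genome)
        # max-distance oracle
        cen = genome["chr1"].centromere_midpoint_bp
        far = max(out.crossovers, key=lambda c: abs(c.midpoint_bp - cen))
        assert [c.obligatory for c in out.crossovers] == [c is far for c in out.crossovers]

    def test_empty_interval_warns(self, genome):
        pair = LocusPair("chr1", 1_304_539, 1_725_539)
        es = self._events([2_500_000], genome)
        with pytest.warns(UserWarning, match="no crossover"):
            out = ev.designate_obligatory(es, pair, genome)
        assert not any(c.obligatory for c in out.crossovers)
        assert out.filters_applied["obligatory_interval_empty"]


class TestSegmentationProperties:
    """Hypothesis checks of the segmentation contract."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _segments_oracle(m):
        out, start = [], 0
        for i in range(1, len(m) + 1):
            if i == len(m) or tuple(m[i]) != tuple(m[start]):
                out.append((start, i - 1, tuple(int(v) for v in m[start])))
                start = i
        return out

    @given(st.lists(st.tuples(*([st.integers(0, 1)] * 4)), min_size=1, max_size=60))
    @settings(max_examples=50, derandomize=True)
    def test_segments_match_oracle_and_partition(self, rows):
        m = np.array(rows, dtype=np.int8)
        ascus, markers = make_ascus(m)
        segs = ev.segment_ascus(ascus, markers)["chrA"]
        assert [(s.first_marker_index, s.last_marker_index, s.genotype_vector)
                for s in segs] == self._segments_oracle(m)
        # partition: contiguous, covering, and adjacent segments differ
        assert segs[0].first_marker_index == 0
        assert segs[-1].last_marker_index == len(m) - 1
        for a, b in zip(segs, segs[1:]):
            assert b.first_marker_index == a.last_marker_index + 1
            assert a.genotype_vector != b.genotype_vector

    @given(st.lists(st.tuples(*([st.integers(0, 1)] * 4)), min_size=4, max_size=60))
    @settings(max_examples=50, derandomize=True)
    def test_single_marker_filter_monotone(self, rows):
        m = np.array(rows, dtype=np.int8)
        genome = ChromosomeSet((ChromosomeInfo("chrA", 1_000_000, 500_000),))
        ascus, markers = make_ascus(m)
        with_f = ev.call_ascus(ascus, markers, genome, single_marker_filter=True)
        without = ev.call_ascus(ascus, markers, genome, single_marker_filter=False)
        n_with = len(with_f.crossovers) + len(with_f.tracts)
        n_without = len(without.crossovers) + len(without.tracts)
        assert n_with <= n_without
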