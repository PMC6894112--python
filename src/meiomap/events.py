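"""Crossover and gene-conversion calling from ascus genotype matrices.

A chromosome is first cut into maximal runs of markers sharing one
segregation vector (one genotype per spore). Runs with the Mendelian
allele sum (2 of 4 in a tetrad; 1 or 2 of 3 in a trio) and either >=2
supporting markers or contact with the unmasked chromosome end serve as
*anchors*; everything between consecutive anchors is then classified by
deterministic rules (see :func:`call_events`). The rules replace the manual
scoring used in the original study with an explicit, reproducible decision
procedure; ambiguous patterns are flagged "complex" rather than silently
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    MISSING,
    AscusGenotypes,
    ChromosomeSet,
    LocusPair,
    MarkerMap,
)

__all__ = [
    "Segment",
    "CrossoverEvent",
    "ConversionTract",
    "ComplexRegion",
    "EventSet",
    "mask_markers",
    "segment_ascus",
    "call_events",
    "call_ascus",
    "classify_two_locus",
    "designate_obligatory",
]


@dataclass(frozen=True)
class Segment:
    """Maximal run of markers with a constant segregation vector."""

    chromosome: str
    first_marker_index: int
    last_marker_index: int
    genotype_vector: tuple[int, ...]

    @property
    def support(self) -> int:
        return self.last_marker_index - self.first_marker_index + 1

    @property
    def allele_sum(self) -> int:
        return int(sum(self.genotype_vector))


@dataclass(frozen=True)
class CrossoverEvent:
    """A reciprocal exchange, bracketed by its flanking informative markers."""

    chromosome: str
    left_pos: int
    right_pos: int
    spores: tuple[str, str]
    obligatory: bool = False
    has_associated_conversion: bool = False

    def __post_init__(self) -> None:
        if not self.left_pos < self.right_pos:
            raise ValueError("crossover interval requires left_pos < right_pos")
        if self.spores[0] == self.spores[1]:
            raise ValueError("crossover spores must be distinct")

    @property
    def midpoint_bp(self) -> int:
        return (self.left_pos + self.right_pos) // 2


@dataclass(frozen=True)
class ConversionTract:
    """A bounded non-Mendelian (3:1 / 4:0) segment: gene conversion."""

    chromosome: str
    start_pos: int
    end_pos: int
    ratio_class: str  # "3:1", "1:3", "4:0", "0:4" or "trio-skew"
    recipient_spores: tuple[str, ...]
    marker_support: int

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("tract requires start_pos <= end_pos")


@dataclass(frozen=True)
class ComplexRegion:
    """A boundary the deterministic rules cannot classify (never dropped silently)."""

    chromosome: str
    left_pos: int
    right_pos: int
    description: str


@dataclass(frozen=True)
class EventSet:
    """All events called for one ascus, with a record of the filters applied."""

    ascus_id: str
    crossovers: tuple[CrossoverEvent, ...]
    tracts: tuple[ConversionTract, ...]
    complex_regions: tuple[ComplexRegion, ...] = ()
    filters_applied: Mapping[str, object] = field(default_factory=dict)
    n_spores: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "crossovers", tuple(self.crossovers))
        object.__setattr__(self, "tracts", tuple(self.tracts))
        object.__setattr__(self, "complex_regions", tuple(self.complex_regions))

    def crossover_counts(self, chromosomes: Sequence[str]) -> dict[str, int]:
        counts = {c: 0 for c in chromosomes}
        for co in self.crossovers:
            counts[co.chromosome] = counts.get(co.chromosome, 0) + 1
        return counts


def mask_markers(
    ascus: AscusGenotypes,
    markers: MarkerMap,
    genome: ChromosomeSet,
    drop_missing: bool = True,
) -> tuple[AscusGenotypes, MarkerMap]:
    """Remove subtelomere-masked markers and (per ascus) markers with missing calls.

    Dropping rows with any missing spore call means segmentation never
    compares vectors of unequal information.
    """
    keep_map: dict[str, np.ndarray] = {}
    matrix: dict[str, np.ndarray] = {}
    for chrom_name, m in ascus.matrix.items():
        if chrom_name not in genome:
            raise ValueError(f"chromosome {chrom_name!r} absent from the genome config")
        chrom = genome[chrom_name]
        pos = markers.positions[chrom_name]
        keep = np.ones(len(pos), dtype=bool)
        for lo, hi in chrom.subtelomere_masks:
            keep &= ~((pos >= lo) & (pos <= hi))
        if drop_missing:
            keep &= ~np.any(m == MISSING, axis=1)
        keep_map[chrom_name] = keep
        matrix[chrom_name] = m[keep]
    for chrom_name in markers.positions:
        keep_map.setdefault(chrom_name, np.ones(len(markers.positions[chrom_name]), dtype=bool))
    masked_markers = markers.subset(keep_map)
    masked = AscusGenotypes(ascus.ascus_id, ascus.spore_labels, matrix)
    return masked, masked_markers


def segment_ascus(
    ascus: AscusGenotypes, markers: MarkerMap
) -> dict[str, list[Segment]]:
    """Cut each chromosome into maximal constant-vector runs.

    The concatenation of the returned runs covers all markers exactly once.
    Input should already be masked (no missing entries).
    """
    ascus.validate_against(markers)
    out: dict[str, list[Segment]] = {}
    for chrom, m in ascus.matrix.items():
        segs: list[Segment] = []
        n = m.shape[0]
        if n == 0:
            out[chrom] = segs
            continue
        change = np.flatnonzero(np.any(m[1:] != m[:-1], axis=1)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change - 1, [n - 1]))
        for s, e in zip(starts, ends):
            segs.append(Segment(chrom, int(s), int(e), tuple(int(v) for v in m[s])))
        out[chrom] = segs
    return out


def _ratio_class(vec: tuple[int, ...], n_spores: int) -> str:
    s = sum(vec)
    if n_spores == 4:
        return {0: "0:4", 1: "1:3", 3: "3:1", 4: "4:0"}.get(s, "2:2")
    return "trio-skew"


def _diff_spores(a: tuple[int, ...], b: tuple[int, ...]) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _is_reciprocal(a: tuple[int, ...], b: tuple[int, ...], diff: list[int]) -> bool:
    if len(diff) != 2:
        return False
    i, j = diff
    return a[i] != a[j] and sum(a) == sum(b)


class _Caller:
    """Stateful helper walking one chromosome's segment list."""

    def __init__(self, chrom: str, segs: list[Segment], pos: np.ndarray,
                 labels: tuple[str, ...], single_marker_filter: bool,
                 max_tract_span_bp: int = 25_000,
                 territory: tuple[int, int] | None = None):
        self.chrom = chrom
        self.segs = segs
        self.pos = pos
        self.labels = labels
        self.max_tract_span = max_tract_span_bp
        # extent of unmasked territory: a terminal event's exchange point can
        # lie anywhere between the outermost marker and this boundary
        if territory is None and len(pos):
            territory = (int(pos[0]), int(pos[-1]))
        self.territory = territory
        self.n = len(labels)
        self.mendel = {2} if self.n == 4 else {1, 2}
        self.filter = single_marker_filter
        self.cos: list[CrossoverEvent] = []
        self.tracts: list[ConversionTract] = []
        self.complex: list[ComplexRegion] = []
        self.n_filtered = 0
        self.unknown = "unknown" if self.n == 4 else "unsampled"

    # -- helpers ---------------------------------------------------------
    def _is_anchor(self, k: int) -> bool:
        seg = self.segs[k]
        if seg.allele_sum not in self.mendel:
            return False
        return seg.support >= 2 or k == 0 or k == len(self.segs) - 1

    def _tract_from(self, seg: Segment, recipients: list[int], ref: tuple[int, ...]) -> None:
        if self.filter and seg.support < 2:
            self.n_filtered += 1
            return
        self.tracts.append(ConversionTract(
            self.chrom,
            int(self.pos[seg.first_marker_index]),
            int(self.pos[seg.last_marker_index]),
            _ratio_class(seg.genotype_vector, self.n),
            tuple(self.labels[i] for i in recipients),
            seg.support,
        ))

    def _complex_between(self, a: Segment, b: Segment, why: str) -> None:
        self.complex.append(ComplexRegion(
            self.chrom,
            int(self.pos[a.last_marker_index]),
            int(self.pos[b.first_marker_index]),
            why,
        ))

    def _middles_are_conversions(self, middles: list[Segment], A: Segment, B: Segment,
                                 allowed: set[int] | None) -> bool:
        """True if every middle is a single-spore deviation from a flank.

        ``allowed`` restricts the deviating spore (to the crossover pair)
        when checking a crossover-with-conversion pattern.
        """
        for m in middles:
            dA = _diff_spores(m.genotype_vector, A.genotype_vector)
            dB = _diff_spores(m.genotype_vector, B.genotype_vector)
            for d in (dA, dB):
                if len(d) == 1 and (allowed is None or d[0] in allowed):
                    break
            else:
                return False
        return True

    # -- main pass -------------------------------------------------------
    def run(self) -> None:
        segs = self.segs
        if not segs:
            return
        anchors = [k for k in range(len(segs)) if self._is_anchor(k)]
        if not anchors:
            # Whole chromosome non-Mendelian: one sweeping tract (e.g. a
            # trio in which every visible spore carries one parent).
            first, last = segs[0], segs[-1]
            vec = max(segs, key=lambda s: s.support).genotype_vector
            self.tracts.append(ConversionTract(
                self.chrom,
                int(self.pos[first.first_marker_index]),
                int(self.pos[last.last_marker_index]),
                _ratio_class(vec, self.n),
                tuple(self.labels[i] for i in range(self.n)
                      if vec[i] != (0 if sum(vec) * 2 < self.n else 1)) or tuple(self.labels),
                sum(s.support for s in segs),
            ))
            return

        self._leading(segs, anchors[0])
        t = 0
        while t < len(anchors) - 1:
            # Trio ambiguity: a bounded single-spore deviation whose middle
            # run itself has a Mendelian sum (1 <-> 2) would read as two
            # crossovers with the unsampled chromatid; score the bounded
            # tract as one conversion instead (minimal-event parsimony).
            if (
                self.n == 3
                and t + 2 < len(anchors)
                and anchors[t + 1] == anchors[t] + 1
                and anchors[t + 2] == anchors[t] + 2
            ):
                A = segs[anchors[t]]
                X = segs[anchors[t + 1]]
                B = segs[anchors[t + 2]]
                d = _diff_spores(A.genotype_vector, X.genotype_vector)
                span = int(self.pos[X.last_marker_index] - self.pos[X.first_marker_index])
                if (A.genotype_vector == B.genotype_vector and len(d) == 1
                        and span <= self.max_tract_span):
                    self._tract_from(X, d, A.genotype_vector)
                    t += 2
                    continue
            self._between(anchors[t], anchors[t + 1])
            t += 1
        self._trailing(segs, anchors[-1])

    def _terminal_run(self, middles: list[Segment], anchor: Segment, at_start: bool) -> None:
        """Deviation run touching the unmasked chromosome end.

        A single-spore deviation persisting to the end is scored as one
        crossover with associated conversion (partner undetermined); other
        patterns are complex.
        """
        if not middles:
            return
        devs = set()
        ok = True
        for m in middles:
            d = _diff_spores(m.genotype_vector, anchor.genotype_vector)
            if len(d) != 1:
                ok = False
                break
            devs.add(d[0])
        total_support = sum(m.support for m in middles)
        if ok and len(devs) == 1:
            if self.filter and total_support < 2:
                self.n_filtered += 1
                return
            spore = self.labels[next(iter(devs))]
            if at_start:
                left = min(self.territory[0],
                           int(self.pos[middles[0].first_marker_index]))
                right = int(self.pos[anchor.first_marker_index])
            else:
                left = int(self.pos[anchor.last_marker_index])
                right = max(self.territory[1],
                            int(self.pos[middles[-1].last_marker_index]))
            if left >= right:  # degenerate single-marker bracket
                self.n_filtered += 1
                return
            self.cos.append(CrossoverEvent(
                self.chrom, left, right, (spore, self.unknown),
                has_associated_conversion=True))
        else:
            first, last = middles[0], middles[-1]
            self.complex.append(ComplexRegion(
                self.chrom,
                int(self.pos[first.first_marker_index]),
                int(self.pos[last.last_marker_index]),
                "unclassifiable terminal deviation"))

    def _leading(self, segs: list[Segment], first_anchor: int) -> None:
        self._terminal_run(segs[:first_anchor], segs[first_anchor], at_start=True)

    def _trailing(self, segs: list[Segment], last_anchor: int) -> None:
        self._terminal_run(segs[last_anchor + 1:], segs[last_anchor], at_start=False)

    def _between(self, ka: int, kb: int) -> None:
        A, B = self.segs[ka], self.segs[kb]
        middles = self.segs[ka + 1:kb]
        diff = _diff_spores(A.genotype_vector, B.genotype_vector)

        if not diff:
            # Identical flanks: every middle must be a conversion tract.
            for m in middles:
                d = _diff_spores(m.genotype_vector, A.genotype_vector)
                s = m.allele_sum
                if len(d) == 1:
                    self._tract_from(m, d, A.genotype_vector)
                elif self.n == 4 and s in (0, 4):
                    self._tract_from(m, d, A.genotype_vector)
                elif self.filter and m.support < 2:
                    # e.g. a single-marker reciprocal flip-and-back: below
                    # the support threshold for any event
                    self.n_filtered += 1
                else:
                    self._complex_between(A, B, "unclassifiable bounded deviation")
            return

        if _is_reciprocal(A.genotype_vector, B.genotype_vector, diff):
            if not middles or self._middles_are_conversions(middles, A, B, set(diff)):
                self.cos.append(CrossoverEvent(
                    self.chrom,
                    int(self.pos[A.last_marker_index]),
                    int(self.pos[B.first_marker_index]),
                    (self.labels[diff[0]], self.labels[diff[1]]),
                    has_associated_conversion=bool(middles)))
            else:
                self._complex_between(A, B, "reciprocal switch with unclassifiable middle")
            return

        if self.n == 3 and len(diff) == 1:
            # Persistent switch of one visible spore: exchange with the
            # unsampled chromatid.
            if not middles or self._middles_are_conversions(middles, A, B, set(diff)):
                self.cos.append(CrossoverEvent(
                    self.chrom,
                    int(self.pos[A.last_marker_index]),
                    int(self.pos[B.first_marker_index]),
                    (self.labels[diff[0]], "unsampled"),
                    has_associated_conversion=bool(middles)))
            else:
                self._complex_between(A, B, "trio switch with unclassifiable middle")
            return

        self._complex_between(A, B, f"{len(diff)} spores change simultaneously")


def call_events(
    segments: Mapping[str, list[Segment]],
    markers: MarkerMap,
    spore_labels: tuple[str, ...],
    ascus_id: str = "ascus",
    single_marker_filter: bool = True,
    filters_applied: Mapping[str, object] | None = None,
    max_tract_span_bp: int = 25_000,
    territory: Mapping[str, tuple[int, int]] | None = None,
) -> EventSet:
    """Classify segment boundaries into crossovers and conversion tracts.

    Rules (tetrads; trios analogous with Mendelian sums 1/2):

    1. a boundary where exactly two spores swap reciprocally between
       Mendelian anchors is one crossover;
    2. a run bounded by identical anchors in which one spore deviates is a
       conversion tract (3:1/1:3); allele sums 0/4 give 4:0 tracts;
    3. a single-spore deviation persisting to the unmasked chromosome end,
       or separating two anchors that differ reciprocally, is one crossover
       with associated conversion (counted once, as a crossover);
    4. tracts supported by a single marker are discarded (the single-SNP
       noncrossover filter); crossovers require each flanking anchor to
       have >=2 markers or to touch the chromosome end;
    5. anything else is flagged as a complex region.

    In trios a bounded single-spore deviation whose run has a Mendelian
    allele sum is ambiguous (one conversion vs. two exchanges with the
    unsampled chromatid); it is scored as a conversion tract only when its
    span is at most ``max_tract_span_bp`` (default 25 kb, an order of
    magnitude above typical conversion tracts), and as two crossovers
    otherwise.
    """
    n_spores = len(spore_labels)
    cos: list[CrossoverEvent] = []
    tracts: list[ConversionTract] = []
    cplx: list[ComplexRegion] = []
    n_filtered = 0
    for chrom, segs in segments.items():
        caller = _Caller(chrom, segs, markers.positions[chrom], spore_labels,
                         single_marker_filter, max_tract_span_bp,
                         (territory or {}).get(chrom))
        caller.run()
        cos.extend(caller.cos)
        tracts.extend(caller.tracts)
        cplx.extend(caller.complex)
        n_filtered += caller.n_filtered

    order = {c: k for k, c in enumerate(markers.positions)}
    cos.sort(key=lambda e: (order.get(e.chromosome, 99), e.midpoint_bp))
    tracts.sort(key=lambda t: (order.get(t.chromosome, 99), (t.start_pos + t.end_pos) // 2))
    cplx.sort(key=lambda c: (order.get(c.chromosome, 99), (c.left_pos + c.right_pos) // 2))
    filters = dict(filters_applied or {})
    filters.setdefault("single_marker_filter", single_marker_filter)
    filters["n_single_marker_filtered"] = n_filtered
    return EventSet(ascus_id, tuple(cos), tuple(tracts), tuple(cplx), filters, n_spores)


def call_ascus(
    ascus: AscusGenotypes,
    markers: MarkerMap,
    genome: ChromosomeSet,
    single_marker_filter: bool = True,
    apply_masks: bool = True,
    max_tract_span_bp: int = 25_000,
) -> EventSet:
    """Convenience pipeline: mask, segment and call one ascus."""
    if apply_masks:
        masked, masked_markers = mask_markers(ascus, markers, genome)
    else:
        masked, masked_markers = ascus, markers
    territory = {}
    for chrom in genome:
        lo, hi = 1, chrom.length_bp
        for a, b in chrom.subtelomere_masks:
            if a <= lo <= b:
                lo = b + 1
            if a <= hi <= b:
                hi = a - 1
        if apply_masks:
            territory[chrom.name] = (lo, hi)
    segs = segment_ascus(masked, masked_markers)
    filters = {
        "subtelomere_masks": {c.name: [list(iv) for iv in c.subtelomere_masks]
                              for c in genome} if apply_masks else {},
    }
    return call_events(segs, masked_markers, masked.spore_labels, ascus.ascus_id,
                       single_marker_filter, filters, max_tract_span_bp,
                       territory or None)


def classify_two_locus(
    ascus: AscusGenotypes, pair: LocusPair, markers: MarkerMap
) -> str:
    """Classify a tetrad at two marked loci as PD, NPD or TT.

    Each locus takes the genotype of its nearest marker (ties toward the
    smaller coordinate). Non-2:2 segregation at either locus, or any missing
    call there, gives ``"unclassifiable"``.
    """
    if ascus.n_spores != 4:
        raise ValueError("two-locus classification requires a tetrad")
    pos = markers.positions[pair.chromosome]
    if len(pos) == 0:
        return "unclassifiable"
    m = ascus.matrix[pair.chromosome]

    def nearest(locus: int) -> int:
        j = int(np.searchsorted(pos, locus))
        cands = [k for k in (j - 1, j) if 0 <= k < len(pos)]
        return min(cands, key=lambda k: (abs(int(pos[k]) - locus), int(pos[k])))

    ga = m[nearest(pair.locusA_pos)]
    gb = m[nearest(pair.locusB_pos)]
    if np.any(ga == MISSING) or np.any(gb == MISSING):
        return "unclassifiable"
    if int(ga.sum()) != 2 or int(gb.sum()) != 2:
        return "unclassifiable"
    combos = {(int(x), int(y)) for x, y in zip(ga, gb)}
    if combos == {(0, 0), (1, 1)}:
        return "PD"
    if combos == {(0, 1), (1, 0)}:
        return "NPD"
    return "TT"


def designate_obligatory(
    events: EventSet, pair: LocusPair, genome: ChromosomeSet
) -> EventSet:
    """Flag the experimentally forced crossover in the marked interval.

    Among crossovers with midpoint inside ``[locusA, locusB]``, the one
    farthest from the centromere midpoint is flagged obligatory; the rest in
    the interval are explicitly non-obligatory; crossovers elsewhere are
    untouched. If no crossover lies in the interval (a violation of the
    experimental design) a warning is recorded and no flag is set.
    """
    cen = genome[pair.chromosome].centromere_midpoint_bp
    inside = [
        k for k, co in enumerate(events.crossovers)
        if co.chromosome == pair.chromosome
        and pair.locusA_pos <= co.midpoint_bp <= pair.locusB_pos
    ]
    filters = dict(events.filters_applied)
    if not inside:
        warnings.warn(
            f"{events.ascus_id}: no crossover in the marked interval "
            f"{pair.chromosome}:{pair.locusA_pos}-{pair.locusB_pos}",
            stacklevel=2,
        )
        filters["obligatory_interval_empty"] = True
        return replace(events, filters_applied=filters)
    far = max(inside, key=lambda k: (abs(events.crossovers[k].midpoint_bp - cen),
                                     events.crossovers[k].midpoint_bp))
    cos = list(events.crossovers)
    for k in inside:
        cos[k] = replace(cos[k], obligatory=(k == far))
    return replace(events, crossovers=tuple(cos), filters_applied=filters)
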