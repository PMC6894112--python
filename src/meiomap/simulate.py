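"""Seedable simulator of marker maps, meioses and SNP-density tracks.

The simulator is the download-free test bed for the whole pipeline. It
emulates the features of the *K. phaffii* GS115 x Pp4 cross that matter for
event calling:

* four chromosomes with the reference lengths and centromere midpoints;
* dense biallelic markers (~4.5 SNP/kb; clustered gaps with median ~100 bp);
* per-chromosome crossover counts with one obligate crossover, positions
  suppressed within ~150 kb of each centromere (linear ramp back to full
  intensity over a further 50 kb);
* 3:1 (and occasionally 4:0) gene-conversion tracts with geometric lengths;
* trio asci (one spore unrecovered) and missing genotype calls.

A meiosis is modeled as four chromatids per chromosome (two per parent).
Each crossover exchanges the distal segments of one chromatid from each
parent (uniformly chosen); sister exchanges are not modeled because they are
genetically invisible. Neither crossover interference nor chromatid
interference is modeled. Draw order per chromosome is fixed (crossover
count, positions, chromatid pairs, conversion count, tracts, missingness) so
a (params, seed) pair is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .genome import (
    MISSING,
    SPORE_LABELS,
    AscusGenotypes,
    ChromosomeInfo,
    ChromosomeSet,
    MarkerMap,
    default_genome,
)

__all__ = [
    "SimParams",
    "SimTruth",
    "TrueCrossover",
    "TrueConversion",
    "expected_visible_crossovers",
    "simulate_marker_map",
    "simulate_meiosis",
    "simulate_experiment",
    "make_trio",
    "simulate_diversity_track",
    "default_low_diversity_regions",
    "crossover_intensity",
    "effective_kb",
]

# Gap-length mixture for the clustered marker map. Real SNPs are clumped:
# the cross shows a 224-bp mean gap but a 96-bp median. A two-component
# exponential mixture with 60% weight on a short-gap component reproduces
# both statistics at 4.46 SNP/kb (component means scale with 1/density).
_GAP_SHORT_WEIGHT = 0.6
_GAP_SHORT_MEAN_FRAC = 80.0 / 224.0
_GAP_LONG_MEAN_FRAC = 440.0 / 224.0

_GRID_STEP = 100  # bp resolution of the crossover-intensity grid


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated meiosis experiment.

    ``co_rate_per_kb`` is the expected number of crossovers per kb of
    *unsuppressed* sequence per meiosis; the default is calibrated so the
    default genome averages ~25.5 crossovers per meiosis (see
    :meth:`calibrated`). Conversion-tract mean length and the per-chromosome
    conversion rate are package choices (no published estimates exist for
    this cross); see docs/methods.md.
    """

    co_rate_per_kb: float = 0.0046
    obligate_crossover: bool = True
    suppression_radius_bp: int = 150_000
    ramp_bp: int = 50_000
    nco_rate_per_chromosome: float = 1.5
    conversion_tract_mean_bp: float = 2_000.0
    marker_density_per_kb: float = 4.46
    missing_rate: float = 0.0
    seed: int = 0
    suppress_inversion: bool = False

    def validate(self, genome: ChromosomeSet | None = None) -> None:
        for name in ("co_rate_per_kb", "nco_rate_per_chromosome"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.conversion_tract_mean_bp <= 0:
            raise ValueError("conversion_tract_mean_bp must be positive")
        if self.marker_density_per_kb <= 0:
            raise ValueError("marker_density_per_kb must be positive")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.suppression_radius_bp < 0 or self.ramp_bp < 0:
            raise ValueError("suppression_radius_bp and ramp_bp must be >= 0")
        if genome is not None:
            for chrom in genome:
                if effective_kb(chrom, self) <= 0:
                    raise ValueError(
                        f"{chrom.name}: crossover intensity is zero everywhere "
                        "(suppression covers the whole chromosome)"
                    )

    @classmethod
    def calibrated(
        cls,
        genome: ChromosomeSet | None = None,
        target_mean_co_per_meiosis: float = 25.5,
        **overrides,
    ) -> "SimParams":
        """Return params whose expected *observable* crossovers match a target.

        Counts published for real crosses are of genotype-visible exchanges;
        a crossover between two chromatids identical-by-state distal to the
        exchange point (e.g. the second exchange of a three-strand double)
        changes no genotype and cannot be counted. The calibration therefore
        targets the expected number of visible crossovers per meiosis,
        accounting both for the zero-truncation that enforces the obligate
        crossover and for the visibility process (an exact two-state Markov
        chain over the chromatid-origin configuration; see
        :func:`expected_visible_crossovers`).
        """
        genome = genome or default_genome()
        base = cls(**overrides)
        eff = [effective_kb(c, base) for c in genome]

        def expected(rate: float) -> float:
            tot = sum(
                expected_visible_crossovers(rate * e, base.obligate_crossover)
                for e in eff
            )
            return tot - target_mean_co_per_meiosis

        rate = brentq(expected, 1e-9, 1.0, xtol=1e-12)
        return replace(base, co_rate_per_kb=float(rate))


@dataclass(frozen=True)
class TrueCrossover:
    chromosome: str
    position_bp: int
    chromatids: tuple[int, int]  # one index in {0,1} (parent0), one in {2,3} (parent1)
    visible: bool = True
    """False when the exchanged chromatids were identical-by-state distal to
    the exchange point (possible after earlier crossovers): such a crossover
    has no genetic signature and is undetectable from genotypes in principle."""


@dataclass(frozen=True)
class TrueConversion:
    chromosome: str
    start_bp: int
    end_bp: int
    recipient_chromatid: int
    direction: str  # "0to1" or "1to0" at the tract start


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth event record for one simulated meiosis."""

    ascus_id: str
    crossovers: tuple[TrueCrossover, ...]
    tracts: tuple[TrueConversion, ...]


def _expected_visible_given_count(m_max: int) -> np.ndarray:
    """E[visible crossovers | m true crossovers] for m = 0..m_max.

    The four chromatid origins always form the multiset {0,0,1,1}; with one
    chromatid drawn uniformly from each homolog, visibility of the next
    exchange depends only on whether the two parent-0 origins sit on the
    same homolog side. That gives a two-state chain: state A (balanced,
    next exchange surely visible), state B (mixed, visible with
    probability 1/2; a visible exchange returns to A). Chromosomes start
    in A, so the first crossover is always visible.
    """
    v = np.empty(m_max + 1)
    v[0] = 0.0
    p_a, p_b, vis = 1.0, 0.0, 0.0
    for m in range(1, m_max + 1):
        vis += p_a + 0.5 * p_b
        p_a, p_b = 0.5 * p_b, p_a + 0.5 * p_b
        v[m] = vis
    return v


def expected_visible_crossovers(lam: float, obligate: bool) -> float:
    """Expected genotype-visible crossovers on a chromosome with intensity lam."""
    if lam <= 1e-12:
        return 1.0 if obligate else 0.0
    m_max = max(12, int(lam + 12 * math.sqrt(lam) + 12))
    m = np.arange(m_max + 1)
    log_pmf = m * math.log(lam) - lam - np.array([math.lgamma(k + 1) for k in m])
    pmf = np.exp(log_pmf)
    if obligate:
        pmf[0] = 0.0
        pmf /= -math.expm1(-lam)
    return float(np.sum(pmf * _expected_visible_given_count(m_max)))


def crossover_intensity(chrom: ChromosomeInfo, params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell relative crossover intensity on a 100-bp grid.

    Returns ``(cell_starts, intensity)`` where cell ``i`` covers
    ``[cell_starts[i], cell_starts[i] + 100 - 1]`` (last cell truncated at
    the chromosome end). Intensity is 0 within ``suppression_radius_bp`` of
    the centromere midpoint, ramps linearly to 1 over ``ramp_bp``, and is 0
    inside subtelomere masks (and the inversion interval when
    ``suppress_inversion`` is set).
    """
    n = (chrom.length_bp + _GRID_STEP - 1) // _GRID_STEP
    starts = np.arange(n, dtype=np.int64) * _GRID_STEP + 1
    ends = np.minimum(starts + _GRID_STEP - 1, chrom.length_bp)
    mid = (starts + ends) / 2.0
    dist = np.abs(mid - chrom.centromere_midpoint_bp)
    if params.ramp_bp > 0:
        inten = np.clip((dist - params.suppression_radius_bp) / params.ramp_bp, 0.0, 1.0)
    else:
        inten = (dist >= params.suppression_radius_bp).astype(float)
    for lo, hi in chrom.subtelomere_masks:
        inten[(mid >= lo) & (mid <= hi)] = 0.0
    if params.suppress_inversion and chrom.inversion_interval is not None:
        lo, hi = chrom.inversion_interval
        inten[(mid >= lo) & (mid <= hi)] = 0.0
    return starts, inten


def effective_kb(chrom: ChromosomeInfo, params: SimParams) -> float:
    """Integral of the relative crossover intensity over the chromosome, in kb."""
    starts, inten = crossover_intensity(chrom, params)
    ends = np.minimum(starts + _GRID_STEP - 1, chrom.length_bp)
    widths = (ends - starts + 1).astype(float)
    return float(np.sum(inten * widths) / 1000.0)


def _clamp_position(pos: int, chrom: ChromosomeInfo, params: SimParams) -> int:
    """Push a grid-sampled position out of zero-intensity territory."""
    cen = chrom.centromere_midpoint_bp
    if abs(pos - cen) < params.suppression_radius_bp:
        pos = cen - params.suppression_radius_bp if pos < cen else cen + params.suppression_radius_bp
    for lo, hi in chrom.subtelomere_masks:
        if lo <= pos <= hi:
            pos = lo - 1 if abs(pos - lo) <= abs(pos - hi) else hi + 1
    return int(np.clip(pos, 1, chrom.length_bp))


def _sample_positions(
    rng: np.random.Generator, n: int, chrom: ChromosomeInfo, params: SimParams
) -> np.ndarray:
    starts, inten = crossover_intensity(chrom, params)
    ends = np.minimum(starts + _GRID_STEP - 1, chrom.length_bp)
    widths = (ends - starts + 1).astype(float)
    mass = inten * widths
    cdf = np.cumsum(mass)
    total = cdf[-1]
    if total <= 0:
        raise ValueError(f"{chrom.name}: crossover intensity is zero everywhere")
    u = rng.random(n) * total
    cells = np.searchsorted(cdf, u, side="right")
    within = rng.random(n)
    pos = starts[cells] + within * widths[cells]
    out = np.array([_clamp_position(int(p), chrom, params) for p in pos], dtype=np.int64)
    out.sort()
    return out


def simulate_marker_map(
    genome: ChromosomeSet,
    density_per_kb: float,
    seed: int,
    clustered: bool = True,
) -> MarkerMap:
    """Draw a biallelic marker map at a given mean density.

    With ``clustered=True`` (default) inter-marker gaps follow the
    two-component exponential mixture described in the module docstring
    (clumped SNPs: short median gap). With ``clustered=False`` gaps are plain
    exponential, i.e. a homogeneous Poisson process.

    Raises
    ------
    ValueError
        If any chromosome draws zero markers (suggesting a higher density).
    """
    if density_per_kb <= 0:
        raise ValueError("density_per_kb must be positive")
    rng = np.random.default_rng(seed)
    mean_gap = 1000.0 / density_per_kb
    positions = {}
    for chrom in genome:
        expect = max(int(chrom.length_bp / mean_gap * 1.3) + 16, 16)
        pos_list: list[np.ndarray] = []
        last = 0.0
        while last <= chrom.length_bp:
            if clustered:
                comp = rng.random(expect) < _GAP_SHORT_WEIGHT
                gaps = np.where(
                    comp,
                    rng.exponential(mean_gap * _GAP_SHORT_MEAN_FRAC, expect),
                    rng.exponential(mean_gap * _GAP_LONG_MEAN_FRAC, expect),
                )
            else:
                gaps = rng.exponential(mean_gap, expect)
            cum = last + np.cumsum(gaps)
            pos_list.append(cum)
            last = float(cum[-1])
        pos = np.concatenate(pos_list)
        pos = np.unique(np.floor(pos[pos <= chrom.length_bp]).astype(np.int64))
        pos = pos[pos >= 1]
        if pos.size == 0:
            raise ValueError(
                f"{chrom.name}: zero markers at density {density_per_kb}/kb; "
                "increase the density"
            )
        positions[chrom.name] = pos
    return MarkerMap(positions, "parent0", "parent1")


def _zero_truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    """Poisson(lam) conditioned on >= 1, by inverse-CDF (one uniform draw)."""
    if lam <= 1e-12:
        return 1
    u = rng.random() * -math.expm1(-lam)  # uniform on (0, P(X >= 1))
    pk = lam * math.exp(-lam)  # P(X = 1)
    cum = pk
    k = 1
    while u > cum and pk > 0:
        k += 1
        pk *= lam / k
        cum += pk
    return k


def simulate_meiosis(
    markers: MarkerMap,
    genome: ChromosomeSet,
    params: SimParams,
    ascus_id: str = "ascus1",
    rng: np.random.Generator | None = None,
) -> tuple[AscusGenotypes, SimTruth]:
    """Simulate one meiosis and read spore genotypes off the four chromatids.

    Chromatids 0 and 1 start as parent0 copies, 2 and 3 as parent1 copies;
    spore ``a``..``d`` receives chromatid 0..3. Returns the (possibly
    missing-injected) tetrad genotypes together with the ground truth.
    """
    params.validate(genome)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    matrix: dict[str, np.ndarray] = {}
    true_cos: list[TrueCrossover] = []
    true_tracts: list[TrueConversion] = []
    for chrom in genome:
        pos = markers.positions.get(chrom.name)
        if pos is None:
            raise ValueError(f"marker map lacks chromosome {chrom.name}")
        lam = params.co_rate_per_kb * effective_kb(chrom, params)
        if params.obligate_crossover:
            n_co = _zero_truncated_poisson(rng, lam)
        else:
            n_co = int(rng.poisson(lam))
        co_pos = _sample_positions(rng, n_co, chrom, params) if n_co else np.array([], dtype=np.int64)
        pairs = [(int(rng.integers(0, 2)), int(rng.integers(2, 4))) for _ in range(n_co)]

        # Parental origin of each chromatid along the chromosome: swaps at
        # crossover positions (material distal to the exchange point).
        geno = np.empty((len(pos), 4), dtype=np.int8)
        origin = [0, 0, 1, 1]
        cuts = np.searchsorted(pos, co_pos, side="right")
        prev = 0
        visible = []
        for cut, (i, j) in zip(cuts, pairs):
            geno[prev:cut] = origin
            visible.append(origin[i] != origin[j])
            origin[i], origin[j] = origin[j], origin[i]
            prev = cut
        geno[prev:] = origin
        for p, pair, vis in zip(co_pos, pairs, visible):
            true_cos.append(TrueCrossover(chrom.name, int(p), pair, vis))

        n_nco = int(rng.poisson(params.nco_rate_per_chromosome))
        for _ in range(n_nco):
            start = int(rng.integers(1, chrom.length_bp + 1))
            length = int(rng.geometric(1.0 / params.conversion_tract_mean_bp))
            end = min(start + length - 1, chrom.length_bp)
            recipient = int(rng.integers(0, 4))
            lo, hi = np.searchsorted(pos, (start, end + 1))
            if hi > lo:
                direction = "0to1" if geno[lo, recipient] == 0 else "1to0"
                geno[lo:hi, recipient] = 1 - geno[lo:hi, recipient]
            else:
                # no marker covered; direction from the origin function
                k = int(np.searchsorted(co_pos, start, side="right"))
                origin = [0, 0, 1, 1]
                for i, j in pairs[:k]:
                    origin[i], origin[j] = origin[j], origin[i]
                direction = "0to1" if origin[recipient] == 0 else "1to0"
            true_tracts.append(TrueConversion(chrom.name, start, end, recipient, direction))

        if params.missing_rate > 0:
            drop = rng.random(geno.shape) < params.missing_rate
            geno = np.where(drop, np.int8(MISSING), geno)
        matrix[chrom.name] = geno

    ascus = AscusGenotypes(ascus_id, SPORE_LABELS, matrix)
    truth = SimTruth(ascus_id, tuple(true_cos), tuple(true_tracts))
    return ascus, truth


def make_trio(ascus: AscusGenotypes, truth: SimTruth, drop_spore: str) -> AscusGenotypes:
    """Drop one spore from a tetrad, producing a trio.

    The truth record is unchanged: events involving the dropped chromatid
    remain real, merely partially observable.
    """
    if ascus.n_spores != 4:
        raise ValueError(f"{ascus.ascus_id}: can only drop a spore from a tetrad")
    if drop_spore not in ascus.spore_labels:
        raise ValueError(f"{ascus.ascus_id}: no spore {drop_spore!r}")
    keep = [i for i, lab in enumerate(ascus.spore_labels) if lab != drop_spore]
    labels = tuple(ascus.spore_labels[i] for i in keep)
    matrix = {c: m[:, keep] for c, m in ascus.matrix.items()}
    return AscusGenotypes(ascus.ascus_id, labels, matrix)


def simulate_experiment(
    genome: ChromosomeSet | None = None,
    params: SimParams | None = None,
    n_tetrads: int = 5,
    n_trios: int = 6,
    seed: int = 0,
    markers: MarkerMap | None = None,
) -> tuple[MarkerMap, list[tuple[AscusGenotypes, SimTruth]]]:
    """Simulate a whole cross: one marker map plus tetrad and trio asci.

    Defaults mirror the original study design (5 tetrads + 6 trios; the
    trios alternate between lacking spore ``a`` and spore ``d``, the two
    phenotype classes that failed to germinate).
    """
    genome = genome or default_genome()
    params = params or SimParams.calibrated(genome)
    rng = np.random.default_rng(seed)
    if markers is None:
        markers = simulate_marker_map(
            genome, params.marker_density_per_kb, seed=int(rng.integers(2**31))
        )
    out = []
    for k in range(n_tetrads):
        ascus, truth = simulate_meiosis(markers, genome, params, f"Tetrad{k + 1}", rng)
        out.append((ascus, truth))
    for k in range(n_trios):
        ascus, truth = simulate_meiosis(markers, genome, params, f"Trio{k + 1}", rng)
        trio = make_trio(ascus, truth, "a" if k % 2 == 0 else "d")
        out.append((trio, truth))
    return markers, out


def detectable_crossovers(
    truth: SimTruth,
    markers: MarkerMap,
    genome: ChromosomeSet,
    min_separation_markers: int = 2,
) -> list[TrueCrossover]:
    """True crossovers a genotype-based caller can in principle recover.

    Keeps visible crossovers (see :class:`TrueCrossover`) that lie at least
    ``min_separation_markers`` unmasked markers inside the chromosome and are
    separated from every adjacent true event boundary (crossover points,
    conversion-tract start and end) by at least that many unmasked markers.
    Used to score detector recovery without conflating algorithmic misses
    with events that left no resolvable signature.
    """
    out: list[TrueCrossover] = []
    k = min_separation_markers
    for chrom in genome:
        pos = markers.positions[chrom.name]
        keep = np.ones(len(pos), dtype=bool)
        for lo, hi in chrom.subtelomere_masks:
            keep &= ~((pos >= lo) & (pos <= hi))
        upos = pos[keep]
        pts: list[tuple[int, int, TrueCrossover | None]] = [
            (c.position_bp, c.position_bp, c)
            for c in truth.crossovers if c.chromosome == chrom.name and c.visible
        ]
        pts += [(t.start_bp, t.end_bp, None)
                for t in truth.tracts if t.chromosome == chrom.name]
        pts.sort(key=lambda x: x[0])
        for i, (a, b, obj) in enumerate(pts):
            ia, ib = np.searchsorted(upos, a), np.searchsorted(upos, b)
            good = ia >= k and ib <= len(upos) - k
            if i > 0:
                good = good and (ia - np.searchsorted(upos, pts[i - 1][1])) >= k
            if i < len(pts) - 1:
                good = good and (np.searchsorted(upos, pts[i + 1][0]) - ib) >= k
            if obj is not None and good:
                out.append(obj)
    return out


def default_low_diversity_regions() -> list[tuple[str, tuple[int, int], float]]:
    """Synthetic stand-ins for the two pericentromeric low-diversity regions.

    Extents match the regions called in the Pp4 vs CBS7435 comparison
    (362 kb spanning *CEN1*: 230 kb left + 132 kb right; 240 kb spanning
    *CEN2*: 110 kb + 130 kb); the inside density of 0.4 SNP/kb is a package
    choice consistent with "below 1 SNP/kb".
    """
    return [
        ("chr1", (1_404_539 - 230_000, 1_404_539 + 132_000), 0.4),
        ("chr2", (847_809 - 110_000, 847_809 + 130_000), 0.4),
    ]


def simulate_diversity_track(
    genome: ChromosomeSet,
    background_density_per_kb: float,
    low_regions: Sequence[tuple[str, tuple[int, int], float]] = (),
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Draw per-strain SNP positions from an inhomogeneous Poisson process.

    ``low_regions`` entries are ``(chromosome, (lo, hi), density_per_kb)``;
    the background rate applies everywhere else. Regions on the same
    chromosome must not overlap.
    """
    if background_density_per_kb < 0:
        raise ValueError("background density must be >= 0")
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom_name, (lo, hi), dens in low_regions:
        length = genome[chrom_name].length_bp
        if not (1 <= lo <= hi <= length):
            raise ValueError(f"{chrom_name}: region [{lo}, {hi}] outside [1, {length}]")
        by_chrom.setdefault(chrom_name, []).append((lo, hi, float(dens)))
    for chrom_name, regions in by_chrom.items():
        regions.sort()
        for (a, b, _), (c, d, _) in zip(regions, regions[1:]):
            if c <= b:
                raise ValueError(f"{chrom_name}: overlapping low_regions")

    rng = np.random.default_rng(seed)
    out = {}
    for chrom in genome:
        pieces = []
        cursor = 1
        for lo, hi, dens in by_chrom.get(chrom.name, []):
            if cursor < lo:
                pieces.append((cursor, lo - 1, background_density_per_kb))
            pieces.append((lo, hi, dens))
            cursor = hi + 1
        if cursor <= chrom.length_bp:
            pieces.append((cursor, chrom.length_bp, background_density_per_kb))
        pos_parts = []
        for lo, hi, dens in pieces:
            width = hi - lo + 1
            n = int(rng.poisson(dens * width / 1000.0))
            if n:
                pos_parts.append(lo + np.floor(rng.random(n) * width).astype(np.int64))
        pos = np.unique(np.concatenate(pos_parts)) if pos_parts else np.array([], dtype=np.int64)
        out[chrom.name] = pos
    return out
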