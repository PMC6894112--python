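"""Recombination-landscape statistics over called event sets.

Aggregates per-ascus crossover calls into the summary table of a cross
(counts, rates per kb, kb per crossover), fits crossover count against
chromosome length, profiles crossover distances from centromeres, and tests
uniformity of crossover positions in a marked interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventSet
from .genome import ChromosomeSet, LocusPair

__all__ = [
    "LandscapeSummary",
    "RegressionFit",
    "DistanceProfile",
    "summarize_counts",
    "summary_from_counts",
    "fit_count_vs_length",
    "centromere_distances",
    "ks_uniform_test",
    "compare_reference_ratio",
    "SCEREVISIAE_MEAN_CROSSOVERS",
]

SCEREVISIAE_MEAN_CROSSOVERS = 90.5
"""Mean crossovers per meiosis in *S. cerevisiae*, the standard comparison point."""


@dataclass(frozen=True)
class LandscapeSummary:
    """Per-ascus x per-chromosome crossover counts and derived rates.

    ``counts`` rows are asci, columns chromosomes; ``is_tetrad`` marks which
    asci are full tetrads. All derived statistics are kept unrounded;
    :meth:`to_table` applies the conventional printed precision (means to
    1 dp, crossovers/kb to 5 dp, kb/crossover to 1 dp).
    """

    counts: pd.DataFrame
    is_tetrad: pd.Series
    genome: ChromosomeSet

    @property
    def n_asci(self) -> int:
        return len(self.counts)

    @property
    def chromosome_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def genome_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def mean_per_meiosis(self) -> float:
        return self.genome_total / self.n_asci

    def mean_per_meiosis_subset(self, tetrads: bool) -> float | None:
        sel = self.counts[self.is_tetrad == tetrads]
        return float(sel.to_numpy().sum() / len(sel)) if len(sel) else None

    @property
    def genome_kb(self) -> float:
        return self.genome.genome_length_bp / 1000.0

    @property
    def crossovers_per_kb(self) -> float:
        return self.mean_per_meiosis / self.genome_kb

    @property
    def kb_per_crossover(self) -> float | None:
        m = self.mean_per_meiosis
        return self.genome_kb / m if m > 0 else None

    def chromosome_means(self) -> pd.Series:
        """Mean crossovers per meiosis for each chromosome (unrounded)."""
        return self.chromosome_totals / self.n_asci

    def to_table(self) -> pd.DataFrame:
        """Summary table mirroring the printed layout of a cross report."""
        chroms = list(self.counts.columns)
        rows = {}
        for ascus in self.counts.index:
            rows[ascus] = list(self.counts.loc[ascus]) + [int(self.counts.loc[ascus].sum())]
        rows["Total COs"] = list(self.chromosome_totals) + [self.genome_total]
        rows["COs per meiosis"] = [round(v, 1) for v in self.chromosome_means()] + [
            round(self.mean_per_meiosis, 1)
        ]
        rows["Chromosome length (kb)"] = [
            round(self.genome[c].length_bp / 1000.0, 3) for c in chroms
        ] + [round(self.genome_kb, 3)]
        rows["Crossovers/kb"] = [
            round(self.chromosome_means()[c] / (self.genome[c].length_bp / 1000.0), 5)
            for c in chroms
        ] + [round(self.crossovers_per_kb, 5)]
        kbco = self.kb_per_crossover
        rows["kb/crossover"] = [
            round((self.genome[c].length_bp / 1000.0) / self.chromosome_means()[c], 1)
            if self.chromosome_means()[c] > 0 else None
            for c in chroms
        ] + [round(kbco, 1) if kbco is not None else None]
        return pd.DataFrame.from_dict(rows, orient="index", columns=chroms + ["genome"])


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of per-chromosome mean crossovers against chromosome length."""

    slope_per_kb: float
    intercept: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("regression requires at least 2 points")

    def predict(self, length_kb: float) -> float:
        return self.intercept + self.slope_per_kb * length_kb


@dataclass(frozen=True)
class DistanceProfile:
    """Crossover distances to the centromere midpoint, pooled across chromosomes."""

    entries: tuple[tuple[str, str, int, int], ...]  # (ascus, chrom, midpoint, distance)

    @property
    def distances(self) -> np.ndarray:
        return np.sort(np.array([e[3] for e in self.entries], dtype=np.int64))

    def count_within(self, distance_bp: int) -> int:
        """Number of crossovers strictly closer than ``distance_bp``."""
        return int(np.searchsorted(self.distances, distance_bp, side="left"))

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted distances, cumulative counts) for plotting."""
        d = self.distances
        return d, np.arange(1, len(d) + 1)

    @property
    def min_distance(self) -> int | None:
        d = self.distances
        return int(d[0]) if len(d) else None


def summarize_counts(
    eventsets: Sequence[EventSet], genome: ChromosomeSet
) -> LandscapeSummary:
    """Tabulate crossover counts for a set of called asci."""
    if not eventsets:
        raise ValueError("need at least one ascus")
    chroms = list(genome.names)
    counts = pd.DataFrame(
        [[es.crossover_counts(chroms)[c] for c in chroms] for es in eventsets],
        index=[es.ascus_id for es in eventsets],
        columns=chroms,
        dtype=int,
    )
    is_tetrad = pd.Series([es.n_spores == 4 for es in eventsets],
                          index=counts.index)
    return LandscapeSummary(counts, is_tetrad, genome)


def summary_from_counts(
    counts: Mapping[str, Sequence[int]] | pd.DataFrame,
    genome: ChromosomeSet,
    is_tetrad: Sequence[bool] | pd.Series | None = None,
) -> LandscapeSummary:
    """Build a summary directly from a per-ascus count table.

    ``counts`` rows are asci, columns chromosomes (in genome order). When
    ``is_tetrad`` is omitted, ascus names starting with "Tetrad" are taken
    as tetrads.
    """
    df = pd.DataFrame(counts) if not isinstance(counts, pd.DataFrame) else counts.copy()
    if list(df.columns) != list(genome.names):
        df.columns = list(genome.names)[: len(df.columns)]
    if is_tetrad is None:
        flags = pd.Series([str(i).lower().startswith("tetrad") for i in df.index],
                          index=df.index)
    else:
        flags = pd.Series(list(is_tetrad), index=df.index)
    return LandscapeSummary(df.astype(int), flags, genome)


def fit_count_vs_length(
    summary: LandscapeSummary, genome: ChromosomeSet | None = None
) -> RegressionFit:
    """OLS of per-chromosome mean crossovers per meiosis vs length in kb.

    Uses one point per chromosome (the chromosome total divided by the
    number of asci, unrounded). An intercept near 1 reflects the obligate
    crossover each chromosome pair requires for faithful segregation.
    """
    genome = genome or summary.genome
    x = np.array([genome[c].length_bp / 1000.0 for c in summary.counts.columns])
    y = summary.chromosome_means().to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("regression requires at least 2 chromosomes")
    if np.ptp(x) == 0:
        raise ValueError("all chromosome lengths identical: singular fit")
    slope, intercept = np.polyfit(x, y, 1)
    return RegressionFit(float(slope), float(intercept), len(x))


def centromere_distances(
    eventsets: Sequence[EventSet],
    genome: ChromosomeSet,
    exclude_obligatory: bool = False,
) -> DistanceProfile:
    """|crossover midpoint - centromere midpoint| for every retained crossover.

    With ``exclude_obligatory`` the crossovers flagged by
    :func:`~meiomap.events.designate_obligatory` are dropped (the marked
    interval forces them, so they would bias the distance distribution).
    """
    entries = []
    for es in eventsets:
        for co in es.crossovers:
            if exclude_obligatory and co.obligatory:
                continue
            cen = genome[co.chromosome].centromere_midpoint_bp
            entries.append((es.ascus_id, co.chromosome, co.midpoint_bp,
                            abs(co.midpoint_bp - cen)))
    return DistanceProfile(tuple(entries))


def ks_uniform_test(
    positions: Sequence[float], interval: tuple[float, float]
) -> tuple[float, float]:
    """One-sample two-sided Kolmogorov-Smirnov test against Uniform(lo, hi).

    Uses the exact small-sample p-value for n <= 100 and the asymptotic
    approximation beyond. Positions outside the interval raise ``ValueError``.
    """
    lo, hi = interval
    if hi <= lo:
        raise ValueError("interval must satisfy lo < hi")
    x = np.asarray(positions, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one position")
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("position(s) outside the interval")
    method = "exact" if x.size <= 100 else "asymp"
    res = stats.kstest(x, stats.uniform(loc=lo, scale=hi - lo).cdf, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_reference_ratio(summary: LandscapeSummary, reference_mean: float) -> float:
    """How many times lower this cross's crossover rate is than a reference.

    Both means enter at 1-dp printed precision, and the ratio is reported to
    one decimal (e.g. 90.5 / 25.5 -> 3.5).
    """
    mean = round(summary.mean_per_meiosis, 1)
    if mean <= 0:
        raise ValueError("summary mean must be positive")
    return round(reference_mean / mean, 1)
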