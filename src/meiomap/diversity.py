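"""SNP-density profiling and centromere-anchored low-diversity region calling.

Per-strain SNP positions (against a reference genome) are histogrammed in
1-kb bins; a low-diversity region is the maximal run of bins around a
centromere whose smoothed density stays below a threshold (default
1 SNP/kb, against a genome-wide average of ~4.5/kb in the divergent
isolates).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome import ChromosomeSet

__all__ = [
    "DensityProfile",
    "LowDiversityRegion",
    "bin_snp_density",
    "genome_mean_density",
    "call_low_diversity_regions",
    "write_profile_tsv",
    "write_regions_bed",
    "read_snp_positions_tsv",
]

BIN_BP = 1000


@dataclass(frozen=True)
class DensityProfile:
    """SNP counts per consecutive 1-kb bin, per chromosome.

    Bin ``i`` (0-based) covers 1-based coordinates
    ``[i*1000 + 1, (i+1)*1000]``; the last bin may be partial and its
    density is computed over its true width.
    """

    strain: str
    counts: Mapping[str, np.ndarray]
    genome: ChromosomeSet

    @property
    def total_snps(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def bin_widths_kb(self, chrom: str) -> np.ndarray:
        length = self.genome[chrom].length_bp
        n = len(self.counts[chrom])
        w = np.full(n, 1.0)
        w[-1] = (length - (n - 1) * BIN_BP) / 1000.0
        return w

    def densities(self, chrom: str) -> np.ndarray:
        """SNPs per kb in each bin (last partial bin scaled by true width)."""
        return self.counts[chrom] / self.bin_widths_kb(chrom)


@dataclass(frozen=True)
class LowDiversityRegion:
    """A bin-aligned span around a centromere with sub-threshold SNP density."""

    chromosome: str
    start_bp: int
    end_bp: int
    length_kb: int
    mean_density: float
    anchored_centromere: str


def bin_snp_density(
    snps: Mapping[str, Sequence[int] | np.ndarray],
    genome: ChromosomeSet,
    strain: str = "strain",
) -> DensityProfile:
    """Exact 1-kb histogram of SNP positions.

    Raises ``ValueError`` for positions outside ``[1, chromosome length]``.
    """
    counts = {}
    for chrom in genome:
        pos = np.asarray(snps.get(chrom.name, ()), dtype=np.int64)
        if pos.size and (pos.min() < 1 or pos.max() > chrom.length_bp):
            raise ValueError(
                f"{chrom.name}: SNP position outside [1, {chrom.length_bp}]"
            )
        n_bins = -(-chrom.length_bp // BIN_BP)
        idx = (pos - 1) // BIN_BP
        counts[chrom.name] = np.bincount(idx, minlength=n_bins).astype(np.int64)
    return DensityProfile(strain, counts, genome)


def genome_mean_density(
    snps: Mapping[str, Sequence[int] | np.ndarray] | int,
    genome: ChromosomeSet,
) -> float:
    """Genome-wide SNPs per kb, to 2 dp.

    Accepts either per-chromosome positions or a total SNP count.
    """
    if isinstance(snps, (int, np.integer)):
        total = int(snps)
    else:
        total = int(sum(len(np.asarray(p)) for p in snps.values()))
    return round(total / (genome.genome_length_bp / 1000.0), 2)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edge-truncated (shorter windows at the ends)."""
    if window == 1:
        return values.astype(float)
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return num / den


def call_low_diversity_regions(
    profile: DensityProfile,
    genome: ChromosomeSet | None = None,
    threshold: float = 1.0,
    smooth_window_kb: int = 21,
) -> list[LowDiversityRegion]:
    """Call the low-diversity region around each centromere, if any.

    The per-bin densities are smoothed by a centered moving average over
    ``smooth_window_kb`` bins (edge-truncated); for each centromere, the
    maximal contiguous run of bins containing the centromere's bin with
    smoothed density below ``threshold`` becomes a region. No region is
    reported for a centromere whose own bin is at or above threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if smooth_window_kb < 1 or smooth_window_kb % 2 == 0:
        raise ValueError("smooth_window_kb must be a positive odd integer")
    genome = genome or profile.genome
    regions = []
    for chrom in genome:
        dens = profile.densities(chrom.name)
        smoothed = _smooth(dens, smooth_window_kb)
        below = smoothed < threshold
        cb = (chrom.centromere_midpoint_bp - 1) // BIN_BP
        if not below[cb]:
            continue
        lo = cb
        while lo > 0 and below[lo - 1]:
            lo -= 1
        hi = cb
        while hi < len(below) - 1 and below[hi + 1]:
            hi += 1
        start_bp = lo * BIN_BP + 1
        end_bp = min((hi + 1) * BIN_BP, chrom.length_bp)
        true_kb = (end_bp - start_bp + 1) / 1000.0
        raw = int(profile.counts[chrom.name][lo:hi + 1].sum())
        regions.append(LowDiversityRegion(
            chromosome=chrom.name,
            start_bp=start_bp,
            end_bp=end_bp,
            length_kb=hi - lo + 1,
            mean_density=raw / true_kb,
            anchored_centromere=chrom.name,
        ))
    return regions


def read_snp_positions_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read a two-column (chrom, pos) TSV of SNP positions; header optional."""
    out: dict[str, list[int]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[1].strip():
                continue
            if line_no == 1 and not parts[1].strip().lstrip("-").isdigit():
                continue  # header
            out.setdefault(parts[0], []).append(int(parts[1]))
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in out.items()}


def write_profile_tsv(profile: DensityProfile, path: str | Path) -> None:
    """Wiggle-like per-bin TSV: chrom, bin start/end (1-based), count, density."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "snp_count", "snps_per_kb"])
        for chrom in profile.genome:
            counts = profile.counts[chrom.name]
            dens = profile.densities(chrom.name)
            for i, (c, d) in enumerate(zip(counts, dens)):
                start = i * BIN_BP + 1
                end = min((i + 1) * BIN_BP, chrom.length_bp)
                w.writerow([chrom.name, start, end, int(c), f"{d:.3f}"])


def write_regions_bed(regions: Sequence[LowDiversityRegion], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in regions:
            name = f"low_diversity:{r.anchored_centromere}"
            w.writerow([r.chromosome, r.start_bp - 1, r.end_bp, name,
                        0, "."])
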