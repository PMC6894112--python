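"""Genome metadata and core domain types for tetrad analysis of a yeast cross.

Coordinates throughout the package are 1-based and inclusive, matching the
CBS7435 reference assembly coordinates used for the *Komagataella phaffii*
GS115 x Pp4 cross; conversion to 0-based half-open happens only at the BED
boundary (:mod:`meiomap.io`).

The built-in default :class:`ChromosomeSet` carries the four *K. phaffii*
chromosomes (lengths, centromere midpoints, subtelomere masks), so the whole
pipeline runs without any external configuration file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

MISSING: int = -1
"""Sentinel for a missing genotype call in an ascus matrix."""

SPORE_LABELS = ("a", "b", "c", "d")


class ConfigError(ValueError):
    """Raised when a chromosome configuration fails validation."""


def _check_interval(iv: Sequence[int], length: int, what: str, name: str) -> tuple[int, int]:
    try:
        lo, hi = int(iv[0]), int(iv[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ConfigError(f"{name}: malformed interval in {what}: {iv!r}") from exc
    if not (1 <= lo <= hi <= length):
        raise ConfigError(
            f"{name}: {what} interval [{lo}, {hi}] outside chromosome [1, {length}]"
        )
    return lo, hi


@dataclass(frozen=True)
class ChromosomeInfo:
    """Metadata for one chromosome.

    Parameters
    ----------
    name
        Chromosome identifier (e.g. ``"chr1"``).
    length_bp
        Chromosome length in bp.
    centromere_midpoint_bp
        Midpoint of the unique central region between the centromeric
        inverted repeats; all centromere distances are measured from here.
    subtelomere_masks
        Closed 1-based intervals excluded from event calling (marker data
        near telomeres are unreliable). Sorted, non-overlapping.
    inversion_interval
        Optional closed interval that inverts between mating types (the
        *MAT* region on chromosome 4); crossovers are lethal inside it.
    """

    name: str
    length_bp: int
    centromere_midpoint_bp: int
    subtelomere_masks: tuple[tuple[int, int], ...] = ()
    inversion_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ConfigError(f"{self.name}: length_bp must be positive, got {self.length_bp}")
        if not (1 <= self.centromere_midpoint_bp <= self.length_bp):
            raise ConfigError(
                f"{self.name}: centromere_midpoint_bp {self.centromere_midpoint_bp} "
                f"outside chromosome [1, {self.length_bp}]"
            )
        masks = tuple(
            _check_interval(iv, self.length_bp, "subtelomere_masks", self.name)
            for iv in self.subtelomere_masks
        )
        for (a, b), (c, d) in zip(masks, masks[1:]):
            if c <= b:
                raise ConfigError(
                    f"{self.name}: subtelomere_masks must be sorted and non-overlapping"
                )
        object.__setattr__(self, "subtelomere_masks", masks)
        if self.inversion_interval is not None:
            iv = _check_interval(self.inversion_interval, self.length_bp, "inversion_interval", self.name)
            object.__setattr__(self, "inversion_interval", iv)

    def in_mask(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.subtelomere_masks)

    def arm_lengths(self) -> tuple[int, int]:
        """(left, right) arm lengths in bp, measured from the centromere midpoint."""
        return self.centromere_midpoint_bp - 1, self.length_bp - self.centromere_midpoint_bp


@dataclass(frozen=True)
class ChromosomeSet:
    """Ordered collection of chromosomes; anchors every coordinate in the package."""

    chromosomes: tuple[ChromosomeInfo, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate chromosome names: {names}")

    @property
    def genome_length_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def __iter__(self) -> Iterator[ChromosomeInfo]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> ChromosomeInfo:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}; have {self.names}")

    def __contains__(self, name: str) -> bool:
        return name in self.names


def default_genome() -> ChromosomeSet:
    """The four *K. phaffii* chromosomes of the CBS7435 reference assembly.

    Lengths and centromere midpoints are the reference values for the
    GS115 x Pp4 cross; subtelomere masks are the intervals excluded from
    event calling (chr1 <8 kb and >2861 kb, chr2 <12 kb and >2373 kb,
    chr3 >2168 kb, chr4 <2 kb and >1795 kb).
    """
    return ChromosomeSet(
        chromosomes=(
            ChromosomeInfo("chr1", 2_895_354, 1_404_539,
                           ((1, 8_000), (2_861_001, 2_895_354))),
            ChromosomeInfo("chr2", 2_396_458, 847_809,
                           ((1, 12_000), (2_373_001, 2_396_458))),
            ChromosomeInfo("chr3", 2_263_458, 37_576,
                           ((2_168_001, 2_263_458),)),
            ChromosomeInfo("chr4", 1_827_941, 61_908,
                           ((1, 2_000), (1_795_001, 1_827_941))),
        )
    )


def load_chromosome_config(path: str | Path | None = None) -> ChromosomeSet:
    """Load a chromosome configuration from YAML, or return the built-in defaults.

    The file must contain a ``chromosomes`` list of mappings with keys
    ``name``, ``length_bp``, ``centromere_midpoint_bp`` and optionally
    ``subtelomere_masks`` (list of ``[lo, hi]``) and ``inversion_interval``.

    Raises
    ------
    ConfigError
        On malformed intervals or a centromere outside its chromosome; the
        message names the offending field.
    FileNotFoundError
        If ``path`` is given but does not exist.
    """
    if path is None:
        return default_genome()
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "chromosomes" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'chromosomes' list")
    chroms = []
    for entry in doc["chromosomes"]:
        try:
            name = str(entry["name"])
            length = int(entry["length_bp"])
            cen = int(entry["centromere_midpoint_bp"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: chromosome entry missing/invalid field: {exc}") from exc
        masks = tuple(tuple(iv) for iv in entry.get("subtelomere_masks") or ())
        inv = entry.get("inversion_interval")
        chroms.append(
            ChromosomeInfo(name, length, cen, masks, tuple(inv) if inv else None)
        )
    return ChromosomeSet(tuple(chroms))


def write_chromosome_config(genome: ChromosomeSet, path: str | Path) -> None:
    doc = {
        "chromosomes": [
            {
                "name": c.name,
                "length_bp": c.length_bp,
                "centromere_midpoint_bp": c.centromere_midpoint_bp,
                "subtelomere_masks": [list(iv) for iv in c.subtelomere_masks],
                "inversion_interval": list(c.inversion_interval) if c.inversion_interval else None,
            }
            for c in genome
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class MarkerMap:
    """Per-chromosome sorted SNP marker positions distinguishing the two parents.

    Allele code 0 means the nucleotide of ``parent0_name`` (GS115 in the
    original cross) and 1 the nucleotide of ``parent1_name`` (Pp4).
    """

    positions: Mapping[str, np.ndarray]
    parent0_name: str = "parent0"
    parent1_name: str = "parent1"

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: positions must be 1-D")
            if arr.size and (np.any(np.diff(arr) <= 0) or arr[0] < 1):
                raise ValueError(f"{chrom}: positions must be strictly increasing and >= 1")
            clean[chrom] = arr
        object.__setattr__(self, "positions", clean)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def gaps(self) -> np.ndarray:
        """All inter-marker distances (bp), pooled across chromosomes."""
        parts = [np.diff(p) for p in self.positions.values() if len(p) > 1]
        return np.concatenate(parts) if parts else np.array([], dtype=np.int64)

    def median_gap(self) -> float:
        g = self.gaps()
        return float(np.median(g)) if g.size else float("nan")

    def subset(self, keep: Mapping[str, np.ndarray]) -> "MarkerMap":
        """New map retaining, per chromosome, positions where ``keep`` is True."""
        return MarkerMap(
            {c: p[np.asarray(keep[c], dtype=bool)] for c, p in self.positions.items()},
            self.parent0_name,
            self.parent1_name,
        )


@dataclass(frozen=True)
class AscusGenotypes:
    """Genotype matrix (markers x spores) for the products of one meiosis.

    Entries are 0 (parent0 allele), 1 (parent1 allele) or :data:`MISSING`.
    A tetrad has four spores; a trio is an ascus from which only three
    spores were recovered.
    """

    ascus_id: str
    spore_labels: tuple[str, ...]
    matrix: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        labels = tuple(self.spore_labels)
        if not (3 <= len(labels) <= 4):
            raise ValueError(f"{self.ascus_id}: need 3 or 4 spores, got {labels}")
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.ascus_id}: duplicate spore labels {labels}")
        object.__setattr__(self, "spore_labels", labels)
        clean = {}
        for chrom, m in self.matrix.items():
            arr = np.asarray(m, dtype=np.int8)
            if arr.ndim != 2 or arr.shape[1] != len(labels):
                raise ValueError(
                    f"{self.ascus_id}/{chrom}: matrix must be markers x {len(labels)} spores"
                )
            bad = ~np.isin(arr, (0, 1, MISSING))
            if np.any(bad):
                raise ValueError(f"{self.ascus_id}/{chrom}: entries must be 0, 1 or missing")
            clean[chrom] = arr
        object.__setattr__(self, "matrix", clean)

    @property
    def n_spores(self) -> int:
        return len(self.spore_labels)

    @property
    def is_tetrad(self) -> bool:
        return self.n_spores == 4

    def validate_against(self, markers: MarkerMap) -> None:
        for chrom, m in self.matrix.items():
            n = len(markers.positions.get(chrom, ()))
            if m.shape[0] != n:
                raise ValueError(
                    f"{self.ascus_id}/{chrom}: {m.shape[0]} rows but marker map has {n}"
                )


@dataclass(frozen=True)
class LocusPair:
    """A marked interval on one chromosome (e.g. the *ARG4*-*HIS4* interval)."""

    chromosome: str
    locusA_pos: int
    locusB_pos: int
    nameA: str = "locusA"
    nameB: str = "locusB"

    def __post_init__(self) -> None:
        if not self.locusA_pos < self.locusB_pos:
            raise ValueError("locusA_pos must be < locusB_pos")

    def check_within(self, genome: ChromosomeSet) -> None:
        length = genome[self.chromosome].length_bp
        if not (1 <= self.locusA_pos and self.locusB_pos <= length):
            raise ValueError(
                f"locus pair [{self.locusA_pos}, {self.locusB_pos}] outside "
                f"{self.chromosome} [1, {length}]"
            )


def default_marked_interval() -> LocusPair:
    """Assumed *ARG4*-*HIS4* interval on chromosome 1 (synthetic placement).

    The two selection loci sit 421 kb apart on opposite sides of *CEN1*; their
    exact reference coordinates are not published, so this default places
    *ARG4* 100 kb left of the centromere midpoint (inside the pericentromeric
    low-diversity region, where the gene is known to lie) and *HIS4* 421 kb
    distal. Analyses of real data should configure the true coordinates.
    """
    cen1 = 1_404_539
    return LocusPair("chr1", cen1 - 100_000, cen1 - 100_000 + 421_000, "ARG4", "HIS4")
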