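"""Readers and writers for the on-disk formats.

* Ascus genotype tables: TSV with header ``ascus  chrom  pos  <spore>...``,
  one row per (ascus, marker); cells are ``0``/``1``/blank (blank = missing).
  A spore column that is entirely blank for an ascus marks a trio.
* Joint multi-sample VCF -> parental-origin matrix conversion.
* BED (0-based half-open) and TSV output of called events.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import MISSING, SPORE_LABELS, AscusGenotypes, MarkerMap

__all__ = [
    "read_ascus_table",
    "write_ascus_table",
    "marker_map_from_table",
    "genotype_matrix_from_vcf",
    "write_events_bed",
    "write_events_tsv",
    "read_events_tsv",
]


class TableFormatError(ValueError):
    """Raised when a genotype table does not parse."""


_BASE_COLUMNS = ("ascus", "chrom", "pos")


def _read_table(path: str | Path, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    try:
        df["pos"] = df["pos"].astype(np.int64)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-integer value in 'pos' column: {exc}") from exc
    return df


def marker_map_from_table(
    path: str | Path,
    parent0_name: str = "parent0",
    parent1_name: str = "parent1",
    column_map: Mapping[str, str] | None = None,
) -> MarkerMap:
    """Derive a :class:`MarkerMap` from the union of positions in a genotype table."""
    df = _read_table(path, column_map)
    positions = {
        chrom: np.array(sorted(sub["pos"].unique()), dtype=np.int64)
        for chrom, sub in df.groupby("chrom", sort=True)
    }
    return MarkerMap(positions, parent0_name, parent1_name)


def read_ascus_table(
    path: str | Path,
    markers: MarkerMap,
    column_map: Mapping[str, str] | None = None,
) -> list[AscusGenotypes]:
    """Parse a TSV genotype table into one :class:`AscusGenotypes` per ascus.

    Every position in the file must exist in ``markers``; rows for markers
    absent from the file become missing calls. Blank cells are missing; a
    spore column entirely blank for an ascus drops that spore (trio).

    Raises
    ------
    TableFormatError
        For unknown positions (listing offending rows) or cell values
        outside ``{0, 1, blank}``.
    """
    df = _read_table(path, column_map)
    spore_cols = [c for c in df.columns if c not in _BASE_COLUMNS]
    if not spore_cols:
        raise TableFormatError(f"{path}: no spore columns found")

    known = np.zeros(len(df), dtype=bool)
    chrom_arr = df["chrom"].to_numpy()
    pos_arr = df["pos"].to_numpy()
    for chrom, arr in markers.positions.items():
        sel = chrom_arr == chrom
        if sel.any() and len(arr):
            j = np.searchsorted(arr, pos_arr[sel])
            ok = (j < len(arr)) & (arr[np.minimum(j, len(arr) - 1)] == pos_arr[sel])
            known[sel] = ok
    bad_rows = (np.flatnonzero(~known) + 2).tolist()  # 1-based file lines incl. header
    if bad_rows:
        raise TableFormatError(
            f"{path}: {len(bad_rows)} row(s) with positions not in the marker map "
            f"(file lines {bad_rows[:10]}{'...' if len(bad_rows) > 10 else ''})"
        )

    valid = {"0": 0, "1": 1, "": MISSING}
    asci: list[AscusGenotypes] = []
    for ascus_id, sub in df.groupby("ascus", sort=True):
        # spores present = columns with at least one non-blank cell
        present = [c for c in spore_cols if (sub[c] != "").any()]
        if not present:
            raise TableFormatError(f"{path}: ascus {ascus_id!r} has no genotype calls")
        matrix = {}
        for chrom, arr in markers.positions.items():
            m = np.full((len(arr), len(present)), MISSING, dtype=np.int8)
            rows = sub[sub["chrom"] == chrom]
            if len(rows):
                idx = np.searchsorted(arr, rows["pos"].to_numpy())
                for k, col in enumerate(present):
                    for r, cell in zip(idx, rows[col]):
                        if cell not in valid:
                            raise TableFormatError(
                                f"{path}: ascus {ascus_id!r} spore {col!r}: "
                                f"invalid cell {cell!r} (expected 0, 1 or blank)"
                            )
                        m[r, k] = valid[cell]
            matrix[chrom] = m
        asci.append(AscusGenotypes(str(ascus_id), tuple(present), matrix))
    return asci


def write_ascus_table(
    asci: Sequence[AscusGenotypes],
    markers: MarkerMap,
    path: str | Path,
    spore_columns: Sequence[str] = SPORE_LABELS,
) -> None:
    """Write asci to the TSV dialect read by :func:`read_ascus_table`.

    All asci share the spore column set ``spore_columns``; a spore absent
    from an ascus is written blank throughout (round-trips to a trio).
    Markers with all-missing rows for an ascus are still written (as blanks)
    so the marker map is recoverable from the file.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(_BASE_COLUMNS) + list(spore_columns))
        for ascus in asci:
            col_of = {lab: i for i, lab in enumerate(ascus.spore_labels)}
            for chrom, arr in markers.positions.items():
                m = ascus.matrix[chrom]
                for r, pos in enumerate(arr):
                    cells = []
                    for lab in spore_columns:
                        if lab not in col_of:
                            cells.append("")
                        else:
                            v = m[r, col_of[lab]]
                            cells.append("" if v == MISSING else str(int(v)))
                    w.writerow([ascus.ascus_id, chrom, int(pos)] + cells)


def genotype_matrix_from_vcf(
    vcf_path: str | Path,
    parent0_sample: str,
    parent1_sample: str,
    spore_samples: Sequence[str],
    exclusion_sites: Iterable[tuple[str, int]] | None = None,
    ascus_id: str = "ascus1",
) -> tuple[MarkerMap, AscusGenotypes]:
    """Convert joint genotype calls to a parental-origin 0/1 matrix.

    Keeps only biallelic SNP sites where both parents are homozygous for
    distinct alleles; indels, heterozygous or missing parental calls, and
    sites listed in ``exclusion_sites`` (``(chrom, pos)`` pairs, e.g. the 69
    SNPs separating the reference strain from the actual parent) are
    discarded. Each spore is coded 0 if it matches the parent0 allele, 1 if
    it matches parent1; heterozygous, missing, or third-allele spore calls
    become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    wanted = [parent0_sample, parent1_sample, *spore_samples]
    absent = [s for s in wanted if s not in samples]
    if absent:
        raise ValueError(f"{vcf_path}: sample(s) {absent} not in VCF (has {samples})")
    idx = {s: samples.index(s) for s in wanted}
    excluded = set(exclusion_sites or ())

    positions: dict[str, list[int]] = {}
    columns: dict[str, list[list[int]]] = {}
    n_spores = len(spore_samples)
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        if (var.CHROM, var.POS) in excluded:
            continue
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        p0 = gts[idx[parent0_sample]]
        p1 = gts[idx[parent1_sample]]
        if p0[0] < 0 or p1[0] < 0 or p0[0] != p0[1] or p1[0] != p1[1]:
            continue  # missing or heterozygous parental call
        a0, a1 = p0[0], p1[0]
        if a0 == a1:
            continue  # uninformative: parents share the allele
        row = []
        for s in spore_samples:
            g = gts[idx[s]]
            if g[0] < 0 or g[0] != g[1]:
                row.append(MISSING)
            elif g[0] == a0:
                row.append(0)
            elif g[0] == a1:
                row.append(1)
            else:
                row.append(MISSING)  # matches neither parent: tolerated as missing
        positions.setdefault(var.CHROM, []).append(var.POS)
        columns.setdefault(var.CHROM, []).append(row)

    if not positions:
        raise ValueError(f"{vcf_path}: zero informative biallelic SNP sites retained")

    pos_map, matrix = {}, {}
    for chrom, plist in positions.items():
        order = np.argsort(plist, kind="stable")
        pos_map[chrom] = np.asarray(plist, dtype=np.int64)[order]
        matrix[chrom] = np.asarray(columns[chrom], dtype=np.int8)[order]
    markers = MarkerMap(pos_map, parent0_sample, parent1_sample)
    labels = tuple(SPORE_LABELS[:n_spores]) if n_spores <= 4 else tuple(spore_samples)
    ascus = AscusGenotypes(ascus_id, labels, matrix)
    return markers, ascus


def _event_rows(eventset) -> list[tuple]:
    rows = []
    for co in eventset.crossovers:
        rows.append(
            (co.chromosome, co.left_pos, co.right_pos, "CO",
             "+".join(co.spores), co.midpoint_bp,
             int(co.obligatory), int(co.has_associated_conversion), "")
        )
    for t in eventset.tracts:
        rows.append(
            (t.chromosome, t.start_pos, t.end_pos, "NCO",
             "+".join(t.recipient_spores), (t.start_pos + t.end_pos) // 2,
             0, 0, t.ratio_class)
        )
    for c in eventset.complex_regions:
        rows.append(
            (c.chromosome, c.left_pos, c.right_pos, "complex", "",
             (c.left_pos + c.right_pos) // 2, 0, 0, c.description)
        )
    return rows


def write_events_bed(eventsets, path: str | Path) -> None:
    """Write called events as BED: 0-based half-open, name ``ascus:type:spores``."""
    single = not isinstance(eventsets, (list, tuple))
    sets = [eventsets] if single else list(eventsets)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for es in sets:
            for chrom, left, right, etype, spores, *_ in _event_rows(es):
                name = f"{es.ascus_id}:{etype}:{spores}"
                w.writerow([chrom, left - 1, right, name, 0, "."])


_EVENT_COLS = [
    "ascus", "chrom", "left", "right", "type", "spores",
    "midpoint", "obligatory", "assoc_conversion", "ratio_class", "n_spores",
]


def write_events_tsv(eventsets, path: str | Path) -> None:
    """Tabular event output (1-based inclusive coordinates), one row per event."""
    single = not isinstance(eventsets, (list, tuple))
    sets = [eventsets] if single else list(eventsets)
    rows = []
    for es in sets:
        for chrom, left, right, etype, spores, mid, obl, conv, extra in _event_rows(es):
            rows.append([es.ascus_id, chrom, left, right, etype, spores,
                         mid, obl, conv, extra, es.n_spores])
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path):
    """Read an event table back into a list of :class:`~meiomap.events.EventSet`."""
    from .events import ComplexRegion, ConversionTract, CrossoverEvent, EventSet

    df = pd.read_csv(path, sep="\t", dtype={"spores": str, "ratio_class": str},
                     keep_default_na=False)
    out = []
    for ascus_id, sub in df.groupby("ascus", sort=True):
        cos, tracts, cplx = [], [], []
        for row in sub.itertuples(index=False):
            if row.type == "CO":
                cos.append(CrossoverEvent(
                    chromosome=row.chrom, left_pos=int(row.left), right_pos=int(row.right),
                    spores=tuple(row.spores.split("+")),
                    obligatory=bool(row.obligatory),
                    has_associated_conversion=bool(row.assoc_conversion)))
            elif row.type == "NCO":
                tracts.append(ConversionTract(
                    chromosome=row.chrom, start_pos=int(row.left), end_pos=int(row.right),
                    ratio_class=row.ratio_class,
                    recipient_spores=tuple(s for s in row.spores.split("+") if s),
                    marker_support=2))
            else:
                cplx.append(ComplexRegion(row.chrom, int(row.left), int(row.right),
                                          row.ratio_class))
        n_spores = int(sub["n_spores"].iloc[0])
        out.append(EventSet(str(ascus_id), cos, tracts, cplx,
                            filters_applied={}, n_spores=n_spores))
    return out
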