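"""Segregation-profile plotting: red/blue parental-origin tracks per spore.

One panel per chromosome, one horizontal track per spore; a bar is drawn at
every marker, colored by parental origin (red = parent0/GS115, blue =
parent1/Pp4), so stretches with no markers appear as white gaps. Green bars
beneath the tracks mark non-Mendelian (3:1 / 4:0) conversion tracts, and
called crossover midpoints are ticked below.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .genome import MISSING, AscusGenotypes, ChromosomeSet, MarkerMap  # noqa: E402
from .events import EventSet  # noqa: E402

COLOR_P0 = "#cc2222"
COLOR_P1 = "#2244cc"
COLOR_TRACT = "#22aa44"


def plot_segregation(
    ascus: AscusGenotypes,
    events: EventSet | None,
    genome: ChromosomeSet,
    markers: MarkerMap,
    path: str | Path,
) -> None:
    """Render the segregation profile of one ascus to an image file.

    The output format follows the file extension (vector formats such as
    ``.svg``/``.pdf`` recommended).
    """
    chroms = [c for c in genome if c.name in ascus.matrix]
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.2 * ascus.n_spores / 4 * len(chroms) + 1),
        squeeze=False,
    )
    for ax_row, chrom in zip(axes, chroms):
        ax = ax_row[0]
        pos = markers.positions[chrom.name]
        m = ascus.matrix[chrom.name]
        for k, label in enumerate(ascus.spore_labels):
            y = ascus.n_spores - k
            for allele, color in ((0, COLOR_P0), (1, COLOR_P1)):
                sel = m[:, k] == allele
                if sel.any():
                    ax.vlines(pos[sel], y - 0.4, y + 0.4, color=color,
                              linewidth=0.3, rasterized=True)
            ax.text(-0.01, y, label, transform=ax.get_yaxis_transform(),
                    ha="right", va="center", fontsize=8)
        if events is not None:
            for t in events.tracts:
                if t.chromosome == chrom.name:
                    ax.plot([t.start_pos, t.end_pos], [0.3, 0.3],
                            color=COLOR_TRACT, linewidth=3, solid_capstyle="butt")
            for co in events.crossovers:
                if co.chromosome == chrom.name:
                    ax.plot(co.midpoint_bp, 0.0, marker="^", color="black",
                            markersize=4, clip_on=False)
        for lo, hi in chrom.subtelomere_masks:
            ax.axvspan(lo, hi, color="0.9", zorder=0)
        ax.plot(chrom.centromere_midpoint_bp, ascus.n_spores + 0.7, marker="o",
                color="0.4", markersize=4, clip_on=False)
        ax.set_xlim(0, max(c.length_bp for c in chroms))
        ax.set_ylim(-0.5, ascus.n_spores + 1)
        ax.set_yticks([])
        ax.set_ylabel(chrom.name, rotation=0, ha="right", va="center")
        ax.spines[["left", "right", "top"]].set_visible(False)
    axes[-1][0].set_xlabel("position (bp)")
    fig.suptitle(f"Segregation profile: {ascus.ascus_id}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_distance_curve(profile, path: str | Path, radius_mark_bp: int | None = None) -> None:
    """Cumulative crossover count as a function of distance from the centromere."""
    d, c = profile.cumulative()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(d / 1000.0, c, where="post")
    if radius_mark_bp:
        ax.axvline(radius_mark_bp / 1000.0, linestyle="--", color="0.6")
    ax.set_xlabel("distance from centromere (kb)")
    ax.set_ylabel("cumulative crossovers")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
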