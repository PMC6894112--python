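"""Published summary data from the *K. phaffii* GS115 x Pp4 cross.

These small tables are inputs to the arithmetic layers of the package
(count summaries, regression, density): the per-ascus crossover counts
observed in the 11 sequenced asci of the cross, and the per-strain SNP
totals of the natural isolates relative to the CBS7435 reference.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cross_crossover_counts",
    "strain_snp_totals",
    "SCEREVISIAE_MEAN_CROSSOVERS",
]

SCEREVISIAE_MEAN_CROSSOVERS = 90.5

_CROSS_COUNTS = {
    # ascus: (chr1, chr2, chr3, chr4)
    "Tetrad 1": (8, 1, 2, 4),
    "Tetrad 16": (8, 6, 8, 10),
    "Tetrad 20": (7, 4, 4, 8),
    "Tetrad 21": (7, 2, 4, 3),
    "Tetrad 27": (7, 6, 5, 6),
    "Trio 10": (10, 5, 5, 12),
    "Trio 12": (6, 8, 3, 4),
    "Trio 19": (12, 12, 11, 0),
    "Trio 22": (6, 15, 11, 5),
    "Trio 31": (1, 2, 7, 1),
    "Trio 34": (11, 10, 8, 5),
}


def cross_crossover_counts() -> pd.DataFrame:
    """Crossover counts per chromosome in the 11 asci (5 tetrads, 6 trios).

    Chromosome 4 of Trio 19 sustained no crossover: all three recovered
    spores carried the Pp4 parent over the whole chromosome.
    """
    return pd.DataFrame.from_dict(
        _CROSS_COUNTS, orient="index", columns=["chr1", "chr2", "chr3", "chr4"]
    )


def strain_snp_totals() -> dict[str, int]:
    """Total SNP counts of the divergent natural isolates vs CBS7435."""
    return {"Pp2": 43_708, "Pp4": 41_838, "Pp5": 15_599}
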