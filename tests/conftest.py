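"""Shared fixtures and helpers for the meiomap test suite."""

from __future__ import annotations

import numpy as np
import pytest

from meiomap import (
    AscusGenotypes,
    ChromosomeInfo,
    ChromosomeSet,
    MarkerMap,
    default_genome,
)
from meiomap import events as ev
from meiomap import simulate as sim


@pytest.fixture(scope="session")
def genome() -> ChromosomeSet:
    return default_genome()


@pytest.fixture(scope="session")
def small_genome() -> ChromosomeSet:
    """Two small chromosomes with masks, for fast focused tests."""
    return ChromosomeSet((
        ChromosomeInfo("chrA", 500_000, 250_000, ((1, 5_000), (495_001, 500_000))),
        ChromosomeInfo("chrB", 300_000, 60_000, ((295_001, 300_000),)),
    ))


def make_ascus(vectors, positions=None, chrom="chrA", labels=None, ascus_id="t"):
    """Build a one-chromosome ascus from a list of per-marker genotype vectors."""
    m = np.array(vectors, dtype=np.int8)
    n_spores = m.shape[1]
    if labels is None:
        labels = ("a", "b", "c", "d")[:n_spores]
    if positions is None:
        positions = 10_000 + 1_000 * np.arange(m.shape[0])
    markers = MarkerMap({chrom: np.asarray(positions, dtype=np.int64)})
    return AscusGenotypes(ascus_id, tuple(labels), {chrom: m}), markers


def clean_true_crossovers(truth: sim.SimTruth, markers: MarkerMap, genome: ChromosomeSet):
    """Visible true crossovers satisfying the event-separation condition."""
    return sim.detectable_crossovers(truth, markers, genome, min_separation_markers=2)


def roundtrip_stats(n_meioses: int, seed: int, genome: ChromosomeSet,
                    params: sim.SimParams | None = None):
    """Simulate, call, and score crossover recovery and bracketing.

    Returns (n_clean_true, n_recovered, n_called, n_called_bracketing).
    """
    params = params or sim.SimParams.calibrated(genome)
    markers, pairs = sim.simulate_experiment(
        genome, params, n_tetrads=n_meioses, n_trios=0, seed=seed)
    n_clean = n_rec = n_called = n_brack = 0
    for ascus, truth in pairs:
        es = ev.call_ascus(ascus, markers, genome)
        for c in clean_true_crossovers(truth, markers, genome):
            n_clean += 1
            if any(e.chromosome == c.chromosome and e.left_pos <= c.position_bp < e.right_pos
                   for e in es.crossovers):
                n_rec += 1
        for e in es.crossovers:
            n_called += 1
            if any(c.chromosome == e.chromosome and e.left_pos <= c.position_bp < e.right_pos
                   for c in truth.crossovers):
                n_brack += 1
            elif (e.has_associated_conversion
                  or "unsampled" in e.spores or "unknown" in e.spores):
                # conversion-associated call: a mask-truncated tract, or
                # overlapping opposite-direction tracts on homologous
                # chromatids, is observationally indistinguishable from a
                # crossover-with-conversion; such truths violate the
                # separation condition, so the call is well-founded when it
                # overlaps a true tract
                if any(t.chromosome == e.chromosome
                       and e.left_pos <= t.end_bp and t.start_bp <= e.right_pos
                       for t in truth.tracts):
                    n_brack += 1
    return n_clean, n_rec, n_called, n_brack
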