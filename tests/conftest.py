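"""Shared fixtures: one miniature genome + aligner per session, plus small
synthetic libraries sized for fast rule-engine tests."""

from __future__ import annotations

import pytest

from piclusterkit.genome import GenomeSpec, build_genome
from piclusterkit import simulate, smallrna


@pytest.fixture(scope="session")
def genome0():
    """Default miniature genome, seed 0 (shared; treat as read-only)."""
    return build_genome(GenomeSpec(seed=0))


@pytest.fixture(scope="session")
def aligner0(genome0):
    return smallrna.ExactAligner(genome0)


@pytest.fixture(scope="session")
def small_params():
    """Reduced library (20k reads) for rule-engine and oracle tests."""
    return simulate.attf6_depletion_default(library_size=20_000, n_typeI=800,
                                            n_typeII=200)


@pytest.fixture(scope="session")
def mature_library(genome0, aligner0, small_params):
    return simulate.simulate_small_rna_library(
        genome0, small_params, protocol="mature", condition="control", seed=1,
        aligner=aligner0)


@pytest.fixture(scope="session")
def cs_library(genome0, aligner0, small_params):
    return simulate.simulate_small_rna_library(
        genome0, small_params, protocol="csRNA", condition="control", seed=2,
        aligner=aligner0)


# ---------------------------------------------------------------------------
# independent re-implementation of the assignment rules (test oracle)
# ---------------------------------------------------------------------------

def recheck_assignment(record, loci_by_pos, protocol):
    """Rule-by-rule re-checker, written independently of the package engine.

    Returns the locus id the read should count for, or None with the first
    violated rule's name.
    """
    if record.multiplicity != 1:
        return None, "not unique"
    if record.mismatches != 0:
        return None, "not perfect"
    length = record.end - record.start
    if not (15 <= length <= 40):
        return None, "length out of bounds"
    five = record.start if record.strand == "+" else record.end - 1
    if protocol == "mature":
        if record.seq[0] != "T":
            return None, "no 5' T"
        offsets = (0, 1, 2)
    else:
        offsets = (-2,)
    for loc in loci_by_pos.get((record.chrom, record.strand), []):
        step = 1 if loc.strand == "+" else -1
        for off in offsets:
            if five == loc.five_prime + step * off:
                return loc.locus_id, None
    return None, "no matching locus 5' position"


def loci_index(loci):
    idx = {}
    for loc in loci:
        idx.setdefault((loc.chrom, loc.strand), []).append(loc)
    return idx
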