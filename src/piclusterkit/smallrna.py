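"""Small-RNA read assignment, normalization and fold-change quantification.

Implements the five-rule mature 21U-RNA assignment (unique, perfect, sense,
5' U, 15-40 nt, 5' end at the annotated 5' end +0/+1/+2 in the transcription
direction), the capped-small-RNA (csRNA) precursor rule (5' end exactly 2 nt
upstream of the annotated 5' end), reads-per-million normalization against
the total mapped-read count, per-class fold changes, the per-locus scatter
table with its background floor, and relative qPCR quantification (ddCt).

The exact-substring aligner here stands in, on the miniature genome, for the
delegated short-read aligner (perfect matches only, all placements reported,
reads with more than ``max_hits`` placements suppressed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .genome import GenomeModel, PiRNALocus, revcomp

MATURE_OFFSETS = (0, 1, 2)  # 5' offsets downstream of the annotated 5' end
CSRNA_OFFSETS = (-2,)       # csRNA 5' ends sit exactly 2 nt upstream
MIN_LEN, MAX_LEN = 15, 40   # inclusive length bounds


class AmbiguousLociError(ValueError):
    """Two same-strand loci with 5' ends closer than the offset window width."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One read placement (0-based half-open; end - start == read length)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    multiplicity: int  # count of equally good genomic placements of the read
    mismatches: int = 0

    def __post_init__(self):
        if self.end - self.start != len(self.seq):
            raise ValueError(f"{self.read_id}: interval length != read length")
        if self.multiplicity < 1 or self.mismatches < 0:
            raise ValueError(f"{self.read_id}: invalid multiplicity/mismatches")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class AlignResult:
    records: list[AlignmentRecord]
    hits: dict[str, int]  # read id -> total perfect hit count (0 = unmapped)

    @property
    def total_mapped(self) -> int:
        """Reads with at least one placement, each counted once."""
        return sum(1 for n in self.hits.values() if n >= 1)


class ExactAligner:
    """Seed-and-verify exact matcher over both strands of a genome."""

    SEED = 12

    def __init__(self, genome: GenomeModel):
        self.genome = genome
        self._index: dict[str, list[tuple[str, int]]] = {}
        k = self.SEED
        for chrom, seq in genome.chromosomes.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def hits_of(self, seq: str) -> list[tuple[str, int, str]]:
        """All perfect placements of ``seq`` as (chrom, plus-strand start, strand)."""
        if not seq:
            raise ValueError("empty read")
        out = []
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            if len(query) < self.SEED:
                for chrom, ref in self.genome.chromosomes.items():
                    start = 0
                    while True:
                        i = ref.find(query, start)
                        if i < 0:
                            break
                        out.append((chrom, i, strand))
                        start = i + 1
                continue
            for chrom, i in self._index.get(query[: self.SEED], ()):
                ref = self.genome.chromosomes[chrom]
                if ref[i : i + len(query)] == query:
                    out.append((chrom, i, strand))
        return out


def align_exact(
    reads: Iterable[tuple[str, str]],
    genome: GenomeModel,
    max_hits: int = 100,
    aligner: ExactAligner | None = None,
) -> AlignResult:
    """Report every perfect placement of each read, up to ``max_hits``.

    Reads with more than ``max_hits`` placements are suppressed (no records)
    but their hit count is still reported, mirroring a ``-m``-style cap.
    """
    aligner = aligner or ExactAligner(genome)
    records: list[AlignmentRecord] = []
    hits: dict[str, int] = {}
    cache: dict[str, list[tuple[str, int, str]]] = {}
    for read_id, seq in reads:
        if not seq:
            raise ValueError(f"empty read: {read_id}")
        placements = cache.get(seq)
        if placements is None:
            placements = aligner.hits_of(seq)
            cache[seq] = placements
        n = len(placements)
        hits[read_id] = n
        if 1 <= n <= max_hits:
            for chrom, start, strand in placements:
                records.append(
                    AlignmentRecord(read_id, chrom, start, start + len(seq), strand, seq, n, 0)
                )
    return AlignResult(records, hits)


@dataclass
class ClassCounts:
    """Per-locus and per-class read counts with their RPM twins."""

    per_locus: dict[str, int]
    totals: dict[str, int]
    total_mapped: int
    per_locus_rpm: dict[str, float] | None = None
    totals_rpm: dict[str, float] | None = None


def _check_spacing(loci: Sequence[PiRNALocus], min_sep: int = 3) -> None:
    by_key: dict[tuple[str, str], list[PiRNALocus]] = {}
    for loc in loci:
        by_key.setdefault((loc.chrom, loc.strand), []).append(loc)
    for group in by_key.values():
        group = sorted(group, key=lambda l: l.five_prime)
        for a, b in zip(group, group[1:]):
            if b.five_prime - a.five_prime < min_sep:
                raise AmbiguousLociError(
                    f"loci {a.locus_id} and {b.locus_id} have 5' ends "
                    f"{b.five_prime - a.five_prime} nt apart (< {min_sep})"
                )


def _position_map(
    loci: Sequence[PiRNALocus], offsets: Sequence[int]
) -> dict[tuple[str, str, int], PiRNALocus]:
    _check_spacing(loci)
    posmap: dict[tuple[str, str, int], PiRNALocus] = {}
    for loc in loci:
        sign = 1 if loc.strand == "+" else -1
        for off in offsets:
            key = (loc.chrom, loc.strand, loc.five_prime + sign * off)
            if key in posmap and posmap[key].locus_id != loc.locus_id:
                raise AmbiguousLociError(
                    f"loci {posmap[key].locus_id} and {loc.locus_id} share 5'-window position"
                )
            posmap[key] = loc
    return posmap


def _assign(
    alignments: AlignResult | Sequence[AlignmentRecord],
    loci: Sequence[PiRNALocus],
    offsets: Sequence[int],
    require_5p_t: bool,
    class_prefix: str,
    total_mapped: int | None,
) -> ClassCounts:
    if isinstance(alignments, AlignResult):
        records = alignments.records
        if total_mapped is None:
            total_mapped = alignments.total_mapped
    else:
        records = list(alignments)
        if total_mapped is None:
            total_mapped = len({r.read_id for r in records})
    posmap = _position_map(loci, offsets)
    per_locus = {loc.locus_id: 0 for loc in loci}
    for rec in records:
        if rec.multiplicity != 1 or rec.mismatches != 0:
            continue
        if not (MIN_LEN <= len(rec.seq) <= MAX_LEN):
            continue
        if require_5p_t and rec.seq[0] != "T":
            continue
        loc = posmap.get((rec.chrom, rec.strand, rec.five_prime))
        if loc is None:
            continue
        per_locus[loc.locus_id] += 1
    totals = {f"{class_prefix}typeI": 0, f"{class_prefix}typeII": 0}
    by_id = {loc.locus_id: loc for loc in loci}
    for lid, n in per_locus.items():
        totals[f"{class_prefix}type{by_id[lid].pirna_type}"] += n
    return ClassCounts(per_locus, totals, total_mapped)


def assign_pirna(
    alignments: AlignResult | Sequence[AlignmentRecord],
    loci: Sequence[PiRNALocus],
    total_mapped: int | None = None,
) -> ClassCounts:
    """Count mature piRNA reads per locus under the five assignment rules."""
    return _assign(alignments, loci, MATURE_OFFSETS, True, "", total_mapped)


def assign_csrna(
    alignments: AlignResult | Sequence[AlignmentRecord],
    loci: Sequence[PiRNALocus],
    total_mapped: int | None = None,
) -> ClassCounts:
    """Count csRNA precursor reads (5' end 2 nt upstream; no 5'-U requirement)."""
    return _assign(alignments, loci, CSRNA_OFFSETS, False, "csRNA_", total_mapped)


def rpm_normalize(counts: ClassCounts) -> ClassCounts:
    """Populate the RPM fields; raw counts are left untouched."""
    if counts.total_mapped <= 0:
        raise ValueError("total_mapped must be positive for RPM normalization")
    scale = 1e6 / counts.total_mapped
    return replace(
        counts,
        per_locus_rpm={k: v * scale for k, v in counts.per_locus.items()},
        totals_rpm={k: v * scale for k, v in counts.totals.items()},
    )


def type_totals_fold_change(control: ClassCounts, treated: ClassCounts) -> pd.DataFrame:
    """Per-class RPM fold changes, reported in both orientations.

    Division by a zero treated total is flagged as infinite rather than
    masked with a pseudocount.
    """
    ctrl = control if control.totals_rpm is not None else rpm_normalize(control)
    trt = treated if treated.totals_rpm is not None else rpm_normalize(treated)
    rows = []
    for cls in ctrl.totals_rpm:
        c, t = ctrl.totals_rpm[cls], trt.totals_rpm.get(cls, 0.0)
        rows.append(
            {
                "class": cls,
                "control_rpm": c,
                "treated_rpm": t,
                "fc_control_over_treated": c / t if t > 0 else math.inf,
                "fc_treated_over_control": t / c if c > 0 else math.inf,
                "infinite": (t == 0 and c > 0) or (c == 0 and t > 0),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def per_locus_scatter(
    control: ClassCounts,
    treated: ClassCounts,
    loci: Sequence[PiRNALocus],
    floor: float = 0.5,
    fc_line: float = 4.0,
    peak_summits: Sequence[tuple[str, int]] | None = None,
    window: int = 5000,
) -> pd.DataFrame:
    """Per-locus (control RPM, treated RPM) table for scatter plots.

    Loci with both values below ``floor`` (default 2^-1 RPM) are dropped as
    background.  Retained loci are flagged when |log2 FC| >= log2(fc_line)
    (inclusive at the line) and when the locus 5' end lies within ``window``
    of any supplied peak summit.
    """
    ctrl = control if control.per_locus_rpm is not None else rpm_normalize(control)
    trt = treated if treated.per_locus_rpm is not None else rpm_normalize(treated)
    by_id = {loc.locus_id: loc for loc in loci}
    rows = []
    thr = math.log2(fc_line)
    for lid in sorted(set(ctrl.per_locus_rpm) | set(trt.per_locus_rpm)):
        c = ctrl.per_locus_rpm.get(lid, 0.0)
        t = trt.per_locus_rpm.get(lid, 0.0)
        if c < floor and t < floor:
            continue
        if t == 0 or c == 0:
            fourfold = True  # an infinite ratio always clears the fold line
        else:
            fourfold = abs(math.log2(c / t)) >= thr
        near = False
        if peak_summits is not None and lid in by_id:
            loc = by_id[lid]
            near = any(
                chrom == loc.chrom and abs(pos - loc.five_prime) <= window
                for chrom, pos in peak_summits
            )
        rows.append(
            {"locus": lid, "control_rpm": c, "treated_rpm": t,
             "fourfold": fourfold, "near_peak": near}
        )
    return pd.DataFrame(rows, columns=["locus", "control_rpm", "treated_rpm", "fourfold", "near_peak"])


def ddct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """Relative abundances by the ddCt method.

    ``ct`` has columns [condition, replicate, gene, ct].  For each replicate,
    dCt = Ct_target - Ct_reference; ddCt subtracts the mean calibrator dCt of
    the same target; relative abundance is 2**-ddCt.  Returns per
    (condition, gene) the mean, SD and n of the replicate values.
    """
    required = {"condition", "replicate", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    ref = ct[ct["gene"] == reference_gene].set_index(["condition", "replicate"])["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    if targets.empty:
        raise ValueError("no target genes besides the reference")
    targets["dct"] = [
        row.ct - ref.loc[(row.condition, row.replicate)]
        for row in targets.itertuples(index=False)
    ]
    cal = (
        targets[targets["condition"] == calibrator_condition]
        .groupby("gene")["dct"]
        .mean()
    )
    targets["rel"] = 2.0 ** -(targets["dct"] - targets["gene"].map(cal))
    out = (
        targets.groupby(["condition", "gene"])["rel"]
        .agg(mean_rel="mean", sd_rel="std", n="size")
        .reset_index()
    )
    out["sd_rel"] = out["sd_rel"].fillna(0.0)
    return out
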