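"""ChIP-seq quantification: coverage ratios, chromosome summaries, peak
filtering, promoter-priority annotation, cluster membership, peak overlap,
hypergeometric overlap tests, summit context extraction, metagene profiles
and Ruby/AT promoter-context scans.

Tracks are consumed and emitted as plain bedGraph text on uniform bin grids;
the experiment/control ratio uses pseudocount 1 in both numerator and
denominator on a common 5-bp grid, and the per-chromosome summary re-bins to
1 kb, floors at 1.2, then averages surviving bins per chromosome and across
replicates — in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel, GeneAnnotation, ClusterInterval, PiRNALocus
from .genome import RUBY_MOTIF, revcomp

# promoter-priority order; first match wins
CLASS_PRIORITY = (
    "snRNA_promoter",
    "snoRNA_promoter",
    "ncRNA",
    "protein_coding_promoter",
    "pseudogene",
)

PEAK_FILTER_PRESETS = {"attf6": (200.0, 3.0), "prde1": (500.0, 3.0)}


@dataclass(frozen=True)
class Peak:
    """narrowPeak-style interval; summit is an offset from ``start``."""

    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str = "."
    signal: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    summit: int = 0

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"peak {self.name}: start must precede end")
        if not 0 <= self.summit < self.end - self.start:
            raise ValueError(f"peak {self.name}: summit offset outside the peak")

    @property
    def summit_pos(self) -> int:
        return self.start + self.summit

    def significance(self, column: str = "qValue") -> float:
        return self.q_value if column == "qValue" else self.p_value


@dataclass
class CoverageTrack:
    """Uniformly binned per-chromosome signal starting at position 0."""

    bin_size: int
    values: dict[str, np.ndarray]
    label: str = ""

    def rebin(self, bin_size: int) -> "CoverageTrack":
        """Re-bin by averaging (old bins must tile the new ones or vice versa)."""
        if bin_size == self.bin_size:
            return self
        out = {}
        if bin_size % self.bin_size == 0:
            k = bin_size // self.bin_size
            for chrom, v in self.values.items():
                pad = (-len(v)) % k
                vv = np.pad(v.astype(float), (0, pad), constant_values=np.nan)
                out[chrom] = np.nanmean(vv.reshape(-1, k), axis=1)
        elif self.bin_size % bin_size == 0:
            k = self.bin_size // bin_size
            for chrom, v in self.values.items():
                out[chrom] = np.repeat(v.astype(float), k)
        else:
            raise ValueError("bin sizes must be integer multiples of one another")
        return CoverageTrack(bin_size, out, self.label)


def coverage_ratio(exp: CoverageTrack, ctrl: CoverageTrack,
                   pseudocount: float = 1.0, bin_size: int = 5) -> CoverageTrack:
    """(exp + pseudocount) / (ctrl + pseudocount) per bin on a common grid."""
    e, c = exp.rebin(bin_size), ctrl.rebin(bin_size)
    if set(e.values) != set(c.values):
        only_e = sorted(set(e.values) - set(c.values))
        only_c = sorted(set(c.values) - set(e.values))
        raise ValueError(
            f"chromosome sets differ: only in experiment {only_e}, only in control {only_c}"
        )
    out = {}
    for chrom in e.values:
        ev, cv = e.values[chrom], c.values[chrom]
        n = max(len(ev), len(cv))
        ev = np.pad(ev.astype(float), (0, n - len(ev)))
        cv = np.pad(cv.astype(float), (0, n - len(cv)))
        out[chrom] = (ev + pseudocount) / (cv + pseudocount)
    return CoverageTrack(bin_size, out, f"ratio({exp.label}/{ctrl.label})")


def chromosome_summary(ratio_tracks: Sequence[CoverageTrack],
                       bin_size: int = 1000, floor: float = 1.2) -> pd.DataFrame:
    """Per-chromosome mean ratio after 1 kb re-binning and the 1.2 floor.

    Bins below ``floor`` are dropped per replicate; surviving bins are
    averaged per chromosome, then across replicates.  A chromosome where no
    bin survives in any replicate is reported as NaN (explicit empty marker).
    """
    chroms = sorted({c for t in ratio_tracks for c in t.values})
    rows = []
    for chrom in chroms:
        rep_means = []
        for t in ratio_tracks:
            if chrom not in t.values:
                continue
            v = t.rebin(bin_size).values[chrom]
            kept = v[~np.isnan(v) & (v >= floor)]
            rep_means.append(kept.mean() if kept.size else np.nan)
        vals = [m for m in rep_means if not np.isnan(m)]
        rows.append({"chrom": chrom,
                     "mean_score": float(np.mean(vals)) if vals else np.nan,
                     "n_replicates_with_signal": len(vals)})
    return pd.DataFrame(rows).set_index("chrom")


def filter_peaks(peaks: Iterable[Peak], min_score: float, min_significance: float,
                 significance_column: str = "qValue") -> list[Peak]:
    """Retain peaks with score >= min_score AND significance >= min_significance
    (both inclusive).  Presets: ``PEAK_FILTER_PRESETS['attf6'|'prde1']``."""
    return [
        p for p in peaks
        if p.score >= min_score and p.significance(significance_column) >= min_significance
    ]


def cluster_membership(peaks: Sequence[Peak],
                       clusters: Sequence[ClusterInterval]) -> tuple[list[bool], float]:
    """Flag peaks whose start AND end lie inside one cluster interval.

    Returns the per-peak flags and the in-cluster percentage rounded to one
    decimal.  A peak straddling a cluster edge is outside.
    """
    flags = [
        any(cl.contains(p.chrom, p.start, p.end) for cl in clusters) for p in peaks
    ]
    pct = round(100.0 * sum(flags) / len(flags), 1) if peaks else 0.0
    return flags, pct


@dataclass(frozen=True)
class PeakClass:
    peak_id: str
    assigned_class: str  # one of CLASS_PRIORITY or "unassigned"
    gene_id: str = ""


def _promoter_interval(g: GeneAnnotation, length: int) -> tuple[int, int]:
    """Strand-aware upstream window, clipped at position 0."""
    if g.strand == "+":
        return max(0, g.start - length), g.start
    return g.end, g.end + length


def annotate_peaks(peaks: Sequence[Peak], annotation: Sequence[GeneAnnotation],
                   promoter_pc: int = 500, promoter_sn: int = 100
                   ) -> tuple[list[PeakClass], pd.Series]:
    """Assign each peak the single highest-priority overlapping feature class.

    Features considered: snRNA and snoRNA promoters (``promoter_sn`` nt
    upstream), ncRNA gene bodies, protein-coding promoters (``promoter_pc``
    nt upstream; histone-flagged genes yield the ``histone`` sub-label in the
    count table), and pseudogene bodies.  Peaks overlapping nothing are
    unassigned.  Output is invariant to peak order.
    """
    features: list[tuple[str, int, int, str, str, bool]] = []
    for g in annotation:
        if g.strand not in ("+", "-"):
            raise ValueError(f"annotation record {g.name} lacks a strand")
        if g.gene_class == "snRNA":
            s, e = _promoter_interval(g, promoter_sn)
            features.append((g.chrom, s, e, "snRNA_promoter", g.name, False))
        elif g.gene_class == "snoRNA":
            s, e = _promoter_interval(g, promoter_sn)
            features.append((g.chrom, s, e, "snoRNA_promoter", g.name, False))
        elif g.gene_class == "ncRNA":
            features.append((g.chrom, g.start, g.end, "ncRNA", g.name, False))
        elif g.gene_class == "protein_coding":
            s, e = _promoter_interval(g, promoter_pc)
            features.append((g.chrom, s, e, "protein_coding_promoter", g.name, g.histone))
    for g in annotation:
        if g.gene_class == "pseudogene":
            features.append((g.chrom, g.start, g.end, "pseudogene", g.name, False))

    rank = {cls: i for i, cls in enumerate(CLASS_PRIORITY)}
    results: list[PeakClass] = []
    counts = {cls: 0 for cls in CLASS_PRIORITY}
    counts["unassigned"] = 0
    counts["histone_promoter"] = 0  # sub-label of protein_coding_promoter
    for p in peaks:
        best: tuple[int, str, str, bool] | None = None
        for chrom, s, e, cls, gid, histone in features:
            if chrom == p.chrom and p.start < e and s < p.end:
                cand = (rank[cls], cls, gid, histone)
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is None:
            results.append(PeakClass(p.name, "unassigned"))
            counts["unassigned"] += 1
        else:
            results.append(PeakClass(p.name, best[1], best[2]))
            counts[best[1]] += 1
            if best[1] == "protein_coding_promoter" and best[3]:
                counts["histone_promoter"] += 1
    return results, pd.Series(counts, name="n_peaks")


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    if K > N or n > N:
        raise ValueError("require K <= N and n <= N")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class OverlapResult:
    pairs: list[tuple[str, str]]
    n_a_shared: int
    n_a_unique: int
    n_b_shared: int
    n_b_unique: int


def peak_overlap(set_a: Sequence[Peak], set_b: Sequence[Peak],
                 min_frac: float = 0.5, reciprocal: bool = False) -> OverlapResult:
    """Pairs of peaks sharing at least ``min_frac`` of a peak's length.

    By default the fraction test passes if EITHER peak's fraction reaches the
    threshold; ``reciprocal=True`` requires both.  Venn-style shared/unique
    counts are reported per set.
    """
    pairs = []
    shared_a, shared_b = set(), set()
    for a in set_a:
        for b in set_b:
            if a.chrom != b.chrom:
                continue
            inter = min(a.end, b.end) - max(a.start, b.start)
            if inter <= 0:
                continue
            fa = inter / (a.end - a.start)
            fb = inter / (b.end - b.start)
            ok = (fa >= min_frac and fb >= min_frac) if reciprocal \
                else (fa >= min_frac or fb >= min_frac)
            if ok:
                pairs.append((a.name, b.name))
                shared_a.add(a.name)
                shared_b.add(b.name)
    return OverlapResult(pairs, len(shared_a), len(set_a) - len(shared_a),
                         len(shared_b), len(set_b) - len(shared_b))


def summit_context(peaks: Sequence[Peak], genome: GenomeModel,
                   flank: int = 100) -> list[tuple[str, str, bool]]:
    """(header, sequence, truncated) for summit +/- ``flank`` of each peak.

    The window is [summit - flank, summit + flank + 1); records clipped at a
    chromosome edge are flagged truncated.  Headers carry the peak id and the
    plus-strand coordinates of the extracted window.
    """
    out = []
    for p in peaks:
        chrom_len = len(genome.chromosomes[p.chrom])
        s = p.summit_pos - flank
        e = p.summit_pos + flank + 1
        cs, ce = max(0, s), min(chrom_len, e)
        truncated = (cs != s) or (ce != e)
        header = f"{p.name}::{p.chrom}:{cs}-{ce}" + ("|truncated" if truncated else "")
        out.append((header, genome.sequence(p.chrom, cs, ce), truncated))
    return out


def metagene_profile(track: CoverageTrack, anchors: Sequence[tuple[str, int, str]],
                     flank: int) -> tuple[np.ndarray, np.ndarray]:
    """Signal matrix around anchor positions, plus the column-mean profile.

    Each row covers [pos - flank, pos + flank) in the track's bins;
    minus-strand anchors are reversed so columns read 5'->3'.  Windows
    running off a chromosome are NaN-padded and the mean profile ignores NaNs.
    """
    bs = track.bin_size
    if flank % bs:
        raise ValueError("flank must be a multiple of the track bin size")
    w = 2 * flank // bs
    mat = np.full((len(anchors), w), np.nan)
    for i, (chrom, pos, strand) in enumerate(anchors):
        vals = track.values[chrom]
        b0 = pos // bs - flank // bs
        for j in range(w):
            b = b0 + j
            if 0 <= b < len(vals):
                mat[i, j] = vals[b]
        if strand == "-":
            mat[i] = mat[i, ::-1]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0) if len(anchors) else np.full(w, np.nan)
    return mat, mean


def motif_context(genome: GenomeModel, loci: Sequence[PiRNALocus],
                  flank: int = 100) -> tuple[pd.DataFrame, np.ndarray]:
    """Ruby-motif hits and the positional AT fraction around locus 5' ends.

    For each locus the window spans [-flank, +flank] in the transcription
    frame (oriented 5'->3'); hits report the offset of the motif start
    relative to the 5' end and whether the match lies on the sense or
    antisense strand of the locus.  The AT profile is the per-position
    fraction of A/T across all loci, index 0 = -flank.
    """
    hits = []
    width = 2 * flank + 1
    at_counts = np.zeros(width)
    n_eff = np.zeros(width)
    rc = revcomp(RUBY_MOTIF)
    for loc in loci:
        try:
            seq = genome.tx_window(loc.chrom, loc.five_prime, loc.strand, -flank, flank + 1)
        except ValueError:
            continue  # locus too close to a chromosome edge for the full window
        for i in range(len(seq) - 7):
            sub = seq[i : i + 8]
            if sub == RUBY_MOTIF:
                hits.append({"locus": loc.locus_id, "offset": i - flank, "orientation": "sense"})
            elif sub == rc:
                hits.append({"locus": loc.locus_id, "offset": i - flank, "orientation": "antisense"})
        arr = np.frombuffer(seq.encode(), dtype="S1")
        at_counts += (arr == b"A") | (arr == b"T")
        n_eff += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(n_eff > 0, at_counts / np.maximum(n_eff, 1), np.nan)
    return pd.DataFrame(hits, columns=["locus", "offset", "orientation"]), profile
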