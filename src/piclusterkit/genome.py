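"""Miniature *C. elegans*-style genome with piRNA, 5S rDNA-SL1 and histone clusters.

The generated genome reproduces, at 1/100 linear scale, the structural
features the downstream analyses depend on:

* two type I piRNA clusters on one chromosome (scaled from the chromosome IV
  intervals 4.75-7.5 Mb and 13.5-17.5 Mb), each locus carrying the Ruby
  promoter octamer ``CTGTTTCA`` with AT-rich flanks at a configurable offset
  upstream of the annotated 5' end;
* type II piRNA loci sharing transcription start sites with protein-coding
  genes outside the clusters;
* a 5S rDNA-SL1 tandem-repeat locus (identical repeat units, so reads from it
  genuinely multi-map);
* dispersed histone mini-clusters (protein-coding genes with a histone flag);
* snRNA / snoRNA / ncRNA / protein-coding / pseudogene annotations.

All coordinates are 0-based half-open.  Every generator is a pure function of
its spec (including the seed): identical specs give byte-identical FASTA/BED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

RUBY_MOTIF = "CTGTTTCA"

GENE_CLASSES = (
    "piRNA_typeI",
    "piRNA_typeII",
    "snRNA",
    "snoRNA",
    "ncRNA",
    "protein_coding",
    "pseudogene",
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CapacityError(ValueError):
    """Raised when a spec asks for more features than fit at minimum spacing."""


@dataclass(frozen=True)
class ClusterInterval:
    name: str
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start >= self.start and end <= self.end


@dataclass(frozen=True)
class GeneAnnotation:
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    gene_class: str
    histone: bool = False

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5'-most transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PiRNALocus:
    locus_id: str
    chrom: str
    five_prime: int
    strand: str
    pirna_type: str  # "I" or "II"


@dataclass
class GenomeSpec:
    """Parameters of the miniature genome.

    Cluster intervals default to the chromosome IV piRNA clusters
    (4.75-7.5 Mb and 13.5-17.5 Mb) scaled by ``scale`` so the in-cluster
    predicate keeps its real-genome structure.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrIV": 200_000, "chrV": 200_000}
    )
    scale: float = 0.01
    clusters: list[ClusterInterval] = field(
        default_factory=lambda: [
            ClusterInterval("piRNA_cluster_I", "chrIV", 47_500, 75_000),
            ClusterInterval("piRNA_cluster_II", "chrIV", 135_000, 175_000),
        ]
    )
    n_typeI_per_cluster: tuple[int, ...] = (40, 60)
    n_typeII: int = 30
    n_decoy_typeI: int = 4  # type I loci duplicated once elsewhere (multi-mappers)
    rdna_sl1_repeats: int = 20
    rdna_sl1_unit_length: int = 1000
    n_histone_clusters: int = 4
    histone_genes_per_cluster: int = 4
    n_snRNA: int = 12
    n_snoRNA: int = 12
    n_ncRNA: int = 15
    n_protein_coding: int = 60
    n_pseudogene: int = 10
    gc_background: float = 0.36
    ruby_offset: int = 40  # motif 3' edge to piRNA 5' end; free parameter, not a measured value
    ruby_flank_len: int = 20
    ruby_flank_at_min: float = 0.70
    pirna_body_len: int = 21
    min_locus_spacing: int = 150
    seed: int = 0

    def validate(self) -> None:
        for cl in self.clusters:
            if cl.chrom not in self.chrom_lengths:
                raise ValueError(f"cluster {cl.name} on unknown chromosome {cl.chrom}")
            if not (0 <= cl.start < cl.end <= self.chrom_lengths[cl.chrom]):
                raise ValueError(f"cluster {cl.name} outside chromosome bounds")
        by_chrom: dict[str, list[ClusterInterval]] = {}
        for cl in self.clusters:
            by_chrom.setdefault(cl.chrom, []).append(cl)
        for cls in by_chrom.values():
            cls = sorted(cls, key=lambda c: c.start)
            for a, b in zip(cls, cls[1:]):
                if a.end > b.start:
                    raise ValueError(f"clusters {a.name} and {b.name} overlap")
        if len(self.n_typeI_per_cluster) != len(self.clusters):
            raise ValueError("n_typeI_per_cluster must match number of clusters")
        if self.n_decoy_typeI > sum(self.n_typeI_per_cluster):
            raise ValueError("more decoy loci than type I loci")
        if not 0.0 <= self.gc_background <= 1.0:
            raise ValueError("gc_background must be in [0, 1]")
        if self.ruby_offset < self.ruby_flank_len:
            raise ValueError("downstream AT flank must fit inside the ruby offset gap")


@dataclass
class GenomeModel:
    chromosomes: dict[str, str]
    genes: list[GeneAnnotation]
    clusters: list[ClusterInterval]
    metadata: dict

    # -- coordinate helpers -------------------------------------------------
    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.chromosomes[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)

    def tx_window(self, chrom: str, five_prime: int, strand: str, a: int, b: int) -> str:
        """Sequence of the transcription-frame window [a, b) relative to a 5' end.

        Positive offsets run downstream in the direction of transcription.
        Raises if the window leaves the chromosome.
        """
        if strand == "+":
            start, end = five_prime + a, five_prime + b
        else:
            start, end = five_prime - b + 1, five_prime - a + 1
        if start < 0 or end > len(self.chromosomes[chrom]):
            raise ValueError(
                f"window [{a},{b}) at {chrom}:{five_prime}({strand}) leaves the chromosome"
            )
        return self.sequence(chrom, start, end, strand)

    def pirna_loci(self) -> list[PiRNALocus]:
        loci = []
        for g in self.genes:
            if g.gene_class == "piRNA_typeI":
                loci.append(PiRNALocus(g.name, g.chrom, g.five_prime, g.strand, "I"))
            elif g.gene_class == "piRNA_typeII":
                loci.append(PiRNALocus(g.name, g.chrom, g.five_prime, g.strand, "II"))
        return loci

    def in_cluster(self, chrom: str, start: int, end: int) -> bool:
        return any(cl.contains(chrom, start, end) for cl in self.clusters)

    # -- serialization ------------------------------------------------------
    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        from . import io as pio

        pio.write_fasta(self.chromosomes.items(), path, width=width)

    def write_bed(self, path: str | Path) -> None:
        from . import io as pio

        pio.write_annotation_bed(self.genes, path)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _at_rich(rng: np.random.Generator, length: int, at_min: float) -> str:
    """AT-rich flank; resampled (deterministically) until the AT fraction passes."""
    at_target = min(0.95, at_min + 0.15)
    probs = [at_target / 2, (1 - at_target) / 2, (1 - at_target) / 2, at_target / 2]
    for _ in range(100):
        s = "".join(rng.choice(list("ACGT"), size=length, p=probs))
        at = sum(c in "AT" for c in s) / length
        if at >= at_min and RUBY_MOTIF not in s and RUBY_MOTIF not in revcomp(s):
            return s
    raise RuntimeError("could not draw an AT-rich flank")  # pragma: no cover


class _Occupancy:
    """Per-chromosome reserved intervals, for non-overlapping feature placement."""

    def __init__(self, length: int):
        self.length = length
        self.taken: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> bool:
        for s, e in self.taken:
            if start < e and s < end:
                return False
        self.taken.append((start, end))
        return True


def _place_features(
    rng: np.random.Generator,
    occ: _Occupancy,
    n: int,
    feat_len: int,
    region: tuple[int, int],
    spacing: int,
    what: str,
    max_tries: int = 200,
) -> list[int]:
    """Random non-overlapping starts for ``n`` features inside ``region``."""
    lo, hi = region
    if n * (feat_len + spacing) > (hi - lo):
        raise CapacityError(
            f"cannot place {n} {what} features of {feat_len} bp at spacing "
            f"{spacing} in a {hi - lo} bp region"
        )
    starts = []
    for _ in range(n):
        for attempt in range(max_tries):
            s = int(rng.integers(lo, hi - feat_len))
            if occ.reserve(s - spacing // 2, s + feat_len + spacing // 2):
                starts.append(s)
                break
        else:
            raise CapacityError(f"placement of {what} features failed (region too dense)")
    return starts


def _scrub_ruby(chrom_seq: bytearray, window: tuple[int, int], keep: set[int]) -> None:
    """Remove unintended Ruby occurrences (both strands) in a window.

    ``keep`` holds plus-strand start coordinates of designated motifs that must
    survive.  Substituted bases are chosen so no new occurrence can appear at
    the same spot; the scan is repeated until clean.
    """
    lo, hi = max(0, window[0]), min(len(chrom_seq), window[1])
    targets = (RUBY_MOTIF.encode(), revcomp(RUBY_MOTIF).encode())
    for _ in range(20):
        dirty = False
        segment = bytes(chrom_seq[lo:hi])
        for motif in targets:
            start = 0
            while True:
                i = segment.find(motif, start)
                if i < 0:
                    break
                pos = lo + i
                if pos not in keep:
                    # flip an interior base; both targets have T at index 3 / A mirrored
                    j = pos + 3
                    chrom_seq[j] = ord("G") if chrom_seq[j] != ord("G") else ord("C")
                    dirty = True
                start = i + 1
        if not dirty:
            return
        # re-scan: a substitution near the window edge could, in principle,
        # have created a new half-overlapping occurrence


def build_genome(spec: GenomeSpec, outdir: str | Path | None = None) -> GenomeModel:
    """Build the miniature genome; optionally write FASTA + annotation BED.

    Postconditions (checked here, re-checkable from the emitted files):
    every type I locus carries ``CTGTTTCA`` ending ``ruby_offset`` nt upstream
    of its annotated 5' end with AT-rich flanks; type I loci lie inside the
    cluster intervals and type II loci outside; all intervals are 0-based
    half-open and within chromosome bounds.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    seqs: dict[str, bytearray] = {}
    occs: dict[str, _Occupancy] = {}
    for chrom, length in spec.chrom_lengths.items():
        seqs[chrom] = bytearray(_random_sequence(rng, length, spec.gc_background).tobytes())
        occs[chrom] = _Occupancy(length)

    genes: list[GeneAnnotation] = []
    body = spec.pirna_body_len
    margin = spec.ruby_offset + 8 + spec.ruby_flank_len + 10

    # ---- type I piRNA loci inside clusters --------------------------------
    typeI: list[GeneAnnotation] = []
    for cl, n in zip(spec.clusters, spec.n_typeI_per_cluster):
        region = (cl.start + margin, cl.end - margin - body)
        if region[1] <= region[0] and n > 0:
            raise CapacityError(f"cluster {cl.name} too small for type I loci")
        starts = _place_features(
            rng, occs[cl.chrom], n, body, region, spec.min_locus_spacing, "type I piRNA"
        )
        for s in starts:
            strand = "+" if rng.random() < 0.5 else "-"
            # s is the placement anchor; the annotated body is [s, s+body)
            typeI.append(
                GeneAnnotation(
                    cl.chrom, s, s + body, strand, f"21ur-{len(typeI) + 1:04d}", "piRNA_typeI"
                )
            )
    genes.extend(typeI)

    # ---- regions available outside clusters -------------------------------
    def non_cluster_regions(chrom: str) -> list[tuple[int, int]]:
        cls = sorted(
            [c for c in spec.clusters if c.chrom == chrom], key=lambda c: c.start
        )
        regions, pos = [], 200
        for c in cls:
            if c.start - 200 > pos:
                regions.append((pos, c.start - 200))
            pos = c.end + 200
        if spec.chrom_lengths[chrom] - 200 > pos:
            regions.append((pos, spec.chrom_lengths[chrom] - 200))
        return regions

    def place_outside(n: int, feat_len: int, spacing: int, what: str) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        chroms = list(spec.chrom_lengths)
        for i in range(n):
            chrom = chroms[i % len(chroms)]
            regions = non_cluster_regions(chrom)
            sizes = np.array([hi - lo for lo, hi in regions], dtype=float)
            placed = False
            for _ in range(4 * len(regions)):
                region = regions[int(rng.choice(len(regions), p=sizes / sizes.sum()))]
                try:
                    s = _place_features(rng, occs[chrom], 1, feat_len, region, spacing, what)[0]
                except CapacityError:
                    continue
                out.append((chrom, s))
                placed = True
                break
            if not placed:
                raise CapacityError(f"placement of {what} features failed (chromosome too dense)")
        return out

    # ---- 5S rDNA-SL1 tandem-repeat locus on the second chromosome ---------
    tandem_chrom = list(spec.chrom_lengths)[-1]
    unit_len = spec.rdna_sl1_unit_length
    tandem_len = spec.rdna_sl1_repeats * unit_len
    tregion = non_cluster_regions(tandem_chrom)[-1]
    if tregion[1] - tregion[0] < tandem_len + 400:
        raise CapacityError("5S rDNA-SL1 tandem array does not fit")
    tstart = tregion[0] + 200
    occs[tandem_chrom].reserve(tstart - 100, tstart + tandem_len + 100)
    unit = _random_sequence(rng, unit_len, spec.gc_background).tobytes()
    for r in range(spec.rdna_sl1_repeats):
        seqs[tandem_chrom][tstart + r * unit_len : tstart + (r + 1) * unit_len] = unit
        u = tstart + r * unit_len
        # oppositely oriented SL1 (snRNA) and 5S rDNA (ncRNA) within each unit
        genes.append(
            GeneAnnotation(tandem_chrom, u + 100, u + 200, "-", f"sl1-rep{r + 1:02d}", "snRNA")
        )
        genes.append(
            GeneAnnotation(tandem_chrom, u + 600, u + 720, "+", f"5s-rdna-rep{r + 1:02d}", "ncRNA")
        )

    # ---- protein-coding genes (incl. histone mini-clusters) ---------------
    pc_len = 1500
    pc: list[GeneAnnotation] = []
    for i, (chrom, s) in enumerate(place_outside(spec.n_protein_coding, pc_len, 300, "protein-coding")):
        strand = "+" if rng.random() < 0.5 else "-"
        pc.append(GeneAnnotation(chrom, s, s + pc_len, strand, f"pcg-{i + 1:03d}", "protein_coding"))
    genes.extend(pc)

    his_len, his_gap = 400, 150
    block_len = spec.histone_genes_per_cluster * (his_len + his_gap)
    hi = 0
    for chrom, s in place_outside(spec.n_histone_clusters, block_len, 300, "histone cluster"):
        for k in range(spec.histone_genes_per_cluster):
            hs = s + k * (his_len + his_gap)
            strand = "+" if rng.random() < 0.5 else "-"
            hi += 1
            genes.append(
                GeneAnnotation(chrom, hs, hs + his_len, strand, f"his-{hi:02d}", "protein_coding", histone=True)
            )

    # ---- other small-gene classes -----------------------------------------
    for cls_name, n, length in (
        ("snRNA", spec.n_snRNA, 150),
        ("snoRNA", spec.n_snoRNA, 120),
        ("ncRNA", spec.n_ncRNA, 300),
        ("pseudogene", spec.n_pseudogene, 800),
    ):
        for i, (chrom, s) in enumerate(place_outside(n, length, 200, cls_name)):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(chrom, s, s + length, strand, f"{cls_name.lower()}-{i + 1:03d}", cls_name)
            )

    # ---- type II piRNA loci at protein-coding TSSs outside clusters -------
    if spec.n_typeII > len(pc):
        raise CapacityError("n_typeII exceeds the number of protein-coding genes")
    for i, g in enumerate(pc[: spec.n_typeII]):
        five = g.five_prime
        if g.strand == "+":
            iv = (five, five + body)
        else:
            iv = (five - body + 1, five + 1)
        genes.append(
            GeneAnnotation(g.chrom, iv[0], iv[1], g.strand, f"21ur-II-{i + 1:03d}", "piRNA_typeII")
        )

    # ---- write promoter/5'-end sequence features --------------------------
    def write_tx(chrom: str, five: int, strand: str, a: int, s: str) -> None:
        """Write transcript-frame sequence ``s`` starting at offset ``a``."""
        if strand == "+":
            start = five + a
            seqs[chrom][start : start + len(s)] = s.encode()
        else:
            end = five - a + 1
            seqs[chrom][end - len(s) : end] = revcomp(s).encode()

    pirna_genes = [g for g in genes if g.gene_class in ("piRNA_typeI", "piRNA_typeII")]
    for g in pirna_genes:
        write_tx(g.chrom, g.five_prime, g.strand, 0, "TTT")  # 5' U and the +1/+2 offset starts

    ruby_plus_starts: dict[str, set[int]] = {c: set() for c in spec.chrom_lengths}
    off, fl = spec.ruby_offset, spec.ruby_flank_len
    for g in (g for g in genes if g.gene_class == "piRNA_typeI"):
        up = _at_rich(rng, fl, spec.ruby_flank_at_min)
        down = _at_rich(rng, fl, spec.ruby_flank_at_min)
        write_tx(g.chrom, g.five_prime, g.strand, -(off + 8 + fl), up + RUBY_MOTIF + down)
        if g.strand == "+":
            ruby_plus_starts[g.chrom].add(g.five_prime - off - 8)
        else:
            ruby_plus_starts[g.chrom].add(g.five_prime + off + 1)

    # remove chance Ruby occurrences near every type I promoter so motif scans
    # recover exactly the designated sites
    scrub_flank = off + 8 + fl + 150
    for g in (g for g in genes if g.gene_class == "piRNA_typeI"):
        _scrub_ruby(
            seqs[g.chrom],
            (g.five_prime - scrub_flank, g.five_prime + scrub_flank),
            ruby_plus_starts[g.chrom],
        )

    # ---- decoy copies of designated type I loci (multi-mapper fixtures) ---
    decoy_ids: list[str] = []
    model_tmp = GenomeModel(
        {c: s.decode() for c, s in ((c, bytes(b)) for c, b in seqs.items())}, [], [], {}
    )
    decoy_pool = [g for g in genes if g.gene_class == "piRNA_typeI"][-spec.n_decoy_typeI or len(typeI):]
    decoy_pool = decoy_pool[: spec.n_decoy_typeI]
    if spec.n_decoy_typeI:
        spots = place_outside(spec.n_decoy_typeI, body + 10, 200, "decoy copy")
        for g, (chrom, s) in zip(decoy_pool, spots):
            copy_seq = model_tmp.tx_window(g.chrom, g.five_prime, g.strand, -2, body + 5)
            seqs[chrom][s : s + len(copy_seq)] = copy_seq.encode()
            decoy_ids.append(g.name)

    chromosomes = {c: bytes(b).decode() for c, b in seqs.items()}
    genes.sort(key=lambda g: (g.chrom, g.start, g.name))

    model = GenomeModel(
        chromosomes=chromosomes,
        genes=genes,
        clusters=list(spec.clusters),
        metadata={
            "scale": spec.scale,
            "ruby_offset": spec.ruby_offset,
            "ruby_flank_len": spec.ruby_flank_len,
            "decoy_typeI_loci": decoy_ids,
            "seed": spec.seed,
            "tandem_locus": (tandem_chrom, tstart, tstart + tandem_len),
        },
    )
    _check_invariants(model, spec)

    if outdir is not None:
        from . import io as pio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        model.write_fasta(outdir / "genome.fa")
        model.write_bed(outdir / "annotation.bed")
        pio.write_genome_meta(model, outdir / "genome_meta.json")
    return model


def _check_invariants(model: GenomeModel, spec: GenomeSpec) -> None:
    for g in model.genes:
        if not (0 <= g.start < g.end <= len(model.chromosomes[g.chrom])):
            raise AssertionError(f"gene {g.name} outside chromosome bounds")
        if g.gene_class == "piRNA_typeI":
            if not model.in_cluster(g.chrom, g.start, g.end):
                raise AssertionError(f"type I locus {g.name} outside clusters")
            promoter = model.tx_window(
                g.chrom, g.five_prime, g.strand, -(spec.ruby_offset + 8), -spec.ruby_offset
            )
            if promoter != RUBY_MOTIF:
                raise AssertionError(f"Ruby motif missing at {g.name}")
        elif g.gene_class == "piRNA_typeII":
            if model.in_cluster(g.chrom, g.start, g.end):
                raise AssertionError(f"type II locus {g.name} inside a cluster")


def find_ruby_sites(seq: str) -> list[tuple[int, str]]:
    """All plus-coordinate Ruby occurrences in ``seq`` as (start, strand)."""
    hits = [(m.start(), "+") for m in re.finditer(RUBY_MOTIF, seq)]
    hits += [(m.start(), "-") for m in re.finditer(revcomp(RUBY_MOTIF), seq)]
    return sorted(hits)
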