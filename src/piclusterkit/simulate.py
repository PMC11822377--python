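"""Synthetic libraries with known ground truth for every pipeline stage.

Every generator is seeded and deterministic; class totals are deterministic
expectations (rounded) so the designed depletion factors are recoverable,
with randomness confined to per-locus allocation, 5' offsets, read lengths
and placements.  Each contaminant class violates exactly one assignment rule
(its defining violation) so each filter has a dedicated negative control.
Truth labels are always verifiable from the emitted files by an independent
predicate — the generators keep no hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, PiRNALocus
from .genome import revcomp
from .smallrna import AlignmentRecord, ExactAligner

CONTAMINANT_CLASSES = ("multimapper", "antisense", "mismatch", "off_length")


# ---------------------------------------------------------------------------
# scenario parameters
# ---------------------------------------------------------------------------

@dataclass
class ScenarioParams:
    """One depletion scenario: library composition and effect sizes.

    The named default scenario (:func:`attf6_depletion_default`) fixes the
    depletion factors to the measured effects: type I piRNAs x1/29, type I
    csRNAs x1/120, bound-gene mRNA x1/2, germline genes x1/1.2.
    """

    name: str = "custom"
    library_size: int = 200_000
    n_typeI: int = 8000          # piRNA reads kept <=5% of the library so RPM
    n_typeII: int = 2000         # fold changes track raw fold changes
    typeI_depletion: float = 1.0
    cs_typeI_depletion: float = 1.0
    typeII_factor: float = 1.0
    cs_typeII_factor: float = 1.0
    bound_gene_fc: float = 1.0
    germline_fc: float = 1.0
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: {c: 0.002 for c in CONTAMINANT_CLASSES}
    )
    mature_lengths: tuple[int, ...] = (20, 21, 22, 23, 24, 25, 26)
    mature_length_probs: tuple[float, ...] = (0.08, 0.60, 0.12, 0.08, 0.05, 0.04, 0.03)
    cs_lengths: tuple[int, ...] = tuple(range(20, 31))
    offset_probs: tuple[float, float, float] = (0.70, 0.20, 0.10)
    # mRNA count sub-model (overdispersed counts, fixed dispersion)
    n_genes: int = 2000
    n_bound: int = 162
    n_germline: int = 200
    dispersion: float = 0.05
    mrna_replicates: int = 2
    mrna_mean_log: float = 5.0
    mrna_sd_log: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for f in (self.typeI_depletion, self.cs_typeI_depletion, self.typeII_factor,
                  self.cs_typeII_factor, self.bound_gene_fc, self.germline_fc):
            if not f > 0:
                raise ValueError("all depletion factors must be > 0")
        fracs = list(self.contaminant_fractions.values())
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("contaminant fractions must lie in [0,1] and sum <= 1")
        if self.n_typeI + self.n_typeII > self.library_size:
            raise ValueError("piRNA reads exceed the library size")


def attf6_depletion_default(seed: int = 0, **overrides) -> ScenarioParams:
    """The measured-depletion scenario: 29x type I piRNA, 120x type I csRNA,
    2x bound-gene mRNA and 1.2x germline mRNA reductions."""
    return ScenarioParams(
        name="attf6_depletion_default",
        typeI_depletion=29.0,
        cs_typeI_depletion=120.0,
        bound_gene_fc=2.0,
        germline_fc=1.2,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# small-RNA libraries
# ---------------------------------------------------------------------------

@dataclass
class SmallRNALibrary:
    condition: str
    protocol: str
    reads: list[tuple[str, str]]
    truth: pd.DataFrame
    alignments: list[AlignmentRecord]

    def write(self, outdir: str | Path, prefix: str | None = None) -> None:
        from . import io as pio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or f"{self.protocol}_{self.condition}"
        pio.write_fasta(self.reads, outdir / f"{prefix}.reads.fa")
        pio.write_tsv(self.truth, outdir / f"{prefix}.truth.tsv")
        rows = [
            (r.chrom, r.start, r.end, r.read_id, 0, r.strand, r.multiplicity, r.mismatches)
            for r in self.alignments
        ]
        pd.DataFrame(rows).to_csv(outdir / f"{prefix}.alignments.bed", sep="\t",
                                  header=False, index=False)


def _class_totals(params: ScenarioParams, protocol: str, condition: str) -> dict[str, int]:
    if protocol == "mature":
        n1, n2 = params.n_typeI, params.n_typeII
        d1, d2 = params.typeI_depletion, params.typeII_factor
        k1, k2 = "typeI", "typeII"
    elif protocol == "csRNA":
        n1, n2 = params.n_typeI, params.n_typeII
        d1, d2 = params.cs_typeI_depletion, params.cs_typeII_factor
        k1, k2 = "csRNA_typeI", "csRNA_typeII"
    else:
        raise ValueError(f"unknown protocol {protocol!r} (use 'mature' or 'csRNA')")
    if condition == "control":
        totals = {k1: n1, k2: n2}
    elif condition == "depleted":
        totals = {k1: int(round(n1 / d1)), k2: int(round(n2 / d2))}
    else:
        raise ValueError(f"unknown condition {condition!r}")
    for cls in CONTAMINANT_CLASSES:
        totals[f"contaminant:{cls}"] = int(round(
            params.contaminant_fractions.get(cls, 0.0) * params.library_size))
    totals["background"] = params.library_size - sum(totals.values())
    if totals["background"] < 0:
        raise ValueError("class counts exceed the library size")
    return totals


def simulate_small_rna_library(
    genome: GenomeModel,
    params: ScenarioParams,
    protocol: str = "mature",
    condition: str = "control",
    seed: int | None = None,
    aligner: ExactAligner | None = None,
) -> SmallRNALibrary:
    """Simulate one small-RNA library with per-read truth labels.

    ``protocol='mature'`` draws piRNA reads with a 5' U and 5' offsets
    {0,+1,+2}; ``protocol='csRNA'`` places 5' ends exactly 2 nt upstream of
    the annotated piRNA 5' end.  Multiplicities in the truth alignment
    records are computed against the genome with the exact aligner.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    aligner = aligner or ExactAligner(genome)

    loci = genome.pirna_loci()
    decoys = set(genome.metadata.get("decoy_typeI_loci", []))
    pool = {
        "I": [l for l in loci if l.pirna_type == "I" and l.locus_id not in decoys],
        "II": [l for l in loci if l.pirna_type == "II"],
    }
    decoy_loci = [l for l in loci if l.locus_id in decoys]
    totals = _class_totals(params, protocol, condition)
    is_cs = protocol == "csRNA"
    base_off = -2 if is_cs else 0

    # 5' positions to keep background reads away from (both protocols' windows)
    forbidden = {
        (l.chrom, l.strand, l.five_prime + d) for l in loci for d in range(-3, 4)
    }

    hit_cache: dict[str, int] = {}

    def n_hits(seq: str) -> int:
        if seq not in hit_cache:
            hit_cache[seq] = len(aligner.hits_of(seq))
        return hit_cache[seq]

    def placement(loc: PiRNALocus, off: int, length: int) -> tuple[int, int]:
        if loc.strand == "+":
            return loc.five_prime + off, loc.five_prime + off + length
        return loc.five_prime - off - length + 1, loc.five_prime - off + 1

    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    alignments: list[AlignmentRecord] = []
    counter = 0

    def emit(seq, label, locus_id, chrom, start, end, strand, mult, mism, off):
        nonlocal counter
        counter += 1
        rid = f"read{counter:06d}"
        reads.append((rid, seq))
        truth_rows.append(
            {"read_id": rid, "label": label, "locus_id": locus_id, "chrom": chrom,
             "start": start, "end": end, "strand": strand, "length": len(seq),
             "multiplicity": mult, "mismatches": mism, "offset": off}
        )
        alignments.append(AlignmentRecord(rid, chrom, start, end, strand, seq, mult, mism))

    def locus_read(loc: PiRNALocus, off: int, length: int) -> tuple[str, int, int]:
        seq = genome.tx_window(loc.chrom, loc.five_prime, loc.strand, off, off + length)
        start, end = placement(loc, off, length)
        return seq, start, end

    # ---- piRNA / csRNA classes -------------------------------------------
    for cls, n in totals.items():
        if cls.startswith("contaminant:") or cls == "background":
            continue
        ptype = "I" if cls.endswith("typeI") else "II"
        cands = pool[ptype]
        weights = rng.lognormal(0.0, 1.0, size=len(cands))
        locus_counts = rng.multinomial(n, weights / weights.sum())
        for loc, cnt in zip(cands, locus_counts):
            for _ in range(cnt):
                if is_cs:
                    off = -2
                    length = int(rng.choice(params.cs_lengths))
                else:
                    off = int(rng.choice((0, 1, 2), p=params.offset_probs))
                    length = int(rng.choice(params.mature_lengths, p=params.mature_length_probs))
                seq, start, end = locus_read(loc, off, length)
                emit(seq, cls, loc.locus_id, loc.chrom, start, end, loc.strand,
                     n_hits(seq), 0, off)

    # ---- contaminants: one defining rule violation each -------------------
    n_mm = totals["contaminant:multimapper"]
    if n_mm and not decoy_loci:
        raise ValueError("multimapper contaminants need decoy type I loci in the genome")
    for i in range(n_mm):
        loc = decoy_loci[i % len(decoy_loci)]
        length = 24 if is_cs else 21
        seq, start, end = locus_read(loc, base_off, length)
        mult = n_hits(seq)
        emit(seq, "contaminant:multimapper", loc.locus_id, loc.chrom, start, end,
             loc.strand, mult, 0, base_off)

    for i in range(totals["contaminant:antisense"]):
        loc = pool["I"][int(rng.integers(len(pool["I"])))]
        length = 24 if is_cs else 21
        sense_seq, start, end = locus_read(loc, base_off, length)
        seq = revcomp(sense_seq)
        strand = "-" if loc.strand == "+" else "+"
        emit(seq, "contaminant:antisense", loc.locus_id, loc.chrom, start, end,
             strand, n_hits(seq), 0, base_off)

    for i in range(totals["contaminant:mismatch"]):
        for _ in range(50):
            loc = pool["I"][int(rng.integers(len(pool["I"])))]
            length = 24 if is_cs else 21
            seq, start, end = locus_read(loc, base_off, length)
            j = int(rng.integers(5, length - 3))
            alt = rng.choice([b for b in "ACGT" if b != seq[j]])
            mutated = seq[:j] + alt + seq[j + 1 :]
            if n_hits(mutated) == 0:  # must not map perfectly anywhere
                emit(mutated, "contaminant:mismatch", loc.locus_id, loc.chrom, start,
                     end, loc.strand, 1, 1, base_off)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not construct a mismatch contaminant")

    for i in range(totals["contaminant:off_length"]):
        length = 44 if i % 2 == 0 else 14
        for _ in range(50):
            loc = pool["I"][int(rng.integers(len(pool["I"])))]
            seq, start, end = locus_read(loc, base_off, length)
            if n_hits(seq) == 1:
                emit(seq, "contaminant:off_length", loc.locus_id, loc.chrom, start,
                     end, loc.strand, 1, 0, base_off)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not construct a unique off-length contaminant")

    # ---- background (degradation-like) reads ------------------------------
    chroms = list(genome.chromosomes)
    lens = {c: len(s) for c, s in genome.chromosomes.items()}
    n_bg = totals["background"]
    made = 0
    while made < n_bg:
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(18, 31))
        start = int(rng.integers(0, lens[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        five = start if strand == "+" else start + length - 1
        if (chrom, strand, five) in forbidden:
            continue
        seq = genome.sequence(chrom, start, start + length, strand)
        emit(seq, "background", "", chrom, start, start + length, strand,
             n_hits(seq), 0, 0)
        made += 1

    truth = pd.DataFrame(truth_rows)
    return SmallRNALibrary(condition, protocol, reads, truth, alignments)


# ---------------------------------------------------------------------------
# narrowPeak fixtures
# ---------------------------------------------------------------------------

@dataclass
class PeakFixtureSpec:
    """Peak-set fixture: totals, in-cluster share and score/significance ranges."""

    name: str = "custom"
    total: int = 100
    in_cluster: int = 50
    score_range: tuple[float, float] = (200.0, 1500.0)
    significance_range: tuple[float, float] = (3.0, 50.0)
    width_range: tuple[int, int] = (50, 200)
    seed: int = 7

    def validate(self) -> None:
        if self.in_cluster > self.total:
            raise ValueError("in_cluster exceeds the peak total")
        if self.width_range[0] < 1 or self.width_range[0] > self.width_range[1]:
            raise ValueError("invalid width range")


def prde1_peakset_default(seed: int = 7) -> PeakFixtureSpec:
    """710 peaks, 642 with both ends inside the piRNA cluster intervals."""
    return PeakFixtureSpec("prde1_peakset_default", total=710, in_cluster=642,
                           score_range=(500.0, 2500.0), seed=seed)


def attf6_peakset_default(seed: int = 8) -> PeakFixtureSpec:
    """735 peaks, 244 in-cluster."""
    return PeakFixtureSpec("attf6_peakset_default", total=735, in_cluster=244,
                           score_range=(200.0, 1500.0), seed=seed)


def simulate_peak_fixture(genome: GenomeModel, spec: PeakFixtureSpec,
                          seed: int | None = None):
    """narrowPeak fixture with exactly ``spec.in_cluster`` in-cluster peaks.

    In-cluster peaks have both start and end inside a cluster interval;
    the rest are placed entirely outside every cluster.
    """
    from .chip import Peak

    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    clusters = genome.clusters
    if not clusters:
        raise ValueError("genome defines no cluster intervals")
    min_w = spec.width_range[0]
    capacity = sum((c.end - c.start) // min_w for c in clusters)
    if spec.in_cluster > capacity:
        raise ValueError(
            f"in_cluster={spec.in_cluster} exceeds cluster capacity {capacity} "
            f"at minimum peak width {min_w}"
        )

    # complement of the clusters, for out-of-cluster placement
    outside: list[tuple[str, int, int]] = []
    for chrom, seq in genome.chromosomes.items():
        pos, length = 0, len(seq)
        for c in sorted([c for c in clusters if c.chrom == chrom], key=lambda c: c.start):
            if c.start > pos:
                outside.append((chrom, pos, c.start))
            pos = c.end
        if length > pos:
            outside.append((chrom, pos, length))

    def draw(regions, widths_src) -> tuple[str, int, int]:
        w = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
        usable = [r for r in regions if r[2] - r[1] > w]
        sizes = np.array([r[2] - r[1] for r in usable], dtype=float)
        chrom, lo, hi = usable[int(rng.choice(len(usable), p=sizes / sizes.sum()))]
        s = int(rng.integers(lo, hi - w))
        return chrom, s, s + w

    peaks = []
    cluster_regions = [(c.chrom, c.start, c.end) for c in clusters]
    for i in range(spec.total):
        if i < spec.in_cluster:
            chrom, s, e = draw(cluster_regions, None)
        else:
            chrom, s, e = draw(outside, None)
        score = float(rng.uniform(*spec.score_range))
        sig = float(rng.uniform(*spec.significance_range))
        summit = int(rng.integers(0, e - s))
        peaks.append(
            Peak(chrom, s, e, f"{spec.name}_peak{i + 1:04d}", score, ".",
                 signal=score / 10.0, p_value=sig + 1.0, q_value=sig, summit=summit)
        )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.name))
    return peaks


# ---------------------------------------------------------------------------
# spectral-count tables
# ---------------------------------------------------------------------------

@dataclass
class SpectralCountParams:
    n_proteins: int = 600
    n_enriched: int = 54
    replicates: int = 3  # per condition; >=2 so the t-test is defined
    effect_size: float = 30.0
    enriched_control_mean: float = 0.5
    n_zero_control: int = 10  # enriched proteins absent from controls (pseudocount cases)
    base_mean_log: float = 0.8
    base_sd_log: float = 0.7
    depth_factors: tuple[float, ...] = (1.0, 1.3, 0.8, 1.1, 0.95, 1.25)
    seed: int = 0


@dataclass
class SpectralCountSim:
    table: pd.DataFrame            # proteins x samples, raw integer counts
    condition_map: dict[str, str]  # sample -> {tagged, control}
    enriched: set[str]             # ground-truth enriched protein ids


def simulate_spectral_counts(params: SpectralCountParams | None = None,
                             seed: int | None = None) -> SpectralCountSim:
    """Spectral-count table with a designated enriched set.

    Enriched proteins get a tagged-condition mean ``effect_size`` times their
    control mean (Poisson counts); everything else is drawn identically in
    both conditions.  Per-sample depth factors vary the column totals so
    total-count normalization has something to undo.
    """
    params = params or SpectralCountParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n, r = params.n_proteins, params.replicates
    if params.n_enriched > n:
        raise ValueError("n_enriched exceeds n_proteins")
    ids = [f"prot{i + 1:04d}" for i in range(n)]
    enriched_idx = rng.choice(n, size=params.n_enriched, replace=False)
    enriched = {ids[i] for i in enriched_idx}

    base = rng.lognormal(params.base_mean_log, params.base_sd_log, size=n)
    ctrl_mean = base.copy()
    tag_mean = base.copy()
    for j, i in enumerate(sorted(enriched_idx)):
        cm = 0.0 if j < params.n_zero_control else params.enriched_control_mean
        ctrl_mean[i] = cm
        tag_mean[i] = params.enriched_control_mean * params.effect_size

    samples, cond_map, cols = [], {}, {}
    for k in range(r):
        s = f"tagged_{k + 1}"
        d = params.depth_factors[k % len(params.depth_factors)]
        cols[s] = rng.poisson(tag_mean * d)
        cond_map[s] = "tagged"
        samples.append(s)
    for k in range(r):
        s = f"control_{k + 1}"
        d = params.depth_factors[(k + r) % len(params.depth_factors)]
        cols[s] = rng.poisson(ctrl_mean * d)
        cond_map[s] = "control"
        samples.append(s)
    table = pd.DataFrame(cols, index=pd.Index(ids, name="protein"))
    return SpectralCountSim(table, cond_map, enriched)


def simulate_null_spectral_counts(n_proteins: int = 1000, replicates: int = 3,
                                  mean: float = 100.0, seed: int = 0) -> SpectralCountSim:
    """Null table: both conditions drawn from the same Poisson distribution."""
    rng = np.random.default_rng(seed)
    ids = [f"prot{i + 1:04d}" for i in range(n_proteins)]
    cols, cond_map = {}, {}
    for cond in ("tagged", "control"):
        for k in range(replicates):
            s = f"{cond}_{k + 1}"
            cols[s] = rng.poisson(mean, size=n_proteins)
            cond_map[s] = cond
    return SpectralCountSim(pd.DataFrame(cols, index=pd.Index(ids, name="protein")),
                            cond_map, set())


# ---------------------------------------------------------------------------
# mRNA count matrices
# ---------------------------------------------------------------------------

@dataclass
class MRNACountSim:
    matrix: pd.DataFrame           # genes x samples, raw integer counts
    condition_map: dict[str, str]  # sample -> {control, depleted}
    groups: pd.DataFrame           # gene, group in {bound, unbound}, germline flag, true_fc


def simulate_mrna_counts(genome: GenomeModel, params: ScenarioParams,
                         seed: int | None = None) -> MRNACountSim:
    """Overdispersed (gamma-Poisson, fixed dispersion) mRNA count matrix.

    Bound genes are depleted by ``bound_gene_fc``, germline-flagged genes by
    ``germline_fc``; the two sets are disjoint so each group median is
    independently recoverable.  Gene ids reuse the genome's protein-coding
    genes first and continue with synthetic ids up to ``n_genes``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pc = [g.name for g in genome.genes if g.gene_class == "protein_coding"]
    ids = pc + [f"gene{i + 1:05d}" for i in range(max(0, params.n_genes - len(pc)))]
    ids = ids[: params.n_genes]
    n = len(ids)
    if params.n_bound + params.n_germline > n:
        raise ValueError("bound + germline sets exceed the gene universe")

    perm = rng.permutation(n)
    bound = {ids[i] for i in perm[: params.n_bound]}
    germline = {ids[i] for i in perm[params.n_bound : params.n_bound + params.n_germline]}

    mu = rng.lognormal(params.mrna_mean_log, params.mrna_sd_log, size=n)
    fc = np.ones(n)
    for i, g in enumerate(ids):
        if g in bound:
            fc[i] = params.bound_gene_fc
        elif g in germline:
            fc[i] = params.germline_fc

    r = params.mrna_replicates
    depth = {"control": (1.0, 1.15), "depleted": (0.9, 1.05)}
    cols, cond_map = {}, {}
    shape = 1.0 / params.dispersion
    for cond in ("control", "depleted"):
        mean = mu if cond == "control" else mu / fc
        for k in range(r):
            s = f"{cond}_{k + 1}"
            d = depth[cond][k % len(depth[cond])]
            lam = rng.gamma(shape, mean * params.dispersion * d)
            cols[s] = rng.poisson(lam)
            cond_map[s] = cond
    matrix = pd.DataFrame(cols, index=pd.Index(ids, name="gene"))
    groups = pd.DataFrame(
        {
            "gene": ids,
            "group": ["bound" if g in bound else "unbound" for g in ids],
            "germline": [g in germline for g in ids],
            "true_fc": fc,
        }
    )
    return MRNACountSim(matrix, cond_map, groups)
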