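"""Coverage ratios, chromosome summaries, peak filtering/annotation/overlap,
hypergeometric tests, summit context, metagene and motif context."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from piclusterkit.genome import (
    ClusterInterval,
    GeneAnnotation,
    GenomeModel,
    PiRNALocus,
    revcomp,
)
from piclusterkit import chip
from piclusterkit.chip import (
    CoverageTrack,
    Peak,
    annotate_peaks,
    chromosome_summary,
    cluster_membership,
    coverage_ratio,
    filter_peaks,
    hypergeom_overlap,
    metagene_profile,
    motif_context,
    peak_overlap,
    summit_context,
)


def track(bin_size=5, **chroms):
    return CoverageTrack(bin_size, {c: np.asarray(v, dtype=float) for c, v in chroms.items()})


# ---------------------------------------------------------------------------
# coverage ratio + summary
# ---------------------------------------------------------------------------

def test_ratio_identity_and_example():
    t = track(c1=[3, 1, 0, 7])
    r = coverage_ratio(t, t)
    assert np.allclose(r.values["c1"], 1.0)
    r2 = coverage_ratio(track(c1=[3.0]), track(c1=[1.0]))
    assert r2.values["c1"][0] == 2.0  # (3+1)/(1+1)


def test_ratio_matches_brute_force_and_monotone():
    rng = np.random.default_rng(0)
    e = rng.uniform(0, 50, 200)
    c = rng.uniform(0, 50, 200)
    r = coverage_ratio(track(c1=e), track(c1=c))
    assert np.allclose(r.values["c1"], (e + 1) / (c + 1))
    bumped = e.copy()
    bumped[17] += 5
    r2 = coverage_ratio(track(c1=bumped), track(c1=c))
    assert r2.values["c1"][17] > r.values["c1"][17]


def test_ratio_chromosome_mismatch_lists_differences():
    with pytest.raises(ValueError, match="c2"):
        coverage_ratio(track(c1=[1.0], c2=[1.0]), track(c1=[1.0]))


def test_rebin_mean_and_expand():
    t = track(bin_size=5, c1=[1, 3, 5, 7])
    up = t.rebin(10)
    assert np.allclose(up.values["c1"], [2, 6])
    down = up.rebin(5)
    assert np.allclose(down.values["c1"], [2, 2, 6, 6])


def test_chromosome_summary_cases():
    # all below the floor: explicit empty marker
    empty = chromosome_summary([track(bin_size=1000, c1=[1.0, 1.1])])
    assert math.isnan(empty.loc["c1", "mean_score"])
    # uniform 2.0 survives everywhere
    uni = chromosome_summary([track(bin_size=1000, c1=[2.0] * 10)])
    assert uni.loc["c1", "mean_score"] == 2.0


def test_chromosome_summary_matches_spreadsheet_oracle():
    rng = np.random.default_rng(1)
    reps = [rng.uniform(0.5, 3.0, 40) for _ in range(2)]
    got = chromosome_summary([track(bin_size=1000, c1=v) for v in reps])
    expected = np.mean([v[v >= 1.2].mean() for v in reps])
    assert got.loc["c1", "mean_score"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# peak filtering / membership
# ---------------------------------------------------------------------------

def mk_peak(start, end, chrom="c1", score=500.0, q=5.0, name=None, summit=None):
    return Peak(chrom, start, end, name or f"p{start}", score, ".",
                score / 10, q + 1, q, summit if summit is not None else (end - start) // 2)


def test_filter_peaks_inclusive_boundaries():
    peaks = [mk_peak(0, 100, score=200, q=3.0), mk_peak(200, 300, score=199, q=50),
             mk_peak(400, 500, score=1000, q=2.99)]
    kept = filter_peaks(peaks, *chip.PEAK_FILTER_PRESETS["attf6"])
    assert [p.start for p in kept] == [0]
    kept_prde1 = filter_peaks([mk_peak(0, 9, score=500, q=3)],
                              *chip.PEAK_FILTER_PRESETS["prde1"])
    assert len(kept_prde1) == 1


def test_filter_peaks_planted_labels(genome0):
    from piclusterkit import simulate

    rng = np.random.default_rng(5)
    peaks, labels = [], []
    for i in range(200):
        score = float(rng.uniform(0, 1000))
        q = float(rng.uniform(0, 10))
        peaks.append(mk_peak(i * 10, i * 10 + 5, score=score, q=q, name=f"x{i}"))
        labels.append(score >= 200 and q >= 3)
    kept = {p.name for p in filter_peaks(peaks, 200, 3)}
    assert kept == {p.name for p, keep in zip(peaks, labels) if keep}


def test_cluster_membership_exact_fraction_and_straddle():
    clusters = [ClusterInterval("cl", "c1", 1000, 2000)]
    inside = [mk_peak(1000, 1500), mk_peak(1500, 2000)]
    straddle = [mk_peak(900, 1100), mk_peak(1900, 2100)]
    flags, pct = cluster_membership(inside + straddle, clusters)
    assert flags == [True, True, False, False]
    assert pct == 50.0
    # the published fractions: 642/710 -> 90.4, 244/735 -> 33.2
    assert round(100 * 642 / 710, 1) == 90.4
    assert round(100 * 244 / 735, 1) == 33.2


def test_cluster_membership_matches_brute_force(genome0):
    rng = np.random.default_rng(7)
    peaks = []
    for _ in range(300):
        chrom = "chrIV" if rng.random() < 0.7 else "chrV"
        s = int(rng.integers(0, 199_000))
        peaks.append(mk_peak(s, s + int(rng.integers(20, 900)), chrom=chrom))
    flags, _ = cluster_membership(peaks, genome0.clusters)
    for p, f in zip(peaks, flags):
        expect = any(
            p.chrom == c.chrom and p.start >= c.start and p.end <= c.end
            for c in genome0.clusters
        )
        assert f == expect


# ---------------------------------------------------------------------------
# annotation priority
# ---------------------------------------------------------------------------

ANN = [
    GeneAnnotation("c1", 1000, 1150, "+", "sn1", "snRNA"),
    GeneAnnotation("c1", 1050, 1170, "+", "sno1", "snoRNA"),
    GeneAnnotation("c1", 980, 1300, "+", "nc1", "ncRNA"),
    GeneAnnotation("c1", 1100, 2600, "+", "pc1", "protein_coding"),
    GeneAnnotation("c1", 900, 1700, "+", "ps1", "pseudogene"),
    GeneAnnotation("c1", 5000, 5400, "-", "his1", "protein_coding", histone=True),
]


def test_annotation_priority_order():
    # peak overlapping snRNA promoter [900,1000) and everything else
    classes, counts = annotate_peaks([mk_peak(950, 1010)], ANN)
    assert classes[0].assigned_class == "snRNA_promoter"
    assert classes[0].gene_id == "sn1"
    # intergenic desert peak
    classes, _ = annotate_peaks([mk_peak(9000, 9100)], ANN)
    assert classes[0].assigned_class == "unassigned"


def test_annotation_histone_sublabel_and_minus_promoter():
    # his1 is minus strand: promoter is [5400, 5900)
    classes, counts = annotate_peaks([mk_peak(5600, 5700)], ANN)
    assert classes[0].assigned_class == "protein_coding_promoter"
    assert counts["histone_promoter"] == 1


def test_annotation_removing_top_feature_demotes_never_promotes():
    peak = mk_peak(950, 1010)
    order = []
    ann = list(ANN)
    while True:
        classes, _ = annotate_peaks([peak], ann)
        cls = classes[0].assigned_class
        order.append(cls)
        if cls == "unassigned":
            break
        ann = [g for g in ann if g.name != classes[0].gene_id]
    ranks = [chip.CLASS_PRIORITY.index(c) for c in order[:-1]]
    assert ranks == sorted(ranks) and len(set(ranks)) == len(ranks)


def test_annotation_matches_brute_force_oracle(genome0):
    rng = np.random.default_rng(11)
    peaks = []
    for i in range(150):
        chrom = "chrV" if rng.random() < 0.5 else "chrIV"
        s = int(rng.integers(0, 198_000))
        peaks.append(mk_peak(s, s + int(rng.integers(30, 1500)), chrom=chrom, name=f"b{i}"))
    classes, _ = annotate_peaks(peaks, genome0.genes)
    got = {c.peak_id: c.assigned_class for c in classes}

    # independent enumerate-and-rank oracle
    def promoter(g, n):
        return (max(0, g.start - n), g.start) if g.strand == "+" else (g.end, g.end + n)

    for p in peaks:
        candidates = []
        for g in genome0.genes:
            if g.chrom != p.chrom:
                continue
            if g.gene_class == "snRNA":
                iv, cls = promoter(g, 100), "snRNA_promoter"
            elif g.gene_class == "snoRNA":
                iv, cls = promoter(g, 100), "snoRNA_promoter"
            elif g.gene_class == "ncRNA":
                iv, cls = (g.start, g.end), "ncRNA"
            elif g.gene_class == "protein_coding":
                iv, cls = promoter(g, 500), "protein_coding_promoter"
            elif g.gene_class == "pseudogene":
                iv, cls = (g.start, g.end), "pseudogene"
            else:
                continue
            if p.start < iv[1] and iv[0] < p.end:
                candidates.append(cls)
        expect = min(candidates, key=chip.CLASS_PRIORITY.index) if candidates else "unassigned"
        assert got[p.name] == expect


def test_annotation_order_invariance_and_strand_error():
    peaks = [mk_peak(950, 1010), mk_peak(5600, 5700), mk_peak(9000, 9100)]
    a, _ = annotate_peaks(peaks, ANN)
    b, _ = annotate_peaks(list(reversed(peaks)), ANN)
    assert {c.peak_id: c.assigned_class for c in a} == {c.peak_id: c.assigned_class for c in b}
    bad = [GeneAnnotation("c1", 10, 50, ".", "x", "snRNA")]
    with pytest.raises(ValueError, match="strand"):
        annotate_peaks([mk_peak(0, 20)], bad)


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

def _enumerated_tail(k, K, n, N):
    """P(X >= k) by exhaustive enumeration over C(N, n) draws."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


def test_hypergeom_trivial_and_single_term():
    assert hypergeom_overlap(0, 4, 3, 10) == 1.0
    # k = min(K, n): single-term closed form C(K,k)C(N-K,n-k)/C(N,n)
    N, K, n = 9, 4, 3
    expect = (math.comb(K, 3) * math.comb(N - K, 0)) / math.comb(N, n)
    assert hypergeom_overlap(3, K, n, N) == pytest.approx(expect)


def test_hypergeom_equals_enumeration_all_small_cases():
    """Exhaustive agreement for every (N <= 12, K, n, k)."""
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_overlap(k, K, n, N) == pytest.approx(
                        _enumerated_tail(k, K, n, N), abs=1e-12), (k, K, n, N)


def test_hypergeom_validates_inputs():
    with pytest.raises(ValueError):
        hypergeom_overlap(5, 4, 3, 10)
    with pytest.raises(ValueError):
        hypergeom_overlap(1, 11, 3, 10)


# ---------------------------------------------------------------------------
# peak overlap
# ---------------------------------------------------------------------------

def test_peak_overlap_examples():
    a = [mk_peak(100, 200, name="a")]
    assert peak_overlap(a, [mk_peak(100, 200, name="b")]).pairs == [("a", "b")]
    # 100 bp vs 1000 bp sharing 60 bp: shorter peak's fraction 60% passes
    a = [mk_peak(940, 1040, name="a")]
    b = [mk_peak(980, 1980, name="b")]
    assert peak_overlap(a, b, 0.5).pairs == [("a", "b")]
    assert peak_overlap(a, b, 0.5, reciprocal=True).pairs == []


def test_peak_overlap_matches_all_pairs_brute_force():
    rng = np.random.default_rng(13)

    def random_set(n, tag):
        out = []
        for i in range(n):
            chrom = "c1" if rng.random() < 0.8 else "c2"
            s = int(rng.integers(0, 5000))
            out.append(mk_peak(s, s + int(rng.integers(10, 400)), chrom=chrom,
                               name=f"{tag}{i}"))
        return out

    A, B = random_set(60, "a"), random_set(60, "b")
    for reciprocal in (False, True):
        got = set(peak_overlap(A, B, 0.5, reciprocal=reciprocal).pairs)
        expect = set()
        for a in A:
            for b in B:
                if a.chrom != b.chrom:
                    continue
                inter = min(a.end, b.end) - max(a.start, b.start)
                if inter <= 0:
                    continue
                fa, fb = inter / (a.end - a.start), inter / (b.end - b.start)
                ok = (fa >= 0.5 and fb >= 0.5) if reciprocal else (fa >= 0.5 or fb >= 0.5)
                if ok:
                    expect.add((a.name, b.name))
        assert got == expect


def test_peak_overlap_venn_counts():
    A = [mk_peak(0, 100, name="a1"), mk_peak(500, 600, name="a2")]
    B = [mk_peak(0, 100, name="b1"), mk_peak(900, 950, name="b2")]
    res = peak_overlap(A, B)
    assert (res.n_a_shared, res.n_a_unique, res.n_b_shared, res.n_b_unique) == (1, 1, 1, 1)


# ---------------------------------------------------------------------------
# summit context / metagene / motif context
# ---------------------------------------------------------------------------

def test_summit_context_window_and_truncation(genome0):
    p = mk_peak(1000, 1200, chrom="chrIV", summit=50)  # summit at 1050
    (header, seq, truncated), = summit_context([p], genome0)
    assert not truncated and len(seq) == 201
    assert seq == genome0.chromosomes["chrIV"][950:1151]
    edge = mk_peak(0, 40, chrom="chrIV", summit=10)
    (_, seq2, trunc2), = summit_context([edge], genome0)
    assert trunc2 and seq2 == genome0.chromosomes["chrIV"][0:111]


def test_metagene_profile_cases():
    t = track(bin_size=10, c1=[2.0] * 100)
    mat, mean = metagene_profile(t, [("c1", 500, "+"), ("c1", 300, "-")], flank=50)
    assert mat.shape == (2, 10)
    assert np.allclose(mean, 2.0)  # uniform track -> flat profile

    vals = np.arange(100, dtype=float)
    t2 = track(bin_size=10, c1=vals)
    mat1, mean1 = metagene_profile(t2, [("c1", 500, "+")], flank=50)
    assert np.allclose(mean1, vals[45:55])  # single anchor = raw window
    mat2, _ = metagene_profile(t2, [("c1", 500, "-")], flank=50)
    assert np.allclose(mat2[0], vals[45:55][::-1])  # minus strand reversed


def test_metagene_matches_brute_force(genome0):
    rng = np.random.default_rng(17)
    vals = rng.uniform(0, 5, 2000)
    t = track(bin_size=100, c1=vals)
    anchors = [("c1", int(rng.integers(2000, 198_000)),
                "+" if rng.random() < 0.5 else "-") for _ in range(40)]
    mat, mean = metagene_profile(t, anchors, flank=1000)
    for i, (chrom, pos, strand) in enumerate(anchors):
        b = pos // 100
        window = vals[b - 10 : b + 10]
        if strand == "-":
            window = window[::-1]
        assert np.allclose(mat[i], window)
    assert np.allclose(mean, np.nanmean(mat, axis=0))


def test_motif_context_finds_one_ruby_per_typeI_locus(genome0):
    loci = [l for l in genome0.pirna_loci() if l.pirna_type == "I"]
    hits, profile = motif_context(genome0, loci, flank=100)
    off = genome0.metadata["ruby_offset"]
    per_locus = hits.groupby("locus")
    assert len(per_locus) == len(loci)
    for lid, sub in per_locus:
        assert len(sub) == 1
        assert sub.iloc[0]["offset"] == -(off + 8)
        assert sub.iloc[0]["orientation"] == "sense"
    # AT-rich flanks show up in the positional profile around the motif
    flank_cols = profile[100 - off - 8 - 10 : 100 - off - 8]
    assert flank_cols.mean() > 0.7


def test_motif_context_gc_only_and_revcomp_symmetry():
    gc = GenomeModel({"c1": "GC" * 300}, [], [], {})
    loci = [PiRNALocus("L", "c1", 300, "+", "I")]
    hits, profile = motif_context(gc, loci, flank=50)
    assert hits.empty
    assert np.allclose(profile, 0.0)

    rng = np.random.default_rng(19)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    seq = seq[:180] + "CTGTTTCA" + seq[188:]
    fwd = GenomeModel({"c1": seq}, [], [], {})
    rev = GenomeModel({"c1": revcomp(seq)}, [], [], {})
    n = len(seq)
    h1, _ = motif_context(fwd, [PiRNALocus("L", "c1", 200, "+", "I")], flank=60)
    h2, _ = motif_context(rev, [PiRNALocus("L", "c1", n - 201, "-", "I")], flank=60)
    assert len(h1) == len(h2) >= 1
    assert sorted(h1["offset"]) == sorted(h2["offset"])
    assert list(h1["orientation"]) == list(h2["orientation"])
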