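import pytest

from eretarget.genome_io import GeneModel, Peak
from eretarget.peak_annotate import (
    CATEGORIES,
    annotate_peak,
    annotate_peaks,
    localization_summary,
)

GENOME_LEN = 1_000_000


def make_gene(gene_id="g1", strand="+", start=500_000, end=503_000, tss=None):
    if tss is None:
        tss = [start] if strand == "+" else [end - 1]
    return GeneModel(gene_id, "chr1", strand, tss, start, end, "protein_coding")


def peak_at(summit, pid="p"):
    return Peak(pid, "chr1", summit - 100, summit + 101, summit=summit)


@pytest.mark.parametrize(
    "offset,category",
    [
        (-1, "upstream_lt2kb"),
        (-1_999, "upstream_lt2kb"),
        (-2_000, "upstream_2_10kb"),
        (-9_999, "upstream_2_10kb"),
        (-10_000, "upstream_10_50kb"),
        (-49_999, "upstream_10_50kb"),
        (-50_000, "distal"),
        (500, "gene_body"),
        (2_999, "gene_body"),
    ],
)
def test_plus_strand_categories(offset, category):
    gene = make_gene(strand="+")
    a = annotate_peak(peak_at(500_000 + offset), [gene])
    assert a.category == category


@pytest.mark.parametrize(
    "offset,category",
    [
        (1, "upstream_lt2kb"),
        (2_000, "upstream_2_10kb"),
        (49_999, "upstream_10_50kb"),
        (50_000, "distal"),
        (-500, "gene_body"),
    ],
)
def test_minus_strand_categories(offset, category):
    gene = make_gene(strand="-")  # TSS at end - 1 = 502_999
    a = annotate_peak(peak_at(502_999 + offset), [gene])
    assert a.category == category


def test_downstream_category_both_strands():
    plus = make_gene(strand="+")  # body [500000, 503000), 3' end 502999
    a = annotate_peak(peak_at(503_500), [plus])
    assert a.category == "downstream"
    # gap is measured from the gene's last base (502_999), inclusive at 50 kb
    a = annotate_peak(peak_at(502_999 + 50_000), [plus])
    assert a.category == "downstream"
    a = annotate_peak(peak_at(502_999 + 50_001), [plus])
    assert a.category == "distal"
    minus = make_gene(strand="-")  # 3' end at start
    a = annotate_peak(peak_at(499_000), [minus])
    assert a.category == "downstream"


def test_gene_body_takes_precedence_over_neighbor_promoter():
    inside = make_gene("host", "+", 500_000, 503_000)
    neighbor = make_gene("near", "+", 503_500, 506_000)
    a = annotate_peak(peak_at(502_900), [inside, neighbor])
    # 600 bp upstream of `near`, but inside `host`: body wins
    assert a.category == "gene_body"
    assert a.nearest_gene_id == "host"


def test_signed_distance_sign_convention():
    gene = make_gene(strand="+")
    up = annotate_peak(peak_at(499_000), [gene])
    assert up.signed_distance == -1_000
    down = annotate_peak(peak_at(500_400), [gene])
    assert down.signed_distance == 400


def test_multi_tss_uses_nearest():
    gene = make_gene(tss=[500_000, 502_000])
    a = annotate_peak(peak_at(501_900), [gene])
    assert a.signed_distance == -100  # relative to the second TSS


def test_gene_free_chromosome_is_distal():
    gene = make_gene()
    peak = Peak("p", "chr2", 100, 301)
    a = annotate_peak(peak, [gene])
    assert a.category == "distal"
    assert a.nearest_gene_id is None


def test_mirror_invariance():
    """Mirroring coordinates and flipping strands preserves every category."""
    genes = [
        make_gene("g1", "+", 100_000, 103_000),
        make_gene("g2", "-", 200_000, 202_500),
        make_gene("g3", "+", 240_000, 241_000),
    ]
    peaks = [peak_at(s, f"p{i}") for i, s in enumerate(
        [99_000, 95_000, 60_000, 101_500, 104_000, 203_400, 199_000, 500_000]
    )]
    fwd = {a.peak_id: a.category for a in annotate_peaks(peaks, genes)}

    def mirror_gene(g):
        return GeneModel(
            g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
            sorted(GENOME_LEN - 1 - t for t in g.tss_list),
            GENOME_LEN - g.end, GENOME_LEN - g.start, g.biotype,
        )

    def mirror_peak(p):
        return Peak(p.peak_id, p.chrom, GENOME_LEN - p.end, GENOME_LEN - p.start,
                    summit=GENOME_LEN - 1 - p.summit)

    mirrored = {
        a.peak_id: a.category
        for a in annotate_peaks([mirror_peak(p) for p in peaks],
                                [mirror_gene(g) for g in genes])
    }
    assert mirrored == fwd


def test_localization_summary_fractions():
    genes = [make_gene()]
    peaks = [peak_at(s, f"p{i}") for i, s in enumerate([499_500, 501_000, 100_000, 120_000])]
    summary = localization_summary(annotate_peaks(peaks, genes))
    assert set(summary) == set(CATEGORIES)
    assert sum(frac for _, frac in summary.values()) == pytest.approx(1.0)
    assert summary["gene_body"] == (1, 0.25)
    assert summary["distal"] == (2, 0.5)


def test_localization_summary_empty_errors():
    with pytest.raises(ValueError):
        localization_summary([])
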