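"""Genomic localization of binding sites relative to gene TSSs.

Distances are measured from the peak summit to the nearest TSS over all
isoforms of all genes, signed in the gene's orientation: negative means the
summit lies upstream (5') of the TSS. Categories partition the peaks with
precedence gene body > upstream bins (<2 kb, 2-10 kb, 10-50 kb) >
downstream (within 50 kb past the gene 3' end) > distal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genome_io import GeneModel, Peak

CATEGORIES = (
    "upstream_lt2kb",
    "upstream_2_10kb",
    "upstream_10_50kb",
    "gene_body",
    "downstream",
    "distal",
)

DOWNSTREAM_LIMIT = 50_000


@dataclass
class PeakAnnotation:
    peak_id: str
    nearest_gene_id: str | None
    signed_distance: int | None  # negative = upstream of the TSS, strand-aware
    category: str


class _ChromIndex:
    """Sorted TSS array plus gene bodies for one chromosome."""

    def __init__(self, genes: list[GeneModel]) -> None:
        entries = sorted(
            (tss, g.gene_id, g) for g in genes for tss in g.tss_list
        )
        self.tss = np.array([e[0] for e in entries], dtype=np.int64)
        self.entries = entries
        self.genes = genes

    def nearest_tss(self, pos: int) -> tuple[int, GeneModel]:
        i = int(np.searchsorted(self.tss, pos))
        candidates = []
        for j in (i - 1, i):
            if 0 <= j < len(self.entries):
                tss, gene_id, gene = self.entries[j]
                candidates.append((abs(pos - tss), gene_id, tss, gene))
        # equidistant TSSs break ties by lexicographic gene id
        _, _, tss, gene = min(candidates)
        return tss, gene

    def containing(self, pos: int) -> list[GeneModel]:
        return [g for g in self.genes if g.start <= pos < g.end]


def _signed_distance(summit: int, tss: int, strand: str) -> int:
    return summit - tss if strand == "+" else tss - summit


def build_gene_index(genes: list[GeneModel]) -> dict[str, _ChromIndex]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return {chrom: _ChromIndex(gs) for chrom, gs in by_chrom.items()}


def annotate_peak(
    peak: Peak,
    genes: list[GeneModel] | None = None,
    index: dict[str, _ChromIndex] | None = None,
) -> PeakAnnotation:
    """Assign one peak its localization category and signed TSS distance."""
    if index is None:
        if genes is None:
            raise ValueError("either genes or a prebuilt index is required")
        index = build_gene_index(genes)
    chrom_index = index.get(peak.chrom)
    if chrom_index is None or len(chrom_index.tss) == 0:
        return PeakAnnotation(peak.peak_id, None, None, "distal")
    summit = peak.summit

    inside = chrom_index.containing(summit)
    if inside:
        # body membership wins; among containing genes pick nearest TSS
        best = min(
            (min(abs(summit - t) for t in g.tss_list), g.gene_id, g)
            for g in inside
        )
        gene = best[2]
        tss = min(gene.tss_list, key=lambda t: (abs(summit - t), t))
        return PeakAnnotation(
            peak.peak_id,
            gene.gene_id,
            _signed_distance(summit, tss, gene.strand),
            "gene_body",
        )

    tss, gene = chrom_index.nearest_tss(summit)
    sd = _signed_distance(summit, tss, gene.strand)
    if sd < 0:
        d = -sd
        if d < 2_000:
            cat = "upstream_lt2kb"
        elif d < 10_000:
            cat = "upstream_2_10kb"
        elif d < 50_000:
            cat = "upstream_10_50kb"
        else:
            cat = "distal"
        return PeakAnnotation(peak.peak_id, gene.gene_id, sd, cat)

    # summit 3' of the TSS but outside every body: past the gene end
    if gene.strand == "+":
        gap = summit - (gene.end - 1)
    else:
        gap = gene.start - summit
    cat = "downstream" if 0 < gap <= DOWNSTREAM_LIMIT else "distal"
    return PeakAnnotation(peak.peak_id, gene.gene_id, sd, cat)


def annotate_peaks(peaks: list[Peak], genes: list[GeneModel]) -> list[PeakAnnotation]:
    index = build_gene_index(genes)
    return [annotate_peak(p, index=index) for p in peaks]


def localization_summary(
    annotations: list[PeakAnnotation],
) -> dict[str, tuple[int, float]]:
    """Category -> (count, fraction); fractions sum to 1 over all peaks."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    counts = Counter(a.category for a in annotations)
    total = len(annotations)
    return {cat: (counts.get(cat, 0), counts.get(cat, 0) / total) for cat in CATEGORIES}
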