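"""Differential-expression calling, direct-target identification, enrichment.

Estrogen-responsive genes are called from DE summary tables at the default
thresholds (mRNA/lncRNA: |log2FC| >= 1 and FDR <= 0.05; miRNA: linear fold
change >= 1.5 or <= 0.667 and FDR <= 0.05, inclusive boundaries as
printed). A responsive gene is a direct target when at least one
ERE-containing binding site has its summit strictly less than 50 kb
upstream (strand-aware) of any TSS of the gene. Over-representation uses
the hypergeometric upper tail with fold enrichment = GeneRatio / BgRatio
and Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ere_scan import SiteEREClassification
from .genome_io import GeneModel, Peak

logger = logging.getLogger(__name__)

MRNA_LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05
MIRNA_FC_UP = 1.5
MIRNA_FC_DOWN = 0.667
MAX_UPSTREAM = 50_000


@dataclass
class DERecord:
    """One gene's expression contrast.

    ``effect`` is log2 fold change for mRNA/lncRNA and linear fold change
    for miRNA (the convention of the respective sequencing pipelines).
    """

    gene_id: str
    biotype: str  # mRNA | lncRNA | miRNA
    effect: float
    fdr: float
    direction: str = "ns"


@dataclass
class DirectTargetCall:
    gene_id: str
    supporting_peaks: list[str]
    min_upstream_distance: int
    n_ere_in_support: int


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # DE genes in term
    n: int  # DE genes annotated
    K: int  # background genes in term
    N: int  # background genes annotated
    fold_enrichment: float
    p_value: float
    q_value: float = field(default=math.nan)


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a DE table TSV with columns gene_id, biotype, effect, fdr."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "biotype", "effect", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE table columns {sorted(missing)}")
    return [
        DERecord(r.gene_id, r.biotype, float(r.effect), float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def call_de(
    records: list[DERecord],
    mrna_lfc: float = MRNA_LFC_THRESHOLD,
    fdr: float = FDR_THRESHOLD,
    mirna_fc_up: float = MIRNA_FC_UP,
    mirna_fc_down: float = MIRNA_FC_DOWN,
) -> list[DERecord]:
    """Set each record's direction (up/down/ns) at the printed thresholds.

    All boundaries are inclusive; calling is idempotent and partitions the
    records into up, down and ns.
    """
    called = []
    for rec in records:
        if rec.biotype == "miRNA":
            if rec.effect <= 0:
                raise ValueError(
                    f"miRNA {rec.gene_id}: fold change must be positive, got {rec.effect}"
                )
            if rec.fdr <= fdr and rec.effect >= mirna_fc_up:
                direction = "up"
            elif rec.fdr <= fdr and rec.effect <= mirna_fc_down:
                direction = "down"
            else:
                direction = "ns"
        else:
            if rec.fdr <= fdr and rec.effect >= mrna_lfc:
                direction = "up"
            elif rec.fdr <= fdr and rec.effect <= -mrna_lfc:
                direction = "down"
            else:
                direction = "ns"
        called.append(replace(rec, direction=direction))
    return called


def responsive_genes(records: list[DERecord]) -> set[str]:
    return {r.gene_id for r in records if r.direction in {"up", "down"}}


def call_direct_targets(
    de_records: list[DERecord],
    peaks: list[Peak],
    site_classes: SiteEREClassification,
    genes: list[GeneModel],
    max_upstream: int = MAX_UPSTREAM,
    require_ere: bool = True,
) -> list[DirectTargetCall]:
    """Call estrogen-responsive genes with a qualifying binding site.

    A site qualifies when its summit lies strictly less than
    ``max_upstream`` bp upstream (strand-aware, distance >= 0) of any TSS of
    the gene and — by default — contains at least one ERE. Output is
    sorted by gene_id with all supporting peaks listed.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    responsive = responsive_genes(de_records)
    unknown = responsive - set(gene_by_id)
    if unknown:
        raise ValueError(f"DE genes missing from the annotation: {sorted(unknown)[:5]}")
    for p in peaks:
        if p.peak_id not in site_classes.per_peak:
            raise ValueError(f"peak {p.peak_id} missing from site classification")

    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        if not require_ere or site_classes.per_peak[p.peak_id] > 0:
            by_chrom.setdefault(p.chrom, []).append(p)

    calls = []
    for gene_id in sorted(responsive):
        gene = gene_by_id[gene_id]
        support: dict[str, int] = {}
        for p in by_chrom.get(gene.chrom, []):
            for tss in gene.tss_list:
                d = tss - p.summit if gene.strand == "+" else p.summit - tss
                if 0 <= d < max_upstream:
                    prev = support.get(p.peak_id)
                    if prev is None or d < prev:
                        support[p.peak_id] = d
        if support:
            calls.append(
                DirectTargetCall(
                    gene_id=gene_id,
                    supporting_peaks=sorted(support),
                    min_upstream_distance=min(support.values()),
                    n_ere_in_support=sum(
                        site_classes.per_peak[pid] for pid in support
                    ),
                )
            )
    return calls


def enrich(
    de_set: set[str],
    term_table: pd.DataFrame,
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``de_set`` in annotation terms.

    ``term_table`` has columns term_id and gene_id; the background universe
    defaults to all annotated genes. p = P(X >= k) for X hypergeometric
    (N population, K term genes, n DE genes drawn); fold enrichment is
    (k/n) / (K/N); q-values are Benjamini-Hochberg across terms.
    """
    required = {"term_id", "gene_id"}
    if required - set(term_table.columns):
        raise ValueError("term table needs columns term_id and gene_id")
    universe = universe or set(term_table["gene_id"])
    outside = de_set - universe
    if outside:
        raise ValueError(
            f"DE genes outside the annotation universe: {sorted(outside)[:5]}"
        )
    N = len(universe)
    de_in_universe = de_set & universe
    n = len(de_in_universe)
    results = []
    for term_id, grp in term_table.groupby("term_id", sort=True):
        term_genes = set(grp["gene_id"]) & universe
        K = len(term_genes)
        if K == 0:
            logger.warning("term %s has no genes in the universe; skipped", term_id)
            continue
        k = len(term_genes & de_in_universe)
        fe = (k / n) / (K / N) if n else math.nan
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(str(term_id), k, n, K, N, fe, p))
    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results
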