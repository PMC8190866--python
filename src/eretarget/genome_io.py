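"""Readers, writers and in-memory models for the genomic inputs of the pipeline.

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive GTF convention happens only at the file boundary. The
transcription start site (TSS) of a transcript is its 5'-most base: the
interval start on the + strand and ``end - 1`` on the - strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")


@dataclass
class GenomeSequence:
    """A genome as a mapping of sequence name to uppercase nucleotide string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence [start, end) of a chromosome (0-based half-open)."""
        return self.sequences[chrom][start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class GeneModel:
    """A gene anchored by its body span and the TSS of each transcript isoform.

    ``tss_list`` holds one 0-based position per distinct isoform start;
    duplicates between isoforms are collapsed. ``body`` is the half-open
    [start, end) union span of the gene.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_list: list[int]
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        for tss in self.tss_list:
            if not (self.start <= tss <= self.end):
                raise ValueError(
                    f"gene {self.gene_id}: TSS {tss} outside body [{self.start},{self.end})"
                )

    @property
    def three_prime_end(self) -> int:
        """Position of the 3'-most base of the gene body."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Peak:
    """A binding-site interval with a summit (midpoint when not given)."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int = field(default=-1)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.peak_id}: start must be < end")
        if self.summit < 0:
            self.summit = (self.start + self.end) // 2
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.peak_id}: summit outside interval")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a multi-record FASTA into a :class:`GenomeSequence`.

    Lowercase (soft-masked) bases are folded to uppercase. Duplicate record
    names and empty files are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name in FASTA: {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_gtf_attributes(feature: gffutils.Feature, key: str) -> str | None:
    values = feature.attributes.get(key)
    return values[0] if values else None


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file (gene/transcript/exon features).

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    The TSS of a + strand transcript is its start, of a - strand transcript
    its end - 1 (both 0-based); isoforms sharing a start collapse to one
    TSS entry.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        if g.end < g.start:
            raise ValueError(f"gene {g.id}: end < start in GTF")
        gene_id = _parse_gtf_attributes(g, "gene_id") or g.id
        genes[gene_id] = {
            "chrom": g.seqid,
            "strand": g.strand,
            "start": g.start - 1,
            "end": g.end,
            "biotype": _parse_gtf_attributes(g, "gene_biotype") or "protein_coding",
            "tss": set(),
        }
    for t in db.features_of_type("transcript"):
        if t.end < t.start:
            raise ValueError(f"transcript {t.id}: end < start in GTF")
        gene_id = _parse_gtf_attributes(t, "gene_id")
        if gene_id is None or gene_id not in genes:
            raise ValueError(f"transcript {t.id} has no parent gene feature")
        start0, end0 = t.start - 1, t.end
        tss = start0 if t.strand == "+" else end0 - 1
        genes[gene_id]["tss"].add(tss)
    models = []
    for gene_id, info in genes.items():
        tss_list = sorted(info.pop("tss")) or (
            [info["start"]] if info["strand"] == "+" else [info["end"] - 1]
        )
        models.append(GeneModel(gene_id=gene_id, tss_list=tss_list, **info))
    return models


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF2.2 (gene + one transcript per TSS, one exon)."""
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\teretarget\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, tss in enumerate(g.tss_list, start=1):
                tid = f"{g.gene_id}.t{i}"
                if g.strand == "+":
                    t_start, t_end = tss, g.end
                else:
                    t_start, t_end = g.start, tss + 1
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\teretarget\ttranscript\t{t_start + 1}\t{t_end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                fh.write(
                    f"{g.chrom}\teretarget\texon\t{t_start + 1}\t{t_end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )


def read_peaks(path: str | Path) -> list[Peak]:
    """Read peaks from BED3+ (0-based half-open). Column 4, if present, names the peak."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype=str)
    peaks = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(f"{path}, line {lineno}: start >= end ({start} >= {end})")
        name = row[3] if len(row) > 3 and isinstance(row[3], str) else f"peak_{lineno}"
        peaks.append(Peak(peak_id=name, chrom=chrom, start=start, end=end))
    return peaks


def write_peaks(peaks: list[Peak], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


def merge_overlapping(peaks: list[Peak]) -> list[Peak]:
    """Merge overlapping or abutting peaks per chromosome.

    The merged set partitions the covered bases ("unique binding sites");
    merged summits are interval midpoints. Output is sorted by
    (chrom, start) and the operation is idempotent.
    """
    merged: list[Peak] = []
    by_pos = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    for p in by_pos:
        if merged and merged[-1].chrom == p.chrom and p.start <= merged[-1].end:
            prev = merged[-1]
            new_end = max(prev.end, p.end)
            merged[-1] = Peak(
                peak_id=prev.peak_id,
                chrom=prev.chrom,
                start=prev.start,
                end=new_end,
                summit=(prev.start + new_end) // 2,
            )
        else:
            merged.append(
                Peak(
                    peak_id=p.peak_id,
                    chrom=p.chrom,
                    start=p.start,
                    end=p.end,
                    summit=(p.start + p.end) // 2,
                )
            )
    return merged
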