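"""Six-criterion lncRNA identification cascade for assembled transcripts.

A transcript is kept as a lncRNA iff (1) exon count >= 2, (2) length >= 200
bp, (3) longest predicted ORF < 300 bp (strict), (4) no Pfam hit, (5)
coding-noncoding index score < 0, and (6) coding potential calculator score
< 0. Classifier scores arrive as input columns; the ORF length is computed
here from the transcript sequence when one is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

STOP_CODONS = {"TAA", "TAG", "TGA"}
ORF_MAX = 300  # nt, strict upper bound, stop codon included

CRITERIA = (
    "exon_count_ge2",
    "length_ge200",
    "orf_lt300",
    "no_pfam_hit",
    "cnci_lt0",
    "cpc_lt0",
)


@dataclass
class TranscriptRecord:
    transcript_id: str
    exon_count: int
    length: int
    pfam_hit: bool
    cnci_score: float
    cpc_score: float
    sequence: str | None = None
    orf_length: int | None = None

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise ValueError(f"{self.transcript_id}: exon_count must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass
class FilterTrace:
    transcript_id: str
    criteria: dict[str, bool]
    passed: bool
    first_failed: str | None


def longest_orf(sequence: str) -> int:
    """Length in nt (stop codon included) of the longest forward-frame ORF.

    An ORF is an ATG-initiated, stop-terminated reading frame in any of the
    three forward frames; 0 when the sequence contains none. Assembled
    transcripts are already oriented, so reverse frames are not searched.
    """
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def evaluate_transcript(rec: TranscriptRecord) -> FilterTrace:
    if rec.orf_length is not None:
        orf = rec.orf_length
    elif rec.sequence is not None:
        orf = longest_orf(rec.sequence)
    else:
        raise ValueError(
            f"{rec.transcript_id}: missing field orf_length (no sequence to compute it from)"
        )
    criteria = {
        "exon_count_ge2": rec.exon_count >= 2,
        "length_ge200": rec.length >= 200,
        "orf_lt300": orf < ORF_MAX,
        "no_pfam_hit": not rec.pfam_hit,
        "cnci_lt0": rec.cnci_score < 0,
        "cpc_lt0": rec.cpc_score < 0,
    }
    passed = all(criteria.values())
    first_failed = next((c for c in CRITERIA if not criteria[c]), None)
    return FilterTrace(rec.transcript_id, criteria, passed, first_failed)


def filter_lncrna(
    records: list[TranscriptRecord],
) -> tuple[list[str], list[FilterTrace]]:
    """Apply the cascade; returns (passing transcript ids, per-record traces)."""
    traces = [evaluate_transcript(r) for r in records]
    passing = [t.transcript_id for t in traces if t.passed]
    return passing, traces


def read_transcript_table(
    path: str | Path, fasta: str | Path | None = None
) -> list[TranscriptRecord]:
    """Read the transcript feature TSV, optionally joining sequences from FASTA."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "exon_count", "length", "pfam_hit", "cnci_score", "cpc_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing transcript columns {sorted(missing)}")
    seqs: dict[str, str] = {}
    if fasta is not None:
        from Bio import SeqIO

        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta), "fasta")}
    records = []
    for r in df.itertuples(index=False):
        records.append(
            TranscriptRecord(
                transcript_id=r.transcript_id,
                exon_count=int(r.exon_count),
                length=int(r.length),
                pfam_hit=bool(r.pfam_hit),
                cnci_score=float(r.cnci_score),
                cpc_score=float(r.cpc_score),
                sequence=seqs.get(r.transcript_id),
                orf_length=int(r.orf_length) if "orf_length" in df.columns else None,
            )
        )
    return records


def trace_table(traces: list[FilterTrace]) -> pd.DataFrame:
    rows = []
    for t in traces:
        row = {"transcript_id": t.transcript_id, **t.criteria,
               "passed": t.passed, "first_failed": t.first_failed or ""}
        rows.append(row)
    return pd.DataFrame(rows)
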