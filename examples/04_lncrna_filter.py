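"""Identify lncRNAs with the six-criterion cascade.

Keep a transcript iff: >= 2 exons, length >= 200 nt, longest ORF < 300 nt
(strict), no Pfam hit, CNCI score < 0 and CPC score < 0.
"""

from eretarget import TranscriptRecord, filter_lncrna, longest_orf

records = [
    TranscriptRecord("lnc-1", exon_count=3, length=850, pfam_hit=False,
                     cnci_score=-0.8, cpc_score=-1.2, orf_length=210),
    TranscriptRecord("mrna-like", exon_count=7, length=1800, pfam_hit=True,
                     cnci_score=1.4, cpc_score=2.1, orf_length=1350),
    TranscriptRecord("single-exon", exon_count=1, length=600, pfam_hit=False,
                     cnci_score=-0.5, cpc_score=-0.5, orf_length=150),
    # ORF computed from sequence when no orf_length is given:
    TranscriptRecord("from-seq", exon_count=2, length=219, pfam_hit=False,
                     cnci_score=-0.3, cpc_score=-0.2,
                     sequence="ATG" + "GCT" * 71 + "TAA" + "C" * 0),
]

passing, traces = filter_lncrna(records)
for trace in traces:
    status = "lncRNA" if trace.passed else f"rejected ({trace.first_failed})"
    print(f"{trace.transcript_id:>12}: {status}")

print(f"\nlongest ORF of the 'from-seq' transcript: "
      f"{longest_orf(records[3].sequence)} nt (219 >= 200, but ORF 219 < 300: kept)")
print(f"kept: {passing}")
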