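"""Call direct target genes: responsive + ERE-containing site < 50 kb upstream.

A gene is a direct target when it is estrogen-responsive (|log2FC| >= 1,
FDR <= 0.05) and at least one ERE-containing peak summit lies within
[0, 50 kb) upstream of one of its TSSs, strand-aware and strict at 50 kb.
"""

from eretarget import (
    DERecord,
    GeneModel,
    Peak,
    SiteEREClassification,
    call_de,
    call_direct_targets,
)

genes = [
    GeneModel("VTG2", "chr8", "+", [100_000], 100_000, 112_000, "protein_coding"),
    GeneModel("APOB", "chr3", "-", [257_999], 250_000, 258_000, "protein_coding"),
    GeneModel("CTRL", "chr8", "+", [500_000], 500_000, 505_000, "protein_coding"),
]

peaks = [
    Peak("peak_a", "chr8", 69_900, 70_101),    # 29,900 bp upstream of VTG2
    Peak("peak_b", "chr3", 307_898, 308_099),  # 49,999 bp upstream of APOB (-)
    Peak("peak_c", "chr8", 449_900, 450_101),  # exactly 50,000: excluded
]

# per-peak ERE counts as produced by classify_sites after scanning
site_classes = SiteEREClassification(
    per_peak={"peak_a": 1, "peak_b": 2, "peak_c": 1}, n_zero=0, n_one=2, n_multiple=1
)

de = call_de([
    DERecord("VTG2", "mRNA", 5.2, 0.001),
    DERecord("APOB", "mRNA", 6.3, 0.0005),
    DERecord("CTRL", "mRNA", 2.0, 0.01),   # responsive, but site at 50 kb exactly
])

for call in call_direct_targets(de, peaks, site_classes, genes):
    print(f"{call.gene_id}: supported by {call.supporting_peaks}, "
          f"nearest summit {call.min_upstream_distance:,} bp upstream, "
          f"{call.n_ere_in_support} ERE(s) in support")
print("CTRL is responsive but NOT called: its peak sits exactly at 50,000 bp.")
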