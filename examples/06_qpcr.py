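"""Relative quantification: 2^-ddCt expression folds and ChIP-qPCR enrichment."""

from eretarget import ChipCtRecord, CtRecord, chip_fold_enrichment, ddct_fold_change

# expression: an 80-fold induction, inverted from Ct values
control = [CtRecord(f"c{i}", 24.0, 18.0, "control") for i in range(3)]
treated = [CtRecord(f"t{i}", 24.0 - 6.3219, 18.0, "treated") for i in range(3)]
res = ddct_fold_change(treated, control)
print(f"expression fold change: {res.treated_mean:.1f} "
      f"(control group mean {res.control_mean:.2f})")

# the textbook toy: dCt 2 vs 4 -> fold 4
toy = ddct_fold_change([CtRecord("t", 20.0, 18.0, "treated")],
                       [CtRecord("c", 22.0, 18.0, "control")])
print(f"toy example fold:       {toy.treated_mean:.1f}")

# ChIP-qPCR: IP 4 cycles earlier than IgG -> 16-fold enrichment;
# the 20%-input correction cancels between antibodies
rec = ChipCtRecord("ERE_site", ct_ip=24.0, ct_input=22.0, ct_igg=28.0,
                   input_fraction=0.20)
print(f"ChIP fold enrichment:   {chip_fold_enrichment(rec):.1f}")
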