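"""Relative quantification arithmetic for qPCR and ChIP-qPCR.

Expression: the 2^-ddCt method. dCt = Ct(target) - Ct(reference gene);
ddCt = dCt(sample) - mean dCt(control group); fold = 2^-ddCt, so the
control group's geometric-mean fold is 1 by construction.

ChIP enrichment: dCt(antibody) = Ct(antibody) - Ct(input) - log2(1/f)
where f is the input chromatin fraction (0.20 in a typical design, hence
the log2(5) correction); ddCt = dCt(IP) - dCt(IgG); fold = 2^-ddCt. The
input-fraction term cancels in ddCt but is retained so per-antibody
percent-input dCt values are reportable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class CtRecord:
    sample_id: str
    target_ct: float
    reference_ct: float
    group: str  # treated | control
    reference_assay: str = "beta-actin"

    @property
    def dct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass
class ChipCtRecord:
    locus_id: str
    ct_ip: float
    ct_input: float
    ct_igg: float
    input_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.input_fraction <= 1:
            raise ValueError(
                f"{self.locus_id}: input_fraction must be in (0, 1], got {self.input_fraction}"
            )


@dataclass
class FoldChangeResult:
    per_sample: dict[str, float]  # sample_id -> fold change
    treated_mean: float
    control_mean: float
    treated_sem: float
    control_sem: float


def _sem(values: list[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def ddct_fold_change(
    treated: list[CtRecord], control: list[CtRecord]
) -> FoldChangeResult:
    """2^-ddCt fold change per sample, with group means and SEM.

    The baseline is the mean dCt of the control group; both groups must use
    the same reference assay.
    """
    if not treated or not control:
        raise ValueError("both groups need at least one Ct record")
    assays = {r.reference_assay for r in treated + control}
    if len(assays) > 1:
        raise ValueError(f"mismatched reference assays: {sorted(assays)}")
    baseline = float(np.mean([r.dct for r in control]))
    per_sample = {
        r.sample_id: 2.0 ** -(r.dct - baseline) for r in treated + control
    }
    treated_folds = [per_sample[r.sample_id] for r in treated]
    control_folds = [per_sample[r.sample_id] for r in control]
    return FoldChangeResult(
        per_sample=per_sample,
        treated_mean=float(np.mean(treated_folds)),
        control_mean=float(np.mean(control_folds)),
        treated_sem=_sem(treated_folds),
        control_sem=_sem(control_folds),
    )


def chip_fold_enrichment(rec: ChipCtRecord) -> float:
    """ChIP-qPCR fold enrichment of the IP antibody over the IgG control."""
    correction = math.log2(1.0 / rec.input_fraction)
    dct_ip = rec.ct_ip - rec.ct_input - correction
    dct_igg = rec.ct_igg - rec.ct_input - correction
    return 2.0 ** -(dct_ip - dct_igg)


def chip_dct(rec: ChipCtRecord) -> tuple[float, float]:
    """Input-corrected per-antibody dCt values (IP, IgG)."""
    correction = math.log2(1.0 / rec.input_fraction)
    return (
        rec.ct_ip - rec.ct_input - correction,
        rec.ct_igg - rec.ct_input - correction,
    )
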