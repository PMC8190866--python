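"""End-to-end orchestration of the estrogen-response target analysis.

``run_pipeline`` consumes a bundle directory (genome FASTA, gene GTF, peak
BED, DE tables, predictor tables, transcript features, Ct tables — the
layout emitted by :mod:`eretarget.synthetic_data`) and runs every stage:
ERE scanning and site classification, peak localization, responsive-gene
calling, direct-target identification, lncRNA filtering, consensus network
construction, and qPCR fold recovery. It returns a :class:`PipelineReport`
whose internal consistency is asserted before it is handed back, and whose
``config_hash`` fingerprints inputs plus parameters so reruns are
verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import de_integrate, ere_scan, genome_io, lncrna_filter, mirna_net, qpcr_math
from .peak_annotate import annotate_peaks, localization_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    """Headline quantities of one pipeline run."""

    config_hash: str
    n_peaks: int
    n_ere_hits: int
    n_peaks_with_ere: int
    fraction_with_ere: float
    site_class_counts: dict[str, int]  # zero / one / multiple
    localization: dict[str, dict[str, float]]
    de_counts: dict[str, dict[str, int]]  # biotype -> {up, down, ns, total}
    n_responsive: int
    direct_targets: list[str]
    n_direct_targets: int
    lncrna_pass: list[str]
    n_lncrna_pass: int
    n_consensus_pairs: int
    n_network_edges: int
    n_network_nodes: int
    qpcr_folds: dict[str, float]
    chip_folds: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def summarize_counts(class_counts: dict[str, tuple[int, int]]) -> dict[str, int]:
    """Sum (up, down) responsive-gene counts per RNA class.

    ``summarize_counts({"mRNA": (540, 422), "lncRNA": (7, 10), "miRNA":
    (5, 6)})`` gives per-class totals 962, 17 and 11 and a grand total of
    990. Negative counts raise.
    """
    out: dict[str, int] = {}
    total = 0
    for cls, (up, down) in class_counts.items():
        if up < 0 or down < 0:
            raise ValueError(f"{cls}: counts must be non-negative, got ({up}, {down})")
        out[cls] = up + down
        total += up + down
    out["total"] = total
    return out


def _hash_inputs(paths: list[Path], params: dict) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    h.update(json.dumps(params, sort_keys=True).encode())
    return h.hexdigest()


@dataclass
class PipelineConfig:
    p_threshold: float = ere_scan.DEFAULT_P_THRESHOLD
    max_mismatches: int = 4
    flank: int = 500
    max_upstream: int = de_integrate.MAX_UPSTREAM
    min_votes: int = 2
    motif_path: str | None = None  # JASPAR file; default built-in ERE model

    def params(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(
    bundle_dir: str | Path,
    outdir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    bundle = Path(bundle_dir)
    config = config or PipelineConfig()

    inputs = {
        "genome": bundle / "genome.fa",
        "genes": bundle / "genes.gtf",
        "peaks": bundle / "peaks.bed",
        "de_mrna": bundle / "de_mrna.tsv",
        "de_lncrna": bundle / "de_lncrna.tsv",
        "de_mirna": bundle / "de_mirna.tsv",
        "transcripts": bundle / "transcripts.tsv",
        "transcripts_fa": bundle / "transcripts.fa",
        "qpcr": bundle / "qpcr_ct.tsv",
        "chip": bundle / "chip_ct.tsv",
    }
    predictor_paths = sorted(bundle.glob("predictions_*.tsv"))
    missing = [str(p) for p in list(inputs.values()) + predictor_paths if not p.exists()]
    if missing or len(predictor_paths) < 2:
        raise FileNotFoundError(
            f"incomplete bundle in {bundle}: missing {missing or 'predictor tables'}"
        )
    config_hash = _hash_inputs(
        list(inputs.values()) + predictor_paths, config.params()
    )

    logger.info("stage 1/7: reading inputs from %s", bundle)
    genome = genome_io.read_fasta(inputs["genome"])
    genes = genome_io.read_gtf(inputs["genes"])
    peaks = genome_io.read_peaks(inputs["peaks"])

    logger.info("stage 2/7: ERE scan over %d peaks", len(peaks))
    if config.motif_path:
        motif = ere_scan.read_jaspar(config.motif_path)
    else:
        motif = ere_scan.default_ere_motif()
    pattern = ere_scan.ConsensusPattern(max_mismatch=config.max_mismatches)
    hits = ere_scan.scan_peaks(
        genome,
        peaks,
        motif,
        pattern=pattern,
        p_threshold=config.p_threshold,
        flank=config.flank,
    )
    site_classes = ere_scan.classify_sites(peaks, hits)

    logger.info("stage 3/7: peak localization against %d genes", len(genes))
    annotations = annotate_peaks(peaks, genes)
    localization = {
        cat: {"count": c, "fraction": f}
        for cat, (c, f) in localization_summary(annotations).items()
    }

    logger.info("stage 4/7: responsive-gene calling")
    de_records = de_integrate.call_de(
        de_integrate.read_de_table(inputs["de_mrna"])
        + de_integrate.read_de_table(inputs["de_lncrna"])
        + de_integrate.read_de_table(inputs["de_mirna"])
    )
    de_counts: dict[str, dict[str, int]] = {}
    for rec in de_records:
        c = de_counts.setdefault(rec.biotype, {"up": 0, "down": 0, "ns": 0, "total": 0})
        c[rec.direction] += 1
        c["total"] += 1
    for biotype, c in de_counts.items():
        if c["up"] + c["down"] + c["ns"] != c["total"]:
            raise AssertionError(f"{biotype}: direction counts do not partition the table")
    responsive = de_integrate.responsive_genes(de_records)

    logger.info("stage 5/7: direct-target calling")
    targets = de_integrate.call_direct_targets(
        de_records, peaks, site_classes, genes, max_upstream=config.max_upstream
    )
    target_ids = [t.gene_id for t in targets]
    if not set(target_ids) <= responsive:
        raise AssertionError("direct targets must be responsive genes")

    logger.info("stage 6/7: lncRNA cascade and consensus network")
    tx = lncrna_filter.read_transcript_table(
        inputs["transcripts"], inputs["transcripts_fa"]
    )
    lnc_pass, _ = lncrna_filter.filter_lncrna(tx)
    tables = {
        p.stem.removeprefix("predictions_"): mirna_net.read_prediction_table(p)
        for p in predictor_paths
    }
    pairs = mirna_net.consensus_pairs(tables, min_votes=config.min_votes)
    edges, node_table = mirna_net.build_network(pairs, de_records)
    if not set(node_table["node_id"]) <= responsive:
        raise AssertionError("network nodes must be responsive genes")

    logger.info("stage 7/7: qPCR fold recovery")
    q = pd.read_csv(inputs["qpcr"], sep="\t", keep_default_na=False)
    qpcr_folds = {}
    for assay, grp in q.groupby("assay_id", sort=True):
        recs = [
            qpcr_math.CtRecord(
                r.sample_id, r.target_ct, r.reference_ct, r.group, r.reference_assay
            )
            for r in grp.itertuples(index=False)
        ]
        res = qpcr_math.ddct_fold_change(
            [r for r in recs if r.group == "treated"],
            [r for r in recs if r.group == "control"],
        )
        qpcr_folds[str(assay)] = res.treated_mean
    chip = pd.read_csv(inputs["chip"], sep="\t", keep_default_na=False)
    chip["input_fraction"] = chip["input_fraction"].astype(float)
    for col in ("ct_ip", "ct_input", "ct_igg"):
        chip[col] = chip[col].astype(float)
    chip_folds = {
        r.locus_id: qpcr_math.chip_fold_enrichment(
            qpcr_math.ChipCtRecord(
                r.locus_id, r.ct_ip, r.ct_input, r.ct_igg, r.input_fraction
            )
        )
        for r in chip.itertuples(index=False)
    }

    report = PipelineReport(
        config_hash=config_hash,
        n_peaks=len(peaks),
        n_ere_hits=len(hits),
        n_peaks_with_ere=site_classes.n_one + site_classes.n_multiple,
        fraction_with_ere=site_classes.fraction_with_ere,
        site_class_counts={
            "zero": site_classes.n_zero,
            "one": site_classes.n_one,
            "multiple": site_classes.n_multiple,
        },
        localization=localization,
        de_counts=de_counts,
        n_responsive=len(responsive),
        direct_targets=sorted(target_ids),
        n_direct_targets=len(target_ids),
        lncrna_pass=sorted(lnc_pass),
        n_lncrna_pass=len(lnc_pass),
        n_consensus_pairs=len(pairs),
        n_network_edges=len(edges),
        n_network_nodes=len(node_table),
        qpcr_folds=qpcr_folds,
        chip_folds=chip_folds,
    )
    if report.n_peaks_with_ere != round(report.fraction_with_ere * report.n_peaks):
        raise AssertionError("ERE peak counts and fraction disagree")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
            outdir / "ere_hits.tsv", sep="\t", index=False
        )
        pd.DataFrame([dataclasses.asdict(a) for a in annotations]).to_csv(
            outdir / "peak_annotation.tsv", sep="\t", index=False
        )
        pd.DataFrame([dataclasses.asdict(t) for t in targets]).to_csv(
            outdir / "direct_targets.tsv", sep="\t", index=False
        )
        mirna_net.write_network(
            edges,
            node_table,
            outdir / "network_edges.tsv",
            outdir / "network_nodes.tsv",
            outdir / "network.graphml",
        )
    return report
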