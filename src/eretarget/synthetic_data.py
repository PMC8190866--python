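"""Synthetic input bundles with planted ground truth.

The generator emits every file the pipeline consumes — genome FASTA, gene
GTF, peak BED, DE tables, predictor tables, transcript features and
sequences, and Ct tables — from a single seeded random stream, together
with a ground-truth JSON describing what was planted.

Layout of the default genome (one chromosome, i.i.d. uniform background):

* a *target zone* of isolated 60 kb slots, one per planted direct-target
  gene; each slot holds the gene and one ERE-containing peak whose summit
  sits a uniform 0-50 kb upstream of the TSS, and upstream windows never
  cross slot boundaries;
* a *gene zone* packing the remaining genes (both strands, mixed biotypes,
  some with two transcript isoforms) with no peaks within 50 kb, so
  non-target DE genes never acquire binding-site support;
* a gene-free *peak zone* holding all background peaks, ERE-planted at the
  configured rate.

Planted EREs are AGGTCA + spacer + TGACCT 15-mers with the spacer drawn
from a C.G-biased distribution; a configurable fraction of ERE peaks
receives two non-overlapping copies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genome_io import GeneModel, GenomeSequence, Peak, write_fasta, write_gtf, write_peaks
from .lncrna_filter import longest_orf

BASES = np.array(list("ACGT"))

PEAK_LEN = 201  # +/-100 bp of the summit, typical narrow-peak geometry
SLOT = 60_000
ZONE_GAP = 60_000  # > max_upstream so zones cannot cross-talk


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    genome_length: int = 2_000_000
    n_genes: int = 200
    strand_fraction: float = 0.5
    n_peaks: int = 300
    ere_planting_rate: float = 0.55
    ere_double_rate: float = 0.4  # fraction of ERE peaks carrying two EREs
    ere_planting_mismatches: int = 0
    n_direct_targets: int = 20
    n_de_mrna: int = 60
    n_de_lncrna: int = 5
    n_de_mirna: int = 4
    mirna_consensus_pairs: int = 30
    predictor_vote3_rate: float = 0.4  # consensus pairs seen by all 3 predictors
    predictor_noise_pairs: int = 20  # single-predictor decoy pairs
    ns_consensus_pairs: int = 10  # consensus pairs touching non-responsive genes
    n_lncrna_like: int = 10
    n_mrna_like: int = 10
    ct_noise_sd: float = 0.2  # cycles
    qpcr_true_folds: dict = field(
        default_factory=lambda: {"APOB_like": 80.0, "APOV1_like": 1250.0, "mid": 4.0, "no_change": 1.0}
    )
    chip_true_folds: dict = field(
        default_factory=lambda: {"site_strong": 16.0, "site_mid": 8.0, "site_weak": 4.0, "site_null": 1.0}
    )
    peak_in_body_fraction: float | None = None  # localization-study mode

    def __post_init__(self) -> None:
        for name in ("strand_fraction", "ere_planting_rate", "ere_double_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_direct_targets > self.n_de_mrna:
            raise ValueError("direct targets must be a subset of DE mRNA genes")
        if self.n_direct_targets > self.n_genes:
            raise ValueError("more direct targets than genes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """What the generator planted, serialized next to the bundle."""

    seed: int
    planted_eres: list[dict]  # peak_id, start, end, spacer, mismatches
    peak_ere_count: dict[str, int]
    direct_targets: list[str]
    target_upstream_distance: dict[str, int]
    de_direction: dict[str, str]  # responsive genes only
    consensus_pairs: list[list]  # [mirna, gene, votes] expected in the network
    ns_consensus_pairs: list[list]  # consensus pairs excluded from the network
    qpcr_folds: dict[str, float]
    chip_folds: dict[str, float]
    lncrna_like: list[str]
    mrna_like: list[str]
    single_fail: dict[str, str]  # criterion -> transcript_id
    body_peak_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _spacer(rng: np.random.Generator) -> str:
    """CNG-biased trinucleotide spacer (C and G each kept with prob 0.7)."""
    s1 = "C" if rng.random() < 0.7 else str(BASES[rng.integers(0, 4)])
    s2 = str(BASES[rng.integers(0, 4)])
    s3 = "G" if rng.random() < 0.7 else str(BASES[rng.integers(0, 4)])
    return s1 + s2 + s3


def _ere_seq(rng: np.random.Generator, n_mismatches: int) -> tuple[str, str, int]:
    spacer = _spacer(rng)
    seq = list("AGGTCA" + spacer + "TGACCT")
    informative = [i for i in range(15) if not 6 <= i <= 8]
    mutated = 0
    if n_mismatches:
        for i in rng.choice(informative, size=n_mismatches, replace=False):
            alternatives = [b for b in "ACGT" if b != seq[i]]
            seq[i] = alternatives[rng.integers(0, 3)]
            mutated += 1
    return "".join(seq), spacer, mutated


def _gene(
    gene_id: str,
    start: int,
    length: int,
    strand: str,
    biotype: str,
    second_tss_offset: int | None = None,
) -> GeneModel:
    end = start + length
    tss = [start] if strand == "+" else [end - 1]
    if second_tss_offset is not None:
        tss.append(
            start + second_tss_offset if strand == "+" else end - 1 - second_tss_offset
        )
    return GeneModel(
        gene_id=gene_id,
        chrom="chr1",
        strand=strand,
        tss_list=sorted(set(tss)),
        start=start,
        end=end,
        biotype=biotype,
    )


def _make_lnc_like_seq(rng: np.random.Generator, length: int) -> str:
    """Random sequence rejected until its longest ORF is < 300 nt."""
    for _ in range(200):
        seq = _random_seq(rng, length)
        if longest_orf(seq) < 300:
            return seq
    raise RuntimeError("could not draw an ORF-free sequence")


def _make_coding_seq(rng: np.random.Generator, length: int, n_codons: int = 120) -> str:
    """Random sequence with a planted ORF of n_codons+1 codons (>= 300 nt)."""
    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in {"TAA", "TAG", "TGA", "ATG"}
    ]
    orf = "ATG" + "".join(
        non_stop[i] for i in rng.integers(0, len(non_stop), size=n_codons)
    ) + "TAA"
    flank = length - len(orf)
    if flank < 0:
        raise ValueError("transcript too short for the planted ORF")
    left = flank // 2
    seq = _random_seq(rng, left) + orf + _random_seq(rng, flank - left)
    assert longest_orf(seq) >= 300
    return seq


def generate(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Write the full input bundle into ``outdir``; returns the ground truth.

    Deterministic given ``config.seed``: the same configuration produces a
    byte-identical bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ------------------------------------------------------------------ layout
    n_targets = config.n_direct_targets
    n_background = config.n_peaks - n_targets
    if n_background < 0:
        raise ValueError("n_peaks must be at least n_direct_targets")
    target_zone_end = n_targets * SLOT
    gene_zone_start = target_zone_end + ZONE_GAP
    n_zone_genes = config.n_genes - n_targets
    gene_zone_len = n_zone_genes * 2_800  # body <= 2500 plus gap <= 300
    peak_zone_start = gene_zone_start + gene_zone_len + ZONE_GAP
    peak_zone_len = n_background * (PEAK_LEN + 300) + 500
    required = peak_zone_start + peak_zone_len
    if config.peak_in_body_fraction is None and required > config.genome_length:
        raise ValueError(
            f"genome too small for the requested placement: need >= {required} bp, "
            f"have {config.genome_length}"
        )

    # ------------------------------------------------------------- genome draft
    seq = list(_random_seq(rng, config.genome_length))

    # ------------------------------------------------------------------- genes
    genes: list[GeneModel] = []
    target_upstream: dict[str, int] = {}
    target_peaks: list[Peak] = []

    def strand_draw() -> str:
        return "+" if rng.random() < config.strand_fraction else "-"

    for i in range(n_targets):
        gid = f"gene_t{i:03d}"
        slot = i * SLOT
        body = int(rng.integers(1_500, 3_001))
        strand = strand_draw()
        if strand == "+":
            g = _gene(gid, slot + 52_000, body, "+", "protein_coding")
            d = int(rng.integers(0, 50_000))
            summit = g.tss_list[0] - d
        else:
            g = _gene(gid, slot + 8_000 - body, body, "-", "protein_coding")
            d = int(rng.integers(0, 50_000))
            summit = g.tss_list[0] + d
        genes.append(g)
        target_upstream[gid] = d
        target_peaks.append(
            Peak(f"peak_t{i:03d}", "chr1", summit - 100, summit + 101, summit=summit)
        )

    # gene-zone biotype plan: enough non-coding genes for the DE quotas
    n_lnc_genes = config.n_de_lncrna + 3
    n_mir_genes = config.n_de_mirna + 4
    if n_lnc_genes + n_mir_genes > n_zone_genes:
        raise ValueError("too few genes for the non-coding biotype quotas")
    biotypes = (
        ["lncRNA"] * n_lnc_genes
        + ["miRNA"] * n_mir_genes
        + ["protein_coding"] * (n_zone_genes - n_lnc_genes - n_mir_genes)
    )
    biotypes = [biotypes[j] for j in rng.permutation(n_zone_genes)]
    pos = gene_zone_start
    for i in range(n_zone_genes):
        gid = f"gene_z{i:03d}"
        body = int(rng.integers(1_500, 2_501))
        pos += int(rng.integers(100, 301))
        second = int(rng.integers(200, body - 200)) if rng.random() < 0.3 else None
        genes.append(_gene(gid, pos, body, strand_draw(), biotypes[i], second))
        pos += body
    if pos > gene_zone_start + gene_zone_len:
        raise ValueError("gene zone overflow; genome too small")

    # ------------------------------------------------------------------- peaks
    background_peaks: list[Peak] = []
    body_peak_ids: list[str] = []
    if config.peak_in_body_fraction is None:
        pos = peak_zone_start
        for i in range(n_background):
            pos += int(rng.integers(80, 301))
            if pos + PEAK_LEN > config.genome_length:
                raise ValueError("peak zone overflow; genome too small")
            background_peaks.append(
                Peak(f"peak_b{i:03d}", "chr1", pos, pos + PEAK_LEN)
            )
            pos += PEAK_LEN
        peaks = target_peaks + background_peaks
    else:
        # localization-study mode: summits planted inside / outside gene bodies
        bodies = [(g.start, g.end) for g in genes]
        peaks = []
        lo, hi = 300, config.genome_length - 300
        for i in range(config.n_peaks):
            pid = f"peak_{i:04d}"
            if rng.random() < config.peak_in_body_fraction:
                g = genes[int(rng.integers(0, len(genes)))]
                summit = int(rng.integers(g.start, g.end))
                body_peak_ids.append(pid)
            else:
                while True:
                    summit = int(rng.integers(lo, hi))
                    if not any(s <= summit < e for s, e in bodies):
                        break
            peaks.append(Peak(pid, "chr1", summit - 100, summit + 101, summit=summit))
        target_upstream = {}

    # --------------------------------------------------------------------- EREs
    n_ere = int(round(config.ere_planting_rate * config.n_peaks))
    if config.peak_in_body_fraction is None:
        ordered = target_peaks + [
            background_peaks[j] for j in rng.permutation(len(background_peaks))
        ]
    else:
        ordered = [peaks[j] for j in rng.permutation(len(peaks))]
    ere_peaks = ordered[:n_ere]
    planted_eres: list[dict] = []
    peak_ere_count = {p.peak_id: 0 for p in peaks}
    for p in ere_peaks:
        double = rng.random() < config.ere_double_rate
        offsets = [30, 120] if double else [int(rng.integers(10, PEAK_LEN - 25))]
        if double:
            offsets = [o + int(rng.integers(-10, 11)) for o in offsets]
        for off in offsets:
            ere, spacer, mm = _ere_seq(rng, config.ere_planting_mismatches)
            start = p.start + off
            seq[start : start + 15] = list(ere)
            planted_eres.append(
                {
                    "peak_id": p.peak_id,
                    "start": start,
                    "end": start + 15,
                    "spacer": spacer,
                    "mismatches": mm,
                }
            )
            peak_ere_count[p.peak_id] += 1

    genome = GenomeSequence({"chr1": "".join(seq)})

    # ---------------------------------------------------------------- DE tables
    target_ids = [g.gene_id for g in genes[:n_targets]]
    zone = genes[n_targets:]
    zone_mrna = [g.gene_id for g in zone if g.biotype == "protein_coding"]
    zone_lnc = [g.gene_id for g in zone if g.biotype == "lncRNA"]
    zone_mir = [g.gene_id for g in zone if g.biotype == "miRNA"]
    n_extra_mrna = config.n_de_mrna - n_targets
    if n_extra_mrna > len(zone_mrna):
        raise ValueError("not enough protein-coding genes for the DE quota")
    de_mrna = target_ids + list(
        rng.choice(zone_mrna, size=n_extra_mrna, replace=False)
    )
    de_lnc = list(rng.choice(zone_lnc, size=config.n_de_lncrna, replace=False))
    de_mir = list(rng.choice(zone_mir, size=config.n_de_mirna, replace=False))

    de_direction: dict[str, str] = {}

    def log2fc_row(gid: str, de: bool) -> tuple[float, float]:
        if de:
            direction = "up" if rng.random() < 0.55 else "down"
            de_direction[gid] = direction
            lfc = float(rng.uniform(1.2, 4.0))
            if direction == "down":
                lfc = -lfc
            return round(lfc, 4), round(float(rng.uniform(1e-5, 0.03)), 6)
        # non-responsive: mostly small effects, some large but non-significant
        if rng.random() < 0.1:
            return round(float(rng.uniform(-2.5, 2.5)), 4), round(
                float(rng.uniform(0.2, 0.95)), 6
            )
        return round(float(rng.uniform(-0.8, 0.8)), 4), round(
            float(rng.uniform(0.05, 0.95)), 6
        )

    def write_de(path: Path, ids: list[str], biotype: str, de_set: set[str]) -> None:
        lines = ["gene_id\tbiotype\teffect\tfdr"]
        for gid in ids:
            if biotype == "miRNA":
                if gid in de_set:
                    direction = "up" if rng.random() < 0.5 else "down"
                    de_direction[gid] = direction
                    fc = (
                        float(rng.uniform(1.6, 5.0))
                        if direction == "up"
                        else float(rng.uniform(0.2, 0.6))
                    )
                    fdr = float(rng.uniform(1e-5, 0.03))
                else:
                    fc = float(rng.uniform(0.75, 1.4))
                    fdr = float(rng.uniform(0.05, 0.95))
                lines.append(f"{gid}\tmiRNA\t{fc:.4f}\t{fdr:.6f}")
            else:
                lfc, fdr = log2fc_row(gid, gid in de_set)
                lines.append(f"{gid}\t{biotype}\t{lfc}\t{fdr:.6f}")
        path.write_text("\n".join(lines) + "\n")

    mrna_ids = target_ids + zone_mrna
    write_de(outdir / "de_mrna.tsv", mrna_ids, "mRNA", set(de_mrna))
    write_de(outdir / "de_lncrna.tsv", zone_lnc, "lncRNA", set(de_lnc))
    write_de(outdir / "de_mirna.tsv", zone_mir, "miRNA", set(de_mir))

    # --------------------------------------------------------- predictor tables
    mirna_up_down = [m for m in de_mir]
    possible = [(m, g) for m in mirna_up_down for g in de_mrna]
    if config.mirna_consensus_pairs + config.ns_consensus_pairs > len(possible):
        raise ValueError("not enough miRNA x gene combinations for the pair quotas")
    chosen_idx = rng.choice(
        len(possible), size=config.mirna_consensus_pairs, replace=False
    )
    consensus = [possible[j] for j in sorted(chosen_idx)]
    ns_mrna = [g for g in mrna_ids if g not in set(de_mrna)]
    ns_pairs = [
        (mirna_up_down[int(rng.integers(0, len(mirna_up_down)))], g)
        for g in rng.choice(ns_mrna, size=config.ns_consensus_pairs, replace=False)
    ]
    tables: dict[str, list[tuple[str, str]]] = {
        "predictorA": [],
        "predictorB": [],
        "predictorC": [],
    }
    names = list(tables)
    consensus_votes: list[list] = []
    for m, g in consensus:
        votes = 3 if rng.random() < config.predictor_vote3_rate else 2
        chosen = (
            names
            if votes == 3
            else [names[j] for j in sorted(rng.choice(3, size=2, replace=False))]
        )
        for name in chosen:
            tables[name].append((m, g))
        consensus_votes.append([m, g, votes])
    ns_votes: list[list] = []
    for m, g in ns_pairs:
        votes = 3 if rng.random() < config.predictor_vote3_rate else 2
        chosen = (
            names
            if votes == 3
            else [names[j] for j in sorted(rng.choice(3, size=2, replace=False))]
        )
        for name in chosen:
            tables[name].append((m, g))
        ns_votes.append([m, g, votes])
    # single-predictor decoys (dropped by the consensus vote)
    for _ in range(config.predictor_noise_pairs):
        m = mirna_up_down[int(rng.integers(0, len(mirna_up_down)))]
        g = mrna_ids[int(rng.integers(0, len(mrna_ids)))]
        if any((m, g) in t for t in tables.values()):
            continue
        tables[names[int(rng.integers(0, 3))]].append((m, g))
    for name, pairs in tables.items():
        lines = ["mirna_id\tgene_id"]
        lines += [f"{m}\t{g}" for m, g in sorted(set(pairs))]
        (outdir / f"predictions_{name}.tsv").write_text("\n".join(lines) + "\n")

    # ------------------------------------------------------ transcript records
    transcripts: list[dict] = []
    tx_seqs: dict[str, str] = {}
    lncrna_like, mrna_like = [], []

    def add_tx(tid, exons, length, pfam, cnci, cpc, sequence):
        transcripts.append(
            {
                "transcript_id": tid,
                "exon_count": exons,
                "length": length,
                "pfam_hit": pfam,
                "cnci_score": round(cnci, 3),
                "cpc_score": round(cpc, 3),
            }
        )
        tx_seqs[tid] = sequence

    for i in range(config.n_lncrna_like):
        tid = f"TX_lnc{i:03d}"
        length = int(rng.integers(400, 1_501))
        add_tx(
            tid,
            int(rng.integers(2, 6)),
            length,
            False,
            -float(rng.uniform(0.1, 2.0)),
            -float(rng.uniform(0.1, 2.0)),
            _make_lnc_like_seq(rng, length),
        )
        lncrna_like.append(tid)
    for i in range(config.n_mrna_like):
        tid = f"TX_cod{i:03d}"
        length = int(rng.integers(800, 2_001))
        add_tx(
            tid,
            int(rng.integers(2, 10)),
            length,
            True,
            float(rng.uniform(0.5, 3.0)),
            float(rng.uniform(0.5, 3.0)),
            _make_coding_seq(rng, length, n_codons=int(rng.integers(100, 200))),
        )
        mrna_like.append(tid)
    # one record failing exactly one criterion each
    single_fail = {}
    ok = dict(exons=3, length=600, pfam=False, cnci=-0.5, cpc=-0.5)
    fails = [
        ("exon_count_ge2", dict(ok, exons=1)),
        ("length_ge200", dict(ok, length=150)),
        ("orf_lt300", dict(ok)),
        ("no_pfam_hit", dict(ok, pfam=True)),
        ("cnci_lt0", dict(ok, cnci=0.5)),
        ("cpc_lt0", dict(ok, cpc=0.5)),
    ]
    for i, (crit, kw) in enumerate(fails):
        tid = f"TX_fail{i}"
        if crit == "orf_lt300":
            s = _make_coding_seq(rng, kw["length"], n_codons=110)
        else:
            s = _make_lnc_like_seq(rng, kw["length"])
        add_tx(tid, kw["exons"], kw["length"], kw["pfam"], kw["cnci"], kw["cpc"], s)
        single_fail[crit] = tid

    lines = ["transcript_id\texon_count\tlength\tpfam_hit\tcnci_score\tcpc_score"]
    for t in transcripts:
        lines.append(
            f"{t['transcript_id']}\t{t['exon_count']}\t{t['length']}\t"
            f"{t['pfam_hit']}\t{t['cnci_score']}\t{t['cpc_score']}"
        )
    (outdir / "transcripts.tsv").write_text("\n".join(lines) + "\n")
    with open(outdir / "transcripts.fa", "w", newline="\n") as fh:
        for tid, s in tx_seqs.items():
            fh.write(f">{tid}\n")
            for j in range(0, len(s), 60):
                fh.write(s[j : j + 60] + "\n")

    # ----------------------------------------------------------------- Ct tables
    qlines = ["assay_id\tsample_id\tgroup\ttarget_ct\treference_ct\treference_assay"]
    for assay, fold in config.qpcr_true_folds.items():
        base = float(rng.uniform(22, 26))
        for j in range(6):
            ct = base + float(rng.normal(0, config.ct_noise_sd)) if config.ct_noise_sd else base
            qlines.append(f"{assay}\tctl_{j+1}\tcontrol\t{ct:.4f}\t18.0000\tbeta-actin")
        for j in range(8):
            ct = base - np.log2(fold)
            if config.ct_noise_sd:
                ct += float(rng.normal(0, config.ct_noise_sd))
            qlines.append(f"{assay}\ttrt_{j+1}\ttreated\t{ct:.4f}\t18.0000\tbeta-actin")
    (outdir / "qpcr_ct.tsv").write_text("\n".join(qlines) + "\n")

    clines = ["locus_id\tct_ip\tct_input\tct_igg\tinput_fraction"]
    for locus, fold in config.chip_true_folds.items():
        ct_igg = 28.0
        ct_ip = ct_igg - float(np.log2(fold))
        if config.ct_noise_sd:
            ct_ip += float(rng.normal(0, config.ct_noise_sd))
        clines.append(f"{locus}\t{ct_ip:.4f}\t22.0000\t{ct_igg:.4f}\t0.20")
    (outdir / "chip_ct.tsv").write_text("\n".join(clines) + "\n")

    counts = rng.integers(0, 5_000, size=len(zone_mir) * 2).reshape(-1, 2)
    mlines = ["mirna_id\tcount_control\tcount_treated"]
    for gid, row in zip(zone_mir, counts):
        mlines.append(f"{gid}\t{row[0]}\t{row[1]}")
    (outdir / "mirna_counts.tsv").write_text("\n".join(mlines) + "\n")

    # --------------------------------------------------------------- main files
    write_fasta(genome, outdir / "genome.fa")
    write_gtf(genes, outdir / "genes.gtf")
    write_peaks(peaks, outdir / "peaks.bed")
    config.to_yaml(outdir / "sim_config.yaml")

    if config.peak_in_body_fraction is None:
        direct_targets = sorted(
            t
            for i, t in enumerate(target_ids)
            if peak_ere_count[f"peak_t{i:03d}"] > 0
        )
    else:
        direct_targets = []
    truth = GroundTruth(
        seed=config.seed,
        planted_eres=planted_eres,
        peak_ere_count=peak_ere_count,
        direct_targets=direct_targets,
        target_upstream_distance=target_upstream,
        de_direction=de_direction,
        consensus_pairs=consensus_votes,
        ns_consensus_pairs=ns_votes,
        qpcr_folds=dict(config.qpcr_true_folds),
        chip_folds=dict(config.chip_true_folds),
        lncrna_like=lncrna_like,
        mrna_like=mrna_like,
        single_fail=single_fail,
        body_peak_ids=body_peak_ids,
    )
    truth.to_json(outdir / "ground_truth.json")
    return truth


def validate_bundle(outdir: str | Path) -> list[str]:
    """Cross-check the emitted files against the ground-truth JSON.

    Returns a list of human-readable discrepancies (empty when consistent).
    """
    from .genome_io import read_fasta, read_gtf, read_peaks

    outdir = Path(outdir)
    truth = GroundTruth.from_json(outdir / "ground_truth.json")
    genome = read_fasta(outdir / "genome.fa")
    genes = {g.gene_id: g for g in read_gtf(outdir / "genes.gtf")}
    peaks = {p.peak_id: p for p in read_peaks(outdir / "peaks.bed")}
    problems = []
    for e in truth.planted_eres:
        seq = genome.fetch("chr1", e["start"], e["end"])
        expected_core = ("AGGTCA", "TGACCT")
        if e["mismatches"] == 0 and (seq[:6], seq[9:]) != expected_core:
            problems.append(f"planted ERE at {e['start']} not found in genome")
        if seq[6:9] != e["spacer"]:
            problems.append(f"planted spacer at {e['start']} disagrees")
        p = peaks.get(e["peak_id"])
        if p is None or not (p.start <= e["start"] and e["end"] <= p.end):
            problems.append(f"planted ERE at {e['start']} outside peak {e['peak_id']}")
    if set(truth.peak_ere_count) != set(peaks):
        problems.append("peak id sets differ between BED and ground truth")
    for gid, d in truth.target_upstream_distance.items():
        g = genes.get(gid)
        if g is None:
            problems.append(f"target gene {gid} missing from GTF")
            continue
        pid = f"peak_t{gid[6:]}"
        p = peaks[pid]
        dist = (
            g.tss_list[0] - p.summit if g.strand == "+" else p.summit - g.tss_list[0]
        )
        if dist != d:
            problems.append(f"{gid}: upstream distance {dist} != planted {d}")
    for gid in truth.de_direction:
        if gid not in genes:
            problems.append(f"DE gene {gid} missing from GTF")
    return problems
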