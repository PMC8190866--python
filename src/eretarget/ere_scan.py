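"""Estrogen response element (ERE) identification in binding sites.

The scanner mirrors FIMO-style matrix scanning: windows are scored with a
log-odds position weight matrix derived from a nucleotide count matrix, and
the score is converted to an exact p-value — the probability that a random
background sequence of motif length scores at least as high — computed by
dynamic programming over a discretized score lattice. A window is called an
ERE only when it satisfies BOTH stringency criteria: PWM p-value below the
threshold (default 5e-4) and at most ``max_mismatch`` (default 4)
substitutions relative to the palindromic 15 bp consensus AGGTCAnnnTGACCT,
whose three middle positions are free spacers.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeSequence, Peak

logger = logging.getLogger(__name__)

ERE_CONSENSUS = "AGGTCAnnnTGACCT"
DEFAULT_P_THRESHOLD = 5e-4
DEFAULT_RESOLUTION = 1e-3  # bits per score bin

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class CountMatrixMotif:
    """A nucleotide count matrix and its derived log-odds (bits) form.

    ``counts`` is a 4 x L array in A, C, G, T row order. The log-odds entry
    for base b at column i is

        log2( (counts[b,i] + pseudocount * background[b])
              / (colsum_i + pseudocount) / background[b] )

    i.e. counts are smoothed with a pseudocount distributed by the
    background composition before the odds ratio is taken.
    """

    counts: np.ndarray
    pseudocount: float = 0.1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.ndim != 2:
            raise ValueError("counts must be a 4 x L array (A, C, G, T rows)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if abs(self.background.sum() - 1.0) > 1e-9 or np.any(self.background <= 0):
            raise ValueError("background must be 4 positive probabilities summing to 1")
        colsum = self.counts.sum(axis=0)
        if np.any(colsum + self.pseudocount <= 0):
            raise ValueError("column count sums must be positive after pseudocount")
        probs = (self.counts + self.pseudocount * self.background[:, None]) / (
            colsum + self.pseudocount
        )
        self.log_odds = np.log2(probs / self.background[:, None])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.counts, axis=0))

    def reverse_complement(self) -> "CountMatrixMotif":
        return CountMatrixMotif(
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
            name=f"{self.name}_rc",
        )

    def quantized(self, resolution: float = DEFAULT_RESOLUTION) -> np.ndarray:
        """Log-odds discretized to integer multiples of ``resolution`` bits."""
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        q = np.rint(self.log_odds / resolution).astype(np.int64)
        if np.all(q.max(axis=0) == q.min(axis=0)):
            raise ValueError(
                "resolution too coarse: every column collapses to a single score bin"
            )
        return q


def read_jaspar(path) -> CountMatrixMotif:
    """Read a JASPAR-format (.jaspar/.pfm) count matrix (A/C/G/T rows)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        m = bio_motifs.read(fh, "jaspar")
    counts = np.array([m.counts[b] for b in _BASES], dtype=float)
    return CountMatrixMotif(counts=counts, name=m.name or "jaspar_motif")


def write_jaspar(motif: CountMatrixMotif, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f">{motif.name}\n")
        for i, b in enumerate(_BASES):
            row = " ".join(f"{v:.0f}" for v in motif.counts[i])
            fh.write(f"{b} [ {row} ]\n")


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def default_ere_motif(n_sites: int = 200) -> CountMatrixMotif:
    """The built-in ERE count matrix (synthetic; see docs/methods.md).

    Constructed from the palindromic consensus AGGTCAnnnTGACCT with a
    transition-tolerant, transversion-intolerant degeneracy profile: each
    inner half-site position carries counts only for the consensus base and
    its transition partner (0.6/0.4), the outermost A/T pair is the least
    conserved and additionally admits one transversion (0.5/0.3/0.2), and
    the three spacer positions are uninformative. This shape makes the PWM
    p-value and the consensus-mismatch criteria complementary: background
    windows reaching the p < 5e-4 score tail are typically transition-rich
    (>4 mismatches) and are rejected by the mismatch co-filter, so random
    sequence yields almost no joint hits while consensus-like sites score
    far into the tail (see :func:`joint_tail_probability`).
    """

    def col(cons: str, probs: tuple[float, ...]) -> list[float]:
        d = {cons: probs[0], _TRANSITION[cons]: probs[1]}
        if len(probs) > 2:
            # one tolerated transversion: C for purine-consensus columns,
            # G for pyrimidine-consensus columns (palindromy-symmetric)
            tv = "C" if cons in "AG" else "G"
            d[tv] = probs[2]
        return [d.get(b, 0.0) for b in _BASES]

    outer = (0.5, 0.3, 0.2)
    inner = (0.6, 0.4)
    half = [col("A", outer)] + [col(c, inner) for c in "GGTCA"]
    spacer = [[0.25] * 4] * 3
    # palindromic second half-site: reverse complement of the first
    second = [c[::-1] for c in half[::-1]]
    probs = np.array(half + spacer + second, dtype=float).T
    counts = np.rint(probs * n_sites)
    return CountMatrixMotif(counts=counts, name="ERE_consensus_synthetic")


@dataclass
class ConsensusPattern:
    """Fixed-base consensus with free ``n`` spacer positions."""

    pattern: str = ERE_CONSENSUS
    max_mismatch: int = 4

    def __post_init__(self) -> None:
        if set(self.pattern) - set("ACGTn"):
            raise ValueError("pattern may contain only A, C, G, T and n")
        self.informative = np.array([c != "n" for c in self.pattern])
        self.codes = encode(self.pattern.upper().replace("N", "A"))

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def is_palindromic(self) -> bool:
        rc = reverse_complement(self.pattern)
        return rc.replace("n", "n") == self.pattern

    @property
    def spacer_slice(self) -> slice:
        """Positions of the n-block (empty slice when the pattern has none)."""
        idx = [i for i, c in enumerate(self.pattern) if c == "n"]
        if not idx:
            return slice(0, 0)
        return slice(min(idx), max(idx) + 1)


def mismatch_count(seq: str, pattern: ConsensusPattern | None = None) -> int:
    """Substitutions of ``seq`` against the consensus, spacer positions free.

    ``N`` in the sequence counts as a mismatch at every informative position.
    """
    pattern = pattern or ConsensusPattern()
    if len(seq) != pattern.length:
        raise ValueError(
            f"sequence length {len(seq)} != pattern length {pattern.length}"
        )
    codes = encode(seq.upper())
    diff = (codes != pattern.codes) & pattern.informative
    return int(diff.sum())


class ScorePValueTable:
    """Exact null distribution of the quantized PWM score.

    Computed by per-position convolution of the background base
    distribution over the integer score lattice (bin width = ``resolution``
    bits). ``p_value(s)`` is P(score >= s) for a random background L-mer;
    it is non-increasing in s and equals 1 at the minimum possible score.
    """

    def __init__(
        self,
        motif: CountMatrixMotif,
        resolution: float = DEFAULT_RESOLUTION,
    ) -> None:
        self.resolution = resolution
        self.qmatrix = motif.quantized(resolution)
        bg = motif.background
        q = self.qmatrix
        self.min_int = int(q.min(axis=0).sum())
        self.max_int = int(q.max(axis=0).sum())
        span = self.max_int - self.min_int + 1
        pmf = np.zeros(span)
        pmf[0] = 1.0  # offset representation: index = score_int - min_int
        lo_done = 0
        for i in range(q.shape[1]):
            col_min = int(q[:, i].min())
            new = np.zeros(span)
            for b in range(4):
                shift = int(q[b, i]) - col_min
                new[shift:] += bg[b] * pmf[: span - shift if shift else span]
            pmf = new
            lo_done += col_min
        # lo_done == min_int by construction
        self.pmf = pmf
        self.sf = np.cumsum(pmf[::-1])[::-1]

    def p_value(self, score_int: int | np.ndarray) -> float | np.ndarray:
        idx = np.clip(np.asarray(score_int) - self.min_int, 0, len(self.sf) - 1)
        out = self.sf[idx]
        return float(out) if np.ndim(score_int) == 0 else out

    def p_value_bits(self, score_bits: float) -> float:
        return self.p_value(int(np.rint(score_bits / self.resolution)))

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose p-value is < p_threshold."""
        passing = np.nonzero(self.sf < p_threshold)[0]
        if len(passing) == 0:
            return self.max_int + 1  # unattainable
        return int(passing[0]) + self.min_int

    def as_mapping(self) -> dict[float, float]:
        """score (bits) -> p-value over all achievable scores."""
        achievable = np.nonzero(self.pmf > 0)[0]
        return {
            float((i + self.min_int) * self.resolution): float(self.sf[i])
            for i in achievable
        }


def score_pvalue_table(
    motif: CountMatrixMotif, resolution: float = DEFAULT_RESOLUTION
) -> ScorePValueTable:
    """Build the exact score -> p-value map for ``motif`` (see class docs)."""
    return ScorePValueTable(motif, resolution)


@dataclass
class EREHit:
    """One scored, strand-aware motif occurrence inside a peak."""

    peak_id: str
    chrom: str
    start: int
    end: int
    strand: str
    pwm_score: float  # bits
    p_value: float
    mismatches: int


@dataclass
class SiteEREClassification:
    """Per-peak ERE occupancy and the zero/one/multiple aggregate tallies."""

    per_peak: dict[str, int]
    n_zero: int
    n_one: int
    n_multiple: int

    @property
    def n_sites(self) -> int:
        return self.n_zero + self.n_one + self.n_multiple

    @property
    def n_with_ere(self) -> int:
        return self.n_one + self.n_multiple

    @property
    def fraction_with_ere(self) -> float:
        return self.n_with_ere / self.n_sites if self.n_sites else 0.0

    @property
    def total_eres(self) -> int:
        return sum(self.per_peak.values())

    def peak_class(self, peak_id: str) -> str:
        n = self.per_peak[peak_id]
        return "zero" if n == 0 else ("one" if n == 1 else "multiple")


def _scan_window(
    codes: np.ndarray,
    qfwd: np.ndarray,
    qrev: np.ndarray,
    pattern: ConsensusPattern,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-position forward/reverse scores and mismatch counts.

    Mismatches are returned for both orientations (identical when the
    pattern is palindromic); the caller picks the matching orientation's
    count.
    """
    L = qfwd.shape[1]
    n_pos = len(codes) - L + 1
    if n_pos <= 0:
        empty = np.zeros(0)
        return empty, empty, empty.astype(int), empty.astype(int), np.zeros(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~np.any(windows == 4, axis=1)
    safe = np.where(windows == 4, 0, windows)
    cols = np.arange(L)
    fwd = qfwd[safe, cols].sum(axis=1)
    rev = qrev[safe, cols].sum(axis=1)
    # N (code 4) mismatches every informative position in either orientation
    mism_fwd = ((windows != pattern.codes) & pattern.informative).sum(axis=1)
    rc_codes = 3 - pattern.codes[::-1]  # complemented, reversed consensus
    mism_rev = ((windows != rc_codes) & pattern.informative[::-1]).sum(axis=1)
    return fwd, rev, mism_fwd, mism_rev, valid


def scan_peaks(
    genome: GenomeSequence,
    peaks: list[Peak],
    motif: CountMatrixMotif | None = None,
    pattern: ConsensusPattern | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    flank: int | None = 500,
    resolution: float = DEFAULT_RESOLUTION,
    table: ScorePValueTable | None = None,
) -> list[EREHit]:
    """Scan peak windows on both strands for EREs.

    Each peak is extended symmetrically around its summit to a ``flank`` bp
    window (``None`` scans the peak interval as-is); windows running over a
    chromosome edge are clipped with a warning. At each position the better
    scoring orientation is kept (the consensus is palindromic, so opposite
    strand matches at one location are duplicates), a window is a candidate
    iff its exact p-value is below ``p_threshold`` AND its consensus
    mismatch count is within the pattern's budget, and overlapping
    candidates within a peak are resolved greedily by ascending p-value.
    Windows containing N never match.
    """
    motif = motif or default_ere_motif()
    pattern = pattern or ConsensusPattern()
    if motif.length != pattern.length:
        raise ValueError("motif and consensus pattern lengths differ")
    table = table or ScorePValueTable(motif, resolution)
    qfwd = table.qmatrix
    qrev = qfwd[::-1, ::-1]
    L = motif.length
    encoded: dict[str, np.ndarray] = {}
    hits: list[EREHit] = []
    for peak in peaks:
        if peak.chrom not in genome:
            raise ValueError(f"peak {peak.peak_id}: unknown chromosome {peak.chrom}")
        chrom_len = len(genome.sequences[peak.chrom])
        if flank is None:
            w_start, w_end = peak.start, peak.end
        else:
            w_start = peak.summit - flank // 2
            w_end = w_start + flank
        if w_start < 0 or w_end > chrom_len:
            logger.warning(
                "peak %s: scan window [%d,%d) clipped to chromosome bounds",
                peak.peak_id,
                w_start,
                w_end,
            )
            w_start, w_end = max(0, w_start), min(chrom_len, w_end)
        if peak.chrom not in encoded:
            encoded[peak.chrom] = encode(genome.sequences[peak.chrom])
        codes = encoded[peak.chrom][w_start:w_end]
        fwd, rev, mism_fwd, mism_rev, valid = _scan_window(codes, qfwd, qrev, pattern)
        if len(fwd) == 0:
            continue
        best = np.maximum(fwd, rev)
        strands = np.where(fwd >= rev, "+", "-")
        mism = np.where(strands == "+", mism_fwd, mism_rev)
        pvals = table.p_value(best)
        cand = valid & (pvals < p_threshold) & (mism <= pattern.max_mismatch)
        idx = np.nonzero(cand)[0]
        # greedy non-overlap: best p first, then higher score, then position
        order = idx[np.lexsort((idx, -best[idx], pvals[idx]))]
        taken: list[tuple[int, int]] = []
        for pos in order:
            s, e = int(pos), int(pos) + L
            if any(s < te and ts < e for ts, te in taken):
                continue
            taken.append((s, e))
            hits.append(
                EREHit(
                    peak_id=peak.peak_id,
                    chrom=peak.chrom,
                    start=w_start + s,
                    end=w_start + e,
                    strand=str(strands[pos]),
                    pwm_score=float(best[pos]) * table.resolution,
                    p_value=float(pvals[pos]),
                    mismatches=int(mism[pos]),
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.start, h.peak_id))
    return hits


def classify_sites(peaks: list[Peak], hits: list[EREHit]) -> SiteEREClassification:
    """Assign every peak a zero/one/multiple ERE class and tally the classes."""
    known = {p.peak_id for p in peaks}
    per_peak = {p.peak_id: 0 for p in peaks}
    for h in hits:
        if h.peak_id not in known:
            raise ValueError(f"hit references unknown peak {h.peak_id!r}")
        per_peak[h.peak_id] += 1
    n = Counter(
        "zero" if c == 0 else ("one" if c == 1 else "multiple")
        for c in per_peak.values()
    )
    return SiteEREClassification(
        per_peak=per_peak,
        n_zero=n.get("zero", 0),
        n_one=n.get("one", 0),
        n_multiple=n.get("multiple", 0),
    )


def reconstruct_motif(
    hits: list[EREHit],
    genome: GenomeSequence,
    pattern: ConsensusPattern | None = None,
    pseudocount: float = 0.1,
) -> tuple[CountMatrixMotif, dict[str, float]]:
    """Rebuild a count matrix from hit sequences in match orientation.

    Also returns the spacer composition: the frequency of each trinucleotide
    at the pattern's n-block positions (7-9 of the 15-mer for the default
    ERE consensus).
    """
    if not hits:
        raise ValueError("cannot reconstruct a motif from zero hits")
    pattern = pattern or ConsensusPattern()
    L = hits[0].end - hits[0].start
    counts = np.zeros((4, L))
    spacers: Counter[str] = Counter()
    sl = pattern.spacer_slice
    for h in hits:
        seq = genome.fetch(h.chrom, h.start, h.end)
        if h.strand == "-":
            seq = reverse_complement(seq)
        codes = encode(seq)
        for i, c in enumerate(codes):
            if c < 4:
                counts[c, i] += 1
        if sl.stop > sl.start:
            spacers[seq[sl]] += 1
    total = sum(spacers.values())
    spacer_freq = {k: v / total for k, v in sorted(spacers.items())}
    motif = CountMatrixMotif(
        counts=counts, pseudocount=pseudocount, name="reconstructed"
    )
    return motif, spacer_freq


def joint_tail_probability(
    motif: CountMatrixMotif,
    pattern: ConsensusPattern | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    resolution: float = DEFAULT_RESOLUTION,
) -> float:
    """Exact P(background window passes score AND mismatch criteria).

    Dynamic programme over (quantized score, capped mismatch count); used
    to audit how stringent the combined detection rule is per scanned
    window under the background model.
    """
    pattern = pattern or ConsensusPattern()
    table = ScorePValueTable(motif, resolution)
    thr = table.score_threshold(p_threshold)
    q = table.qmatrix
    bg = motif.background
    mm_cap = pattern.max_mismatch + 1
    span = table.max_int - table.min_int + 1
    dp = np.zeros((span, mm_cap + 1))
    dp[0, 0] = 1.0
    offset = 0
    for i in range(q.shape[1]):
        col_min = int(q[:, i].min())
        new = np.zeros_like(dp)
        informative = pattern.informative[i]
        cons = pattern.codes[i] if informative else -1
        for b in range(4):
            shift = int(q[b, i]) - col_min
            dm = 1 if (informative and b != cons) else 0
            src = dp[: span - shift if shift else span]
            if dm:
                new[shift:, 1:] += bg[b] * src[:, :-1]
                new[shift:, -1] += bg[b] * src[:, -1]
            else:
                new[shift:] += bg[b] * src
        dp = new
        offset += col_min
    pass_idx = max(0, thr - table.min_int)
    return float(dp[pass_idx:, :mm_cap].sum())
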