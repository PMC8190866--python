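import itertools

import numpy as np
import pytest

from eretarget.genome_io import GenomeSequence, Peak
from eretarget.ere_scan import (
    ERE_CONSENSUS,
    ConsensusPattern,
    CountMatrixMotif,
    ScorePValueTable,
    classify_sites,
    default_ere_motif,
    joint_tail_probability,
    mismatch_count,
    read_jaspar,
    reconstruct_motif,
    reverse_complement,
    scan_peaks,
    write_jaspar,
)

RNG = np.random.default_rng(97)
BASES = np.array(list("ACGT"))


def random_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, size=n)])


def enumeration_sf(motif, resolution=1e-3):
    """Exhaustive null score distribution: an independent oracle for the DP."""
    q = motif.quantized(resolution)
    scores = np.zeros(1, dtype=np.int64)
    for i in range(q.shape[1]):
        scores = (scores[:, None] + q[:, i][None, :]).ravel()
    return scores  # one entry per k-mer, uniform background


# ---------------------------------------------------------------- primitives


def test_reverse_complement():
    assert reverse_complement("AGGTCA") == "TGACCT"
    assert reverse_complement(ERE_CONSENSUS) == ERE_CONSENSUS  # palindrome
    seq = random_seq(50)
    assert reverse_complement(reverse_complement(seq)) == seq


def test_consensus_is_palindromic():
    pat = ConsensusPattern()
    assert pat.is_palindromic
    assert mismatch_count(ERE_CONSENSUS.upper().replace("N", "A")) == 0


def test_mismatch_count_spacer_free_and_n_penalized():
    assert mismatch_count("AGGTCAGGGTGACCT") == 0  # spacer differs: free
    assert mismatch_count("CGGTCAAAATGACCT") == 1
    assert mismatch_count("NGGTCAAAATGACCT") == 1  # N mismatches
    assert mismatch_count("AGGTCANNNTGACCT") == 0  # N in spacer: still free
    with pytest.raises(ValueError):
        mismatch_count("AGGTCA")


# ----------------------------------------------------------------- the motif


def test_default_motif_consensus_matches_ere():
    motif = default_ere_motif()
    assert motif.consensus == "AGGTCAAAATGACCT"[:6] + motif.consensus[6:9] + "TGACCT"
    assert motif.length == 15


def test_log_odds_formula_single_column():
    m = CountMatrixMotif(counts=np.array([[8.0], [0.0], [0.0], [0.0]]), pseudocount=0.1)
    expected_a = np.log2(((8 + 0.1 * 0.25) / 8.1) / 0.25)
    assert m.log_odds[0, 0] == pytest.approx(expected_a)
    expected_c = np.log2(((0 + 0.1 * 0.25) / 8.1) / 0.25)
    assert m.log_odds[1, 0] == pytest.approx(expected_c)


def test_motif_validation():
    with pytest.raises(ValueError):
        CountMatrixMotif(counts=np.array([[1.0, -1.0]] * 4))
    with pytest.raises(ValueError):
        CountMatrixMotif(counts=np.ones((3, 5)))
    with pytest.raises(ValueError):
        CountMatrixMotif(counts=np.ones((4, 2)), pseudocount=0.0)


def test_reverse_complement_motif_scores_mirror():
    counts = RNG.integers(0, 20, size=(4, 7)).astype(float)
    m = CountMatrixMotif(counts=counts)
    rc = m.reverse_complement()
    seq = random_seq(7)
    codes = "ACGT"
    fwd = sum(m.log_odds[codes.index(b), i] for i, b in enumerate(seq))
    rev = sum(
        rc.log_odds[codes.index(b), i] for i, b in enumerate(reverse_complement(seq))
    )
    assert fwd == pytest.approx(rev)


def test_jaspar_round_trip(tmp_path, ere_motif):
    path = tmp_path / "m.jaspar"
    write_jaspar(
        CountMatrixMotif(counts=np.rint(ere_motif.counts), name="ERE"), path
    )
    back = read_jaspar(path)
    assert np.allclose(back.counts, np.rint(ere_motif.counts))


def test_quantization_resolution_guard(ere_motif):
    with pytest.raises(ValueError):
        ere_motif.quantized(resolution=1e6)


# --------------------------------------------------------- exact p-value DP


def test_pvalue_table_monotone_and_bounds(ere_table):
    sf = ere_table.sf
    assert np.all(np.diff(sf) <= 1e-15)
    assert ere_table.p_value(ere_table.min_int) == pytest.approx(1.0)
    assert ere_table.p_value(ere_table.max_int) > 0


def test_pvalue_single_column_trivial():
    # one column, counts 8/4/2/2: quantized scores distinct, uniform background
    m = CountMatrixMotif(counts=np.array([[8.0], [4.0], [2.0], [1.0]]))
    # a single informative column plus a flat column to pass the collapse guard
    m2 = CountMatrixMotif(counts=np.hstack([m.counts, np.full((4, 1), 5.0)]))
    t = ScorePValueTable(m2)
    q = m2.quantized()
    best = int(q[:, 0].max() + q[:, 1].max())
    assert t.p_value(best) == pytest.approx(0.25)  # only base A attains it


@pytest.mark.parametrize("length", [2, 4])
def test_dp_matches_enumeration_small(length):
    counts = np.random.default_rng(length).integers(0, 30, size=(4, length)).astype(float)
    m = CountMatrixMotif(counts=counts)
    t = ScorePValueTable(m)
    scores = enumeration_sf(m)
    for s in np.unique(scores):
        exact = float(np.mean(scores >= s))
        assert t.p_value(int(s)) == pytest.approx(exact, rel=1e-9)


def test_score_threshold_semantics(ere_table):
    thr = ere_table.score_threshold(5e-4)
    assert ere_table.p_value(thr) < 5e-4
    assert ere_table.p_value(thr - 1) >= 5e-4


def test_as_mapping_consistent(ere_table):
    mapping = ere_table.as_mapping()
    probs = sorted(mapping.items())
    assert probs[0][1] == pytest.approx(1.0)
    values = [p for _, p in probs]
    assert all(a >= b for a, b in zip(values, values[1:]))


# -------------------------------------------------------------------- scanning


def plant(seq, pos, insert):
    return seq[:pos] + insert + seq[pos + len(insert):]


def test_scan_finds_planted_consensus(ere_motif):
    background = random_seq(600)
    ere = "AGGTCACAGTGACCT"
    seq = plant(background, 300, ere)
    genome = GenomeSequence({"chr1": seq})
    peaks = [Peak("p1", "chr1", 200, 401)]
    hits = scan_peaks(genome, peaks, ere_motif)
    assert any(h.start == 300 and h.end == 315 and h.mismatches == 0 for h in hits)


def test_scan_reverse_complement_site_is_found(ere_motif):
    # the full 15-mer including spacer, reverse complemented: still an ERE
    background = random_seq(600)
    seq = plant(background, 300, reverse_complement("AGGTCACAGTGACCT"))
    genome = GenomeSequence({"chr1": seq})
    hits = scan_peaks(genome, [Peak("p1", "chr1", 200, 401)], ere_motif)
    assert any(h.start == 300 and h.mismatches == 0 for h in hits)


def test_scan_reports_minus_strand_for_asymmetric_motif():
    counts = np.zeros((4, 6))
    for i, b in enumerate("AGGTCA"):
        counts["ACGT".index(b), i] = 20.0
    motif = CountMatrixMotif(counts=counts)
    pattern = ConsensusPattern(pattern="AGGTCA", max_mismatch=1)
    background = random_seq(200)
    seq = plant(background, 100, "TGACCT")  # reverse complement of the motif
    genome = GenomeSequence({"chr1": seq})
    hits = scan_peaks(
        genome, [Peak("p1", "chr1", 50, 151)], motif, pattern=pattern, flank=None
    )
    assert any(h.start == 100 and h.strand == "-" for h in hits)


def test_scan_window_with_n_never_matches(ere_motif):
    seq = plant(random_seq(600), 300, "AGGTCACNGTGACCT")  # N inside the site
    genome = GenomeSequence({"chr1": seq})
    hits = scan_peaks(genome, [Peak("p1", "chr1", 200, 401)], ere_motif)
    assert not any(h.start == 300 for h in hits)


def test_scan_resolves_overlapping_candidates(ere_motif):
    # two EREs 8 bp apart: overlapping windows, only compatible subset kept
    seq = plant(random_seq(600), 300, "AGGTCACAGTGACCTCCAGGTCATTTTGACCT")
    genome = GenomeSequence({"chr1": seq})
    hits = scan_peaks(genome, [Peak("p1", "chr1", 200, 451)], ere_motif)
    spans = sorted((h.start, h.end) for h in hits)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2  # non-overlapping


def test_scan_clips_window_at_chromosome_edge(ere_motif):
    seq = plant(random_seq(300), 10, "AGGTCACAGTGACCT")
    genome = GenomeSequence({"chr1": seq})
    hits = scan_peaks(genome, [Peak("p1", "chr1", 0, 61)], ere_motif)
    assert any(h.start == 10 for h in hits)


def test_scan_unknown_chromosome_errors(ere_motif):
    genome = GenomeSequence({"chr1": random_seq(100)})
    with pytest.raises(ValueError):
        scan_peaks(genome, [Peak("p1", "chrX", 0, 50)], ere_motif, flank=None)


def test_scan_on_random_background_is_quiet(ere_motif):
    """Expected hit count on motif-free sequence is ~0 (joint FP audit)."""
    rng = np.random.default_rng(5)
    seq = "".join(BASES[rng.integers(0, 4, size=200_000)])
    genome = GenomeSequence({"chr1": seq})
    peaks = [
        Peak(f"p{i}", "chr1", s, s + 201)
        for i, s in enumerate(range(100, 199_500, 500))
    ]
    hits = scan_peaks(genome, peaks, ere_motif)
    cls = classify_sites(peaks, hits)
    assert cls.fraction_with_ere < 0.05


def test_joint_tail_probability_is_stringent(ere_motif):
    # per-window pass probability under background: the basis of the <5%
    # false-site guarantee for ~500 scanned windows per peak
    assert 0 < joint_tail_probability(ere_motif) < 1e-4


# ------------------------------------------------------------- classification


def test_classify_sites_counts(ere_motif):
    peaks = [Peak(p, "chr1", i * 1000, i * 1000 + 201) for i, p in enumerate("abc")]
    hits = scan_peaks(
        GenomeSequence(
            {
                "chr1": plant(
                    plant(random_seq(3000), 1050, "AGGTCACAGTGACCT"),
                    2020,
                    "AGGTCAAAATGACCTGG" + "AGGTCATTTTGACCT",
                )
            }
        ),
        peaks,
        ere_motif,
    )
    cls = classify_sites(peaks, hits)
    assert cls.per_peak["a"] == 0
    assert cls.per_peak["b"] == 1
    assert cls.per_peak["c"] == 2
    assert (cls.n_zero, cls.n_one, cls.n_multiple) == (1, 1, 1)
    assert cls.peak_class("c") == "multiple"
    assert cls.fraction_with_ere == pytest.approx(2 / 3)


def test_classify_sites_unknown_peak_errors(ere_motif):
    from eretarget.ere_scan import EREHit

    hit = EREHit("ghost", "chr1", 0, 15, "+", 10.0, 1e-5, 0)
    with pytest.raises(ValueError):
        classify_sites([Peak("a", "chr1", 0, 100)], [hit])


def test_reconstruct_motif_recovers_consensus(ere_motif):
    rng = np.random.default_rng(3)
    pieces, peaks, pos = [], [], 0
    for i in range(40):
        bg = "".join(BASES[rng.integers(0, 4, size=400)])
        site = "AGGTCA" + "CTG" + "TGACCT"
        seq = bg[:200] + site + bg[215:]
        peaks.append(Peak(f"p{i}", "chr1", pos + 100, pos + 301))
        pieces.append(seq)
        pos += 400
    genome = GenomeSequence({"chr1": "".join(pieces)})
    hits = scan_peaks(genome, peaks, ere_motif)
    rebuilt, spacer_freq = reconstruct_motif(hits, genome)
    assert rebuilt.consensus[:6] == "AGGTCA"
    assert rebuilt.consensus[9:] == "TGACCT"
    assert max(spacer_freq, key=spacer_freq.get) == "CTG"
    with pytest.raises(ValueError):
        reconstruct_motif([], genome)
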