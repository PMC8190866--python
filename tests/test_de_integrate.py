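import math
from itertools import combinations

import pandas as pd
import pytest

from eretarget.de_integrate import (
    DERecord,
    call_de,
    call_direct_targets,
    enrich,
    read_de_table,
    responsive_genes,
)
from eretarget.ere_scan import SiteEREClassification
from eretarget.genome_io import GeneModel, Peak


def rec(gene_id, biotype, effect, fdr):
    return DERecord(gene_id, biotype, effect, fdr)


# ------------------------------------------------------------------ DE calling


@pytest.mark.parametrize(
    "effect,fdr,direction",
    [
        (1.0, 0.05, "up"),       # both boundaries inclusive
        (0.999, 0.05, "ns"),
        (1.0, 0.051, "ns"),
        (-1.0, 0.05, "down"),
        (-0.999, 0.05, "ns"),
        (3.0, 0.04, "up"),
    ],
)
def test_mrna_thresholds(effect, fdr, direction):
    (called,) = call_de([rec("g", "mRNA", effect, fdr)])
    assert called.direction == direction


@pytest.mark.parametrize(
    "fc,fdr,direction",
    [
        (1.5, 0.05, "up"),       # inclusive
        (1.499, 0.05, "ns"),
        (0.667, 0.05, "down"),   # inclusive
        (0.668, 0.05, "ns"),
        (1.5, 0.0501, "ns"),
        (5.0, 0.01, "up"),
    ],
)
def test_mirna_thresholds(fc, fdr, direction):
    (called,) = call_de([rec("m", "miRNA", fc, fdr)])
    assert called.direction == direction


def test_mirna_nonpositive_fold_change_errors():
    with pytest.raises(ValueError):
        call_de([rec("m", "miRNA", 0.0, 0.01)])


def test_call_de_partitions_and_is_idempotent():
    records = [rec(f"g{i}", "mRNA", e, f) for i, (e, f) in enumerate(
        [(2, 0.01), (-2, 0.01), (0.5, 0.01), (2, 0.5)]
    )]
    called = call_de(records)
    assert [r.direction for r in called] == ["up", "down", "ns", "ns"]
    assert [r.direction for r in call_de(called)] == ["up", "down", "ns", "ns"]
    assert responsive_genes(called) == {"g0", "g1"}


def test_read_de_table(tmp_path):
    path = tmp_path / "de.tsv"
    path.write_text("gene_id\tbiotype\teffect\tfdr\ng1\tmRNA\t2.5\t0.01\n")
    (r,) = read_de_table(path)
    assert (r.gene_id, r.biotype, r.effect, r.fdr) == ("g1", "mRNA", 2.5, 0.01)
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene_id\teffect\ng1\t2.5\n")
    with pytest.raises(ValueError):
        read_de_table(bad)


# ------------------------------------------------------------- direct targets


def classification(per_peak):
    n = list(per_peak.values())
    return SiteEREClassification(
        per_peak=per_peak,
        n_zero=sum(v == 0 for v in n),
        n_one=sum(v == 1 for v in n),
        n_multiple=sum(v > 1 for v in n),
    )


def target_scene(summit, strand="+", ere=1):
    """One DE gene with TSS at 100_000 (+) and one peak at the given summit."""
    if strand == "+":
        gene = GeneModel("g", "chr1", "+", [100_000], 100_000, 103_000, "protein_coding")
    else:
        gene = GeneModel("g", "chr1", "-", [102_999], 100_000, 103_000, "protein_coding")
    peak = Peak("p", "chr1", summit - 100, summit + 101, summit=summit)
    de = call_de([rec("g", "mRNA", 2.0, 0.01)])
    return de, [peak], classification({"p": ere}), [gene]


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("distance,called", [(0, True), (49_999, True), (50_000, False)])
def test_upstream_distance_rule_is_strict_at_50kb(strand, distance, called):
    tss = 100_000 if strand == "+" else 102_999
    summit = tss - distance if strand == "+" else tss + distance
    calls = call_direct_targets(*target_scene(summit, strand))
    assert bool(calls) is called
    if called:
        assert calls[0].min_upstream_distance == distance


def test_downstream_peak_never_supports():
    calls = call_direct_targets(*target_scene(100_001))
    assert calls == []


def test_ere_requirement():
    args = target_scene(90_000, ere=0)
    assert call_direct_targets(*args) == []
    assert len(call_direct_targets(*args, require_ere=False)) == 1


def test_multi_tss_takes_min_distance():
    gene = GeneModel("g", "chr1", "+", [100_000, 101_000], 100_000, 103_000, "protein_coding")
    peak = Peak("p", "chr1", 99_400, 99_601, summit=99_500)
    de = call_de([rec("g", "mRNA", 2.0, 0.01)])
    (call,) = call_direct_targets(de, [peak], classification({"p": 1}), [gene])
    assert call.min_upstream_distance == 500
    assert call.n_ere_in_support == 1


def test_unknown_gene_and_missing_classification_error():
    de, peaks, cls, genes = target_scene(90_000)
    with pytest.raises(ValueError):
        call_direct_targets(de, peaks, cls, [])
    with pytest.raises(ValueError):
        call_direct_targets(de, peaks, classification({}), genes)


def test_non_responsive_genes_are_never_targets():
    de, peaks, cls, genes = target_scene(90_000)
    ns = call_de([rec("g", "mRNA", 0.2, 0.9)])
    assert call_direct_targets(ns, peaks, cls, genes) == []


# ---------------------------------------------------------------- enrichment


def term_table(assignments):
    return pd.DataFrame(
        [(t, g) for t, genes in assignments.items() for g in genes],
        columns=["term_id", "gene_id"],
    )


def test_fold_enrichment_worked_example():
    universe = {f"g{i}" for i in range(1000)}
    term_genes = [f"g{i}" for i in range(50)]
    de = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(900, 905)}
    (res,) = enrich(de, term_table({"T": term_genes}), universe=universe)
    assert (res.k, res.n, res.K, res.N) == (5, 10, 50, 1000)
    assert res.fold_enrichment == pytest.approx(10.0)
    assert 0 < res.p_value < 1e-4


def exhaustive_hypergeom_p(k, N, K, n):
    """P(X >= k) by direct summation — independent oracle for small N."""
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
        for j in range(k, min(K, n) + 1)
    )


def test_hypergeometric_matches_exhaustive_oracle_n20():
    universe = {f"g{i}" for i in range(20)}
    term_genes = [f"g{i}" for i in range(8)]  # K = 8
    de = {f"g{i}" for i in range(4, 10)}      # n = 6, k = 4
    (res,) = enrich(de, term_table({"T": term_genes}), universe=universe)
    assert res.p_value == pytest.approx(exhaustive_hypergeom_p(4, 20, 8, 6), rel=1e-12)


def test_bh_qvalues_monotone_in_p():
    universe = {f"g{i}" for i in range(100)}
    terms = {f"T{j}": [f"g{i}" for i in range(j, j + 20)] for j in range(0, 60, 10)}
    de = {f"g{i}" for i in range(10)}
    results = enrich(de, term_table(terms), universe=universe)
    by_p = sorted(results, key=lambda r: r.p_value)
    qs = [r.q_value for r in by_p]
    assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
    assert all(r.q_value >= r.p_value - 1e-12 for r in results)


def test_de_gene_outside_universe_errors():
    with pytest.raises(ValueError):
        enrich({"ghost"}, term_table({"T": ["g1"]}), universe={"g1"})


def test_empty_term_skipped(caplog):
    universe = {"g1", "g2"}
    table = term_table({"T1": ["g1"], "T2": ["zz"]})  # T2 outside universe
    results = enrich({"g1"}, table, universe=universe)
    assert [r.term_id for r in results] == ["T1"]
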