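"""Peak filtering, strand-aware gene assignment, motif scan, direct regulon."""

import logging

import pytest

from regulonflow import GeneAnnotation, OperonMap, Peak
from regulonflow.binding import (
    MotifSpec,
    assign_peaks,
    classify_peak,
    direct_regulon,
    filter_peaks,
    reverse_complement,
    scan_motif,
)
from regulonflow.regulons import Regulon

from conftest import make_peak
from oracles import brute_force_classify, brute_force_filter, brute_force_scan


def random_peaks(rng, n=100, contig_len=20000):
    peaks = []
    for i in range(n):
        summit = int(rng.integers(100, contig_len - 100))
        peaks.append(Peak("chr", summit - 50, summit + 51, summit,
                          float(rng.uniform(0.5, 10.0)),
                          float(rng.uniform(0.0, 0.2)), name=f"p{i}"))
    return peaks


# ---------------------------------------------------------------- filtering

def test_fold_enrichment_cutoff_is_strict():
    assert filter_peaks([make_peak(500, fe=2.0, q=0.01)]) == []
    assert len(filter_peaks([make_peak(500, fe=2.0001, q=0.01)])) == 1


def test_q_cutoff_is_inclusive():
    assert filter_peaks([make_peak(500, fe=3.5, q=0.06)]) == []
    assert len(filter_peaks([make_peak(500, fe=3.5, q=0.05)])) == 1


def test_filter_matches_brute_force_and_preserves_order(rng):
    peaks = random_peaks(rng)
    assert filter_peaks(peaks) == brute_force_filter(peaks)


# ---------------------------------------------------------------- classify

def test_summit_inside_gene_is_genic(two_plus_genes):
    assert classify_peak(make_peak(1500), two_plus_genes) == "genic"


def test_summit_between_genes_is_intergenic(two_plus_genes):
    assert classify_peak(make_peak(2500), two_plus_genes) == "intergenic"


def test_classification_matches_brute_force(rng):
    genes = [GeneAnnotation(f"g{i}", "chr", 1 + i * 1200 + 300, i * 1200 + 1200,
                            "+" if i % 2 else "-") for i in range(15)]
    for peak in random_peaks(rng, n=60, contig_len=15 * 1200):
        assert classify_peak(peak, genes) == brute_force_classify(peak, genes)


# ---------------------------------------------------------------- assignment

def test_intergenic_summit_upstream_of_plus_gene_only(two_plus_genes):
    # both genes on '+': the gap is downstream of geneA, upstream of geneB
    assignments = assign_peaks([make_peak(2500, name="pk")], two_plus_genes)
    assert set(assignments) == {"geneB"}
    assert assignments["geneB"].evidence == {("pk", "upstream")}


def test_divergent_genes_share_the_upstream_summit():
    genes = [GeneAnnotation("geneA", "chr", 1001, 2000, "-"),
             GeneAnnotation("geneB", "chr", 3001, 4000, "+")]
    assignments = assign_peaks([make_peak(2500, name="pk")], genes)
    assert set(assignments) == {"geneA", "geneB"}


def test_convergent_genes_get_no_upstream_evidence():
    genes = [GeneAnnotation("geneA", "chr", 1001, 2000, "+"),
             GeneAnnotation("geneB", "chr", 3001, 4000, "-")]
    assert assign_peaks([make_peak(2500)], genes) == {}


def test_summit_inside_gene_gives_in_gene_evidence(two_plus_genes):
    assignments = assign_peaks([make_peak(1200, name="pk")], two_plus_genes)
    assert assignments["geneA"].evidence == {("pk", "in_gene")}


def test_upstream_cap_truncates_assignment(two_plus_genes):
    # summit at 0-based 2499 = 1-based 2500; geneB starts at 3001 -> 501 bp away
    assignments = assign_peaks([make_peak(2499)], two_plus_genes, upstream_cap=500)
    assert assignments == {}
    assignments = assign_peaks([make_peak(2499)], two_plus_genes, upstream_cap=501)
    assert set(assignments) == {"geneB"}


def test_operon_evidence_propagates_and_names_partner(two_plus_genes):
    operons = OperonMap({"op1": ["geneB", "geneC"]})
    assignments = assign_peaks([make_peak(2500, name="pk")], two_plus_genes, operons)
    assert assignments["geneC"].evidence == {("pk", "operon", "geneB")}
    assert not assignments["geneC"].has_direct
    # closure soundness: the named partner carries direct evidence
    assert assignments["geneB"].has_direct


def test_peak_on_unknown_contig_is_skipped_with_warning(two_plus_genes, caplog):
    with caplog.at_level(logging.WARNING, logger="regulonflow"):
        assignments = assign_peaks([make_peak(500, contig="plasmid")], two_plus_genes)
    assert assignments == {}
    assert "plasmid" in caplog.text


def test_no_peaks_give_empty_assignment(two_plus_genes):
    assert assign_peaks([], two_plus_genes) == {}


# ---------------------------------------------------------------- motif scan

def test_consensus_hit_is_found_at_expected_position():
    # TTAA + GCTGCTA (7-mer spacer) + TTAAC starting at position 0
    hits = scan_motif("TTAAGCTGCTATTAAC", both_strands=False)
    assert hits == [(0, "+")]


def test_homopolymer_has_no_hits():
    assert scan_motif("A" * 200) == []


def test_n_matches_spacer_but_not_halfsites():
    motif = MotifSpec("TTAA", 7, "TTAAC")
    assert scan_motif("TTAA" + "N" * 7 + "TTAAC", motif, both_strands=False) \
        == [(0, "+")]
    assert scan_motif("TTAN" + "A" * 7 + "TTAAC", motif, both_strands=False) == []


def test_reverse_complement_flips_strand_and_preserves_count(rng):
    bases = "ACGT"
    seq = "TTAAGCTGCTATTAAC" + "".join(
        bases[i] for i in rng.integers(0, 4, size=200)) + "TTAACCCCCCCTTAAC"
    rc = reverse_complement(seq)
    hits_fwd = scan_motif(seq)
    hits_rc = scan_motif(rc)
    assert len(hits_fwd) == len(hits_rc)
    w = len(MotifSpec("TTAA", 7, "TTAAC"))
    flipped = sorted((len(seq) - p - w, {"+": "-", "-": "+"}[s])
                     for p, s in hits_fwd)
    assert flipped == hits_rc


def test_scan_matches_brute_force_double_strand(rng):
    bases = "ACGTN"
    motif = MotifSpec("TTAA", 7, "TTAAC")
    for _ in range(10):
        seq = "".join(bases[i] for i in rng.integers(0, 5, size=300))
        seq = seq[:40] + "TTAAGCTGCTATTAAC" + seq[56:]  # ensure some signal
        assert scan_motif(seq, motif) == brute_force_scan(seq, motif)


def test_overlapping_hits_are_all_reported():
    motif = MotifSpec("AA", 1, "AA")
    hits = scan_motif("AAAAAAA", motif, both_strands=False)
    assert [p for p, _ in hits] == [0, 1, 2]


# ---------------------------------------------------------------- direct regulon

def _assignments(genes, mode="upstream"):
    from regulonflow.binding import BindingAssignment

    return {g: BindingAssignment(g, {(f"pk_{g}", mode)}) for g in genes}


def test_disjoint_regulon_and_binding_give_empty_direct():
    total = Regulon("total", {"g1", "g2"})
    assert len(direct_regulon(total, _assignments({"g3"}))) == 0


def test_total_subset_of_bound_gives_direct_equal_total():
    total = Regulon("total", {"g1", "g2"})
    direct = direct_regulon(total, _assignments({"g1", "g2", "g3"}))
    assert direct.members == total.members


def test_direct_regulon_is_subset_and_monotone(rng):
    genes = [f"g{i}" for i in range(40)]
    for _ in range(10):
        reg = set(rng.choice(genes, size=20, replace=False))
        bound = set(rng.choice(genes, size=15, replace=False))
        small = direct_regulon(Regulon("t", reg), _assignments(bound))
        assert small.members <= reg
        grown = direct_regulon(Regulon("t", reg | {"g99"}),
                               _assignments(bound | {"g99"}))
        assert small.members <= grown.members


def test_direct_vs_operon_binding_provenance_split():
    from regulonflow.binding import BindingAssignment

    total = Regulon("total", {"g1", "g2"})
    assignments = {
        "g1": BindingAssignment("g1", {("pk", "in_gene")}),
        "g2": BindingAssignment("g2", {("pk", "operon", "g1")}),
    }
    direct = direct_regulon(total, assignments)
    assert direct.provenance == {"g1": "direct", "g2": "operon"}


def test_planted_upstream_peaks_recover_exact_gene_set():
    # ten '+' genes in a row; plant peaks upstream of a chosen subset
    genes = [GeneAnnotation(f"g{i}", "chr", i * 2000 + 501, i * 2000 + 1500, "+")
             for i in range(10)]
    chosen = {"g2", "g5", "g7"}
    peaks = [make_peak(i * 2000 + 250, name=f"pk{i}")
             for i in (2, 5, 7)]
    assignments = assign_peaks(peaks, genes)
    assert set(assignments) == chosen
    assert all(assignments[g].has_direct for g in chosen)
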