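"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity by direct enumeration or via an
unrelated library code path, never by calling the implementation under test.
"""

import numpy as np
from scipy import stats as sps


def paired_t_oracle(mutant, wildtype, pseudocount=1.0):
    """(log2fc, p) via scipy's paired t-test on log2-transformed values."""
    m = np.log2(np.asarray(mutant, float) + pseudocount)
    w = np.log2(np.asarray(wildtype, float) + pseudocount)
    res = sps.ttest_rel(m, w)
    return float(np.mean(m - w)), float(res.pvalue)


def brute_force_filter(peaks, min_fe=2.0, max_q=0.05):
    out = []
    for p in peaks:
        keep = True
        if not (p.fold_enrichment > min_fe):
            keep = False
        if not (p.q_value <= max_q):
            keep = False
        if keep:
            out.append(p)
    return out


def brute_force_classify(peak, genes):
    pos = peak.summit + 1  # 1-based
    for g in genes:
        if g.contig != peak.contig:
            continue
        inside = False
        for coord in range(g.start, g.end + 1):
            if coord == pos:
                inside = True
                break
        if inside:
            return "genic"
    return "intergenic"


def _matches_at(seq, pos, motif):
    pat = motif.left_halfsite + "." * motif.spacer_length + motif.right_halfsite
    if pos + len(pat) > len(seq):
        return False
    for off, want in enumerate(pat):
        got = seq[pos + off]
        if want == ".":
            continue
        if got != want:
            return False
    return True


def brute_force_scan(seq, motif):
    """Double-strand scan by per-position character comparison."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(seq))
    hits = []
    for pos in range(len(seq)):
        if _matches_at(seq, pos, motif):
            hits.append((pos, "+"))
        if _matches_at(rc, pos, motif):
            hits.append((len(seq) - pos - len(motif), "-"))
    return sorted(hits)


def brute_force_flow(edges, node_sets, direct, universe):
    """Flow percentages by explicit per-gene membership counting."""
    nodes = set(node_sets)
    nD = sum(1 for g in universe if g in direct)

    def pct(count):
        return 100.0 * count / nD

    node_input = {}
    for n in nodes:
        count = sum(1 for g in universe if g in node_sets[n] and g in direct)
        node_input[n] = pct(count)
    edge_flux = {}
    for (u, v) in edges:
        count = sum(1 for g in universe
                    if g in node_sets[u] and g in node_sets[v] and g in direct)
        edge_flux[(u, v)] = pct(count)
    missing = {}
    for n in nodes:
        preds = [u for (u, v) in edges if v == n]
        if not preds:
            continue
        count = 0
        for g in universe:
            if g in node_sets[n] and g in direct:
                if not any(g in node_sets[p] for p in preds):
                    count += 1
        missing[n] = pct(count)
    return node_input, edge_flux, missing
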