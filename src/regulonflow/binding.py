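"""ChIP peak filtering, peak-to-gene assignment and the direct regulon.

A peak is assigned to a gene by its summit: a summit inside a gene gives
``in_gene`` evidence; a summit in an intergenic interval gives ``upstream``
evidence to each flanking gene whose 5' end faces the interval (so a summit
between divergently transcribed genes hits both, and one between convergent
genes hits neither).  Binding evidence then propagates to all co-operonic
genes (``operon`` evidence).  Intersecting the bound gene set with a node's
expression regulon yields the *direct* regulon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import GeneAnnotation, OperonMap, Peak, ValidationError
from .regulons import Regulon

logger = logging.getLogger("regulonflow")

__all__ = [
    "BindingAssignment",
    "MotifSpec",
    "filter_peaks",
    "assign_peaks",
    "classify_peak",
    "scan_motif",
    "direct_regulon",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifSpec:
    """Two half-sites separated by a fixed-length arbitrary spacer."""

    left_halfsite: str
    spacer_length: int
    right_halfsite: str

    def __post_init__(self):
        for hs in (self.left_halfsite, self.right_halfsite):
            if not hs or set(hs) - set("ACGT"):
                raise ValidationError(f"half-site {hs!r} must be non-empty over ACGT")
        if self.spacer_length < 0:
            raise ValidationError("spacer_length must be >= 0")

    def __len__(self) -> int:
        return len(self.left_halfsite) + self.spacer_length + len(self.right_halfsite)


#: Consensus bound by the master cell-cycle regulator: TTAA-N7-TTAAC.
CTRA_MOTIF = MotifSpec("TTAA", 7, "TTAAC")


@dataclass
class BindingAssignment:
    """Binding evidence for one gene: (peak name, mode[, operon partner])."""

    gene_id: str
    evidence: set = field(default_factory=set)

    def modes(self) -> set[str]:
        return {mode for _, mode, *_ in self.evidence}

    @property
    def has_direct(self) -> bool:
        return bool(self.modes() & {"upstream", "in_gene"})


# ---------------------------------------------------------------------------
# Peak filtering and classification
# ---------------------------------------------------------------------------

def filter_peaks(peaks: Sequence[Peak], min_fold_enrichment: float = 2.0,
                 max_q: float = 0.05) -> list[Peak]:
    """Retain peaks with fold enrichment strictly above the cutoff and q <= max_q."""
    return [p for p in peaks
            if p.fold_enrichment > min_fold_enrichment and p.q_value <= max_q]


def classify_peak(peak: Peak, annotation: Sequence[GeneAnnotation]) -> str:
    """``genic`` iff the summit falls within any gene's [start, end]; else ``intergenic``.

    Gene coordinates are 1-based inclusive; the summit is 0-based, so base
    ``summit`` corresponds to 1-based position ``summit + 1``.
    """
    pos = peak.summit + 1
    for g in annotation:
        if g.contig == peak.contig and g.start <= pos <= g.end:
            return "genic"
    return "intergenic"


# ---------------------------------------------------------------------------
# Peak -> gene assignment
# ---------------------------------------------------------------------------

def _peak_name(peak: Peak, index: int) -> str:
    return peak.name or f"peak_{index}"


def assign_peaks(peaks: Sequence[Peak], annotation: Sequence[GeneAnnotation],
                 operons: OperonMap | None = None,
                 upstream_cap: int | None = None) -> dict[str, BindingAssignment]:
    """Assign filtered peaks to genes by summit position.

    Returns a mapping gene_id -> :class:`BindingAssignment`.  ``upstream``
    evidence is strand-aware: an intergenic summit belongs to the upstream
    region of the right-flanking gene when that gene is on '+', and of the
    left-flanking gene when that gene is on '-'.  ``upstream_cap`` bounds
    the summit-to-5'-end distance (in bp) when set.  Operon evidence
    propagates from any gene with direct evidence to its co-operonic genes,
    naming the partner that carries the direct evidence.
    """
    operons = operons or OperonMap.empty()
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_contig.setdefault(g.contig, []).append(g)
    for genes in by_contig.values():
        genes.sort(key=lambda g: (g.start, g.end))

    assignments: dict[str, BindingAssignment] = {}

    def add(gene: str, peak_ref: str, mode: str, partner: str | None = None):
        a = assignments.setdefault(gene, BindingAssignment(gene))
        a.evidence.add((peak_ref, mode) if partner is None else (peak_ref, mode, partner))

    for i, peak in enumerate(peaks):
        name = _peak_name(peak, i)
        genes = by_contig.get(peak.contig)
        if genes is None:
            logger.warning("peak %s on contig %r absent from annotation; skipped",
                           name, peak.contig)
            continue
        pos = peak.summit + 1  # 1-based
        hits = [g for g in genes if g.start <= pos <= g.end]
        if hits:
            for g in hits:
                add(g.locus_tag, name, "in_gene")
            continue
        # intergenic: nearest flanking genes
        left = None
        right = None
        for g in genes:
            if g.end < pos:
                if left is None or g.end > left.end:
                    left = g
            elif g.start > pos:
                if right is None or g.start < right.start:
                    right = g
        if left is not None and left.strand == "-":
            if upstream_cap is None or (pos - left.end) <= upstream_cap:
                add(left.locus_tag, name, "upstream")
        if right is not None and right.strand == "+":
            if upstream_cap is None or (right.start - pos) <= upstream_cap:
                add(right.locus_tag, name, "upstream")

    # operon propagation from direct evidence
    direct_genes = [g for g, a in assignments.items() if a.has_direct]
    for g in direct_genes:
        for partner in operons.members(g):
            if partner == g:
                continue
            for peak_ref, mode, *_ in list(assignments[g].evidence):
                if mode in ("upstream", "in_gene"):
                    add(partner, peak_ref, "operon", partner=g)
    return assignments


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_one_strand(seq: str, motif: MotifSpec) -> list[int]:
    # N in the sequence never matches a half-site base; the spacer is free.
    pattern = (re.escape(motif.left_halfsite)
               + "[ACGTN]{%d}" % motif.spacer_length
               + re.escape(motif.right_halfsite))
    return [m.start() for m in re.finditer(f"(?=({pattern}))", seq)]


def scan_motif(sequence: str, motif: MotifSpec = CTRA_MOTIF,
               both_strands: bool = True) -> list[tuple[int, str]]:
    """All motif occurrences; minus-strand hits in forward coordinates.

    Returns (start, strand) pairs, sorted by position, where start is the
    0-based position of the leftmost base of the match on the forward
    strand.  Overlapping matches are all reported.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValidationError("sequence must be over {A,C,G,T,N}")
    hits = [(pos, "+") for pos in _scan_one_strand(seq, motif)]
    if both_strands:
        rc = reverse_complement(seq)
        L = len(seq)
        w = len(motif)
        hits += [(L - pos - w, "-") for pos in _scan_one_strand(rc, motif)]
    return sorted(hits)


# ---------------------------------------------------------------------------
# Direct regulon
# ---------------------------------------------------------------------------

def direct_regulon(total_regulon: Regulon,
                   assignments: Mapping[str, BindingAssignment],
                   name: str = "direct") -> Regulon:
    """Intersect a (operon-augmented) regulon with the bound gene set.

    Provenance records whether the binding evidence is ``direct`` (a peak
    upstream of or inside the gene itself) or ``operon`` (mediated by a
    co-operonic partner with direct evidence).
    """
    members = total_regulon.members & set(assignments)
    provenance = {
        g: ("direct" if assignments[g].has_direct else "operon") for g in members
    }
    stats = {g: total_regulon.stats[g] for g in members if g in total_regulon.stats}
    return Regulon(name, members, provenance, stats)
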