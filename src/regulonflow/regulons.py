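"""Differential expression statistics and regulon calling.

A *regulon* is the set of genes whose expression responds to perturbing a
pathway node.  Differential statistics come from paired replicate contrasts
(mutant vs wild type): the per-gene log2 fold change is the mean of the
per-replicate-pair log ratios, and the p-value is a two-sided paired t-test
on per-pair log2 values.  A threshold policy (abundance, fold change,
significance) then defines regulon membership; genes co-operonic with a
differential gene can be added as operon-augmented members.

Two policy presets reflect the two perturbation designs:

* ``depletion`` contrasts (conditional shutoff of an essential gene, strong
  effects): |log2FC| >= 1.3, p <= 0.05, operon augmentation on.
* ``deletion`` contrasts (clean knockout, weak effects): |log2FC| >= 0.5,
  p <= 0.25, operon augmentation off.

In both, genes whose RPKM never exceeds 25 across the contrast are excluded.
Tie rules: fold-change threshold inclusive (>=), abundance strict (>),
p threshold inclusive (<=).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import stats as sps

from .io import ExpressionTable, OperonMap, ValidationError

__all__ = [
    "ThresholdPolicy",
    "DifferentialRecord",
    "Regulon",
    "compute_differential",
    "call_regulon",
    "union_regulon",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Filters that turn differential statistics into regulon membership."""

    min_rpkm: float = 25.0
    min_abs_log2fc: float = 1.3
    max_p: float = 0.05
    apply_p_filter: bool = True
    apply_operon_augmentation: bool = True

    def __post_init__(self):
        if self.min_rpkm < 0:
            raise ValidationError("min_rpkm must be >= 0")
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if not (0 < self.max_p <= 1):
            raise ValidationError("max_p must be in (0, 1]")

    @classmethod
    def depletion(cls, **overrides) -> "ThresholdPolicy":
        """Strong-effect contrasts: 1.3 log2FC, p <= 0.05, operons on."""
        return replace(cls(), **overrides)

    @classmethod
    def deletion(cls, **overrides) -> "ThresholdPolicy":
        """Weak-effect contrasts: 0.5 log2FC, p <= 0.25, operons off."""
        return replace(cls(min_abs_log2fc=0.5, max_p=0.25,
                           apply_operon_augmentation=False), **overrides)

    def without_p_filter(self) -> "ThresholdPolicy":
        return replace(self, apply_p_filter=False)


@dataclass
class DifferentialRecord:
    """Per-gene differential statistics for one contrast."""

    gene_id: str
    log2fc: float
    p_value: float
    max_rpkm: float
    pass_abundance: bool = False
    pass_fc: bool = False
    pass_p: bool = False

    def apply_policy(self, policy: ThresholdPolicy) -> "DifferentialRecord":
        self.pass_abundance = self.max_rpkm > policy.min_rpkm
        self.pass_fc = abs(self.log2fc) >= policy.min_abs_log2fc
        self.pass_p = (not policy.apply_p_filter) or (self.p_value <= policy.max_p)
        return self

    @property
    def passes(self) -> bool:
        return self.pass_abundance and self.pass_fc and self.pass_p


@dataclass
class Regulon:
    """A node's gene set with per-gene provenance.

    Provenance tags: ``differential`` for genes passing the thresholds,
    ``operon`` for operon-augmented members (and, for direct regulons built
    by :func:`regulonflow.binding.direct_regulon`, ``direct`` vs ``operon``
    binding evidence).
    """

    node: str
    members: set[str]
    provenance: dict[str, str] = field(default_factory=dict)
    stats: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        self.members = set(self.members)
        for g in self.members:
            self.provenance.setdefault(g, "differential")
        extra = set(self.provenance) - self.members
        for g in extra:
            del self.provenance[g]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def tagged(self, tag: str) -> set[str]:
        return {g for g, t in self.provenance.items() if t == tag}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Regulon):
            return NotImplemented
        return (self.node == other.node and self.members == other.members
                and self.provenance == other.provenance)


# ---------------------------------------------------------------------------
# Differential statistics
# ---------------------------------------------------------------------------

def _paired_t_pvalues(diffs: np.ndarray) -> np.ndarray:
    """Two-sided paired-t p-values for each row of per-pair differences.

    Degenerate rows (zero variance across pairs) use the limit behaviour of
    the t statistic: all differences equal and nonzero -> p = 0; all zero
    -> p = 1.
    """
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    p = np.empty(len(diffs))
    zero_var = sd == 0
    p[zero_var & (mean != 0)] = 0.0
    p[zero_var & (mean == 0)] = 1.0
    ok = ~zero_var
    if ok.any():
        t = mean[ok] / (sd[ok] / math.sqrt(n))
        p[ok] = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    return p


def compute_differential(table: ExpressionTable,
                         contrast: tuple[str, str],
                         pseudocount: float = 1.0,
                         require_p: bool = True) -> list[DifferentialRecord]:
    """Per-gene log2 fold changes and paired-t p-values for one contrast.

    Parameters
    ----------
    contrast
        ``(mutant_condition, wildtype_condition)``.  Replicate indices must
        match between the two conditions (paired design).
    pseudocount
        Added to RPKM before the log2 transform; tolerates zeros.
    require_p
        With fewer than 2 replicate pairs a p-value is undefined; raise
        unless this is False (then p is reported as NaN).
    """
    mutant, wildtype = contrast
    for cond in contrast:
        if cond not in table.conditions:
            raise ValidationError(f"condition {cond!r} not present in table")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    reps_m = table.replicates(mutant)
    reps_w = table.replicates(wildtype)
    if reps_m != reps_w:
        raise ValidationError(
            f"replicate sets differ between conditions: {reps_m} vs {reps_w}")
    n_pairs = len(reps_m)
    m = table.condition_values(mutant).to_numpy(dtype=float)
    w = table.condition_values(wildtype).to_numpy(dtype=float)

    log_m = np.log2(m + pseudocount)
    log_w = np.log2(w + pseudocount)
    diffs = log_m - log_w
    log2fc = diffs.mean(axis=1)
    if n_pairs < 2:
        if require_p:
            raise ValidationError(
                "fewer than 2 replicate pairs: paired-t p-value undefined "
                "(pass require_p=False to proceed without p-values)")
        p = np.full(len(log2fc), np.nan)
    else:
        p = _paired_t_pvalues(diffs)
    max_rpkm = np.maximum(m.max(axis=1), w.max(axis=1))

    return [
        DifferentialRecord(gene, float(fc), float(pv), float(mr))
        for gene, fc, pv, mr in zip(table.genes, log2fc, p, max_rpkm)
    ]


# ---------------------------------------------------------------------------
# Regulon calling
# ---------------------------------------------------------------------------

def call_regulon(records: Iterable[DifferentialRecord],
                 policy: ThresholdPolicy,
                 operons: OperonMap | None = None,
                 node: str = "node") -> Regulon:
    """Apply a threshold policy to differential records; augment by operon.

    Differential members pass all enabled filters; with augmentation on,
    every gene sharing an operon with a differential member joins with the
    ``operon`` tag.  Idempotent: re-calling on the same records and policy
    returns the same regulon.
    """
    operons = operons or OperonMap.empty()
    records = list(records)
    stats = {r.gene_id: {"log2fc": r.log2fc, "p_value": r.p_value,
                         "max_rpkm": r.max_rpkm} for r in records}
    differential = {r.gene_id for r in records if r.apply_policy(policy).passes}
    provenance = {g: "differential" for g in differential}
    members = set(differential)
    if policy.apply_operon_augmentation:
        for g in differential:
            for partner in operons.members(g):
                if partner not in members:
                    members.add(partner)
                    provenance[partner] = "operon"
    kept_stats = {g: stats[g] for g in members if g in stats}
    return Regulon(node, members, provenance, kept_stats)


def union_regulon(a: Regulon, b: Regulon, name: str) -> Regulon:
    """Set union of two regulons; 'differential' wins over 'operon' on conflict."""
    members = a.members | b.members
    provenance: dict[str, str] = {}
    for g in members:
        tags = {r.provenance[g] for r in (a, b) if g in r.members}
        provenance[g] = "differential" if "differential" in tags else sorted(tags)[0]
    stats = {**b.stats, **a.stats}
    stats = {g: v for g, v in stats.items() if g in members}
    return Regulon(name, members, provenance, stats)
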