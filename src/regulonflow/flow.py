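"""Information-flow quantification through a signaling DAG by regulon overlap.

With D the direct (sink) regulon, normalized to 100%:

* node input:      input(X)   = 100 * |R_X ∩ D| / |D|
* edge flux:       flux(X→Y)  = 100 * |R_X ∩ R_Y ∩ D| / |D|
* missing input:   miss(Y)    = 100 * |(R_Y ∩ D) \\ ∪_pred R_X| / |D|

All percentages count genes, so they are multiples of 100/|D|; the gene
lists behind every number are retained for audit.  Because a gene can sit
in several predecessors' regulons, the per-edge fluxes into a node can sum
to more than its input.  A node whose observed signal is not covered by its
modeled predecessors (missing input > 0) marks the attachment point of an
unidentified upstream factor — the "leaky pipeline" readout.

Declared hidden intermediates (nodes without a measured regulon) get the
set-algebra regulon (∪ predecessors' regulons) ∩ (∪ successors' regulons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import PathwayGraph, ValidationError
from .regulons import DifferentialRecord, Regulon, ThresholdPolicy, call_regulon

__all__ = [
    "FlowResult",
    "overlap_fraction",
    "quantify_flow",
    "infer_hidden_inputs",
    "build_flux_regulons",
]


class UndefinedOverlapError(ValidationError):
    """Overlap against an empty denominator set is undefined."""


@dataclass
class FlowResult:
    """Per-node input, per-edge flux and per-node missing input (percent of D)."""

    reference_size: int
    node_input_pct: dict[str, float]
    edge_flux_pct: dict[tuple[str, str], float]
    missing_input_pct: dict[str, float]
    node_input_genes: dict[str, set[str]] = field(default_factory=dict)
    edge_flux_genes: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    missing_input_genes: dict[str, set[str]] = field(default_factory=dict)
    hidden_nodes: list[tuple[str, float]] = field(default_factory=list)

    def summary(self) -> dict:
        """Percentages rounded to the nearest integer (full precision is kept)."""
        return {
            "reference_size": self.reference_size,
            "node_input_pct": {k: round(v) for k, v in self.node_input_pct.items()},
            "edge_flux_pct": {f"{u}->{v}": round(p)
                              for (u, v), p in self.edge_flux_pct.items()},
            "missing_input_pct": {k: round(v)
                                  for k, v in self.missing_input_pct.items()},
        }


def overlap_fraction(a: Regulon, b: Regulon,
                     denominator: str = "first") -> tuple[float, set[str]]:
    """Percentage overlap of two regulons, with the shared member list.

    ``denominator`` selects the reference set: ``first`` (the subject
    regulon a, the default reading of "a shows X% overlap with b"),
    ``second``, or ``union``.
    """
    inter = a.members & b.members
    if denominator == "first":
        denom = a.members
    elif denominator == "second":
        denom = b.members
    elif denominator == "union":
        denom = a.members | b.members
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    if not denom:
        raise UndefinedOverlapError("overlap denominator set is empty")
    return 100.0 * len(inter) / len(denom), inter


def _hidden_regulon(pathway: PathwayGraph, node: str,
                    regulons: dict[str, Regulon]) -> Regulon:
    pred_union: set[str] = set()
    for p in pathway.predecessors(node):
        pred_union |= regulons[p].members
    succ_union: set[str] = set()
    for s in pathway.successors(node):
        if s in regulons:
            succ_union |= regulons[s].members
    return Regulon(node, pred_union & succ_union,
                   {g: "inferred" for g in pred_union & succ_union})


def quantify_flow(pathway: PathwayGraph, regulons: Mapping[str, Regulon],
                  direct: Regulon) -> FlowResult:
    """Quantify signal flow toward the sink, normalized to the direct regulon.

    Every non-hidden node needs an entry in ``regulons``; declared hidden
    nodes get the neighbor set-algebra regulon.  Hidden regulons are
    resolved in reverse topological order so a hidden node's successors
    (closer to the sink) are available first.
    """
    D = set(direct.members)
    if not D:
        raise ValidationError("direct regulon is empty")
    resolved: dict[str, Regulon] = {}
    order = pathway.topological_order()
    for node in reversed(order):
        if pathway.is_hidden(node):
            continue
        if node not in regulons:
            raise ValidationError(f"node {node!r} has no regulon")
        resolved[node] = regulons[node]
    for node in reversed(order):
        if pathway.is_hidden(node):
            resolved[node] = _hidden_regulon(pathway, node, resolved)

    nD = len(D)
    node_input_pct: dict[str, float] = {}
    node_input_genes: dict[str, set[str]] = {}
    for node in order:
        genes = resolved[node].members & D
        node_input_genes[node] = genes
        node_input_pct[node] = 100.0 * len(genes) / nD

    edge_flux_pct: dict[tuple[str, str], float] = {}
    edge_flux_genes: dict[tuple[str, str], set[str]] = {}
    for (u, v) in pathway.edges:
        genes = resolved[u].members & resolved[v].members & D
        edge_flux_genes[(u, v)] = genes
        edge_flux_pct[(u, v)] = 100.0 * len(genes) / nD

    missing_input_pct: dict[str, float] = {}
    missing_input_genes: dict[str, set[str]] = {}
    for node in order:
        preds = pathway.predecessors(node)
        if not preds:
            continue  # undefined/omitted for source nodes
        covered: set[str] = set()
        for p in preds:
            covered |= resolved[p].members
        genes = (resolved[node].members & D) - covered
        missing_input_genes[node] = genes
        missing_input_pct[node] = 100.0 * len(genes) / nD

    hidden_nodes = [(n, pct) for n, pct in sorted(missing_input_pct.items()) if pct > 0]
    return FlowResult(nD, node_input_pct, edge_flux_pct, missing_input_pct,
                      node_input_genes, edge_flux_genes, missing_input_genes,
                      hidden_nodes)


def infer_hidden_inputs(pathway: PathwayGraph, flow: FlowResult,
                        threshold_pct: float = 0.0) -> PathwayGraph:
    """Attach a hidden input node wherever missing input exceeds the threshold.

    Each node Y with miss(Y) > threshold gains a node ``missing_Y`` with an
    edge into Y; naming is deterministic.
    """
    if threshold_pct < 0:
        raise ValidationError("threshold_pct must be >= 0")
    nodes = [(n, pathway.regulon_source(n), pathway.is_hidden(n))
             for n in pathway.nodes]
    edges = list(pathway.edges)
    for node in sorted(flow.missing_input_pct):
        pct = flow.missing_input_pct[node]
        if pct > threshold_pct:
            hid = f"missing_{node}"
            nodes.append((hid, None, True))
            edges.append((hid, node))
    return PathwayGraph(nodes, edges, pathway.sink)


def build_flux_regulons(records_by_node: Mapping[str, Iterable[DifferentialRecord]],
                        modes: Mapping[str, str],
                        operons=None,
                        policies: Mapping[str, ThresholdPolicy] | None = None,
                        ) -> dict[str, Regulon]:
    """Regulons as used for the flux analysis.

    Deletion-mutant nodes contribute weak signals, so their flux regulons
    drop the p-value filter (fold change and abundance only); depletion
    nodes keep the full strict policy with operon augmentation.  ``modes``
    maps node -> ``"deletion"`` or ``"depletion"``; ``policies`` can
    override the preset per node (the p filter is still dropped for
    deletion nodes).
    """
    policies = policies or {}
    out: dict[str, Regulon] = {}
    for node, records in records_by_node.items():
        mode = modes[node]
        if mode == "deletion":
            policy = policies.get(node, ThresholdPolicy.deletion()).without_p_filter()
        elif mode == "depletion":
            policy = policies.get(node, ThresholdPolicy.depletion())
        else:
            raise ValidationError(f"node {node!r}: unknown mode {mode!r}")
        out[node] = call_regulon(records, policy, operons, node=node)
    return out
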