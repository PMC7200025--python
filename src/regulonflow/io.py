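"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* ChIP peaks use 0-based, half-open coordinates internally (BED convention).
  One-based tabular inputs are converted at the read boundary.
* Gene annotations use 1-based, inclusive coordinates (GFF3 convention).
* TSV is the canonical tabular dialect.  Decimal commas are rejected.
* Unknown extra columns are carried through untouched on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("regulonflow")

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionTable",
    "GeneAnnotation",
    "Peak",
    "OperonMap",
    "PathwayGraph",
    "read_expression_table",
    "write_expression_table",
    "read_peak_table",
    "write_peak_table",
    "read_annotation",
    "write_annotation",
    "read_operon_table",
    "write_operon_table",
    "read_pathway_config",
    "write_pathway_config",
    "read_fasta",
    "read_regulon_table",
    "write_regulon_table",
    "read_flow_table",
    "write_flow_outputs",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect (missing columns...)."""


class ValidationError(ValueError):
    """A file parses, but its contents violate a domain invariant."""


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

class ExpressionTable:
    """Rectangular table of RPKM values: genes x (condition, replicate).

    Wraps a wide :class:`pandas.DataFrame` whose index is ``gene_id`` and
    whose columns are a ``(condition, replicate)`` MultiIndex with integer
    replicate indices starting at 1.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 2:
            raise ValidationError("expression data needs (condition, replicate) columns")
        if data.isna().any().any():
            missing = data.stack(future_stack=True)
            missing = missing[missing.isna()]
            raise ValidationError(
                f"expression table is not rectangular; first missing cell: "
                f"{missing.index[0]}"
            )
        neg = data.lt(0)
        if neg.any().any():
            gene = data.index[neg.any(axis=1)][0]
            raise ValidationError(f"negative rpkm for gene {gene!r}")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        data = data.copy()
        data.columns = pd.MultiIndex.from_tuples(
            [(str(c), int(r)) for c, r in data.columns],
            names=["condition", "replicate"],
        )
        data.index.name = "gene_id"
        self.data = data.sort_index(axis=1)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ExpressionTable":
        required = {"gene_id", "condition", "replicate", "rpkm"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(sorted(missing))}")
        extra = set(df.columns) - required
        if extra:
            logger.warning("ignoring unknown expression columns: %s", sorted(extra))
        wide = df.pivot_table(
            index="gene_id", columns=["condition", "replicate"], values="rpkm",
            aggfunc="first",
        )
        return cls(wide)

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data.columns.get_level_values(0).unique())

    def replicates(self, condition: str) -> list[int]:
        if condition not in self.data.columns.get_level_values(0):
            raise KeyError(f"condition {condition!r} not in table")
        return sorted(self.data[condition].columns)

    def condition_values(self, condition: str) -> pd.DataFrame:
        """Genes x replicates matrix for one condition."""
        return self.data[condition]

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack(["condition", "replicate"], future_stack=True)
        long.name = "rpkm"
        return long.reset_index()[["gene_id", "condition", "replicate", "rpkm"]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        return self.data.sort_index().equals(other.data.sort_index())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_samples = self.data.shape[1]
        return f"ExpressionTable({len(self.genes)} genes, {n_samples} samples)"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", **kwargs)
    # decimal-comma locales produce object columns like "1,5"; reject early
    for col in df.columns:
        if df[col].dtype == object and df[col].astype(str).str.fullmatch(r"-?\d+,\d+").any():
            raise FormatError(f"column {col!r} uses decimal commas; expected '.'")
    return df


def read_expression_table(path: str | Path, dialect: str = "long") -> ExpressionTable:
    """Read an RPKM table.

    ``long`` dialect: columns gene_id, condition, replicate, rpkm.
    ``wide`` dialect: gene_id column followed by ``condition:replicate`` columns.
    """
    if dialect not in ("long", "wide"):
        raise FormatError(f"unknown expression dialect {dialect!r}")
    df = _read_tsv(path)
    if dialect == "long":
        return ExpressionTable.from_long(df)
    if "gene_id" not in df.columns:
        raise FormatError("missing required column(s): gene_id")
    df = df.set_index("gene_id")
    cols = []
    for col in df.columns:
        if ":" not in col:
            raise FormatError(f"wide column {col!r} is not 'condition:replicate'")
        cond, rep = col.rsplit(":", 1)
        cols.append((cond, int(rep)))
    df.columns = pd.MultiIndex.from_tuples(cols)
    return ExpressionTable(df)


def write_expression_table(table: ExpressionTable, path: str | Path,
                           dialect: str = "long") -> None:
    if dialect == "long":
        table.to_long().to_csv(path, sep="\t", index=False)
    elif dialect == "wide":
        wide = table.data.copy()
        wide.columns = [f"{c}:{r}" for c, r in wide.columns]
        wide.to_csv(path, sep="\t")
    else:
        raise FormatError(f"unknown expression dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gene annotation (GFF3, 1-based inclusive)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """One gene: 1-based inclusive coordinates, strand '+' or '-'."""
    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.locus_tag}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.locus_tag}: bad strand {self.strand!r}")


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        tag = feat.attributes.get("locus_tag", feat.attributes.get("ID", [feat.id]))[0]
        if tag in seen:
            raise ValidationError(f"duplicate locus_tag {tag!r}")
        seen.add(tag)
        genes.append(GeneAnnotation(tag, feat.seqid, feat.start, feat.end, feat.strand))
    return sorted(genes, key=lambda g: (g.contig, g.start))


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path,
                     source: str = "regulonflow") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.locus_tag};locus_tag={g.locus_tag}\n"
            )


# ---------------------------------------------------------------------------
# ChIP peaks (0-based half-open)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """A called ChIP peak. 0-based half-open [start, end); summit absolute."""
    contig: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    q_value: float
    name: str = ""
    extra: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.name or self.contig}: start {self.start} >= end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.name or self.contig}: summit {self.summit} outside "
                f"[{self.start}, {self.end})")
        if self.fold_enrichment <= 0:
            raise ValidationError("fold_enrichment must be positive")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(f"q_value {self.q_value} outside [0, 1]")


_TABULAR_REQUIRED = ("start", "end", "summit", "fold_enrichment", "q_value")


def read_peak_table(path: str | Path, dialect: str = "tabular") -> list[Peak]:
    """Read peaks.

    ``tabular``: named columns contig, start, end, summit, fold_enrichment,
    q_value in **1-based inclusive** coordinates, converted on read.
    ``bed6plus``: BED6 (0-based half-open) plus three extra columns
    fold_enrichment, q_value, summit_offset (relative to start); the BED
    score column is unused.
    """
    if dialect == "tabular":
        df = _read_tsv(path)
        missing = [c for c in _TABULAR_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        peaks = []
        for row in df.itertuples(index=False):
            peaks.append(Peak(
                contig=str(getattr(row, "contig", "chr")),
                start=int(row.start) - 1,          # 1-based -> 0-based
                end=int(row.end),                  # inclusive -> half-open
                summit=int(row.summit) - 1,
                fold_enrichment=float(row.fold_enrichment),
                q_value=float(row.q_value),
                name=str(getattr(row, "name", "")),
            ))
        return peaks
    if dialect == "bed6plus":
        names = ["contig", "start", "end", "name", "score", "strand",
                 "fold_enrichment", "q_value", "summit_offset"]
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                         skip_blank_lines=True)
        peaks = []
        for row in df.itertuples(index=False):
            peaks.append(Peak(
                contig=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                summit=int(row.start) + int(row.summit_offset),
                fold_enrichment=float(row.fold_enrichment),
                q_value=float(row.q_value),
                name="" if pd.isna(row.name) or row.name == "." else str(row.name),
            ))
        return peaks
    raise FormatError(f"unknown peak dialect {dialect!r}")


def write_peak_table(peaks: Sequence[Peak], path: str | Path,
                     dialect: str = "tabular") -> None:
    if dialect == "tabular":
        rows = [{
            "contig": p.contig,
            "start": p.start + 1,      # back to 1-based inclusive
            "end": p.end,
            "summit": p.summit + 1,
            "fold_enrichment": p.fold_enrichment,
            "q_value": p.q_value,
            "name": p.name,
        } for p in peaks]
        pd.DataFrame(rows, columns=["contig", "start", "end", "summit",
                                    "fold_enrichment", "q_value", "name"]
                     ).to_csv(path, sep="\t", index=False)
    elif dialect == "bed6plus":
        with open(path, "w") as fh:
            for p in peaks:
                fh.write("\t".join(map(str, [
                    p.contig, p.start, p.end, p.name or ".", 0, ".",
                    p.fold_enrichment, p.q_value, p.summit - p.start])) + "\n")
    else:
        raise FormatError(f"unknown peak dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Operons
# ---------------------------------------------------------------------------

class OperonMap:
    """Partition of (a subset of) genes into operons of >= 2 genes."""

    def __init__(self, operons: Mapping[str, Sequence[str]]):
        self.operons: dict[str, list[str]] = {}
        gene_to_operon: dict[str, str] = {}
        for op_id, members in operons.items():
            members = [str(m) for m in members]
            if len(members) < 2:
                raise ValidationError(f"operon {op_id!r} has fewer than 2 genes")
            for g in members:
                if g in gene_to_operon:
                    raise ValidationError(
                        f"gene {g!r} listed in operons {gene_to_operon[g]!r} and {op_id!r}")
                gene_to_operon[g] = str(op_id)
            self.operons[str(op_id)] = members
        self._gene_to_operon = gene_to_operon

    def operon_of(self, gene: str) -> str | None:
        return self._gene_to_operon.get(gene)

    def members(self, gene: str) -> list[str]:
        """All genes sharing an operon with *gene* (including itself)."""
        op = self._gene_to_operon.get(gene)
        return list(self.operons[op]) if op else [gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_to_operon

    def __len__(self) -> int:
        return len(self.operons)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OperonMap):
            return NotImplemented
        return self.operons == other.operons

    @classmethod
    def empty(cls) -> "OperonMap":
        return cls({})


def read_operon_table(path: str | Path) -> OperonMap:
    """Two-column TSV: operon_id <tab> comma-separated locus tags."""
    operons: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("operon_id\t"):
                continue
            try:
                op_id, genes = line.split("\t")
            except ValueError as exc:
                raise FormatError(f"bad operon line: {line!r}") from exc
            operons[op_id] = [g.strip() for g in genes.split(",") if g.strip()]
    return OperonMap(operons)


def write_operon_table(operons: OperonMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tgenes\n")
        for op_id in sorted(operons.operons):
            fh.write(f"{op_id}\t{','.join(operons.operons[op_id])}\n")


# ---------------------------------------------------------------------------
# Pathway graph
# ---------------------------------------------------------------------------

class PathwayGraph:
    """The signaling DAG: named nodes, directed edges, one sink.

    Node attributes: ``regulon_source`` (key naming where the node's regulon
    comes from; optional) and ``hidden`` (declared intermediate without a
    measured regulon).
    """

    def __init__(self, nodes: Iterable[tuple[str, str | None, bool]],
                 edges: Iterable[tuple[str, str]], sink: str):
        g = nx.DiGraph()
        for name, source, hidden in nodes:
            g.add_node(name, regulon_source=source, hidden=bool(hidden))
        for u, v in edges:
            for n in (u, v):
                if n not in g:
                    raise ValidationError(f"edge references unknown node {n!r}")
            g.add_edge(u, v)
        if sink not in g:
            raise ValidationError(f"sink {sink!r} is not a declared node")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join([u for u, _ in cycle] + [cycle[0][0]])
            raise ValidationError(f"pathway is not a DAG; cycle: {path}")
        self.graph = g
        self.sink = sink

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def is_hidden(self, node: str) -> bool:
        return bool(self.graph.nodes[node].get("hidden", False))

    def regulon_source(self, node: str) -> str | None:
        return self.graph.nodes[node].get("regulon_source")

    def predecessors(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    def successors(self, node: str) -> list[str]:
        return sorted(self.graph.successors(node))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(
            [(n, self.regulon_source(n), self.is_hidden(n)) for n in self.nodes],
            self.edges, self.sink)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return (self.sink == other.sink
                and set(self.edges) == set(other.edges)
                and {n: (self.regulon_source(n), self.is_hidden(n)) for n in self.nodes}
                == {n: (other.regulon_source(n), other.is_hidden(n)) for n in other.nodes})


def read_pathway_config(path: str | Path) -> PathwayGraph:
    """Read a pathway from a YAML config with keys nodes, edges, sink."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return pathway_from_dict(cfg)


def pathway_from_dict(cfg: Mapping) -> PathwayGraph:
    for key in ("nodes", "edges", "sink"):
        if key not in cfg:
            raise FormatError(f"pathway config missing key {key!r}")
    nodes = []
    for entry in cfg["nodes"]:
        if isinstance(entry, str):
            nodes.append((entry, None, False))
        else:
            nodes.append((entry["name"], entry.get("regulon"),
                          bool(entry.get("hidden", False))))
    edges = [(u, v) for u, v in cfg["edges"]]
    return PathwayGraph(nodes, edges, cfg["sink"])


def write_pathway_config(pathway: PathwayGraph, path: str | Path) -> None:
    cfg = {
        "nodes": [
            {"name": n,
             **({"regulon": pathway.regulon_source(n)} if pathway.regulon_source(n) else {}),
             **({"hidden": True} if pathway.is_hidden(n) else {})}
            for n in pathway.nodes
        ],
        "edges": [list(e) for e in pathway.edges],
        "sink": pathway.sink,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences (uppercased) keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Regulon tables
# ---------------------------------------------------------------------------

def write_regulon_table(regulon, path: str | Path) -> None:
    """Serialize a Regulon as TSV: node, gene_id, provenance, statistics."""
    rows = []
    for gene in sorted(regulon.members):
        stats = regulon.stats.get(gene, {})
        rows.append({
            "node": regulon.node,
            "gene_id": gene,
            "provenance": regulon.provenance[gene],
            "log2fc": stats.get("log2fc", ""),
            "p_value": stats.get("p_value", ""),
            "max_rpkm": stats.get("max_rpkm", ""),
        })
    pd.DataFrame(rows, columns=["node", "gene_id", "provenance", "log2fc",
                                "p_value", "max_rpkm"]).to_csv(path, sep="\t", index=False)


def read_regulon_table(path: str | Path):
    from .regulons import Regulon

    df = _read_tsv(path, dtype={"gene_id": str})
    if df.empty:
        raise FormatError(f"empty regulon table {path}")
    node = str(df["node"].iloc[0])
    provenance = dict(zip(df["gene_id"], df["provenance"]))
    stats = {}
    for row in df.itertuples(index=False):
        entry = {}
        for key in ("log2fc", "p_value", "max_rpkm"):
            val = getattr(row, key, None)
            if val is not None and not pd.isna(val) and val != "":
                entry[key] = float(val)
        if entry:
            stats[row.gene_id] = entry
    return Regulon(node, set(df["gene_id"]), provenance, stats)


# ---------------------------------------------------------------------------
# Flow outputs
# ---------------------------------------------------------------------------

def write_flow_outputs(flow_result, tsv_path: str | Path,
                       dot_path: str | Path | None = None) -> None:
    """Write a FlowResult as a TSV of percentages and a DOT diagram.

    DOT edge labels carry the flux percentage; pen widths are proportional
    to flux.  Hidden-input nodes are emitted wherever missing input > 0.
    """
    rows = [{"kind": "reference", "item": "direct_regulon",
             "pct": 100.0, "genes": flow_result.reference_size}]
    for node in sorted(flow_result.node_input_pct):
        rows.append({"kind": "node_input", "item": node,
                     "pct": flow_result.node_input_pct[node],
                     "genes": len(flow_result.node_input_genes[node])})
    for (u, v) in sorted(flow_result.edge_flux_pct):
        rows.append({"kind": "edge_flux", "item": f"{u}->{v}",
                     "pct": flow_result.edge_flux_pct[(u, v)],
                     "genes": len(flow_result.edge_flux_genes[(u, v)])})
    for node in sorted(flow_result.missing_input_pct):
        rows.append({"kind": "missing_input", "item": node,
                     "pct": flow_result.missing_input_pct[node],
                     "genes": len(flow_result.missing_input_genes[node])})
    pd.DataFrame(rows, columns=["kind", "item", "pct", "genes"]).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.10g")

    if dot_path is None:
        return
    lines = ["digraph flow {", '  rankdir=TB;', '  node [shape=box];']
    for node in sorted(flow_result.node_input_pct):
        pct = flow_result.node_input_pct[node]
        lines.append(f'  "{node}" [label="{node}\\n{pct:.0f}%"];')
    for (u, v), pct in sorted(flow_result.edge_flux_pct.items()):
        width = max(0.2, 6.0 * pct / 100.0)
        lines.append(
            f'  "{u}" -> "{v}" [label="{pct:.0f}%", penwidth={width:.2f}];')
    for node, pct in sorted(flow_result.missing_input_pct.items()):
        if pct > 0:
            hid = f"missing_{node}"
            width = max(0.2, 6.0 * pct / 100.0)
            lines.append(f'  "{hid}" [shape=oval, style=dashed, '
                         f'label="?\\n{pct:.0f}%"];')
            lines.append(f'  "{hid}" -> "{node}" [style=dashed, '
                         f'label="{pct:.0f}%", penwidth={width:.2f}];')
    lines.append("}")
    Path(dot_path).write_text("\n".join(lines) + "\n")


def read_flow_table(path: str | Path) -> dict:
    """Re-read a flow TSV into {kind: {item: pct}} for round-trip checks."""
    df = _read_tsv(path)
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.kind, {})[row.item] = float(row.pct)
    return out
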