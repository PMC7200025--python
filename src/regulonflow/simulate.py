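"""Seedable generator of complete synthetic cascade datasets.

The generator plants a ground-truth signal flow on a pathway DAG and then
emits every file the analysis pipeline consumes: per-contrast RPKM tables,
a ChIP peak table with decoys, a GFF3 annotation, an operon table and the
pathway config — plus the planted truth for parameter-recovery tests.

Generative model
----------------
Membership of the direct (sink) regulon D is drawn *backward* from the
sink: a gene observed at node Y entered there exogenously with probability
``node_exogenous_fraction[Y]``; otherwise, for every predecessor edge X→Y
it was carried via X with probability ``edge_transmission[(X, Y)]``,
independently per edge and per gene.  A gene carried by X is part of X's
true regulon; genes at Y carried by no predecessor constitute Y's missing
input.  This makes the recovered flux on an edge a binomial count over |D|
with success probability equal to the planted transmission, which is the
quantity the flow analysis estimates.

Each node's measured regulon additionally contains off-pathway target
genes (signal that never reaches the sink), drawn disjointly from D and
from all ChIP-bound genes so that the noiseless pipeline recovers the
planted sets exactly.

Expression is simulated at the gene level (the pipeline consumes
normalized tables): per-gene baselines are log-normal, perturbing a node
shifts the log2 mean of every gene in its true regulon by a signed effect,
deletion contrasts are scaled-down (weak) versions of depletion contrasts,
and replicates add log2-scale Gaussian noise.

The default genome is a single contig of 900 bp genes separated by 300 bp
gaps on alternating strands; each even/odd gene pair shares a divergent
intergenic gap, so a planted upstream peak also hits the divergent partner
(bound-but-not-regulated genes, as real ChIP data shows).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .flow import FlowResult
from .io import (
    ExpressionTable,
    GeneAnnotation,
    OperonMap,
    PathwayGraph,
    Peak,
    ValidationError,
    write_annotation,
    write_expression_table,
    write_operon_table,
    write_pathway_config,
    write_peak_table,
)
from .stability import DecayDataset

__all__ = [
    "CascadeSimConfig",
    "SyntheticTruth",
    "SimulatedDataset",
    "default_pathway",
    "simulate_cascade",
    "simulate_decay",
    "write_dataset",
]

GENE_LENGTH = 900
GAP_LENGTH = 300
SPACING = GENE_LENGTH + GAP_LENGTH
CONTIG = "chr"


def default_pathway() -> PathwayGraph:
    """The two-component cascade: DivJ/PleC -> DivK -> DivL -> CckA -> ChpT -> sink."""
    nodes = [(n, n, False)
             for n in ("DivJ", "PleC", "DivK", "DivL", "CckA", "ChpT", "CtrA")]
    edges = [("DivJ", "DivK"), ("PleC", "DivK"), ("DivK", "DivL"),
             ("DivL", "CckA"), ("CckA", "ChpT"), ("ChpT", "CtrA")]
    return PathwayGraph(nodes, edges, "CtrA")


_DEFAULT_MODES = {"DivJ": "deletion", "PleC": "deletion", "DivK": "deletion",
                  "DivL": "depletion", "CckA": "depletion", "ChpT": "depletion"}

# Leak structure representative of the study: a small unexplained input into
# DivK, a dominant one into DivL and a modest one into ChpT.
_DEFAULT_EXOGENOUS = {"DivK": 0.01, "DivL": 0.44, "CckA": 0.0, "ChpT": 0.10,
                      "CtrA": 0.0}
_DEFAULT_TRANSMISSION = {("DivJ", "DivK"): 0.5, ("PleC", "DivK"): 0.55,
                         ("DivK", "DivL"): 0.5, ("DivL", "CckA"): 1.0,
                         ("CckA", "ChpT"): 0.9, ("ChpT", "CtrA"): 1.0}


@dataclass(frozen=True)
class CascadeSimConfig:
    """Generative parameters.  Defaults emulate the study design: a ~90-gene
    direct regulon in a ~3,500-gene genome, two biological replicates,
    weak-effect deletions of the upstream kinases and strong-effect
    depletions of the essential downstream components."""

    n_genes: int = 3500
    direct_regulon_size: int = 90
    pathway: PathwayGraph | None = None
    edge_transmission: Mapping[tuple[str, str], float] | None = None
    node_exogenous_fraction: Mapping[str, float] | None = None
    node_modes: Mapping[str, str] | None = None
    total_nodes: tuple[str, ...] | None = None
    effect_log2_mean: float = 2.5
    effect_log2_sd: float = 0.7
    deletion_effect_scale: float = 0.35
    replicate_noise_sd: float = 0.1
    n_replicates: int = 2
    baseline_log_rpkm_mean: float = 7.0
    baseline_log_rpkm_sd: float = 1.5
    decoy_peak_count: int = 130
    operon_gene_fraction: float = 0.35
    off_target_ratio: float = 2.0
    seed: int = 0

    def resolve(self) -> "CascadeSimConfig":
        """Fill in pathway-dependent defaults and validate."""
        pw = self.pathway or default_pathway()
        trans = dict(_DEFAULT_TRANSMISSION if self.edge_transmission is None
                     else self.edge_transmission)
        exo = dict(_DEFAULT_EXOGENOUS if self.node_exogenous_fraction is None
                   else self.node_exogenous_fraction)
        modes = dict(_DEFAULT_MODES if self.node_modes is None else self.node_modes)
        for e in pw.edges:
            trans.setdefault(tuple(e), 1.0)
        for n in pw.nodes:
            exo.setdefault(n, 0.0)
            if n != pw.sink and not pw.is_hidden(n):
                modes.setdefault(n, "depletion")
        total = self.total_nodes
        if total is None:
            total = tuple(sorted(pw.predecessors(pw.sink)))
            # extend one level up when the sink has a single feeder chain
            extended = set(total)
            for n in total:
                extended |= {p for p in pw.predecessors(n)
                             if modes.get(p) == "depletion"}
            total = tuple(sorted(extended))
        cfg = replace(self, pathway=pw, edge_transmission=trans,
                      node_exogenous_fraction=exo, node_modes=modes,
                      total_nodes=tuple(total))
        if cfg.direct_regulon_size > cfg.n_genes:
            raise ValidationError("direct regulon larger than genome")
        if cfg.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        for e, p in trans.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"transmission {e}: {p} outside [0,1]")
        for n, f in exo.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"exogenous fraction {n}: {f} outside [0,1]")
        return cfg


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated cascade."""

    direct: set[str]
    carried: dict[str, set[str]]            # node -> sink-reaching genes at node
    exogenous: dict[str, set[str]]          # node -> genes entering there
    transmitted: dict[tuple[str, str], set[str]]
    off_pathway: dict[str, set[str]]
    true_regulons: dict[str, set[str]]      # carried ∪ off-pathway, per node
    bound_genes: set[str]                   # genes with planted binding evidence
    flow: FlowResult


@dataclass
class SimulatedDataset:
    """In-memory counterpart of the files the simulator writes."""

    expression: dict[str, ExpressionTable]  # node -> contrast table (wt vs mutant)
    contrasts: dict[str, tuple[str, str]]   # node -> (mutant cond, wt cond)
    peaks: list[Peak]
    annotation: list[GeneAnnotation]
    operons: OperonMap
    pathway: PathwayGraph
    modes: dict[str, str]
    total_nodes: tuple[str, ...]


# ---------------------------------------------------------------------------
# genome geometry
# ---------------------------------------------------------------------------

def _gene_name(i: int) -> str:
    return f"g{i:05d}"


def _make_annotation(n_genes: int) -> list[GeneAnnotation]:
    genes = []
    for i in range(1, n_genes + 1):
        start = (i - 1) * SPACING + GAP_LENGTH + 1
        strand = "+" if i % 2 == 1 else "-"
        genes.append(GeneAnnotation(_gene_name(i), CONTIG, start,
                                    start + GENE_LENGTH - 1, strand))
    return genes


def _upstream_gap(i: int, n_genes: int) -> tuple[int, int] | None:
    """1-based inclusive span of gene i's upstream intergenic gap."""
    if i % 2 == 1:  # '+' strand: gap before the gene
        lo = (i - 1) * SPACING + 1
        return lo, lo + GAP_LENGTH - 1
    # '-' strand: gap after the gene
    lo = i * SPACING + 1
    return lo, lo + GAP_LENGTH - 1


def _divergent_partner(i: int, n_genes: int) -> int | None:
    """The gene sharing gene i's upstream gap (divergent pair), if any."""
    if i % 2 == 1:
        return i - 1 if i > 1 else None
    return i + 1 if i < n_genes else None


# ---------------------------------------------------------------------------
# cascade simulation
# ---------------------------------------------------------------------------

def _backward_membership(cfg: CascadeSimConfig, direct_idx: np.ndarray,
                         rng: np.random.Generator):
    pw = cfg.pathway
    d = len(direct_idx)
    carried: dict[str, np.ndarray] = {pw.sink: np.ones(d, dtype=bool)}
    exogenous: dict[str, np.ndarray] = {}
    transmitted: dict[tuple[str, str], np.ndarray] = {}
    for node in reversed(pw.topological_order()):
        at_node = carried.get(node)
        if at_node is None:
            at_node = np.zeros(d, dtype=bool)
            carried[node] = at_node
        exo = np.zeros(d, dtype=bool)
        e = cfg.node_exogenous_fraction[node]
        if e > 0:
            exo = at_node & (rng.random(d) < e)
        exogenous[node] = exo
        candidates = at_node & ~exo
        for pred in pw.predecessors(node):
            t = cfg.edge_transmission[(pred, node)]
            via = candidates & (rng.random(d) < t)
            transmitted[(pred, node)] = via
            carried[pred] = carried.get(pred, np.zeros(d, dtype=bool)) | via
    return carried, exogenous, transmitted


def _truth_flow(cfg: CascadeSimConfig, direct: list[str],
                carried_sets: dict[str, set[str]]) -> FlowResult:
    """Flow percentages implied by the planted sets (sink regulon = D)."""
    pw = cfg.pathway
    D = set(direct)
    nD = len(D)
    node_input, node_genes = {}, {}
    for n in pw.topological_order():
        genes = carried_sets[n] & D
        node_genes[n] = genes
        node_input[n] = 100.0 * len(genes) / nD
    edge_flux, edge_genes = {}, {}
    for (u, v) in pw.edges:
        genes = carried_sets[u] & carried_sets[v] & D
        edge_genes[(u, v)] = genes
        edge_flux[(u, v)] = 100.0 * len(genes) / nD
    missing, missing_genes = {}, {}
    for n in pw.topological_order():
        preds = pw.predecessors(n)
        if not preds:
            continue
        covered = set().union(*(carried_sets[p] for p in preds))
        genes = (carried_sets[n] & D) - covered
        missing_genes[n] = genes
        missing[n] = 100.0 * len(genes) / nD
    hidden = [(n, pct) for n, pct in sorted(missing.items()) if pct > 0]
    return FlowResult(nD, node_input, edge_flux, missing, node_genes,
                      edge_genes, missing_genes, hidden)


def _make_operons(cfg: CascadeSimConfig, rng: np.random.Generator) -> OperonMap:
    target = int(cfg.operon_gene_fraction * cfg.n_genes)
    operons: dict[str, list[str]] = {}
    in_operon = 0
    i = 1
    op_no = 1
    while i <= cfg.n_genes - 1 and in_operon < target:
        if rng.random() < 0.5:
            size = int(rng.integers(2, 5))
            size = min(size, cfg.n_genes - i + 1)
            operons[f"op{op_no:04d}"] = [_gene_name(j) for j in range(i, i + size)]
            op_no += 1
            in_operon += size
            i += size + 1  # leave a gap so operons never touch
        else:
            i += 1
    return OperonMap(operons)


def simulate_cascade(config: CascadeSimConfig,
                     out_dir: str | Path | None = None
                     ) -> tuple[SyntheticTruth, SimulatedDataset]:
    """Generate a full synthetic dataset plus its planted truth.

    Fully reproducible from ``config.seed``; when ``out_dir`` is given the
    dataset and truth are also written there (see :func:`write_dataset`).
    """
    cfg = config.resolve()
    rng = np.random.default_rng(cfg.seed)
    pw = cfg.pathway
    n = cfg.n_genes
    gene_names = [_gene_name(i) for i in range(1, n + 1)]

    # --- reserve gene index pools (1-based indices), disjoint by construction
    perm = rng.permutation(n) + 1
    d = cfg.direct_regulon_size
    n_strong_decoys = cfg.decoy_peak_count // 2
    n_genic_decoys = max(1, n_strong_decoys // 10) if cfg.decoy_peak_count else 0
    need = d + n_strong_decoys + n_genic_decoys
    if need > n:
        raise ValidationError("genome too small for direct regulon plus decoys")
    direct_idx = np.sort(perm[:d])
    strong_decoy_idx = perm[d:d + n_strong_decoys]
    genic_decoy_idx = perm[d + n_strong_decoys:need]
    direct = [_gene_name(i) for i in direct_idx]

    # --- backward membership on D
    carried_b, exo_b, trans_b = _backward_membership(cfg, direct_idx, rng)
    to_set = lambda mask: {direct[k] for k in np.flatnonzero(mask)}
    carried_sets = {node: to_set(m) for node, m in sorted(carried_b.items())}
    exogenous_sets = {node: to_set(m) for node, m in sorted(exo_b.items())}
    transmitted_sets = {e: to_set(m) for e, m in sorted(trans_b.items())}

    # --- bound genes implied by the planted peak geometry
    bound_idx: set[int] = set()
    for i in list(direct_idx) + list(strong_decoy_idx):
        bound_idx.add(int(i))
        partner = _divergent_partner(int(i), n)
        if partner is not None:
            bound_idx.add(partner)
    bound_idx |= {int(i) for i in genic_decoy_idx}
    bound_genes = {_gene_name(i) for i in bound_idx}

    # --- off-pathway targets, disjoint from D and from every bound gene
    forbidden = bound_idx | {int(i) for i in direct_idx}
    free_pool = np.array([i for i in range(1, n + 1) if i not in forbidden])
    off_pathway: dict[str, set[str]] = {}
    for node in pw.topological_order():
        if node == pw.sink or pw.is_hidden(node):
            off_pathway[node] = set()
            continue
        k = int(round(cfg.off_target_ratio * len(carried_sets[node])))
        k = min(k, len(free_pool))
        pick = rng.choice(free_pool, size=k, replace=False) if k else np.array([], int)
        off_pathway[node] = {_gene_name(int(i)) for i in pick}

    true_regulons = {node: carried_sets[node] | off_pathway[node]
                     for node in pw.nodes if node != pw.sink and not pw.is_hidden(node)}
    true_regulons[pw.sink] = set(direct)

    # --- annotation, operons
    annotation = _make_annotation(n)
    operons = _make_operons(cfg, rng)

    # --- expression tables: one paired contrast per perturbable node
    name_to_pos = {g: i for i, g in enumerate(gene_names)}
    baseline = rng.normal(cfg.baseline_log_rpkm_mean, cfg.baseline_log_rpkm_sd, n)
    sign = rng.choice([-1.0, 1.0], size=n)
    magnitude = np.maximum(rng.normal(cfg.effect_log2_mean, cfg.effect_log2_sd, n), 0.1)

    expression: dict[str, ExpressionTable] = {}
    contrasts: dict[str, tuple[str, str]] = {}
    modes = dict(cfg.node_modes)
    for node in pw.topological_order():
        if node == pw.sink or pw.is_hidden(node):
            continue
        mode = modes[node]
        scale = 1.0 if mode == "depletion" else cfg.deletion_effect_scale
        effect = np.zeros(n)
        idx = np.array([name_to_pos[g] for g in sorted(true_regulons[node])], int)
        if len(idx):
            effect[idx] = sign[idx] * magnitude[idx] * scale
        mut_cond, wt_cond = f"{node}_mut", "wt"
        cols = {}
        for rep in range(1, cfg.n_replicates + 1):
            noise_w = rng.normal(0.0, cfg.replicate_noise_sd, n) \
                if cfg.replicate_noise_sd else np.zeros(n)
            noise_m = rng.normal(0.0, cfg.replicate_noise_sd, n) \
                if cfg.replicate_noise_sd else np.zeros(n)
            cols[(wt_cond, rep)] = np.power(2.0, baseline + noise_w)
            cols[(mut_cond, rep)] = np.power(2.0, baseline + effect + noise_m)
        import pandas as pd
        frame = pd.DataFrame(cols, index=pd.Index(gene_names, name="gene_id"))
        expression[node] = ExpressionTable(frame)
        contrasts[node] = (mut_cond, wt_cond)

    # --- peaks: one passing peak upstream of every direct-regulon gene,
    #     strong decoys upstream of reserved non-regulated genes, genic
    #     decoys inside reserved genes, plus weak decoys that fail filters.
    peaks: list[Peak] = []

    def plant_upstream(i: int, tag: str) -> None:
        gap = _upstream_gap(i, n)
        lo, hi = gap
        pos1 = int(rng.integers(lo + 10, hi - 10 + 1))   # 1-based summit
        summit = pos1 - 1
        start = max(0, summit - 75)
        end = summit + 76
        fe = float(rng.uniform(2.5, 30.0))
        q = float(rng.uniform(1e-6, 0.04))
        peaks.append(Peak(CONTIG, start, end, summit, fe, q,
                          name=f"{tag}_{_gene_name(i)}"))

    for i in direct_idx:
        plant_upstream(int(i), "site")
    for i in strong_decoy_idx:
        plant_upstream(int(i), "decoy")
    for i in genic_decoy_idx:
        g_start = (int(i) - 1) * SPACING + GAP_LENGTH + 1
        summit = g_start - 1 + int(rng.integers(100, GENE_LENGTH - 100))
        peaks.append(Peak(CONTIG, summit - 75, summit + 76, summit,
                          float(rng.uniform(2.5, 15.0)),
                          float(rng.uniform(1e-6, 0.04)),
                          name=f"genic_{_gene_name(int(i))}"))
    n_weak = cfg.decoy_peak_count - n_strong_decoys - n_genic_decoys
    contig_len = n * SPACING + GAP_LENGTH
    for j in range(max(0, n_weak)):
        summit = int(rng.integers(100, contig_len - 100))
        if rng.random() < 0.5:
            fe, q = float(rng.uniform(0.5, 2.0)), float(rng.uniform(1e-6, 0.04))
        else:
            fe, q = float(rng.uniform(2.5, 10.0)), float(rng.uniform(0.06, 0.5))
        peaks.append(Peak(CONTIG, summit - 75, summit + 76, summit, fe, q,
                          name=f"weak_{j:04d}"))

    truth = SyntheticTruth(
        direct=set(direct),
        carried=carried_sets,
        exogenous=exogenous_sets,
        transmitted=transmitted_sets,
        off_pathway=off_pathway,
        true_regulons=true_regulons,
        bound_genes=bound_genes,
        flow=_truth_flow(cfg, direct, carried_sets),
    )
    dataset = SimulatedDataset(expression, contrasts, peaks, annotation,
                               operons, pw, modes, tuple(cfg.total_nodes))
    if out_dir is not None:
        write_dataset(dataset, truth, out_dir)
    return truth, dataset


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, truth: SyntheticTruth,
                  out_dir: str | Path) -> Path:
    """Write the dataset in the exact formats the readers consume, plus truth/."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for node in sorted(dataset.expression):
        write_expression_table(dataset.expression[node],
                               out / f"expression_{node}.tsv")
    write_peak_table(dataset.peaks, out / "peaks.tsv")
    write_annotation(dataset.annotation, out / "annotation.gff3")
    write_operon_table(dataset.operons, out / "operons.tsv")
    write_pathway_config(dataset.pathway, out / "pathway.yaml")
    meta = {
        "contrasts": {k: list(v) for k, v in sorted(dataset.contrasts.items())},
        "modes": dict(sorted(dataset.modes.items())),
        "total_nodes": list(dataset.total_nodes),
    }
    (out / "dataset.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    with open(tdir / "gene_sets.tsv", "w") as fh:
        fh.write("set\tname\tgenes\n")
        fh.write(f"direct\tdirect\t{','.join(sorted(truth.direct))}\n")
        fh.write(f"bound\tbound\t{','.join(sorted(truth.bound_genes))}\n")
        for node in sorted(truth.carried):
            fh.write(f"carried\t{node}\t{','.join(sorted(truth.carried[node]))}\n")
        for node in sorted(truth.true_regulons):
            fh.write(f"regulon\t{node}\t"
                     f"{','.join(sorted(truth.true_regulons[node]))}\n")
    from .io import write_flow_outputs
    write_flow_outputs(truth.flow, tdir / "flow.tsv", tdir / "flow.dot")
    return out


# ---------------------------------------------------------------------------
# decay fixtures
# ---------------------------------------------------------------------------

def simulate_decay(t_half: float, timepoints, signal0: float = 100.0,
                   growth_doubling_time: float | None = None,
                   noise_sd: float = 0.0, seed: int = 0) -> DecayDataset:
    """Simulate an OD-normalized translation-shutoff decay series.

    ``t_half`` may be ``numpy.inf`` for a perfectly stable protein.  When a
    doubling time is given, the emitted per-biomass signal is diluted by
    growth (``growth_factor`` is stored so the correction can be applied).
    Multiplicative log-normal noise with log2-scale sd ``noise_sd``.  The
    planted parameters are stored in ``dataset.meta``.
    """
    t = np.asarray(list(timepoints), dtype=float)
    if t_half <= 0:
        raise ValidationError("t_half must be positive (or inf)")
    rng = np.random.default_rng(seed)
    total = signal0 * np.power(2.0, -t / t_half) if np.isfinite(t_half) \
        else np.full_like(t, signal0)
    growth = np.power(2.0, t / growth_doubling_time) \
        if growth_doubling_time else np.ones_like(t)
    signal = total / growth
    if noise_sd:
        signal = signal * np.power(2.0, rng.normal(0.0, noise_sd, len(t)))
    return DecayDataset(
        timepoints=tuple(t),
        signals=tuple(signal),
        growth_factor=tuple(growth) if growth_doubling_time else None,
        meta={"t_half": t_half, "signal0": signal0,
              "growth_doubling_time": growth_doubling_time,
              "noise_sd": noise_sd, "seed": seed},
    )
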