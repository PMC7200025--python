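"""End-to-end orchestration: simulate -> regulons -> binding -> flow -> report.

Every stage persists its intermediates so each number in the report can be
reproduced by invoking the corresponding module operation in isolation on
the persisted files.  A machine-readable log records every threshold that
was actually applied, plus the membership diffs between the strict and the
flux regulons (the distinction that drives the flow analysis).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import yaml

from . import binding as bd
from . import flow as fl
from . import io as rio
from . import regulons as rg
from .simulate import CascadeSimConfig, simulate_cascade

__all__ = ["RunConfig", "PipelineStageError", "AnalysisResult", "analyze",
           "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one run needs; see ``from_yaml`` for the file layout."""

    inputs: dict                       # expression: {node: path}, peaks, annotation,
                                       # operons, pathway
    contrasts: dict                    # node -> {mutant, wildtype, mode}
    total_nodes: list                  # nodes whose union is the sink's total regulon
    simulate: dict | None = None       # optional CascadeSimConfig overrides
    motif: dict | None = None          # left/spacer/right
    upstream_cap: int | None = None
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            inputs=cfg.get("inputs", {}),
            contrasts=cfg.get("contrasts", {}),
            total_nodes=cfg.get("total_nodes", []),
            simulate=cfg.get("simulate"),
            motif=cfg.get("motif"),
            upstream_cap=cfg.get("upstream_cap"),
            pseudocount=cfg.get("pseudocount", 1.0),
            seed=cfg.get("seed", 0),
        )


def _policy_for(mode: str) -> rg.ThresholdPolicy:
    if mode == "depletion":
        return rg.ThresholdPolicy.depletion()
    if mode == "deletion":
        return rg.ThresholdPolicy.deletion()
    raise ValueError(f"unknown contrast mode {mode!r}")


@dataclass
class AnalysisResult:
    """Everything the analysis computes for one dataset."""

    records: dict                      # node -> list[DifferentialRecord]
    strict: dict                       # node -> strict Regulon
    flux: dict                         # node -> flux Regulon
    retained_peaks: list
    assignments: dict                  # gene -> BindingAssignment
    total: rg.Regulon
    direct: rg.Regulon
    flow: fl.FlowResult


def analyze(tables: Mapping, contrasts: Mapping, modes: Mapping,
            peaks, annotation, operons, pathway, total_nodes,
            pseudocount: float = 1.0,
            upstream_cap: int | None = None) -> AnalysisResult:
    """The full analysis on in-memory objects.

    ``tables`` maps node -> ExpressionTable, ``contrasts`` node ->
    (mutant condition, wildtype condition), ``modes`` node -> deletion or
    depletion.  The sink's regulon for the flow step is the union of the
    ``total_nodes`` strict regulons; the direct regulon is that union
    intersected with the ChIP-bound gene set.
    """
    records: dict[str, list] = {}
    strict: dict[str, rg.Regulon] = {}
    for node in sorted(contrasts):
        recs = rg.compute_differential(tables[node], tuple(contrasts[node]),
                                       pseudocount=pseudocount)
        records[node] = recs
        strict[node] = rg.call_regulon(recs, _policy_for(modes[node]),
                                       operons, node=node)
    flux = fl.build_flux_regulons(records, modes, operons)

    retained = bd.filter_peaks(peaks)
    assignments = bd.assign_peaks(retained, annotation, operons,
                                  upstream_cap=upstream_cap)

    missing_total = [n for n in total_nodes if n not in strict]
    if missing_total:
        raise ValueError(f"total_nodes without contrasts: {missing_total}")
    total = strict[total_nodes[0]]
    for node in total_nodes[1:]:
        total = rg.union_regulon(total, strict[node], "total")
    total.node = "total"
    direct = bd.direct_regulon(total, assignments, name="direct")

    flow_regulons = dict(flux)
    flow_regulons[pathway.sink] = total
    flow = fl.quantify_flow(pathway, flow_regulons, direct)
    return AnalysisResult(records, strict, flux, retained, assignments,
                          total, direct, flow)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage; returns the run directory.

    Layout: ``inputs/`` (when simulating), ``regulons/``, ``binding/``,
    ``flow/``, ``report.json`` and ``run_log.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"started": time.strftime("%Y-%m-%dT%H:%M:%S"), "stages": {}}

    # ------------------------------------------------------------------ simulate
    cfg = config
    if cfg.simulate is not None:
        sim_cfg = CascadeSimConfig(**{**cfg.simulate, "seed": cfg.seed}).resolve()
        _, dataset = simulate_cascade(sim_cfg, out_dir=out / "inputs")
        cfg = RunConfig(
            inputs={
                "expression": {node: str(out / "inputs" / f"expression_{node}.tsv")
                               for node in dataset.expression},
                "peaks": str(out / "inputs" / "peaks.tsv"),
                "annotation": str(out / "inputs" / "annotation.gff3"),
                "operons": str(out / "inputs" / "operons.tsv"),
                "pathway": str(out / "inputs" / "pathway.yaml"),
            },
            contrasts={node: {"mutant": m, "wildtype": w,
                              "mode": dataset.modes[node]}
                       for node, (m, w) in dataset.contrasts.items()},
            total_nodes=list(dataset.total_nodes),
            motif=cfg.motif, upstream_cap=cfg.upstream_cap,
            pseudocount=cfg.pseudocount, seed=cfg.seed,
        )
        log["stages"]["simulate"] = {"seed": cfg.seed,
                                     "n_genes": sim_cfg.n_genes,
                                     "direct_regulon_size": sim_cfg.direct_regulon_size}

    # ------------------------------------------------------------------ inputs
    try:
        for key in ("peaks", "annotation", "operons", "pathway"):
            if key not in cfg.inputs or not Path(cfg.inputs[key]).exists():
                raise FileNotFoundError(f"missing input {key!r}")
        for node, path in cfg.inputs.get("expression", {}).items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"missing expression file for node {node!r}: {path}")
        tables = {node: rio.read_expression_table(path)
                  for node, path in cfg.inputs["expression"].items()}
        peaks = rio.read_peak_table(cfg.inputs["peaks"])
        annotation = rio.read_annotation(cfg.inputs["annotation"])
        operons = rio.read_operon_table(cfg.inputs["operons"])
        pathway = rio.read_pathway_config(cfg.inputs["pathway"])
    except Exception as exc:
        raise PipelineStageError("read_inputs", str(exc)) from exc

    # ------------------------------------------------------------------ analysis
    modes = {node: spec["mode"] for node, spec in cfg.contrasts.items()}
    contrast_pairs = {node: (spec["mutant"], spec["wildtype"])
                      for node, spec in cfg.contrasts.items()}
    try:
        res = analyze(tables, contrast_pairs, modes, peaks, annotation,
                      operons, pathway, list(cfg.total_nodes),
                      pseudocount=cfg.pseudocount,
                      upstream_cap=cfg.upstream_cap)
    except Exception as exc:
        raise PipelineStageError("analysis", str(exc)) from exc

    # ------------------------------------------------------------------ persist
    reg_dir = out / "regulons"
    reg_dir.mkdir(exist_ok=True)
    strict, flux, total, direct, result = (res.strict, res.flux, res.total,
                                           res.direct, res.flow)
    for node in sorted(strict):
        rio.write_regulon_table(strict[node], reg_dir / f"strict_{node}.tsv")
    for node in sorted(flux):
        rio.write_regulon_table(flux[node], reg_dir / f"flux_{node}.tsv")
    rio.write_regulon_table(total, reg_dir / "total.tsv")
    rio.write_regulon_table(direct, reg_dir / "direct.tsv")
    log["stages"]["regulons"] = {
        node: {"mode": modes[node],
               "policy": asdict(_policy_for(modes[node])),
               "strict_size": len(strict[node]),
               "flux_size": len(flux[node]),
               "flux_only_genes": sorted(flux[node].members
                                         - strict[node].members)}
        for node in sorted(strict)
    }

    bind_dir = out / "binding"
    bind_dir.mkdir(exist_ok=True)
    rio.write_peak_table(res.retained_peaks, bind_dir / "peaks_filtered.tsv")
    with open(bind_dir / "assignments.tsv", "w") as fh:
        fh.write("gene_id\tpeak\tmode\tpartner\n")
        for gene in sorted(res.assignments):
            for ev in sorted(res.assignments[gene].evidence):
                peak_ref, mode, *partner = ev
                fh.write(f"{gene}\t{peak_ref}\t{mode}\t"
                         f"{partner[0] if partner else ''}\n")
    n_intergenic = sum(1 for p in res.retained_peaks
                       if bd.classify_peak(p, annotation) == "intergenic")
    log["stages"]["binding"] = {
        "peaks_total": len(peaks), "peaks_retained": len(res.retained_peaks),
        "min_fold_enrichment": 2.0, "max_q": 0.05,
        "intergenic": n_intergenic,
        "genic": len(res.retained_peaks) - n_intergenic,
        "genes_with_evidence": len(res.assignments),
    }
    log["stages"]["direct_regulon"] = {
        "total_size": len(total), "direct_size": len(direct),
        "direct_binding": len(direct.tagged("direct")),
        "operon_binding": len(direct.tagged("operon")),
    }

    flow_dir = out / "flow"
    flow_dir.mkdir(exist_ok=True)
    rio.write_flow_outputs(result, flow_dir / "flow.tsv", flow_dir / "flow.dot")
    augmented = fl.infer_hidden_inputs(pathway, result)
    rio.write_pathway_config(augmented, flow_dir / "pathway_augmented.yaml")
    log["stages"]["flow"] = result.summary()

    # ------------------------------------------------------------------ report
    overlaps = {}
    for a, b in combinations(sorted(strict), 2):
        try:
            pct, _ = fl.overlap_fraction(strict[a], strict[b], "first")
            overlaps[f"{a}_vs_{b}"] = round(pct, 2)
        except fl.UndefinedOverlapError:
            overlaps[f"{a}_vs_{b}"] = None
    report = {
        "regulon_sizes": {n: len(r) for n, r in sorted(strict.items())},
        "flux_regulon_sizes": {n: len(r) for n, r in sorted(flux.items())},
        "total_regulon_size": len(total),
        "direct_regulon": {
            "size": len(direct),
            "direct_binding": len(direct.tagged("direct")),
            "operon_binding": len(direct.tagged("operon")),
        },
        "pairwise_overlap_pct": overlaps,
        "flow": result.summary(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return out
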