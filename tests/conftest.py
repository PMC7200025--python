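import numpy as np
import pandas as pd
import pytest

from regulonflow import ExpressionTable, GeneAnnotation, OperonMap, PathwayGraph, Peak


def make_table(cells: dict) -> ExpressionTable:
    """Build an ExpressionTable from {gene: {(condition, replicate): rpkm}}."""
    frame = pd.DataFrame.from_dict(cells, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    frame.index.name = "gene_id"
    return ExpressionTable(frame)


def paired_table(genes: dict, conditions=("mut", "wt")) -> ExpressionTable:
    """{gene: (mutant_values, wildtype_values)} -> table with paired replicates."""
    cells = {}
    for gene, (mut, wt) in genes.items():
        row = {}
        for i, v in enumerate(mut, start=1):
            row[(conditions[0], i)] = v
        for i, v in enumerate(wt, start=1):
            row[(conditions[1], i)] = v
        cells[gene] = row
    return make_table(cells)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_plus_genes():
    """Two '+' genes with an intergenic gap between them."""
    return [
        GeneAnnotation("geneA", "chr", 1001, 2000, "+"),
        GeneAnnotation("geneB", "chr", 3001, 4000, "+"),
    ]


@pytest.fixture
def small_operons():
    return OperonMap({"op1": ["g1", "g2", "g3"]})


def make_peak(summit, fe=5.0, q=0.001, contig="chr", half_width=75, name=""):
    return Peak(contig, max(0, summit - half_width), summit + half_width + 1,
                summit, fe, q, name=name)


@pytest.fixture
def chain_pathway():
    """X -> Y -> sink Z."""
    return PathwayGraph([("X", "X", False), ("Y", "Y", False), ("Z", "Z", False)],
                        [("X", "Y"), ("Y", "Z")], "Z")
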