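import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from utrkit.models import CellCountMatrix, TranscriptModel


@pytest.fixture
def plus_gene():
    """Single-exon plus-strand gene with two isoforms 400 nt apart."""
    short = TranscriptModel("txA.1", "gA", "chr1", "+", [(1000, 3000)],
                            cds_start=1100, cds_end=2200)
    long = TranscriptModel("txA.2", "gA", "chr1", "+", [(1000, 3400)],
                           cds_start=1100, cds_end=2200)
    return [short, long]


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(0)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}


def make_ccm(counts, groups=None, genes_per=2):
    counts = np.asarray(counts)
    n_cells, n_iso = counts.shape
    n_genes = n_iso // genes_per
    gene_ids = [f"g{i}" for i in range(n_genes) for _ in range(genes_per)]
    iso_ids = [f"g{i}.iso{j}" for i in range(n_genes) for j in range(genes_per)]
    groups = groups if groups is not None else ["A"] * n_cells
    barcodes = [f"bc{i}" for i in range(n_cells)]
    return CellCountMatrix(sparse.csr_matrix(counts), barcodes, groups, iso_ids, gene_ids)


@pytest.fixture
def small_ccm():
    counts = np.array([
        [5, 0, 2, 1],
        [3, 1, 0, 0],
        [0, 2, 4, 4],
    ])
    return make_ccm(counts, groups=["A", "A", "B"])
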