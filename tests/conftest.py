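import numpy as np
import pytest

from spottype import GeneSpotMatrix, MarkerDatabase
from spottype.markerdb import MarkerEntry

BRAIN_DB_TSV = """\
tissueType\tcellName\tgeneSymbolmore1\tgeneSymbolmore2
Brain\tAstrocyte\tGFAP,AQP4\t
Brain\tNeuron\tRBFOX3,SYT1\tGFAP
Brain\tMicroglia\tAIF1,P2RY12,TMEM119\t
Immune system\tT cell\tCD3D,CD3E\t
"""


@pytest.fixture
def brain_db_path(tmp_path):
    path = tmp_path / "markers.tsv"
    path.write_text(BRAIN_DB_TSV)
    return path


def make_db(entries, tissue="T"):
    """Build a MarkerDatabase from (cell_type, pos, neg) triples."""
    return MarkerDatabase(
        [
            MarkerEntry(
                tissue=tissue,
                cell_type=ct,
                positive_genes=frozenset(pos),
                negative_genes=frozenset(neg),
            )
            for ct, pos, neg in entries
        ]
    )


def make_z(values, genes, spots):
    """A 'zscored' GeneSpotMatrix from an explicit array (for scoring tests)."""
    return GeneSpotMatrix(
        values=np.asarray(values, dtype=float),
        gene_ids=genes,
        spot_ids=spots,
        layer="zscored",
    )


def sctype_score_bruteforce(z, db, tissue, w):
    """Independent nested-loop reference for the enrichment score.

    Loops explicitly over cell types, spots and marker genes; shares no
    code with the vectorized implementation.
    """
    gidx = {g: i for i, g in enumerate(z.gene_ids)}
    zmat = z.dense()
    rows, kept = [], []
    for e in db.entries_for(tissue):
        pos = [g for g in sorted(e.positive_genes) if g in gidx]
        neg = [g for g in sorted(e.negative_genes) if g in gidx]
        if not pos and not neg:
            continue
        row = []
        for s in range(len(z.spot_ids)):
            total = 0.0
            for g in pos:
                total += w.weights[g] * zmat[gidx[g], s]
            for g in neg:
                total -= w.weights[g] * zmat[gidx[g], s]
            row.append(total / np.sqrt(len(pos) + len(neg)))
        rows.append(row)
        kept.append(e.cell_type)
    return np.array(rows), kept


def random_scoring_instance(rng, n_genes=20, n_spots=10, n_types=4,
                            with_negatives=True):
    """A random z-matrix, marker DB and weights for oracle comparisons."""
    from spottype import SpecificityWeights

    genes = [f"G{i}" for i in range(n_genes)]
    spots = [f"S{j}" for j in range(n_spots)]
    z = make_z(rng.normal(size=(n_genes, n_spots)), genes, spots)
    entries = []
    for k in range(n_types):
        pos = set(rng.choice(genes, size=rng.integers(1, 6), replace=False))
        neg = set()
        if with_negatives and rng.random() < 0.7:
            neg = set(rng.choice(genes, size=rng.integers(1, 4), replace=False)) - pos
        entries.append((f"CT{k}", pos, neg))
    db = make_db(entries)
    weights = SpecificityWeights(
        weights={g: float(rng.uniform(0, 1)) for g in genes},
        tissue="T",
        n_cell_types=n_types,
    )
    return z, db, weights
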