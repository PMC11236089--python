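"""Synthetic spatial transcriptomics generator.

Cells of K types are placed on a 2D micron grid, assigned expression from a
negative-binomial model with planted, pairwise-disjoint marker blocks, and
probed by fixed-diameter capture spots on a square lattice — emulating a
spatially organized tissue measured by a high-resolution ST assay (10 um
spots by default).  Each spot's ground-truth label is the modal type of the
cells it captures ("Empty" when it captures none), which is what a
marker-based annotator is asked to recover.

The default configuration is the benchmark condition used throughout the
test suite: 4 cell types x 5 markers each, NB means 10 (marker) vs 0.2
(background) with dispersion 2, 2000 cells on a 500 x 500 um tissue, 10 um
spots on a 20 um pitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneSpotMatrix, SpotGeometry
from .errors import ValidationError
from .markerdb import MarkerDatabase, MarkerEntry

__all__ = [
    "SimulationConfig",
    "SimulatedTissue",
    "place_cells",
    "draw_expression",
    "probe_spots",
    "simulate",
    "reference_profiles",
]

EMPTY = "Empty"
SIM_TISSUE = "Simulated"


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class SimulationConfig:
    """Tissue, expression-model and spot-lattice parameters.

    ``genes`` is the concatenation of one disjoint marker block of size
    ``markers_per_type`` per cell type, followed by ``n_background_genes``
    genes that mark nothing.  Counts are NB(mean mu_high) for a cell's own
    marker genes and NB(mean mu_low) everywhere else, with shared
    dispersion ``theta`` (variance mu + mu^2/theta).
    """

    width_um: float = 500.0
    height_um: float = 500.0
    n_cells: int = 2000
    cell_types: tuple[str, ...] = ("Astro", "Excit", "Inhib", "Oligo")
    layout: str = "blobs"
    markers_per_type: int = 5
    n_background_genes: int = 20
    mu_high: float = 10.0
    mu_low: float = 0.2
    theta: float = 2.0
    spot_diameter_um: float = 10.0
    spot_pitch_um: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ValidationError("need at least 2 cell types")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValidationError("cell type labels must be unique")
        if not (self.mu_high > self.mu_low >= 0):
            raise ValidationError("need mu_high > mu_low >= 0")
        if self.theta <= 0:
            raise ValidationError("dispersion theta must be > 0")
        if self.spot_pitch_um < self.spot_diameter_um / 2:
            raise ValidationError("spot pitch must be >= spot diameter / 2")
        if self.markers_per_type < 1:
            raise ValidationError("markers_per_type must be >= 1")

    @property
    def marker_blocks(self) -> dict[str, list[str]]:
        """Planted marker genes per type; blocks are pairwise disjoint."""
        return {
            t: [f"{t.upper()}-M{i + 1}" for i in range(self.markers_per_type)]
            for t in self.cell_types
        }

    @property
    def genes(self) -> list[str]:
        out = [g for t in self.cell_types for g in self.marker_blocks[t]]
        out += [f"BG-{i + 1}" for i in range(self.n_background_genes)]
        return out

    def to_marker_db(self) -> MarkerDatabase:
        """Marker database matching the planted blocks (no negatives)."""
        entries = [
            MarkerEntry(
                tissue=SIM_TISSUE,
                cell_type=t,
                positive_genes=frozenset(self.marker_blocks[t]),
                negative_genes=frozenset(),
            )
            for t in self.cell_types
        ]
        return MarkerDatabase(entries)


@dataclass
class SimulatedTissue:
    """Full output of one simulation: placements, expression, spot captures,

    the spot count matrix and per-spot ground truth."""

    config: SimulationConfig
    cells: pd.DataFrame            # columns x_um, y_um, cell_type
    cell_expr: np.ndarray          # genes x cells
    spots: SpotGeometry
    capture: dict[str, list[int]]  # spot barcode -> captured cell indices
    spot_matrix: GeneSpotMatrix
    truth: dict[str, str]          # spot barcode -> modal type or "Empty"

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": self.spots.barcodes,
                "true_label": [self.truth[b] for b in self.spots.barcodes],
                "n_cells_captured": [len(self.capture[b]) for b in self.spots.barcodes],
            }
        )


def place_cells(config: SimulationConfig, seed) -> pd.DataFrame:
    """Place ``n_cells`` uniformly in the rectangle and assign types by layout.

    Layouts: ``random`` — iid uniform over types; ``stripes`` — K
    equal-width vertical bands, type given by the band of x; ``blobs`` — K
    Gaussian-jittered centers on a grid, type given by the nearest center.
    Deterministic given the seed.
    """
    k = len(config.cell_types)
    if config.n_cells > 0 and k > config.n_cells:
        raise ValidationError(
            f"{k} cell types but only {config.n_cells} cells to place"
        )
    pos_ss, type_ss = _seedseq(seed).spawn(2)
    pos_rng = np.random.default_rng(pos_ss)
    type_rng = np.random.default_rng(type_ss)

    n = config.n_cells
    x = pos_rng.uniform(0.0, config.width_um, size=n)
    y = pos_rng.uniform(0.0, config.height_um, size=n)

    if config.layout == "random":
        idx = type_rng.integers(0, k, size=n)
    elif config.layout == "stripes":
        band = config.width_um / k
        idx = np.minimum((x // band).astype(int), k - 1)
    elif config.layout == "blobs":
        g = math.ceil(math.sqrt(k))
        cx, cy = np.meshgrid(
            (np.arange(g) + 0.5) * config.width_um / g,
            (np.arange(g) + 0.5) * config.height_um / g,
        )
        centers = np.column_stack([cx.ravel(), cy.ravel()])[:k]
        jitter = type_rng.normal(
            0.0, min(config.width_um, config.height_um) / (6 * g), size=centers.shape
        )
        centers = centers + jitter
        d2 = (x[:, None] - centers[None, :, 0]) ** 2 + (
            y[:, None] - centers[None, :, 1]
        ) ** 2
        idx = d2.argmin(axis=1)
    else:
        raise ValidationError(f"unknown layout {config.layout!r}")

    types = np.array(config.cell_types, dtype=object)[idx] if n else np.array([], dtype=object)
    return pd.DataFrame({"x_um": x, "y_um": y, "cell_type": types})


def draw_expression(
    placements: pd.DataFrame, config: SimulationConfig, seed
) -> np.ndarray:
    """Draw a genes x cells NB count matrix given placements; deterministic

    given the seed.  NB(mean mu, dispersion theta) is parameterized as
    numpy's negative_binomial(n=theta, p=theta/(theta+mu))."""
    rng = np.random.default_rng(_seedseq(seed))
    genes = config.genes
    type_index = {t: i for i, t in enumerate(config.cell_types)}
    mu_by_type = np.full((len(genes), len(config.cell_types)), config.mu_low)
    for t, block in config.marker_blocks.items():
        for g in block:
            mu_by_type[genes.index(g), type_index[t]] = config.mu_high

    n = len(placements)
    if n == 0:
        return np.zeros((len(genes), 0), dtype=np.int64)
    cols = np.array([type_index[t] for t in placements["cell_type"]])
    mu = mu_by_type[:, cols]  # genes x cells
    p = config.theta / (config.theta + mu)
    return rng.negative_binomial(config.theta, p)


def _lattice(config: SimulationConfig) -> tuple[np.ndarray, pd.DataFrame]:
    pitch = config.spot_pitch_um
    nx = max(1, math.ceil(config.width_um / pitch))
    ny = max(1, math.ceil(config.height_um / pitch))
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    centers = np.column_stack([(cols + 0.5) * pitch, (rows + 0.5) * pitch])
    table = pd.DataFrame(
        {
            "barcode": [f"SPOT-{r:03d}-{c:03d}" for r, c in zip(rows, cols)],
            "in_tissue": 1,
            "array_row": rows,
            "array_col": cols,
            "x_um": centers[:, 0],
            "y_um": centers[:, 1],
        }
    )
    return centers, table


def probe_spots(
    placements: pd.DataFrame, cell_expr: np.ndarray, config: SimulationConfig
) -> SimulatedTissue:
    """Overlay a square spot lattice and capture cells into spots.

    A cell is captured by the spot whose center is nearest iff it lies
    within the closed disk of radius diameter/2 around that center; each
    cell is therefore captured by at most one spot.  Spot counts are the
    gene-wise sums over captured cells; ground truth is the modal captured
    type (lexicographic tie-break) or "Empty".
    """
    centers, table = _lattice(config)
    geom = SpotGeometry(table=table, spot_diameter_um=config.spot_diameter_um)
    barcodes = geom.barcodes
    pitch = config.spot_pitch_um
    nx = max(1, math.ceil(config.width_um / pitch))
    ny = max(1, math.ceil(config.height_um / pitch))

    capture: dict[str, list[int]] = {b: [] for b in barcodes}
    r2 = (config.spot_diameter_um / 2.0) ** 2
    xs = placements["x_um"].to_numpy() if len(placements) else np.empty(0)
    ys = placements["y_um"].to_numpy() if len(placements) else np.empty(0)
    ci = np.clip(np.round(xs / pitch - 0.5).astype(int), 0, nx - 1) if len(xs) else np.empty(0, int)
    ri = np.clip(np.round(ys / pitch - 0.5).astype(int), 0, ny - 1) if len(ys) else np.empty(0, int)
    for cell, (row, col) in enumerate(zip(ri, ci)):
        spot = row * nx + col
        dx = xs[cell] - centers[spot, 0]
        dy = ys[cell] - centers[spot, 1]
        if dx * dx + dy * dy <= r2:
            capture[barcodes[spot]].append(cell)

    n_genes = cell_expr.shape[0]
    mat = np.zeros((n_genes, len(barcodes)), dtype=np.int64)
    truth: dict[str, str] = {}
    types = placements["cell_type"].to_numpy() if len(placements) else np.empty(0, object)
    for j, b in enumerate(barcodes):
        cells = capture[b]
        if cells:
            mat[:, j] = cell_expr[:, cells].sum(axis=1)
            labels, counts = np.unique(types[cells], return_counts=True)
            # modal type; np.unique sorts labels, argmax takes the first
            # (lexicographically smallest) on ties
            truth[b] = str(labels[counts.argmax()])
        else:
            truth[b] = EMPTY

    spot_matrix = GeneSpotMatrix(
        values=mat, gene_ids=config.genes, spot_ids=barcodes, layer="counts"
    )
    return SimulatedTissue(
        config=config,
        cells=placements,
        cell_expr=cell_expr,
        spots=geom,
        capture=capture,
        spot_matrix=spot_matrix,
        truth=truth,
    )


def simulate(config: SimulationConfig, out_dir: str | None = None) -> SimulatedTissue:
    """Run place -> draw -> probe under one seed schedule.

    The master seed spawns independent substreams for placement/typing and
    expression, so the stages are independently reproducible.  When
    ``out_dir`` is given, writes the MTX bundle, positions CSV, truth TSV
    and the planted marker database there.
    """
    place_ss, expr_ss = _seedseq(config.seed).spawn(2)
    placements = place_cells(config, place_ss)
    cell_expr = draw_expression(placements, config, expr_ss)
    tissue = probe_spots(placements, cell_expr, config)
    if out_dir is not None:
        from . import spatial_io

        spatial_io.write_mtx_bundle(tissue.spot_matrix, out_dir)
        spatial_io.write_tissue_positions(
            tissue.spots, f"{out_dir}/tissue_positions.csv"
        )
        tissue.truth_frame().to_csv(f"{out_dir}/truth.tsv", sep="\t", index=False)
        config.to_marker_db().to_tsv(f"{out_dir}/markers.tsv")
    return tissue


def reference_profiles(
    config: SimulationConfig, cells_per_type: int = 3
) -> tuple[GeneSpotMatrix, dict[str, str]]:
    """Noiseless reference profiles: expected NB means per type, replicated.

    Useful as an idealized single-cell reference for marker derivation;
    counts equal the model means exactly (no sampling).
    """
    genes = config.genes
    cols: list[str] = []
    labels: dict[str, str] = {}
    mats = []
    for t in config.cell_types:
        mu = np.full(len(genes), config.mu_low)
        for g in config.marker_blocks[t]:
            mu[genes.index(g)] = config.mu_high
        for rep in range(cells_per_type):
            name = f"{t}-ref{rep + 1}"
            cols.append(name)
            labels[name] = t
            mats.append(mu)
    return (
        GeneSpotMatrix(
            values=np.column_stack(mats),
            gene_ids=genes,
            spot_ids=cols,
            layer="counts",
        ),
        labels,
    )
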