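"""Cell line-specific heterogeneous drug-drug interaction graphs.

For each cell line the measured pairs are split by interaction class into
three type-specific undirected subgraphs (synergistic, additive,
antagonistic).  Their adjacency matrices are stacked into an n x n x 3
interaction tensor whose frontal slices are the per-type adjacencies; this
tensor feeds both the Tucker factorization (global drug features) and the
graph transformer (local drug features).

Edges are binary by default; a score-weighted mode stores the synergy score
on the edge instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CLASSES, SCHEMES, SynergyDataset, ThresholdScheme

#: fixed slice order of the interaction tensor
SLICE_ORDER = CLASSES  # (synergistic, additive, antagonistic)


@dataclass
class HeteroGraph:
    """Three type-specific adjacency matrices for one cell line."""

    cell_line: str
    n: int
    adjacency: np.ndarray  # (3, n, n), slice t = A_{r|t}
    edge_weights_mode: str = "binary"

    def __post_init__(self):
        a = self.adjacency
        if a.shape != (3, self.n, self.n):
            raise ValueError(f"adjacency must be (3, n, n), got {a.shape}")
        if not np.isfinite(a).all():
            raise ValueError("non-finite adjacency entries")

    def slice(self, label: str) -> np.ndarray:
        return self.adjacency[SLICE_ORDER.index(label)]

    def edge_count(self) -> int:
        """Number of undirected edges across all three types."""
        return int(np.count_nonzero(self.adjacency) // 2)


@dataclass
class InteractionTensor:
    """The stacked n x n x 3 interaction tensor for one cell line."""

    cell_line: str
    values: np.ndarray  # (n, n, 3)

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError(f"expected (n, n, 3) tensor, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite tensor entries")


def build_cell_graph(
    dataset: SynergyDataset,
    cell_line: str,
    metric: str = "loewe",
    scheme: ThresholdScheme | None = None,
    edge_source=None,
    edge_weights: str = "binary",
) -> HeteroGraph:
    """Build the heterogeneous graph for one cell line.

    Parameters
    ----------
    edge_source
        Iterable of record indices allowed to contribute edges (e.g. the
        training fold, so held-out pairs never leak into the graph).  ``None``
        uses all records.
    edge_weights
        ``"binary"`` stores 1 on each edge; ``"score"`` stores the synergy
        score.
    """
    if cell_line not in dataset.cell_lines:
        raise ValueError(f"unknown cell line {cell_line!r}")
    if edge_weights not in ("binary", "score"):
        raise ValueError(f"edge_weights must be 'binary' or 'score', got {edge_weights!r}")
    scheme = scheme or SCHEMES[metric]
    n = dataset.n_drugs
    adjacency = np.zeros((3, n, n))
    indices = range(len(dataset.records)) if edge_source is None else edge_source
    for idx in indices:
        rec = dataset.records[idx]
        if rec.cell_line != cell_line or metric not in rec.scores:
            continue
        i = dataset.drug_index(rec.drug_i)
        j = dataset.drug_index(rec.drug_j)
        t = SLICE_ORDER.index(scheme.label(rec.scores[metric]))
        w = 1.0 if edge_weights == "binary" else rec.scores[metric]
        adjacency[t, i, j] = adjacency[t, j, i] = w
    return HeteroGraph(cell_line, n, adjacency, edge_weights)


def stack_tensor(graph: HeteroGraph) -> InteractionTensor:
    """Stack the three adjacencies into the interaction tensor; frontal slice
    ``l`` equals the type-``l`` adjacency exactly."""
    return InteractionTensor(graph.cell_line, np.moveaxis(graph.adjacency, 0, 2).copy())


def unstack_tensor(tensor: InteractionTensor,
                   edge_weights_mode: str = "binary") -> HeteroGraph:
    """Inverse of :func:`stack_tensor`."""
    values = np.moveaxis(tensor.values, 2, 0).copy()
    return HeteroGraph(tensor.cell_line, values.shape[1], values, edge_weights_mode)


def build_all_graphs(
    dataset: SynergyDataset,
    metric: str = "loewe",
    edge_source=None,
    edge_weights: str = "binary",
) -> dict[str, HeteroGraph]:
    return {
        cell: build_cell_graph(dataset, cell, metric, edge_source=edge_source,
                               edge_weights=edge_weights)
        for cell in dataset.cell_lines
    }


def edge_list(graph: HeteroGraph) -> pd.DataFrame:
    """Upper-triangular edge list (i, j, type, weight) for export/debugging."""
    rows = []
    for t, label in enumerate(SLICE_ORDER):
        ii, jj = np.nonzero(np.triu(graph.adjacency[t], k=1))
        for i, j in zip(ii, jj):
            rows.append({"i": int(i), "j": int(j), "type": label,
                         "weight": graph.adjacency[t, i, j]})
    return pd.DataFrame(rows, columns=["i", "j", "type", "weight"])
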