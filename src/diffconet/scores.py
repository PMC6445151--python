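"""Edge sets and the differential connectivity (DC) score.

The DC score between two association networks S1, S2 over an edge set E is
the size-normalized p-norm of the edgewise differences,

    delta_E = ( (1/|E|) * sum_{(i,j) in E} |S1_ij - S2_ij|**p )**(1/p)

for p >= 1; for 0 < p < 1 the outer 1/p exponent is dropped. Choosing E
gives three granularities: every pair in a pathway (pathway-level), the
star of one gene (gene-level), or a single pair (edge-level, where p is
immaterial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import AssociationMatrix

__all__ = ["EdgeSet", "DCScore", "edges_pathway", "edges_gene", "edge_single", "delta_E"]


@dataclass(frozen=True)
class EdgeSet:
    """A set of index pairs (i, j), i < j, over a pathway's gene order."""

    edges: frozenset[tuple[int, int]]
    scope: str  # pathway | gene | edge
    anchor: object = None  # gene id for scope=gene, (id, id) for scope=edge

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("edge set must be non-empty")
        for i, j in self.edges:
            if not i < j:
                raise ValueError(f"edge ({i},{j}) must have i < j")
        if self.scope not in ("pathway", "gene", "edge"):
            raise ValueError(f"unknown scope {self.scope!r}")

    def __len__(self) -> int:
        return len(self.edges)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = sorted(self.edges)
        ii = np.array([p[0] for p in pairs], dtype=int)
        jj = np.array([p[1] for p in pairs], dtype=int)
        return ii, jj


@dataclass(frozen=True)
class DCScore:
    value: float
    p_norm: float
    edge_count: int


def edges_pathway(gene_ids: list[str]) -> EdgeSet:
    """All |G|(|G|-1)/2 pairs of a pathway."""
    m = len(gene_ids)
    if m < 2:
        raise ValueError("pathway-level edge set needs at least 2 genes")
    pairs = frozenset((i, j) for i in range(m) for j in range(i + 1, m))
    return EdgeSet(pairs, "pathway")


def edges_gene(gene_ids: list[str], gene: str) -> EdgeSet:
    """The |G|-1 pairs incident to one gene."""
    if len(gene_ids) < 2:
        raise ValueError("gene-level edge set needs at least 2 genes")
    try:
        k = gene_ids.index(gene)
    except ValueError:
        raise ValueError(f"gene {gene!r} not in pathway") from None
    pairs = frozenset(
        (min(k, other), max(k, other)) for other in range(len(gene_ids)) if other != k
    )
    return EdgeSet(pairs, "gene", anchor=gene)


def edge_single(gene_ids: list[str], gene_i: str, gene_j: str) -> EdgeSet:
    """The singleton edge set for one gene pair."""
    a, b = gene_ids.index(gene_i), gene_ids.index(gene_j)
    if a == b:
        raise ValueError("edge endpoints must differ")
    i, j = min(a, b), max(a, b)
    return EdgeSet(
        frozenset({(i, j)}), "edge", anchor=(gene_ids[i], gene_ids[j])
    )


def delta_E(
    S1: AssociationMatrix, S2: AssociationMatrix, E: EdgeSet, p: float = 2.0
) -> DCScore:
    """Differential connectivity of E between two association networks."""
    if p <= 0:
        raise ValueError("p must be positive")
    if S1.gene_ids != S2.gene_ids:
        raise ValueError("association matrices must share an identical gene order")
    ii, jj = E.index_arrays()
    if ii.max() >= S1.n_genes:
        raise IndexError("edge set indexes beyond the gene order")
    diffs = np.abs(S1.scores[ii, jj] - S2.scores[ii, jj])
    mean_pow = float((diffs**p).mean())
    value = mean_pow ** (1.0 / p) if p >= 1 else mean_pow
    return DCScore(value, p, len(E))
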