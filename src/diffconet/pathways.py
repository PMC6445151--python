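"""Pathway collections: GMT I/O, Jaccard merging, size/activity filters,
and controlled misspecification for benchmarking.

Curated pathway databases decompose processes into overlapping events that
can differ by a single gene; near-duplicates are merged by complete-linkage
hierarchical clustering on Jaccard distance, cut low (default 0.1) so that
only heavily overlapping event sets collapse while higher-level pathways
stay separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "jaccard_distance",
    "merge_overlapping",
    "filter_by_size",
    "filter_inactive",
    "misspecify",
]


@dataclass
class PathwayCollection:
    """An ordered collection of named gene sets."""

    pathways: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [name for name, _ in self.pathways]
        if len(names) != len(set(names)):
            raise ValueError("pathway names must be unique")
        self.pathways = [(name, frozenset(genes)) for name, genes in self.pathways]
        for name, genes in self.pathways:
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def names(self) -> list[str]:
        return [name for name, _ in self.pathways]

    def genes(self, name: str) -> frozenset[str]:
        for n, g in self.pathways:
            if n == name:
                return g
        raise KeyError(name)

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, g in self.pathways:
            out |= g
        return frozenset(out)

    @classmethod
    def single_pathway(cls, genes, name: str = "all_genes") -> "PathwayCollection":
        """One pathway containing every gene — the no-pathway-information
        analysis is run through this."""
        return cls([(name, frozenset(genes))], source="all-genes")


def read_gmt(path) -> PathwayCollection:
    """Read gene sets from GMT: name TAB description TAB gene TAB gene ...

    Duplicate genes within a line are deduplicated; lines with fewer than
    three fields are rejected with the offending line number.
    """
    pathways: list[tuple[str, frozenset[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} field(s) found)"
                )
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways.append((name, genes))
    return PathwayCollection(pathways, source=str(path))


def write_gmt(P: PathwayCollection, path, description: str = "na") -> None:
    """Write a collection back as GMT (genes sorted for stable output)."""
    with open(path, "w") as fh:
        if P.source:
            fh.write(f"# source: {P.source}\n")
        for name, genes in P:
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def jaccard_distance(A, B) -> float:
    """1 minus the Jaccard index, |A∩B|/|A∪B|."""
    A, B = set(A), set(B)
    if not A and not B:
        raise ValueError("Jaccard distance undefined for two empty sets")
    return 1.0 - len(A & B) / len(A | B)


def merge_overlapping(
    P: PathwayCollection, cut_height: float = 0.1, representative: str = "largest"
) -> PathwayCollection:
    """Collapse near-duplicate pathways by hierarchical clustering.

    Complete linkage on pairwise Jaccard distances, dendrogram cut at
    ``cut_height``, so every within-cluster pair overlaps at least
    ``1 - cut_height``. Each cluster is represented either by its largest
    member pathway (ties broken by name; ``representative="largest"``) or by
    the union of its members (``representative="union"``).
    """
    if len(P) == 0:
        raise ValueError("empty pathway collection")
    if representative not in ("largest", "union"):
        raise ValueError("representative must be 'largest' or 'union'")
    if len(P) == 1:
        return PathwayCollection(list(P.pathways), source=P.source)
    items = list(P.pathways)
    k = len(items)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = jaccard_distance(items[i][1], items[j][1])
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    merged: list[tuple[str, frozenset[str]]] = []
    seen_clusters: list[int] = []
    for lab in labels:
        if lab not in seen_clusters:
            seen_clusters.append(lab)
    for lab in seen_clusters:
        members = [items[i] for i in range(k) if labels[i] == lab]
        if representative == "largest":
            rep = min(members, key=lambda nm: (-len(nm[1]), nm[0]))
            merged.append(rep)
        else:
            union: set[str] = set()
            for _, g in members:
                union |= g
            rep_name = min(m[0] for m in members)
            merged.append((rep_name, frozenset(union)))
    return PathwayCollection(merged, source=P.source)


def filter_by_size(
    P: PathwayCollection, min_size: int = 10, max_size: int = 100
) -> PathwayCollection:
    """Keep pathways with min_size <= |G| <= max_size (both inclusive)."""
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    kept = [(n, g) for n, g in P if min_size <= len(g) <= max_size]
    return PathwayCollection(kept, source=P.source)


def filter_inactive(
    P: PathwayCollection,
    expressed_genes,
    max_unexpressed_fraction: float = 0.20,
) -> PathwayCollection:
    """Drop pathways whose unexpressed-gene fraction strictly exceeds the
    threshold; surviving pathways keep their full membership."""
    expressed = set(expressed_genes)
    kept = []
    for name, genes in P:
        frac = len([g for g in genes if g not in expressed]) / len(genes)
        if frac <= max_unexpressed_fraction:
            kept.append((name, genes))
    return PathwayCollection(kept, source=P.source)


def misspecify(
    P: PathwayCollection, knowledge: float, gene_universe, seed: int
) -> PathwayCollection:
    """Emulate imperfect pathway databases.

    Per pathway, k = round((1 - knowledge) * |G|) members (round-half-up)
    are removed and replaced by genes drawn uniformly without replacement
    from ``gene_universe`` minus the pathway, leaving sizes unchanged.
    """
    if not 0.0 <= knowledge <= 1.0:
        raise ValueError("knowledge must be in [0, 1]")
    universe = set(gene_universe)
    rng = np.random.default_rng(seed)
    out: list[tuple[str, frozenset[str]]] = []
    for name, genes in P:
        size = len(genes)
        k = int(np.floor((1.0 - knowledge) * size + 0.5))  # round-half-up
        if k == 0:
            out.append((name, genes))
            continue
        outside = sorted(universe - genes)
        if len(outside) < k:
            raise ValueError(
                f"pathway {name!r}: need {k} replacement genes, only "
                f"{len(outside)} available outside the pathway"
            )
        members = sorted(genes)
        drop_idx = rng.choice(size, size=k, replace=False)
        dropped = {members[i] for i in drop_idx}
        added = rng.choice(len(outside), size=k, replace=False)
        new_genes = (genes - dropped) | {outside[i] for i in added}
        out.append((name, frozenset(new_genes)))
    return PathwayCollection(out, source=P.source)
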