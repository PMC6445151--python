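"""Two-group Gaussian-graphical-model benchmark generator.

Two multivariate-normal populations share a common network backbone and
differ by hub perturbations. Construction of the first network:

1. pathway sizes are drawn from a negative binomial with mean 20 and
   standard deviation 10 (method-of-moments: size r = mu^2/(sigma^2 - mu),
   success probability r/(r + mu)), floored at a minimum so small-world
   wiring is well-defined;
2. each pathway's nodes are sampled from the gene pool and wired with the
   Watts-Strogatz small-world generator;
3. hub nodes are drawn from the union of pathway members; a hub is
   connected to each co-pathway node independently with probability 1/2.

The second network starts as a copy: one third of the hubs are turned off
(all connections removed), another third rewired, the rest unchanged, and
2.5% of non-hub member nodes are rewired degree-preservingly within their
pathways. Nonzero precision entries are drawn uniformly from
(-1,-0.5) u (0.5,1); edges common to both networks share the same value;
positive definiteness is enforced by adding c = max(c1, c2) to both
diagonals, with c_k = (lmax_k/10 - lmin_k) * I(lmin_k < lmax_k/10).
Expression data are i.i.d. zero-mean multivariate normal draws with
covariance inv(Omega_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ExpressionMatrix
from .pathways import PathwayCollection

__all__ = [
    "NetworkPair",
    "SyntheticTruth",
    "draw_pathway_sizes",
    "generate_structure",
    "assign_precision_values",
    "sample_expression",
    "extract_truth",
    "simulate_pair",
    "FULL_PRESET",
    "SMALL_PRESET",
]

# First benchmark design: 500 genes, 20 pathways, 9 hubs.
FULL_PRESET = dict(m=500, n_pathways=20, n_hubs=9)
# Second design: 100 genes, one hub, a single pathway spanning the network.
SMALL_PRESET = dict(m=100, n_pathways=1, n_hubs=1, pathway_sizes=[100])


@dataclass
class NetworkPair:
    """Paired network structures (and, once filled, precision matrices)."""

    adjacency1: np.ndarray
    adjacency2: np.ndarray
    pathways: PathwayCollection
    hubs: list[str]
    hub_fates: dict[str, str]  # gene id -> off | rewired | unchanged
    gene_ids: list[str]
    omega1: np.ndarray | None = None
    omega2: np.ndarray | None = None
    diag_shift: float = 0.0  # c added to both diagonals for positive definiteness

    @property
    def m(self) -> int:
        return len(self.gene_ids)


@dataclass
class SyntheticTruth:
    """Ground-truth differential-connectivity labels."""

    dc_edges: frozenset[tuple[str, str]]
    dc_genes: frozenset[str] = field(default_factory=frozenset)
    dc_pathways: frozenset[str] = field(default_factory=frozenset)


def draw_pathway_sizes(
    n_pathways: int,
    mean: float = 20.0,
    sd: float = 10.0,
    seed: int = 0,
    min_size: int | None = 5,
) -> np.ndarray:
    """Negative-binomial pathway sizes with the given mean and sd.

    ``min_size=None`` disables the floor (useful when checking the raw
    distribution's moments).
    """
    if sd**2 <= mean:
        raise ValueError("need sd^2 > mean for a negative binomial")
    r = mean**2 / (sd**2 - mean)
    p = r / (r + mean)
    rng = np.random.default_rng(seed)
    sizes = rng.negative_binomial(r, p, size=n_pathways)
    if min_size is not None:
        sizes = np.maximum(sizes, min_size)
    return sizes.astype(int)


def _bernoulli_star(rng, hub: int, partners: list[int], adj: np.ndarray) -> None:
    for node in partners:
        if node != hub and rng.random() < 0.5:
            adj[hub, node] = adj[node, hub] = True


def _clear_node(adj: np.ndarray, node: int) -> None:
    adj[node, :] = False
    adj[:, node] = False


def generate_structure(
    m: int = 500,
    n_pathways: int = 20,
    n_hubs: int = 9,
    seed: int = 0,
    size_mean: float = 20.0,
    size_sd: float = 10.0,
    min_size: int = 5,
    ws_neighbors: int = 2,
    ws_rewire_prob: float = 0.1,
    nonhub_rewire_frac: float = 0.025,
    pathway_sizes: list[int] | None = None,
) -> NetworkPair:
    """Build the paired network structures (adjacencies, pathways, hubs)."""
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1}" for i in range(m)]
    if pathway_sizes is None:
        sizes = draw_pathway_sizes(
            n_pathways, size_mean, size_sd,
            seed=int(rng.integers(2**31)), min_size=min_size,
        )
    else:
        sizes = np.asarray(pathway_sizes, dtype=int)
        if len(sizes) != n_pathways:
            raise ValueError("pathway_sizes length must equal n_pathways")
    if np.any(sizes > m):
        raise ValueError("a pathway size exceeds the number of genes")

    adj1 = np.zeros((m, m), dtype=bool)
    memberships: list[np.ndarray] = []
    for size in sizes:
        nodes = rng.choice(m, size=int(size), replace=False)
        memberships.append(np.sort(nodes))
        k = min(ws_neighbors, int(size) - 1)
        g = nx.watts_strogatz_graph(
            int(size), k, ws_rewire_prob, seed=int(rng.integers(2**31))
        )
        for a, b in g.edges():
            adj1[nodes[a], nodes[b]] = adj1[nodes[b], nodes[a]] = True

    member_union = np.unique(np.concatenate(memberships))
    if len(member_union) < n_hubs:
        raise ValueError("fewer pathway member nodes than requested hubs")
    hubs = rng.choice(member_union, size=n_hubs, replace=False)
    pathway_of: dict[int, list[int]] = {}
    for pi, nodes in enumerate(memberships):
        for node in nodes:
            pathway_of.setdefault(int(node), []).append(pi)
    for hub in hubs:
        _clear_node(adj1, hub)  # rewired *as* a hub: prior edges replaced
        for pi in pathway_of[int(hub)]:
            _bernoulli_star(rng, int(hub), [int(x) for x in memberships[pi]], adj1)

    adj2 = adj1.copy()
    n_off = n_hubs // 3
    n_rew = n_hubs // 3
    fates: dict[str, str] = {}
    for idx, hub in enumerate(hubs):
        if idx < n_off:
            fate = "off"
            _clear_node(adj2, hub)
        elif idx < n_off + n_rew:
            fate = "rewired"
            _clear_node(adj2, hub)
            for pi in pathway_of[int(hub)]:
                _bernoulli_star(rng, int(hub), [int(x) for x in memberships[pi]], adj2)
        else:
            fate = "unchanged"
        fates[gene_ids[int(hub)]] = fate

    hub_set = set(int(h) for h in hubs)
    off_hubs = {int(h) for h in hubs if fates[gene_ids[int(h)]] == "off"}
    nonhub_members = [int(x) for x in member_union if int(x) not in hub_set]
    k_rewire = int(np.floor(nonhub_rewire_frac * len(nonhub_members) + 0.5))
    if k_rewire > 0:
        chosen = rng.choice(len(nonhub_members), size=k_rewire, replace=False)
        for ci in chosen:
            node = nonhub_members[ci]
            degree = int(adj2[node].sum())
            _clear_node(adj2, node)
            # turned-off hubs must stay isolated in the second network
            partners = sorted(
                {int(x) for pi in pathway_of[node] for x in memberships[pi]}
                - {node} - off_hubs
            )
            degree = min(degree, len(partners))
            if degree > 0:
                new = rng.choice(len(partners), size=degree, replace=False)
                for ni in new:
                    adj2[node, partners[ni]] = adj2[partners[ni], node] = True

    pathway_list = [
        (f"pathway_{pi + 1}", frozenset(gene_ids[int(x)] for x in nodes))
        for pi, nodes in enumerate(memberships)
    ]
    return NetworkPair(
        adjacency1=adj1,
        adjacency2=adj2,
        pathways=PathwayCollection(pathway_list, source="synthetic"),
        hubs=[gene_ids[int(h)] for h in hubs],
        hub_fates=fates,
        gene_ids=gene_ids,
    )


def assign_precision_values(pair: NetworkPair, seed: int = 0) -> NetworkPair:
    """Fill both precision matrices on the generated supports.

    Edge values are uniform on (-1,-0.5) u (0.5,1) with equal sign
    probability; edges common to both networks share the same value; the
    same diagonal shift c = max(c1, c2) is added to both matrices so the
    common entries stay bitwise equal.
    """
    rng = np.random.default_rng(seed)
    m = pair.m
    omega1 = np.eye(m)
    omega2 = np.eye(m)

    def draw_value() -> float:
        mag = rng.uniform(0.5, 1.0)
        return mag if rng.random() < 0.5 else -mag

    ii, jj = np.where(np.tril(pair.adjacency1 | pair.adjacency2, k=-1))
    for a, b in zip(ii, jj):
        val = draw_value()
        if pair.adjacency1[a, b]:
            omega1[a, b] = omega1[b, a] = val
        if pair.adjacency2[a, b]:
            omega2[a, b] = omega2[b, a] = val

    def shift(om: np.ndarray) -> float:
        eig = np.linalg.eigvalsh(om)
        lmin, lmax = eig[0], eig[-1]
        return (lmax / 10.0 - lmin) if lmin < lmax / 10.0 else 0.0

    c = max(shift(omega1), shift(omega2))
    omega1[np.diag_indices(m)] += c
    omega2[np.diag_indices(m)] += c
    pair.omega1 = omega1
    pair.omega2 = omega2
    pair.diag_shift = c
    return pair


def sample_expression(
    pair: NetworkPair, n_per_group: int, seed: int = 0
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw i.i.d. samples from N(0, inv(Omega_k)) for each group."""
    if pair.omega1 is None or pair.omega2 is None:
        raise ValueError("precision values not assigned; call assign_precision_values")
    rng = np.random.default_rng(seed)
    out = []
    for k, omega in enumerate((pair.omega1, pair.omega2), start=1):
        try:
            np.linalg.cholesky(omega)
        except np.linalg.LinAlgError:
            raise ValueError(f"omega{k} is not positive definite") from None
        cov = np.linalg.inv(omega)
        cov = (cov + cov.T) / 2.0
        vals = rng.multivariate_normal(
            np.zeros(pair.m), cov, size=n_per_group, method="cholesky"
        )
        out.append(
            ExpressionMatrix(
                vals,
                list(pair.gene_ids),
                [f"grp{k}_s{i + 1}" for i in range(n_per_group)],
                group_label=f"group{k}",
            )
        )
    return out[0], out[1]


def extract_truth(pair: NetworkPair) -> SyntheticTruth:
    """Label DC edges (Omega1_ij != Omega2_ij), genes, and pathways."""
    if pair.omega1 is None or pair.omega2 is None:
        raise ValueError("precision values not assigned")
    ii, jj = np.where(np.triu(pair.omega1 != pair.omega2, k=1))
    # canonical edge form: lexicographically sorted gene-id pairs
    dc_edges = frozenset(
        tuple(sorted((pair.gene_ids[int(a)], pair.gene_ids[int(b)])))
        for a, b in zip(ii, jj)
    )
    dc_genes = frozenset(g for edge in dc_edges for g in edge)
    dc_pathways = frozenset(
        name
        for name, genes in pair.pathways
        if any(a in genes and b in genes for a, b in dc_edges)
    )
    return SyntheticTruth(dc_edges, dc_genes, dc_pathways)


def simulate_pair(
    n_per_group: int,
    seed: int = 0,
    **structure_kwargs,
) -> tuple[NetworkPair, ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Full benchmark draw: structure, precision values, expression, truth.

    A master seed spawns independent child seeds for the three stages so
    each can be varied on its own.
    """
    ss = np.random.SeedSequence(seed)
    s_struct, s_vals, s_expr = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    pair = generate_structure(seed=s_struct, **structure_kwargs)
    pair = assign_precision_values(pair, seed=s_vals)
    X1, X2 = sample_expression(pair, n_per_group, seed=s_expr)
    return pair, X1, X2, extract_truth(pair)
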