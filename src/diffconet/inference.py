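"""Permutation inference for differential connectivity scores.

Under the null that an edge set E is identically connected in both groups,
group labels are exchangeable: the stacked samples are reshuffled, networks
are re-estimated on each permuted split, and the DC score recomputed. The
Monte-Carlo p-value is (b + 1)/(B + 1) with b = #{i : d0 <= d_i}, which is
never zero. When the number of distinct splits is small (at most
``exhaustive_cap``), all splits are enumerated instead — for equal group
sizes, up to the group-label swap, since delta_E is symmetric in the
groups — and p = #{d_i >= d0}/N over the full reference set including the
observed split. With n = 3 per group this gives C(6,3)/2 = 10 splits and a
p-value floor of 0.1.

When several edge sets are tested within one pathway, the same permutations
are shared across all of them and Westfall-Young step-down maxT p-values
monotonize the results: larger observed scores always receive
smaller-or-equal adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .association import estimate_association
from .io import ExpressionMatrix
from .scores import EdgeSet

__all__ = [
    "PermutationPlan",
    "PermutationResult",
    "permute_labels",
    "permutation_pvalue",
    "monotonize",
    "run_permutation_test",
]


@dataclass
class PermutationPlan:
    """How to build the permutation reference set.

    ``exhaustive`` may be True, False, or None (decide automatically: use
    enumeration when the number of distinct splits is <= exhaustive_cap).
    """

    B: int = 100
    seed: int = 0
    exhaustive: bool | None = None
    exhaustive_cap: int = 200

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class PermutationResult:
    """Observed scores with raw and monotonized permutation p-values."""

    edge_sets: list[EdgeSet]
    d0: np.ndarray  # (H,)
    perm_scores: np.ndarray  # (H, B) — includes the observed split if exhaustive
    p_raw: np.ndarray
    p_mono: np.ndarray
    exhaustive: bool
    n_permutations: int
    seed: int = 0
    genes: list[str] = field(default_factory=list)


def permute_labels(
    X1: ExpressionMatrix, X2: ExpressionMatrix, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Shuffle the stacked rows of both groups and re-split at n1."""
    if X1.gene_ids != X2.gene_ids:
        raise ValueError("groups must share an identical gene order")
    n1 = X1.n_samples
    stacked = np.vstack([X1.values, X2.values])
    ids = list(X1.sample_ids) + list(X2.sample_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(stacked.shape[0])
    shuffled = stacked[order]
    ids = [ids[i] for i in order]
    Xa = ExpressionMatrix(shuffled[:n1], list(X1.gene_ids), ids[:n1], X1.group_label)
    Xb = ExpressionMatrix(shuffled[n1:], list(X1.gene_ids), ids[n1:], X2.group_label)
    return Xa, Xb


def permutation_pvalue(d0: float, perm_scores: np.ndarray) -> float:
    """Monte-Carlo p-value (b + 1)/(B + 1), b = #{i : d0 <= d_i}."""
    perm_scores = np.asarray(perm_scores, dtype=float)
    B = perm_scores.size
    if B < 1:
        raise ValueError("need at least one permutation score")
    b = int((d0 <= perm_scores).sum())
    return (b + 1) / (B + 1)


def _equalize_ties(d0: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hypotheses with identical observed scores share the same adjusted
    p-value (the largest within the tie group)."""
    out = q.copy()
    for val in np.unique(d0):
        mask = d0 == val
        out[mask] = out[mask].max()
    return out


def monotonize(
    d0s: np.ndarray, perm_scores: np.ndarray, exhaustive: bool = False
) -> np.ndarray:
    """Westfall-Young step-down maxT adjusted p-values.

    Hypotheses are ordered by decreasing observed score; for rank h the
    reference statistic in permutation b is the maximum permuted score over
    ranks >= h, and q_h = (#exceedances + 1)/(B + 1) (or #/N when the
    reference set exhaustively includes the observed split). Monotonicity
    q_1 <= q_2 <= ... is then enforced, so larger observed scores always
    receive smaller-or-equal adjusted p-values.
    """
    d0s = np.asarray(d0s, dtype=float)
    perm_scores = np.asarray(perm_scores, dtype=float)
    if perm_scores.ndim != 2 or perm_scores.shape[0] != d0s.shape[0]:
        raise ValueError("perm_scores must be (n_hypotheses, n_permutations)")
    H, B = perm_scores.shape
    order = np.argsort(-d0s, kind="stable")  # decreasing d0
    # running max over ranks h..H-1 of each permutation's scores
    tail_max = np.maximum.accumulate(perm_scores[order][::-1], axis=0)[::-1]
    counts = (tail_max >= d0s[order][:, np.newaxis]).sum(axis=1)
    if exhaustive:
        q = counts / B
    else:
        q = (counts + 1) / (B + 1)
    q = np.maximum.accumulate(q)  # enforce step-down monotonicity
    out = np.empty(H, dtype=float)
    out[order] = q
    return _equalize_ties(d0s, out)


def _delta_from_diff(D: np.ndarray, E: EdgeSet, p: float) -> float:
    ii, jj = E.index_arrays()
    mean_pow = float((D[ii, jj] ** p).mean())
    return mean_pow ** (1.0 / p) if p >= 1 else mean_pow


def _distinct_splits(n1: int, n2: int) -> int:
    n = comb(n1 + n2, n1)
    return n // 2 if n1 == n2 else n


def run_permutation_test(
    X1: ExpressionMatrix,
    X2: ExpressionMatrix,
    genes: list[str],
    edge_sets: list[EdgeSet],
    measure: str = "partial_shrinkage",
    p_norm: float = 2.0,
    plan: PermutationPlan | None = None,
    beta: float = 1.0,
    gamma: float = 0.5,
) -> PermutationResult | None:
    """Permutation test for every edge set of one pathway.

    ``genes`` is the ordered pathway gene list; edge sets index into that
    order. Association networks are re-estimated on every permuted split,
    and the SAME splits are shared across all edge sets so that the
    step-down monotonization is valid. Returns None (with a warning) when
    fewer than 2 pathway genes are present in both groups.
    """
    if plan is None:
        plan = PermutationPlan()
    shared = [g for g in genes if g in X1.gene_ids and g in X2.gene_ids]
    if len(shared) < 2:
        warnings.warn(
            f"pathway has {len(shared)} gene(s) present in both groups; skipped",
            stacklevel=2,
        )
        return None
    if shared != list(genes):
        raise ValueError(
            "edge sets were built for a gene order that is not fully present "
            "in both expression matrices; intersect first"
        )
    X1g = X1.subset_genes(shared)
    X2g = X2.subset_genes(shared)
    n1, n2 = X1g.n_samples, X2g.n_samples
    stacked = np.vstack([X1g.values, X2g.values])
    n = n1 + n2

    def estimate(vals: np.ndarray):
        Xm = ExpressionMatrix(vals, shared)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return estimate_association(Xm, measure, beta=beta, gamma=gamma)

    S1 = estimate(X1g.values)
    S2 = estimate(X2g.values)
    D0 = np.abs(S1.scores - S2.scores)
    d0 = np.array([_delta_from_diff(D0, E, p_norm) for E in edge_sets])

    n_splits = _distinct_splits(n1, n2)
    exhaustive = plan.exhaustive
    if exhaustive is None:
        exhaustive = n_splits <= plan.exhaustive_cap

    H = len(edge_sets)
    if exhaustive:
        splits = []
        for combo in combinations(range(n), n1):
            if n1 == n2 and 0 not in combo:
                continue  # label swap gives an identical delta_E
            splits.append(combo)
        perm = np.empty((H, len(splits)))
        for b, combo in enumerate(splits):
            idx1 = np.array(combo)
            mask = np.ones(n, dtype=bool)
            mask[idx1] = False
            Sa = estimate(stacked[idx1])
            Sb = estimate(stacked[mask])
            D = np.abs(Sa.scores - Sb.scores)
            perm[:, b] = [_delta_from_diff(D, E, p_norm) for E in edge_sets]
        counts = (perm >= d0[:, np.newaxis]).sum(axis=1)
        p_raw = counts / len(splits)
        n_perm = len(splits)
    else:
        rng = np.random.default_rng(plan.seed)
        perm = np.empty((H, plan.B))
        for b in range(plan.B):
            order = rng.permutation(n)
            Sa = estimate(stacked[order[:n1]])
            Sb = estimate(stacked[order[n1:]])
            D = np.abs(Sa.scores - Sb.scores)
            perm[:, b] = [_delta_from_diff(D, E, p_norm) for E in edge_sets]
        p_raw = np.array([permutation_pvalue(d, perm[h]) for h, d in enumerate(d0)])
        n_perm = plan.B
    p_mono = monotonize(d0, perm, exhaustive=exhaustive)
    return PermutationResult(
        list(edge_sets), d0, perm, p_raw, p_mono, exhaustive, n_perm, plan.seed, shared
    )
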