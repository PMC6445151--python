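"""Model / Results interface for pathway-integrated differential network
analysis.

``DifferentialNetworkModel`` holds two groups of expression samples and a
pathway collection; ``fit`` estimates an association network per group
within every pathway, scores differential connectivity at the requested
granularities, and attaches permutation p-values (raw and Westfall-Young
monotonized, the latter computed jointly within each pathway). The returned
``DifferentialNetworkResults`` carries the tidy hypothesis table, a
``summary()`` view, and ranking/filtering helpers.

Pathways are analyzed independently: each pathway derives its permutation
seed from the master seed and its own name, so results do not depend on
the order pathways are visited.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .association import MEASURES
from .inference import PermutationPlan, run_permutation_test
from .io import ExpressionMatrix
from .pathways import PathwayCollection
from .scores import edges_gene, edges_pathway, edge_single

__all__ = ["AnalysisConfig", "DifferentialNetworkModel", "DifferentialNetworkResults"]


@dataclass
class AnalysisConfig:
    """Analysis-wide choices; serialized verbatim into run manifests."""

    measure: str = "partial_shrinkage"
    p_norm: float = 2.0
    B: int = 100
    alpha: float = 0.05
    seed: int = 0
    scopes: tuple[str, ...] = ("pathway", "gene")
    soft_beta: float = 1.0
    hard_gamma: float = 0.5
    exhaustive: bool | None = None
    exhaustive_cap: int = 200
    merge_cut_height: float = 0.1
    min_pathway_size: int = 10
    max_pathway_size: int = 100
    max_unexpressed_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        if self.p_norm <= 0:
            raise ValueError("p_norm must be positive")
        bad = [s for s in self.scopes if s not in ("pathway", "gene", "edge")]
        if bad:
            raise ValueError(f"unknown scope(s): {bad}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scopes"] = list(self.scopes)
        return d


def _pathway_seed(master_seed: int, name: str) -> int:
    """Stable per-pathway child seed, independent of pathway order."""
    state = np.random.SeedSequence([master_seed, zlib.crc32(name.encode())])
    return int(state.generate_state(1)[0] % 2**31)


class DifferentialNetworkModel:
    """Two-group differential co-expression network model.

    Parameters
    ----------
    X1, X2 : ExpressionMatrix
        Samples x genes expression for the two groups; gene sets may
        differ, pathways are intersected with the genes present in both.
    pathways : PathwayCollection, optional
        Gene sets to analyze. When omitted, a single pathway containing
        all shared genes is used (the no-pathway-information analysis).
    config : AnalysisConfig, optional
        Analysis-wide settings; keyword arguments override its fields.
    """

    def __init__(
        self,
        X1: ExpressionMatrix,
        X2: ExpressionMatrix,
        pathways: PathwayCollection | None = None,
        config: AnalysisConfig | None = None,
        **config_overrides,
    ) -> None:
        self.X1 = X1
        self.X2 = X2
        cfg = config if config is not None else AnalysisConfig()
        if config_overrides:
            d = cfg.to_dict()
            d.update(config_overrides)
            d["scopes"] = tuple(d["scopes"])
            cfg = AnalysisConfig(**d)
        self.config = cfg
        shared = [g for g in X1.gene_ids if g in set(X2.gene_ids)]
        if len(shared) < 2:
            raise ValueError("groups share fewer than 2 genes")
        self.shared_genes = shared
        if pathways is None:
            pathways = PathwayCollection.single_pathway(shared)
        if len(pathways) == 0:
            raise ValueError("empty pathway collection")
        self.pathways = pathways

    @classmethod
    def from_dataframes(
        cls,
        df1: pd.DataFrame,
        df2: pd.DataFrame,
        pathways: PathwayCollection | None = None,
        group_labels: tuple[str, str] = ("group1", "group2"),
        **kwargs,
    ) -> "DifferentialNetworkModel":
        return cls(
            ExpressionMatrix.from_dataframe(df1, group_labels[0]),
            ExpressionMatrix.from_dataframe(df2, group_labels[1]),
            pathways,
            **kwargs,
        )

    def _edge_sets(self, genes: list[str]):
        cfg = self.config
        sets, anchors = [], []
        if "pathway" in cfg.scopes:
            sets.append(edges_pathway(genes))
            anchors.append(("pathway", ""))
        if "gene" in cfg.scopes:
            for g in genes:
                sets.append(edges_gene(genes, g))
                anchors.append(("gene", g))
        if "edge" in cfg.scopes:
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    sets.append(edge_single(genes, genes[i], genes[j]))
                    anchors.append(("edge", f"{genes[i]}|{genes[j]}"))
        return sets, anchors

    def fit(self, seed: int | None = None) -> "DifferentialNetworkResults":
        """Run the full analysis over every pathway."""
        cfg = self.config
        master_seed = cfg.seed if seed is None else seed
        all_vals: dict[str, list[np.ndarray]] = {}
        for X in (self.X1, self.X2):
            for j, g in enumerate(X.gene_ids):
                all_vals.setdefault(g, []).append(X.values[:, j])
        gene_means = {g: float(np.concatenate(v).mean()) for g, v in all_vals.items()}

        rows = []
        n_dropped_total = 0
        for name, genes in self.pathways:
            ordered = [g for g in self.shared_genes if g in genes]
            n_dropped = len(genes) - len(ordered)
            n_dropped_total += n_dropped
            if len(ordered) < 2:
                warnings.warn(
                    f"pathway {name!r}: fewer than 2 genes in the expression "
                    "data; skipped",
                    stacklevel=2,
                )
                continue
            edge_sets, anchors = self._edge_sets(ordered)
            plan = PermutationPlan(
                B=cfg.B,
                seed=_pathway_seed(master_seed, name),
                exhaustive=cfg.exhaustive,
                exhaustive_cap=cfg.exhaustive_cap,
            )
            res = run_permutation_test(
                self.X1,
                self.X2,
                ordered,
                edge_sets,
                measure=cfg.measure,
                p_norm=cfg.p_norm,
                plan=plan,
                beta=cfg.soft_beta,
                gamma=cfg.hard_gamma,
            )
            if res is None:
                continue
            for h, (scope, anchor) in enumerate(anchors):
                if scope == "pathway":
                    expr = float(np.mean([gene_means[g] for g in ordered]))
                elif scope == "gene":
                    expr = gene_means[anchor]
                else:
                    a, b = anchor.split("|")
                    expr = (gene_means[a] + gene_means[b]) / 2.0
                rows.append(
                    {
                        "pathway": name,
                        "scope": scope,
                        "anchor": anchor,
                        "n_genes": len(ordered),
                        "d0": res.d0[h],
                        "p_raw": res.p_raw[h],
                        "p_mono": res.p_mono[h],
                        "n_permutations": res.n_permutations,
                        "exhaustive": res.exhaustive,
                        "seed": plan.seed,
                        "mean_expr": expr,
                        "de_flag": False,  # hook for externally supplied DE calls
                    }
                )
        table = pd.DataFrame(rows)
        return DifferentialNetworkResults(
            self, table, master_seed, n_dropped_total, gene_means
        )


class DifferentialNetworkResults:
    """Fitted differential-connectivity hypotheses with p-values."""

    def __init__(
        self,
        model: DifferentialNetworkModel,
        table: pd.DataFrame,
        seed: int,
        n_genes_dropped: int = 0,
        gene_means: dict[str, float] | None = None,
    ) -> None:
        self.model = model
        self.table = table
        self.seed = seed
        self.n_genes_dropped = n_genes_dropped
        self.gene_means = gene_means or {}

    def significant(self, alpha: float | None = None, monotonized: bool = True):
        """Rows called differentially connected at level alpha."""
        alpha = self.model.config.alpha if alpha is None else alpha
        col = "p_mono" if monotonized else "p_raw"
        return self.table[self.table[col] <= alpha]

    def rank(self, require_high_expression: bool = False) -> pd.DataFrame:
        """Sort by (p_mono, -d0); optionally keep only hypotheses whose
        anchor's mean expression is at or above the gene-wise median."""
        t = self.table
        if require_high_expression and len(t):
            median = float(np.median(list(self.gene_means.values())))
            t = t[t["mean_expr"] >= median]
        return t.sort_values(
            ["p_mono", "d0"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary(self, top: int = 10) -> str:
        cfg = self.model.config
        t = self.table
        lines = [
            "Differential Network Analysis Results",
            "=" * 61,
            f"measure: {cfg.measure:<22} p-norm: {cfg.p_norm}",
            f"groups:  n1={self.model.X1.n_samples}, n2={self.model.X2.n_samples}"
            f"   pathways analyzed: {t['pathway'].nunique() if len(t) else 0}",
            f"permutations: B={cfg.B} (exhaustive where feasible)   seed: {self.seed}",
            f"hypotheses: {len(t)}   significant at alpha={cfg.alpha}: "
            f"{len(self.significant())}",
            "-" * 61,
        ]
        if len(t):
            head = self.rank().head(top)
            lines.append(
                f"{'pathway':<22}{'scope':<9}{'anchor':<14}"
                f"{'d0':>7}{'p_raw':>8}{'p_mono':>8}"
            )
            for _, r in head.iterrows():
                lines.append(
                    f"{str(r['pathway'])[:21]:<22}{r['scope']:<9}"
                    f"{str(r['anchor'])[:13]:<14}{r['d0']:>7.3f}"
                    f"{r['p_raw']:>8.3g}{r['p_mono']:>8.3g}"
                )
        lines.append("=" * 61)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DifferentialNetworkResults: {len(self.table)} hypotheses, "
            f"seed={self.seed}>"
        )
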