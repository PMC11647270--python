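"""Prior-based gene–cell specificity scoring and gene selection.

The core idea: a gene whose expression is concentrated in one cell type is
far less likely to have its between-condition signal masked (or faked) by
the cell-type mixing inside spots. Scoring each gene's specificity from a
single-cell prior, keeping only genes whose best score clears a threshold,
attributing each kept gene to its top cell type, and restricting the FDR
correction to the kept genes turns an uninformative regional comparison
into a usable per-cell-type DEG analysis.

Two specificity metrics are supported, both row-normalized so scores per
gene sum to one across cell types:

``mean``        score[g, c] = mean_expr[g, c] / Σ_j mean_expr[g, j]
``frequency``   score[g, c] = detect_rate[g, c] / Σ_j detect_rate[g, j]
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .deg import DEGResult, bh_adjust
from .singlecell import SCDataset

__all__ = [
    "SpecificityScores",
    "mean_specificity",
    "frequency_specificity",
    "select_genes",
    "prior_selected_deg",
    "matched_baselines",
]


@dataclass
class SpecificityScores:
    """Genes × cell types specificity in [0, 1], rows summing to 1.

    Genes with a zero denominator (never expressed / never detected) are
    flagged unscored and excluded from any selection.
    """

    genes: np.ndarray
    cell_types: np.ndarray
    score: np.ndarray  # (G, C); rows of unscored genes are 0
    metric: str  # 'mean' | 'frequency'
    unscored: np.ndarray  # (G,) bool

    @property
    def argmax_type(self) -> np.ndarray:
        """Top cell type per gene (ties -> lexicographically smallest id)."""
        order = np.argsort(self.cell_types)
        best = order[np.argmax(self.score[:, order], axis=1)]
        return self.cell_types[best]

    def to_frame(self) -> pd.DataFrame:
        g, c = np.meshgrid(
            np.arange(len(self.genes)), np.arange(len(self.cell_types)), indexing="ij"
        )
        is_argmax = self.cell_types[c.ravel()] == np.repeat(
            self.argmax_type, len(self.cell_types)
        )
        return pd.DataFrame(
            {
                "gene": self.genes[g.ravel()],
                "cell_type": self.cell_types[c.ravel()],
                "score": self.score.ravel(),
                "metric": self.metric,
                "argmax": is_argmax & ~np.repeat(self.unscored, len(self.cell_types)),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpecificityScores":
        df = pd.read_csv(path, sep="\t")
        genes = df["gene"].drop_duplicates().to_numpy()
        cts = df["cell_type"].drop_duplicates().to_numpy()
        score = (
            df.pivot(index="gene", columns="cell_type", values="score")
            .loc[genes, cts]
            .to_numpy()
        )
        unscored = score.sum(axis=1) == 0
        return cls(genes, cts, score, str(df["metric"].iloc[0]), unscored)


def _normalize_rows(
    genes: np.ndarray, cell_types: np.ndarray, raw: np.ndarray, metric: str
) -> SpecificityScores:
    denom = raw.sum(axis=1)
    unscored = denom == 0
    score = np.zeros_like(raw, dtype=float)
    ok = ~unscored
    score[ok] = raw[ok] / denom[ok, None]
    return SpecificityScores(
        np.asarray(genes, dtype=object),
        np.asarray(cell_types, dtype=object),
        score,
        metric,
        unscored,
    )


def mean_specificity(
    type_means: np.ndarray, genes: np.ndarray, cell_types: np.ndarray
) -> SpecificityScores:
    """Mean-expression specificity: each cell type's average expression of a
    gene, scaled by the sum of the averages across all cell types."""
    type_means = np.asarray(type_means, dtype=float)
    if np.any(type_means < 0):
        raise ValueError("type means must be non-negative")
    return _normalize_rows(genes, cell_types, type_means, "mean")


def frequency_specificity(sc: SCDataset) -> SpecificityScores:
    """Detection-frequency specificity: the per-type fraction of cells
    expressing the gene, scaled by the sum of fractions across types."""
    cts = np.array(list(dict.fromkeys(sc.cell_type)), dtype=object)
    rate = np.empty((sc.counts.shape[1], len(cts)))
    for c, ct in enumerate(cts):
        block = sc.counts[sc.cell_type == ct]
        if block.shape[0] == 0:
            raise ValueError(f"cell type {ct!r} has no cells")
        rate[:, c] = (block > 0).mean(axis=0)
    return _normalize_rows(sc.genes, cts, rate, "frequency")


def select_genes(scores: SpecificityScores, threshold: float) -> dict:
    """Keep genes whose top score clears the (inclusive) threshold.

    Each kept gene is attributed to exactly one cell type — its argmax —
    so downstream it is evaluated for that type only, if at all. Unscored
    genes can never clear any threshold.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    keep = (scores.score.max(axis=1) >= threshold) & ~scores.unscored
    attribution = scores.argmax_type
    return {
        str(g): str(attribution[i]) for i, g in enumerate(scores.genes) if keep[i]
    }


def prior_selected_deg(
    p_values: np.ndarray,
    genes: np.ndarray,
    selection: dict,
    alpha: float = 0.01,
    method: str = "ttest",
) -> list[DEGResult]:
    """Subset-restricted FDR on regional p-values.

    Selection happens after the test ran on all genes and affects only the
    correction: BH is applied with m = number of selected genes, and each
    selected gene is called for its attributed cell type alone.
    """
    genes = np.asarray(genes, dtype=object)
    sel_mask = np.array([str(g) in selection for g in genes])
    if not sel_mask.any():
        import warnings

        warnings.warn("empty gene selection; no DEG calls possible")
        return []
    sub_genes = genes[sel_mask]
    p_sub = np.asarray(p_values, dtype=float)[sel_mask]
    p_adj = bh_adjust(p_sub)
    attributed = np.array([selection[str(g)] for g in sub_genes], dtype=object)
    results = []
    for ct in sorted(set(attributed)):
        m = attributed == ct
        results.append(
            DEGResult(
                f"{method}+prior",
                str(ct),
                sub_genes[m],
                p_sub[m],
                p_adj[m],
                p_adj[m] <= alpha,
            )
        )
    return results


def matched_baselines(
    genes: np.ndarray,
    k: int,
    mode: str = "random",
    seed: int = 0,
    external_list: np.ndarray | None = None,
) -> np.ndarray:
    """Size-matched control selections for the prior-based scheme.

    ``random`` draws k genes uniformly without replacement. With
    ``external_list`` (e.g. a data-driven tool's own gene subset), k genes
    are drawn from the list without repetition; if k exceeds the list, the
    whole list is used and genes repeat to reach k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = stage_rng(seed, "matched_baselines")
    genes = np.asarray(genes, dtype=object)
    if mode == "random":
        if k > len(genes):
            raise ValueError("k exceeds the number of genes")
        return rng.choice(genes, size=k, replace=False)
    if mode == "external_list":
        if external_list is None:
            raise ValueError("external_list mode requires a gene list")
        pool = np.asarray(external_list, dtype=object)
        if k <= len(pool):
            return rng.choice(pool, size=k, replace=False)
        extra = rng.choice(pool, size=k - len(pool), replace=True)
        return np.concatenate([pool, extra])
    raise ValueError(f"unknown mode {mode!r}")
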