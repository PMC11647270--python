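"""Filtering, normalization, and native DEG tests for spot data.

Tests compare the two condition regions per cell type under three input
modes: ``containing`` (spots holding at least one cell of the focal type —
the informative default), ``single`` (spots predominantly of one type,
mimicking annotation tools that treat spots as single cells), and
``regional`` (whole condition regions, no composition knowledge — the
practical scenario the specificity selection scheme is built for).

Any test failure (degenerate groups, zero variance) yields a missing
p-value that is treated as 1 downstream, so untestable genes are never
called differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tissue import SpotDataset

__all__ = [
    "DEGResult",
    "filter_dataset",
    "normalize_loglib",
    "select_test_units",
    "deg_ttest",
    "deg_wilcoxon",
    "deg_lm_covariate",
    "majority_vote",
    "bh_adjust",
    "run_deg",
]

_EXACT_WILCOXON_MAX_N = 25


@dataclass
class DEGResult:
    """Per-gene raw/adjusted p-values and calls for one method × cell type."""

    method: str
    cell_type: str
    genes: np.ndarray
    p: np.ndarray  # raw p in [0, 1]; failures already mapped to 1
    p_adj: np.ndarray
    call: np.ndarray  # bool, p_adj <= alpha
    flagged: bool = False  # degenerate design / empty group

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "method": self.method,
                "cell_type": self.cell_type,
                "gene": self.genes,
                "p": self.p,
                "p_adj": self.p_adj,
                "call": self.call,
            }
        )


def filter_dataset(ds: SpotDataset) -> SpotDataset:
    """Standard pre-test filtering.

    Genes need at least three counts array-wide; spots must hold at least
    one allocated cell (background that merely received leaked transcripts
    is dropped) and at least one count; genes are then re-filtered to at
    least one count — necessary after leakage + downsampling, which can
    empty genes within the surviving spots.
    """
    ds = ds.subset_genes(np.flatnonzero(ds.counts.sum(axis=0) >= 3))
    keep_spots = (ds.composition.sum(axis=1) > 0) & (ds.counts.sum(axis=1) > 0)
    ds = ds.subset_spots(np.flatnonzero(keep_spots))
    ds = ds.subset_genes(np.flatnonzero(ds.counts.sum(axis=0) >= 1))
    if ds.counts.size == 0:
        raise ValueError("filtering removed all spots or genes")
    return ds


def normalize_loglib(
    counts: np.ndarray, scale: float = 1e4, pseudocount: float = 1.0
) -> np.ndarray:
    """log(count / spot_total · scale + pseudocount), the library-size log
    normalization. Depth-invariant: doubling a spot's counts leaves its
    values unchanged."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("spots with zero total counts; filter the dataset first")
    return np.log(counts / totals * scale + pseudocount)


def select_test_units(
    ds: SpotDataset, cell_type: str, input_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Spot indices of the two test groups (condition A, condition B)."""
    if input_mode not in ("containing", "single", "regional"):
        raise ValueError(f"unknown input_mode {input_mode!r}")
    c = int(np.flatnonzero(ds.cell_types == cell_type)[0])
    if input_mode == "containing":
        mask = ds.composition[:, c] >= 1
    elif input_mode == "single":
        comp = ds.composition
        others = np.delete(comp, c, axis=1)
        mask = (comp[:, c] > 0) & (
            comp[:, c] > (others.max(axis=1) if others.shape[1] else -1)
        )
    else:  # regional: whole condition regions, composition-agnostic
        mask = ds.is_tissue
    return (
        np.flatnonzero(mask & (ds.condition == "A")),
        np.flatnonzero(mask & (ds.condition == "B")),
    )


def deg_ttest(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test per gene (columns); failures -> p = 1."""
    if len(values_a) < 2 or len(values_b) < 2:
        return np.ones(values_a.shape[1] if values_a.ndim > 1 else 1)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant columns
        p = stats.ttest_ind(values_a, values_b, axis=0, equal_var=False).pvalue
    return np.where(np.isfinite(p), p, 1.0)


def deg_wilcoxon(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum test per gene; failures -> p = 1.

    The exact null distribution is used for tie-free genes with both group
    sizes <= 25; otherwise the normal approximation with tie correction.
    """
    n_a, n_b = len(values_a), len(values_b)
    G = values_a.shape[1]
    if n_a == 0 or n_b == 0:
        return np.ones(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.mannwhitneyu(
            values_a, values_b, axis=0, method="asymptotic"
        ).pvalue
    p = np.where(np.isfinite(p), p, 1.0)
    if max(n_a, n_b) <= _EXACT_WILCOXON_MAX_N:
        for g in range(G):
            col = np.concatenate([values_a[:, g], values_b[:, g]])
            if len(np.unique(col)) == len(col):  # tie-free
                p[g] = stats.mannwhitneyu(
                    values_a[:, g], values_b[:, g], method="exact"
                ).pvalue
    return p


def deg_lm_covariate(
    expr: np.ndarray, condition: np.ndarray, cell_ratio: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Interaction test: expr ~ condition + ratio + condition:ratio.

    Returns the two-sided p-value of the interaction coefficient per gene
    and a flag; a rank-deficient design (e.g. constant cell ratio) yields
    p = 1 for every gene with the flag set.
    """
    expr = np.asarray(expr, dtype=float)
    cond = (np.asarray(condition) == "B").astype(float)
    ratio = np.asarray(cell_ratio, dtype=float)
    n = len(cond)
    X = np.column_stack([np.ones(n), cond, ratio, cond * ratio])
    G = expr.shape[1]
    if n <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
        return np.ones(G), True
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ expr  # (4, G)
    resid = expr - X @ beta
    df = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[3, 3])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[3] / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return np.where(np.isfinite(p), p, 1.0), False


def majority_vote(calls: np.ndarray) -> np.ndarray:
    """Consensus call: DEG iff at least floor(n_methods/2) + 1 methods agree.

    ``calls`` is (n_methods, G) boolean.
    """
    calls = np.asarray(calls, dtype=bool)
    if calls.ndim != 2 or calls.shape[0] < 2:
        raise ValueError("majority vote needs >= 2 methods")
    needed = calls.shape[0] // 2 + 1
    return calls.sum(axis=0) >= needed


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment over the p-values passed.

    Subset-restricted FDR control is obtained by passing only the selected
    genes' p-values: m is always the length of the input vector.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_deg(
    ds: SpotDataset,
    method: str = "ttest",
    input_mode: str = "containing",
    alpha: float = 0.01,
    normalize: bool = False,
) -> list[DEGResult]:
    """Run one native DEG test per cell type on a (filtered) spot dataset.

    ``method`` is one of ``ttest``, ``wilcoxon``, ``lm`` (condition ×
    cell-ratio interaction model over all spots, using ground-truth
    composition). Values are raw counts by default, or loglib-normalized
    with ``normalize=True``; in practice normalization barely moves the
    results, so raw is the default.
    """
    if method not in ("ttest", "wilcoxon", "lm"):
        raise ValueError(f"unknown method {method!r}")
    values = normalize_loglib(ds.counts) if normalize else ds.counts
    results = []
    for c, ct in enumerate(ds.cell_types):
        flagged = False
        if method == "lm":
            tissue = np.flatnonzero(ds.is_tissue)  # all spots included
            totals = ds.composition[tissue].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(totals > 0, ds.composition[tissue, c] / totals, 0.0)
            p, flagged = deg_lm_covariate(
                values[tissue], ds.condition[tissue], ratio
            )
        else:
            ia, ib = select_test_units(ds, ct, input_mode)
            if len(ia) == 0 or len(ib) == 0:
                p = np.ones(len(ds.genes))
                flagged = True
            elif method == "ttest":
                p = deg_ttest(values[ia], values[ib])
            elif method == "wilcoxon":
                p = deg_wilcoxon(values[ia], values[ib])
            else:
                raise ValueError(f"unknown method {method!r}")
        p_adj = bh_adjust(p)
        results.append(
            DEGResult(method, str(ct), ds.genes, p, p_adj, p_adj <= alpha, flagged)
        )
    return results
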