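"""Two-condition single-cell NB simulator with a validated DEG ground truth.

Cells are drawn per (cell type, condition) from gene-wise negative binomial
distributions. Condition A uses the reference means; condition B multiplies
the mean of each injected DEG by ``2**logfc``. Because the injected fold
changes are known exactly, the simulated data carry a ground truth that any
downstream differential-expression call can be scored against — provided the
realized counts actually reflect the requested parameters, which is what
:func:`qc_ground_truth` checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .config import SimConfig

__all__ = [
    "SCReference",
    "SCDataset",
    "GroundTruth",
    "QCReport",
    "estimate_prior",
    "simulate_sc",
    "qc_ground_truth",
    "inflate_sc_baseline",
]

# Dispersion cap: beyond this the NB is numerically Poisson.
MAX_DISPERSION = 1e8


@dataclass
class SCReference:
    """Per-gene, per-cell-type NB parameters — the simulation prior.

    ``mean[g, c]`` is the expected count of gene ``g`` in a cell of type
    ``c``; ``dispersion[g]`` is the NB size parameter (variance =
    mu + mu**2 / dispersion).
    """

    genes: np.ndarray  # (G,) str
    cell_types: np.ndarray  # (C,) str
    mean: np.ndarray  # (G, C) float, >= 0
    dispersion: np.ndarray  # (G,) float, > 0

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        self.mean = np.asarray(self.mean, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if self.mean.shape != (len(self.genes), len(self.cell_types)):
            raise ValueError("mean matrix shape does not match gene/type ids")
        if np.any(self.mean < 0):
            raise ValueError("NB means must be non-negative")
        if np.any(self.dispersion <= 0):
            raise ValueError("NB dispersions must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for c, ct in enumerate(self.cell_types):
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.genes,
                        "cell_type": ct,
                        "mean": self.mean[:, c],
                        "dispersion": self.dispersion,
                    }
                )
            )
        pd.concat(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SCReference":
        df = pd.read_csv(path, sep="\t")
        genes = df["gene"].drop_duplicates().to_numpy()
        cts = df["cell_type"].drop_duplicates().to_numpy()
        mean = (
            df.pivot(index="gene", columns="cell_type", values="mean")
            .loc[genes, cts]
            .to_numpy()
        )
        disp = (
            df.drop_duplicates("gene").set_index("gene").loc[genes, "dispersion"].to_numpy()
        )
        return cls(genes, cts, mean, disp)


@dataclass
class SCDataset:
    """Simulated (or filtered real) single cells from two conditions."""

    counts: np.ndarray  # (N cells, G genes) int
    genes: np.ndarray  # (G,) str
    cell_type: np.ndarray  # (N,) str
    condition: np.ndarray  # (N,) 'A' | 'B'

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.genes = np.asarray(self.genes, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        n, g = self.counts.shape
        if len(self.genes) != g or len(self.cell_type) != n or len(self.condition) != n:
            raise ValueError("label lengths do not match the count matrix")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def subset(self, idx: np.ndarray) -> "SCDataset":
        return SCDataset(
            self.counts[idx], self.genes, self.cell_type[idx], self.condition[idx]
        )


@dataclass
class GroundTruth:
    """The benchmark's answer key: injected DE flags and fold changes."""

    genes: np.ndarray
    cell_types: np.ndarray
    is_de: np.ndarray  # (G, C) bool
    logfc: np.ndarray  # (G, C) float, log2; 0 where not DE
    mean_A: np.ndarray  # (G, C) float
    mean_B: np.ndarray  # (G, C) float; == mean_A * 2**logfc

    def __post_init__(self):
        if np.any(self.logfc[~self.is_de] != 0):
            raise ValueError("non-DE genes must have logfc == 0")
        if not np.allclose(self.mean_B, self.mean_A * np.exp2(self.logfc)):
            raise ValueError("mean_B must equal mean_A * 2**logfc")

    def to_frame(self) -> pd.DataFrame:
        g, c = np.meshgrid(
            np.arange(len(self.genes)), np.arange(len(self.cell_types)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "gene": self.genes[g.ravel()],
                "cell_type": self.cell_types[c.ravel()],
                "is_de": self.is_de.ravel(),
                "logfc": self.logfc.ravel(),
                "mean_A": self.mean_A.ravel(),
                "mean_B": self.mean_B.ravel(),
            }
        )


@dataclass
class QCReport:
    """Verdict of the four ground-truth fidelity criteria.

    1. at most 5% of (gene, cell type) pairs unanalyzable (zero empirical
       mean in both conditions);
    2. no injected DEG with positive means deviating more than 0.1 from its
       parameterized log2 fold change;
    3. the empirically detected DE fraction (per-gene Welch t-test, p < .01)
       within 2 percentage points of the requested ``p_de``;
    4. at least 60% of the 100 analyzable pairs with the largest empirical
       |log2FC| are injected DEGs.
    """

    frac_unanalyzable: float
    logfc_violations: int
    de_count_rel_error: float
    top100_congruence: float
    criteria: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frac_unanalyzable": [self.frac_unanalyzable],
                "logfc_violations": [self.logfc_violations],
                "de_count_rel_error": [self.de_count_rel_error],
                "top100_congruence": [self.top100_congruence],
                "passed": [self.passed],
                **{k: [v] for k, v in self.criteria.items()},
            }
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray, n: int):
    """n cells x G genes of NB(mean, dispersion) counts."""
    disp = np.minimum(dispersion, MAX_DISPERSION)
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=(n, len(mean))).astype(np.int32)


def estimate_prior(
    counts: np.ndarray,
    cell_labels: np.ndarray,
    donor_labels: np.ndarray | None = None,
    mito_gene_mask: np.ndarray | None = None,
    genes: np.ndarray | None = None,
    *,
    min_cells_per_type_donor: int = 50,
    min_counts_per_cell: int = 500,
    max_mito_frac: float = 0.12,
    min_cells_expressing: int = 10,
    low_mean_cutoff: float = 0.005,
) -> SCReference:
    """Fit NB simulation priors from an annotated count matrix.

    Filtering follows droplet-data conventions: cell types need at least 50
    cells per donor; cells need >= 500 counts and < 12% mitochondrial
    content; genes must exceed one count in at least 10 cells and clear a
    low-mean cutoff (means below it cannot be simulated faithfully and would
    corrupt the realized fold changes of any DEG).

    Dispersions are per-gene method-of-moments estimates pooled across cell
    types; genes at or below Poisson variance get a numerically-Poisson cap.
    """
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_labels = np.asarray(cell_labels, dtype=object)
    if genes is None:
        genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    donors = (
        np.zeros(n_cells, dtype=object)
        if donor_labels is None
        else np.asarray(donor_labels, dtype=object)
    )

    # cell types with >= min cells per type, per donor
    keep_types = []
    for ct in pd.unique(cell_labels):
        per_donor = pd.Series(donors[cell_labels == ct]).value_counts()
        if (per_donor >= min_cells_per_type_donor).all() and set(
            pd.unique(donors)
        ) == set(per_donor.index):
            keep_types.append(ct)
    cell_ok = np.isin(cell_labels, keep_types)

    totals = counts.sum(axis=1)
    cell_ok &= totals >= min_counts_per_cell
    if mito_gene_mask is not None:
        mito = counts[:, np.asarray(mito_gene_mask, bool)].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        cell_ok &= frac < max_mito_frac

    sub = counts[cell_ok]
    labels = cell_labels[cell_ok]
    surviving = [ct for ct in keep_types if (labels == ct).sum() > 0]
    if len(surviving) < 2:
        raise ValueError(
            f"fewer than 2 cell types survive filtering (got {len(surviving)})"
        )

    gene_ok = (sub > 1).sum(axis=0) >= min_cells_expressing
    gene_ok &= sub.mean(axis=0) >= low_mean_cutoff
    sub = sub[:, gene_ok]
    genes = genes[gene_ok]

    cts = np.array(surviving, dtype=object)
    mean = np.empty((sub.shape[1], len(cts)))
    num = np.zeros(sub.shape[1])  # sum_c n_c * mu_c^2
    den = np.zeros(sub.shape[1])  # sum_c n_c * (s2_c - mu_c)
    for c, ct in enumerate(cts):
        block = sub[labels == ct]
        mu = block.mean(axis=0)
        s2 = block.var(axis=0, ddof=1) if block.shape[0] > 1 else np.zeros_like(mu)
        mean[:, c] = mu
        num += block.shape[0] * mu**2
        den += block.shape[0] * (s2 - mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(den > 0, num / den, MAX_DISPERSION)
    disp = np.clip(disp, 1e-8, MAX_DISPERSION)
    return SCReference(genes, cts, mean, disp)


def simulate_sc(
    prior: SCReference, config: SimConfig, seed: int | None = None
) -> tuple[SCDataset, GroundTruth]:
    """Simulate a two-condition SC dataset with injected DEGs.

    Per cell type, a fraction ``p_de`` of genes is flagged DE with
    log2 fold change ±``logfc_magnitude`` (signs balanced in expectation).
    """
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "simulate_sc")
    G, C = prior.n_genes, prior.n_cell_types
    n_de = int(round(config.p_de * G))

    is_de = np.zeros((G, C), dtype=bool)
    logfc = np.zeros((G, C))
    for c in range(C):
        de_idx = rng.choice(G, size=n_de, replace=False)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        is_de[de_idx, c] = True
        logfc[de_idx, c] = sign * config.logfc_magnitude

    mean_A = prior.mean.copy()
    mean_B = mean_A * np.exp2(logfc)
    gt = GroundTruth(prior.genes, prior.cell_types, is_de, logfc, mean_A, mean_B)

    n = config.n_cells_per_type
    blocks, type_lab, cond_lab = [], [], []
    for c in range(C):
        for cond, means in (("A", mean_A[:, c]), ("B", mean_B[:, c])):
            blocks.append(_nb_draw(rng, means, prior.dispersion, n))
            type_lab += [prior.cell_types[c]] * n
            cond_lab += [cond] * n
    ds = SCDataset(
        np.vstack(blocks),
        prior.genes,
        np.array(type_lab, dtype=object),
        np.array(cond_lab, dtype=object),
    )
    return ds, gt


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Welch t-test p-values; degenerate columns -> 1."""
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant columns
        p = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    return np.where(np.isfinite(p), p, 1.0)


def qc_ground_truth(
    ds: SCDataset,
    gt: GroundTruth,
    config: SimConfig,
    *,
    logfc_tol: float = 0.1,
    max_unanalyzable: float = 0.05,
    de_frac_tol: float = 0.02,
    de_alpha: float = 0.01,
    top_k: int = 100,
    min_top_congruence: float = 0.6,
) -> QCReport:
    """Check that the realized counts honor the requested ground truth."""
    G = len(gt.genes)
    C = len(gt.cell_types)
    emp_A = np.zeros((G, C))
    emp_B = np.zeros((G, C))
    pvals = np.ones((G, C))
    for c, ct in enumerate(gt.cell_types):
        a = ds.counts[(ds.cell_type == ct) & (ds.condition == "A")]
        b = ds.counts[(ds.cell_type == ct) & (ds.condition == "B")]
        if len(a) == 0 or len(b) == 0:
            continue
        emp_A[:, c] = a.mean(axis=0)
        emp_B[:, c] = b.mean(axis=0)
        pvals[:, c] = _welch_p(a, b)

    unanalyzable = (emp_A == 0) & (emp_B == 0)
    analyzable = (emp_A > 0) & (emp_B > 0)
    frac_un = unanalyzable.mean()

    with np.errstate(divide="ignore", invalid="ignore"):
        emp_lfc = np.log2(np.where(analyzable, emp_B, np.nan) / np.where(analyzable, emp_A, np.nan))
    de_pos = gt.is_de & analyzable
    violations = int(np.nansum(np.abs(emp_lfc - gt.logfc)[de_pos] > logfc_tol))

    detected = (pvals < de_alpha) & analyzable
    n_analyzable = int(analyzable.sum())
    if n_analyzable:
        de_err = abs(int(detected.sum()) - int(de_pos.sum())) / n_analyzable
    else:
        de_err = np.inf

    flat_lfc = np.abs(np.where(analyzable, emp_lfc, -np.inf)).ravel()
    k = min(top_k, n_analyzable)
    if k:
        top = np.argpartition(flat_lfc, -k)[-k:]
        congruence = gt.is_de.ravel()[top].mean()
    else:
        congruence = 0.0

    criteria = {
        "unanalyzable_ok": bool(frac_un <= max_unanalyzable),
        "logfc_ok": violations == 0,
        "de_count_ok": bool(de_err < de_frac_tol),
        "top_congruence_ok": bool(congruence >= min_top_congruence),
    }
    return QCReport(float(frac_un), violations, float(de_err), float(congruence), criteria)


def inflate_sc_baseline(ds: SCDataset, n_cells: int = 5000, seed: int = 0) -> SCDataset:
    """Random subsample of the cell pool, for a fair SC-vs-spatial contrast.

    The spatial tissue holds thousands of cells; comparing it against the
    full simulated pool would conflate data type with sample size, so the SC
    baseline is drawn to a matched size (default 5000 cells).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if n_cells > ds.n_cells:
        raise ValueError(f"n_cells={n_cells} exceeds pool of {ds.n_cells}")
    rng = stage_rng(seed, "inflate_sc_baseline")
    idx = rng.choice(ds.n_cells, size=n_cells, replace=False)
    return ds.subset(idx)
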