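"""Synthetic simulation priors and spatial reference summaries.

Every downstream stage of the benchmark can be exercised without any
external download: :func:`make_sc_prior` draws a plausible droplet-data
prior (sparse, overdispersed, with a controllable fraction of cell-type
markers), and :func:`make_st_reference_summaries` assembles a tissue from
that prior and records the per-gene depth distributions that the
downsampling calibration compares against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import stage_rng
from .config import SimConfig
from .singlecell import SCReference

__all__ = ["STReferenceSummary", "make_sc_prior", "make_st_reference_summaries"]


@dataclass
class STReferenceSummary:
    """Per-gene depth summaries of a spatial reference.

    ``gene_totals[g]`` — total counts of gene ``g`` over the tissue;
    ``gene_means[g]`` — mean counts per tissue spot. The two distributions
    are the calibration targets for depth selection.
    """

    gene_totals: np.ndarray  # (G,) non-negative ints
    gene_means: np.ndarray  # (G,) non-negative reals

    def __post_init__(self):
        self.gene_totals = np.asarray(self.gene_totals)
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        if self.gene_totals.shape != self.gene_means.shape:
            raise ValueError("summary vectors must have equal length")


def make_sc_prior(
    n_genes: int,
    n_cell_types: int,
    seed: int = 0,
    *,
    marker_fraction: float = 0.2,
    marker_fold: float = 8.0,
    type_effect_sd: float = 0.25,
    baseline_log_mean: float = np.log(0.5),
    baseline_log_sd: float = 1.2,
    dispersion_shape: float = 2.0,
    dispersion_scale: float = 1.0,
    min_mean: float = 0.01,
) -> SCReference:
    """Draw an NB simulation prior.

    Baseline per-gene means are log-normal; every (gene, type) mean gets a
    mild lognormal effect (sd ``type_effect_sd`` in ln units, 0 disables
    it) so cell types differ gradually, and a ``marker_fraction`` subset
    of genes is additionally boosted ``marker_fold``-fold in one randomly
    chosen home cell type, making it type-restricted. Dispersions are
    gamma. All means are clipped to ``min_mean`` so the prior always
    clears the low-mean filter that
    :func:`~spotsim.singlecell.estimate_prior` applies to real data.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_cell_types < 2:
        raise ValueError("n_cell_types must be >= 2")
    rng = stage_rng(seed, "make_sc_prior")
    base = np.maximum(rng.lognormal(baseline_log_mean, baseline_log_sd, n_genes), min_mean)
    mean = np.tile(base[:, None], (1, n_cell_types))
    if type_effect_sd > 0:
        mean = mean * rng.lognormal(0.0, type_effect_sd, mean.shape)
    n_markers = int(round(marker_fraction * n_genes))
    if n_markers:
        marker_idx = rng.choice(n_genes, size=n_markers, replace=False)
        home = rng.integers(n_cell_types, size=n_markers)
        mean[marker_idx, home] *= marker_fold
    dispersion = np.maximum(
        rng.gamma(dispersion_shape, dispersion_scale, n_genes), 1e-3
    )
    genes = np.array([f"g{i:04d}" for i in range(n_genes)], dtype=object)
    cts = np.array([f"ct{j}" for j in range(n_cell_types)], dtype=object)
    return SCReference(genes, cts, mean, dispersion)


def make_st_reference_summaries(
    prior: SCReference,
    target_depth_pct: float,
    seed: int = 0,
    config: SimConfig | None = None,
) -> STReferenceSummary:
    """Assemble a tissue from ``prior`` and summarize it at a given depth.

    The tissue is built with the standard pipeline (placement, condition
    split, cell allocation) and downsampled to ``target_depth_pct`` of its
    transcripts; per-gene totals and means over tissue spots are returned.
    A depth of 1.0 returns full-depth summaries.
    """
    if not 0 < target_depth_pct <= 1:
        raise ValueError("target_depth_pct must be in (0, 1]")
    # local import: this module sits upstream of the tissue builders
    from .artifacts import downsample
    from .pipeline import simulate_tissue

    if config is None:
        config = SimConfig(
            n_genes=prior.n_genes,
            n_cell_types=prior.n_cell_types,
            n_spots=80,
            array_rows=30,
            array_cols=30,
            n_cells_per_type=400,
        )
    _, _, _, ds = simulate_tissue(prior, config, seed=seed)
    if target_depth_pct < 1:
        ds = downsample(
            ds, target_depth_pct, accurate=False, seed=seed,
            sd_frac=config.downsample.sd_frac,
        )
    tissue = ds.counts[ds.is_tissue]
    return STReferenceSummary(tissue.sum(axis=0), tissue.mean(axis=0))
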