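"""Spatial artifact models: transcript leakage and depth downsampling.

Leakage moves a Poisson-distributed share of each spot's transcripts into
neighboring array positions (background included) under a distance-weighted
Gaussian kernel; the global transcript total is conserved exactly.
Downsampling thins each spot to a Normal-drawn target total, emulating the
sparsity and shallow depth of real spot-based data. Applying leakage then
downsampling yields the realistic ST-LD configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from ._rng import stage_rng
from .reference import STReferenceSummary
from .tissue import SpotDataset, physical_coords

__all__ = [
    "LeakageModel",
    "apply_leakage",
    "downsample",
    "select_downsample_pct",
]

log = logging.getLogger(__name__)

#: kernel support radius in units of kernel_sd; weights beyond are dropped
_KERNEL_SUPPORT = 4.0


@dataclass
class LeakageModel:
    """Row-normalized Gaussian diffusion kernel between array positions.

    ``bleed_rate`` is the expected fraction of a spot's transcripts that
    leave it; ``kernel_sd`` the Gaussian bandwidth in spot units (adjacent
    spot centers are 1 unit apart). Self-weights are excluded; each source
    row of weights sums to 1.
    """

    bleed_rate: float
    kernel_sd: float
    _dest: dict = field(default_factory=dict, repr=False)  # src -> (idx, w)

    def __post_init__(self):
        if not 0 <= self.bleed_rate <= 1:
            raise ValueError("bleed_rate must be in [0, 1]")
        if self.kernel_sd <= 0:
            raise ValueError("kernel_sd must be positive")

    def fit_positions(self, positions: np.ndarray) -> "LeakageModel":
        """Precompute destination weights for every array position."""
        xy = physical_coords(positions)
        tree = cKDTree(xy)
        radius = _KERNEL_SUPPORT * self.kernel_sd
        self._dest = {}
        for i, neighbors in enumerate(tree.query_ball_point(xy, r=radius)):
            idx = np.array([j for j in neighbors if j != i], dtype=int)
            if len(idx) == 0:
                self._dest[i] = (idx, np.empty(0))
                continue
            d2 = ((xy[idx] - xy[i]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2 * self.kernel_sd**2))
            self._dest[i] = (idx, w / w.sum())
        return self


def apply_leakage(
    ds: SpotDataset, model: LeakageModel, seed: int = 0
) -> SpotDataset:
    """Diffuse transcripts between array positions.

    Per (spot, gene) the leaked-out count is Poisson(bleed_rate · count),
    capped at the available count. Capped draws trigger the correction
    rule: their transcripts are re-distributed over positions that already
    received that gene, with probability proportional to the excess of
    each position's received count over the mean received count (minimum
    zero); all other leaked transcripts follow the kernel weights. The
    final count is remaining + received, so the array-wide total is
    conserved exactly.
    """
    if ds.stage not in ("ST-M", "ST-D"):
        raise ValueError(f"leakage expects stage ST-M or ST-D, got {ds.stage}")
    rng = stage_rng(seed, "apply_leakage")
    counts = ds.counts
    S, G = counts.shape
    if not model._dest:
        model = LeakageModel(model.bleed_rate, model.kernel_sd).fit_positions(
            ds.positions
        )
    if model.bleed_rate == 0:
        return ds.replace_counts(counts.copy(), _next_stage(ds.stage, "L"))

    raw = rng.poisson(model.bleed_rate * counts)
    leaked = np.minimum(raw, counts)
    corrected = raw > counts  # correction rule applies to these draws
    remaining = counts - leaked
    received = np.zeros_like(counts)

    normal_leak = np.where(corrected, 0, leaked)
    sources = np.flatnonzero(normal_leak.sum(axis=1))
    for s in sources:
        idx, w = model._dest[s]
        if len(idx) == 0:
            remaining[s] += normal_leak[s]  # isolated spot keeps its transcripts
            continue
        genes = np.flatnonzero(normal_leak[s])
        draws = rng.multinomial(normal_leak[s, genes], w)  # (len(genes), len(idx))
        received[np.ix_(idx, genes)] += draws.T

    n_corr = int(corrected.sum())
    if n_corr:
        log.info("leakage correction triggered for %d (spot, gene) draws", n_corr)
        for s, g in zip(*np.nonzero(corrected)):
            amount = leaked[s, g]
            if amount == 0:
                continue
            rec_g = received[:, g].astype(float)
            rec_g[s] = 0.0
            got = rec_g > 0
            p = np.maximum(rec_g - rec_g[got].mean(), 0) if got.any() else rec_g
            if p.sum() == 0:
                idx, w = model._dest[s]
                if len(idx) == 0:
                    remaining[s, g] += amount
                    continue
                received[idx, g] += rng.multinomial(amount, w)
            else:
                received[:, g] += rng.multinomial(amount, p / p.sum())

    return ds.replace_counts(remaining + received, _next_stage(ds.stage, "L"))


def _next_stage(stage: str, artifact: str) -> str:
    flags = set(stage.removeprefix("ST-")) - {"M"} | {artifact}
    return "ST-" + "".join(sorted(flags)) if flags else "ST-M"


def downsample(
    ds: SpotDataset,
    pct: float,
    accurate: bool = False,
    seed: int = 0,
    sd_frac: float = 0.1,
) -> SpotDataset:
    """Thin each spot to roughly ``pct`` of its transcripts.

    The per-spot target total is Normal(pct·total, sd_frac·pct·total),
    rounded and clipped to [0, total]; genes are then drawn with
    probability equal to their original proportions in the spot
    (multinomial). With ``accurate=True`` sampling is without replacement
    (multivariate hypergeometric), so no gene can exceed its original
    count.
    """
    if not 0 < pct <= 1:
        raise ValueError("pct must be in (0, 1]")
    rng = stage_rng(seed, "downsample")
    counts = ds.counts
    totals = counts.sum(axis=1)
    mu = pct * totals
    targets = np.rint(rng.normal(mu, sd_frac * mu)).astype(np.int64)
    targets = np.clip(targets, 0, totals)
    out = np.zeros_like(counts)
    for s in np.flatnonzero(targets):
        row = counts[s]
        if accurate:
            out[s] = rng.multivariate_hypergeometric(row, targets[s])
        else:
            out[s] = rng.multinomial(targets[s], row / totals[s])
    return ds.replace_counts(out, _next_stage(ds.stage, "D"))


def select_downsample_pct(
    full: SpotDataset,
    candidates: tuple[float, ...],
    ref: STReferenceSummary,
    seed: int = 0,
    sd_frac: float = 0.1,
) -> float:
    """Pick the candidate depth best matching a reference's distributions.

    Each candidate depth is applied to ``full``; the per-gene total-count
    and mean-expression distributions over tissue spots are compared with
    the reference's via two-sample Kolmogorov–Smirnov statistics, and the
    candidate minimizing their sum wins. Ties break toward the larger
    depth.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    best_pct, best_stat = None, np.inf
    for i, pct in enumerate(sorted(candidates, reverse=True)):
        ds = downsample(full, pct, accurate=False, seed=seed + 7919 * i, sd_frac=sd_frac)
        tissue = ds.counts[ds.is_tissue]
        totals = tissue.sum(axis=0)
        means = tissue.mean(axis=0)
        stat = (
            stats.ks_2samp(totals, ref.gene_totals).statistic
            + stats.ks_2samp(means, ref.gene_means).statistic
        )
        if stat < best_stat:
            best_pct, best_stat = pct, stat
    return best_pct
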