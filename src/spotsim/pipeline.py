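"""End-to-end orchestration of the simulation stages.

``simulate_tissue`` chains single-cell simulation, ground-truth QC, spot
placement, condition assignment, and cell allocation into the mixed-spot
dataset (ST-M); ``build_stages`` derives the artifact configurations
(ST-L, ST-D, ST-LD) from it. Each stage draws its randomness from an
independent substream of one global seed.
"""

from __future__ import annotations

import dataclasses
import logging

from .artifacts import LeakageModel, apply_leakage, downsample
from .config import SimConfig
from .singlecell import (
    GroundTruth,
    QCReport,
    SCDataset,
    SCReference,
    qc_ground_truth,
    simulate_sc,
)
from .tissue import (
    PoolShortfallError,
    SpotDataset,
    aggregate_counts,
    allocate_cells,
    assign_conditions,
    place_spots,
)

__all__ = ["simulate_tissue", "build_stages", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("ST-M", "ST-L", "ST-D", "ST-LD")


def simulate_tissue(
    prior: SCReference, config: SimConfig, seed: int | None = None
) -> tuple[SCDataset, GroundTruth, QCReport, SpotDataset]:
    """Simulate cells and assemble them into a mixed-spot tissue (ST-M).

    If the allocation demands more cells of some (type, condition) than
    were simulated, the single-cell pool is re-simulated larger rather
    than reusing cells (reuse would correlate spots).
    """
    if seed is None:
        seed = config.seed
    layout = assign_conditions(place_spots(
        config.n_spots, config.array_rows, config.array_cols, seed
    ), seed)
    for _ in range(4):
        sc, gt = simulate_sc(prior, config, seed)
        try:
            assignment = allocate_cells(sc, layout, config, seed)
            break
        except PoolShortfallError as err:
            worst = max(
                need / config.n_cells_per_type for need, _ in err.shortfall.values()
            )
            new_n = int(config.n_cells_per_type * worst * 1.2) + 1
            log.info(
                "cell pool short (%s); re-simulating with n_cells_per_type=%d",
                err.shortfall,
                new_n,
            )
            config = dataclasses.replace(config, n_cells_per_type=new_n)
    else:
        raise RuntimeError("could not satisfy cell demand after re-simulation")
    qc = qc_ground_truth(sc, gt, config)
    st_m = aggregate_counts(sc, assignment, layout)
    return sc, gt, qc, st_m


def build_stages(
    st_m: SpotDataset,
    config: SimConfig,
    seed: int,
    stages: tuple[str, ...] = STAGES,
) -> dict[str, SpotDataset]:
    """Derive the requested artifact configurations from an ST-M dataset.

    ST-L adds leakage; ST-D adds downsampling; ST-LD applies leakage first
    and then downsampling (the realistic baseline).
    """
    out: dict[str, SpotDataset] = {}
    st_l = None
    if {"ST-L", "ST-LD"} & set(stages):
        model = LeakageModel(config.leakage.bleed_rate, config.leakage.kernel_sd)
        model.fit_positions(st_m.positions)
        st_l = apply_leakage(st_m, model, seed)
    if "ST-M" in stages:
        out["ST-M"] = st_m
    if "ST-L" in stages:
        out["ST-L"] = st_l
    if "ST-D" in stages:
        out["ST-D"] = downsample(
            st_m,
            config.downsample.pct,
            accurate=config.downsample.accurate,
            seed=seed,
            sd_frac=config.downsample.sd_frac,
        )
    if "ST-LD" in stages:
        out["ST-LD"] = downsample(
            st_l,
            config.downsample.pct,
            accurate=config.downsample.accurate,
            seed=seed + 1,
            sd_frac=config.downsample.sd_frac,
        )
    return out
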