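"""Simulation parameter schema and JSON loading.

All tunable parameters of the benchmark live in a single :class:`SimConfig`
loaded from a JSON file (or built in code). Every stage of the pipeline is a
pure function of (config, seed), which makes any emitted dataset traceable to
one parameter file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

__all__ = [
    "ConfigError",
    "LeakageConfig",
    "DownsampleConfig",
    "DegConfig",
    "SpecificityConfig",
    "SimConfig",
    "load_config",
    "DEFAULT_CANDIDATE_PCTS",
]

#: Candidate downsampling depths (fractions of original transcripts).
DEFAULT_CANDIDATE_PCTS: tuple[float, ...] = (0.10, 0.07, 0.05, 0.03, 0.02, 0.01, 0.005)


class ConfigError(ValueError):
    """Raised when a parameter file violates the schema.

    ``keys`` lists the offending parameter names.
    """

    def __init__(self, message: str, keys: Sequence[str]):
        super().__init__(f"{message}: {', '.join(keys)}")
        self.keys = list(keys)


@dataclass(frozen=True)
class LeakageConfig:
    bleed_rate: float = 0.3  # fraction of a spot's transcripts that leave
    kernel_sd: float = 2.0  # Gaussian bandwidth, in spot units


@dataclass(frozen=True)
class DownsampleConfig:
    candidate_pcts: tuple[float, ...] = DEFAULT_CANDIDATE_PCTS
    accurate: bool = False
    sd_frac: float = 0.1  # sd of the per-spot target total, as a fraction of its mean
    pct: float = 0.05  # depth used when not auto-selected against a reference


@dataclass(frozen=True)
class DegConfig:
    alpha: float = 0.01
    input_mode: str = "containing"  # containing | single | regional


@dataclass(frozen=True)
class SpecificityConfig:
    metric: str = "mean"  # mean | frequency
    threshold: float = 0.2


@dataclass(frozen=True)
class SimConfig:
    """Full parameter set for one simulated benchmark run."""

    seed: int = 0
    n_genes: int = 4000
    n_cell_types: int = 5
    p_de: float = 0.1  # fraction of DE genes per cell type
    logfc_magnitude: float = 1.0  # |log2 fold change| of injected DEGs
    n_cells_per_type: int = 800  # cells simulated per (cell type, condition)
    n_spots: int = 500
    array_rows: int = 78
    array_cols: int = 64
    uniformity_prob: tuple[float, ...] = ()  # per cell type; filled post-init
    density_high_rate: float = 4.0  # cells/spot in the high-density state
    density_low_rate: float = 0.5
    density_high_prob: tuple[float, ...] = ()
    sparse_subset_frac: float = 0.02  # sparse-state eligible fraction of region spots
    leakage: LeakageConfig = field(default_factory=LeakageConfig)
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    deg: DegConfig = field(default_factory=DegConfig)
    specificity: SpecificityConfig = field(default_factory=SpecificityConfig)

    def __post_init__(self):
        for name in ("uniformity_prob", "density_high_prob"):
            val = getattr(self, name)
            if isinstance(val, (int, float)):
                val = (float(val),) * self.n_cell_types
            elif len(val) == 0:
                val = (0.5,) * self.n_cell_types
            else:
                val = tuple(float(v) for v in val)
            object.__setattr__(self, name, val)
        self.validate()

    def validate(self) -> None:
        bad: list[str] = []
        pos_int = {
            "n_genes": self.n_genes,
            "n_cell_types": self.n_cell_types,
            "n_cells_per_type": self.n_cells_per_type,
            "n_spots": self.n_spots,
            "array_rows": self.array_rows,
            "array_cols": self.array_cols,
        }
        for k, v in pos_int.items():
            if not (isinstance(v, (int,)) and v > 0):
                bad.append(k)
        fractions = {
            "p_de": self.p_de,
            "sparse_subset_frac": self.sparse_subset_frac,
            "leakage.bleed_rate": self.leakage.bleed_rate,
            "deg.alpha": self.deg.alpha,
            "specificity.threshold": self.specificity.threshold,
        }
        for i, p in enumerate(self.uniformity_prob):
            fractions[f"uniformity_prob[{i}]"] = p
        for i, p in enumerate(self.density_high_prob):
            fractions[f"density_high_prob[{i}]"] = p
        for k, v in fractions.items():
            if not (0.0 <= v <= 1.0):
                bad.append(k)
        positive = {
            "logfc_magnitude": self.logfc_magnitude,
            "density_high_rate": self.density_high_rate,
            "density_low_rate": self.density_low_rate,
            "leakage.kernel_sd": self.leakage.kernel_sd,
            "downsample.sd_frac": self.downsample.sd_frac,
        }
        for k, v in positive.items():
            if not v > 0:
                bad.append(k)
        if len(self.uniformity_prob) != self.n_cell_types:
            bad.append("uniformity_prob")
        if len(self.density_high_prob) != self.n_cell_types:
            bad.append("density_high_prob")
        if not self.downsample.candidate_pcts or not all(
            0 < p <= 1 for p in self.downsample.candidate_pcts
        ):
            bad.append("downsample.candidate_pcts")
        if not 0 < self.downsample.pct <= 1:
            bad.append("downsample.pct")
        if self.deg.input_mode not in ("containing", "single", "regional"):
            bad.append("deg.input_mode")
        if self.specificity.metric not in ("mean", "frequency"):
            bad.append("specificity.metric")
        if self.n_spots > (self.array_rows * self.array_cols + 1) // 2:
            bad.append("n_spots")
        if bad:
            raise ConfigError("invalid simulation parameters", bad)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


_NESTED = {
    "leakage": LeakageConfig,
    "downsample": DownsampleConfig,
    "deg": DegConfig,
    "specificity": SpecificityConfig,
}


def _build_nested(cls, raw: dict, prefix: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = [f"{prefix}.{k}" for k in raw if k not in known]
    if unknown:
        raise ConfigError("unknown parameters", unknown)
    kwargs = dict(raw)
    if cls is DownsampleConfig and "candidate_pcts" in kwargs:
        kwargs["candidate_pcts"] = tuple(kwargs["candidate_pcts"])
    return cls(**kwargs)


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a JSON parameter file.

    Absent keys are filled with documented defaults; unknown or out-of-range
    keys raise :class:`ConfigError` naming them.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("parameter file must be a JSON object", ["<root>"])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ConfigError("unknown parameters", unknown)
    kwargs = {}
    for k, v in raw.items():
        if k in _NESTED:
            if not isinstance(v, dict):
                raise ConfigError("expected a JSON object", [k])
            kwargs[k] = _build_nested(_NESTED[k], v, k)
        elif k in ("uniformity_prob", "density_high_prob"):
            kwargs[k] = tuple(v) if isinstance(v, (list, tuple)) else v
        else:
            kwargs[k] = v
    return SimConfig(**kwargs)
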