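"""Tissue assembly: spot placement, condition regions, cell allocation.

Spots live on a pseudo-hexagonal Visium-like lattice in 0-based
(array_row, array_col) coordinates with the doubled-column convention:
positions satisfy (row + col) % 2 == 0 and the six neighbors of (r, c) are
(r, c±2) and (r±1, c±1). Physical distances use x = col/2, y = row·√3/2 so
adjacent spot centers are one spot unit apart.

A tissue is grown by a random walk, partitioned into two spatially
contiguous, mutually exclusive condition regions, and populated with
simulated single cells under per-cell-type uniformity (evenly spread vs
sparse) and density (high vs low cells/spot) states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._rng import stage_rng
from .config import SimConfig
from .singlecell import SCDataset

__all__ = [
    "TissueLayout",
    "SpotAssignment",
    "SpotDataset",
    "PoolShortfallError",
    "place_spots",
    "assign_conditions",
    "allocate_cells",
    "aggregate_counts",
    "lattice_positions",
    "physical_coords",
]

_NEIGHBOR_STEPS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))

ROW_PITCH = math.sqrt(3.0) / 2.0


def lattice_positions(rows: int, cols: int) -> np.ndarray:
    """All valid (row, col) positions of the doubled-column lattice."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    ok = (r + c) % 2 == 0
    return np.column_stack([r[ok], c[ok]])


def physical_coords(positions: np.ndarray) -> np.ndarray:
    """(row, col) array coordinates -> physical x/y in spot units."""
    pos = np.asarray(positions, dtype=float)
    return np.column_stack([pos[:, 1] * 0.5, pos[:, 0] * ROW_PITCH])


class PoolShortfallError(RuntimeError):
    """Cell pool exhausted during allocation; carries the shortfall."""

    def __init__(self, shortfall: dict):
        self.shortfall = shortfall
        msg = "; ".join(
            f"{ct}/{cond}: need {need}, have {have}"
            for (ct, cond), (need, have) in shortfall.items()
        )
        super().__init__(f"SC pool exhausted: {msg}")


@dataclass
class TissueLayout:
    """Occupied lattice positions and their condition labels."""

    array_rows: int
    array_cols: int
    occupied: np.ndarray  # (n, 2) int positions, placement order
    condition: np.ndarray | None = None  # (n,) 'A'|'B' once assigned

    def __post_init__(self):
        self.occupied = np.asarray(self.occupied)
        pos = {tuple(p) for p in self.occupied}
        if len(pos) != len(self.occupied):
            raise ValueError("occupied positions must be unique")
        for r, c in self.occupied:
            if not (0 <= r < self.array_rows and 0 <= c < self.array_cols):
                raise ValueError(f"position ({r},{c}) out of bounds")
            if (r + c) % 2:
                raise ValueError(f"position ({r},{c}) off the doubled-column lattice")

    @property
    def n_spots(self) -> int:
        return len(self.occupied)

    def graph(self) -> nx.Graph:
        """6-neighbor adjacency over occupied spots (nodes = indices)."""
        index = {tuple(p): i for i, p in enumerate(self.occupied)}
        g = nx.Graph()
        g.add_nodes_from(range(self.n_spots))
        for (r, c), i in index.items():
            for dr, dc in _NEIGHBOR_STEPS:
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    g.add_edge(i, j)
        return g


@dataclass
class SpotAssignment:
    """Which simulated cells sit in which occupied spot."""

    cells_in_spot: dict  # occupied index -> (cell id array)
    n_cells: np.ndarray  # (n occupied, C) int
    cell_types: np.ndarray  # (C,) type ids
    states: dict = field(default_factory=dict)  # type -> {'uniform':…, 'high_density':…}


@dataclass
class SpotDataset:
    """Spots × genes counts over the whole capture array at one stage.

    Rows cover every valid lattice position; ``is_tissue`` marks occupied
    spots. Background rows have zero composition and (before leakage) zero
    counts. ``stage`` is one of ST-M, ST-L, ST-D, ST-LD.
    """

    counts: np.ndarray  # (S, G) int
    genes: np.ndarray
    cell_types: np.ndarray
    positions: np.ndarray  # (S, 2) int
    is_tissue: np.ndarray  # (S,) bool
    condition: np.ndarray  # (S,) 'A'|'B'|'' (background)
    composition: np.ndarray  # (S, C) int
    stage: str = "ST-M"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.composition[~self.is_tissue] != 0):
            raise ValueError("background spots must have zero composition")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def barcodes(self) -> np.ndarray:
        return np.array(
            [f"spot_{r}_{c}" for r, c in self.positions], dtype=object
        )

    def subset_spots(self, idx: np.ndarray) -> "SpotDataset":
        return SpotDataset(
            self.counts[idx],
            self.genes,
            self.cell_types,
            self.positions[idx],
            self.is_tissue[idx],
            self.condition[idx],
            self.composition[idx],
            self.stage,
        )

    def subset_genes(self, idx: np.ndarray) -> "SpotDataset":
        return SpotDataset(
            self.counts[:, idx],
            self.genes[idx],
            self.cell_types,
            self.positions,
            self.is_tissue,
            self.condition,
            self.composition,
            self.stage,
        )

    def replace_counts(self, counts: np.ndarray, stage: str) -> "SpotDataset":
        return SpotDataset(
            counts,
            self.genes,
            self.cell_types,
            self.positions,
            self.is_tissue,
            self.condition,
            self.composition,
            stage,
        )


def place_spots(
    n_spots: int, array_rows: int, array_cols: int, seed: int = 0, max_trials: int = 1000
) -> TissueLayout:
    """Grow a tissue by random walk on the lattice.

    The first spot is uniform over the array; each subsequent spot steps
    0–2 rows and 0–2 columns (each direction independently) from the
    current position. An invalid or occupied proposal restarts from a
    random occupied spot; a spot failing ``max_trials`` proposals raises.
    """
    valid = lattice_positions(array_rows, array_cols)
    if n_spots > len(valid):
        raise ValueError(f"n_spots={n_spots} exceeds array capacity {len(valid)}")
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    rng = stage_rng(seed, "place_spots")
    first = tuple(valid[rng.integers(len(valid))])
    occupied: list[tuple[int, int]] = [first]
    occupied_set = {first}
    current = first
    for i in range(1, n_spots):
        placed = False
        for _ in range(max_trials):
            dr, dc = rng.integers(-2, 3, size=2)
            cand = (current[0] + int(dr), current[1] + int(dc))
            ok = (
                0 <= cand[0] < array_rows
                and 0 <= cand[1] < array_cols
                and (cand[0] + cand[1]) % 2 == 0
                and cand not in occupied_set
            )
            if ok:
                occupied.append(cand)
                occupied_set.add(cand)
                current = cand
                placed = True
                break
            current = occupied[rng.integers(len(occupied))]
        if not placed:
            raise RuntimeError(
                f"could not place spot {i}: {max_trials} trials exhausted"
            )
    return TissueLayout(array_rows, array_cols, np.array(occupied))


def _repair_contiguity(labels: np.ndarray, graph: nx.Graph) -> np.ndarray:
    """Flip minority components of each label to the other label."""
    labels = labels.copy()
    for _ in range(50):
        changed = False
        for lab in ("A", "B"):
            nodes = [i for i in graph if labels[i] == lab]
            if not nodes:
                continue
            comps = sorted(
                nx.connected_components(graph.subgraph(nodes)), key=len, reverse=True
            )
            for comp in comps[1:]:
                for i in comp:
                    labels[i] = "A" if lab == "B" else "B"
                changed = True
        if not changed:
            break
    return labels


def _rebalance(labels: np.ndarray, graph: nx.Graph, rng: np.random.Generator) -> np.ndarray:
    """Move frontier spots from the larger to the smaller region until the
    sizes differ by at most one, preferring moves that keep the donor
    region connected."""
    labels = labels.copy()
    guard = 4 * len(labels)
    while guard > 0:
        guard -= 1
        n_a = int((labels == "A").sum())
        n_b = len(labels) - n_a
        if abs(n_a - n_b) <= 1:
            break
        donor, acceptor = ("A", "B") if n_a > n_b else ("B", "A")
        donor_nodes = [i for i in graph if labels[i] == donor]
        frontier = [
            i
            for i in donor_nodes
            if any(labels[j] == acceptor for j in graph.neighbors(i))
        ]
        if not frontier:  # disconnected tissue; fall back to any donor spot
            frontier = donor_nodes
        frontier.sort()
        moved = False
        for i in frontier:
            rest = [j for j in donor_nodes if j != i]
            sub = graph.subgraph(rest)
            if len(rest) == 0 or nx.number_connected_components(sub) <= nx.number_connected_components(
                graph.subgraph(donor_nodes)
            ):
                labels[i] = acceptor
                moved = True
                break
        if not moved:
            labels[frontier[int(rng.integers(len(frontier)))]] = acceptor
    return labels


def assign_conditions(layout: TissueLayout, seed: int = 0) -> TissueLayout:
    """Partition occupied spots into two contiguous, balanced regions.

    Spots are split by a random line through their centroid (balanced at
    the median projection), enclaves are flipped to the surrounding label,
    and the split is rebalanced to |#A − #B| ≤ 1 along the frontier.
    """
    if layout.n_spots == 0:
        raise ValueError("layout has no occupied spots")
    rng = stage_rng(seed, "assign_conditions")
    xy = physical_coords(layout.occupied)
    theta = rng.uniform(0, 2 * np.pi)
    proj = xy @ np.array([np.cos(theta), np.sin(theta)])
    order = np.lexsort((layout.occupied[:, 1], layout.occupied[:, 0], proj))
    labels = np.full(layout.n_spots, "B", dtype=object)
    labels[order[: (layout.n_spots + 1) // 2]] = "A"
    graph = layout.graph()
    labels = _repair_contiguity(labels, graph)
    if not (labels == "A").any() or not (labels == "B").any():
        labels = np.full(layout.n_spots, "B", dtype=object)
        labels[order[: (layout.n_spots + 1) // 2]] = "A"  # degenerate repair; keep raw split
    labels = _rebalance(labels, graph, rng)
    return TissueLayout(layout.array_rows, layout.array_cols, layout.occupied, labels)


def allocate_cells(
    sc: SCDataset, layout: TissueLayout, config: SimConfig, seed: int = 0
) -> SpotAssignment:
    """Fill spots with simulated cells of matching condition.

    Per cell type, a uniformity state (evenly spread vs sparse) and a
    density state (high vs low cells/spot) are drawn; eligible spots then
    receive Poisson-distributed numbers of cells of that type, sampled
    without replacement from the SC pool of the spot's condition.
    """
    if layout.condition is None:
        raise ValueError("layout must have conditions assigned")
    rng = stage_rng(seed, "allocate_cells")
    cts = np.array(
        [str(c) for c in dict.fromkeys(sc.cell_type)], dtype=object
    )
    n = layout.n_spots
    n_cells = np.zeros((n, len(cts)), dtype=np.int64)
    plan: dict[int, list] = {i: [] for i in range(n)}
    states: dict = {}

    region_idx = {
        cond: np.flatnonzero(layout.condition == cond) for cond in ("A", "B")
    }
    pools = {}
    for ct in cts:
        for cond in ("A", "B"):
            pool = np.flatnonzero((sc.cell_type == ct) & (sc.condition == cond))
            pools[(ct, cond)] = rng.permutation(pool)

    # draw states and per-spot demand first, so shortfalls report in full
    demand: dict[tuple, np.ndarray] = {}
    shortfall = {}
    for t, ct in enumerate(cts):
        uniform = rng.random() < config.uniformity_prob[t]
        high = rng.random() < config.density_high_prob[t]
        rate = config.density_high_rate if high else config.density_low_rate
        states[ct] = {"uniform": bool(uniform), "high_density": bool(high)}
        for cond in ("A", "B"):
            spots = region_idx[cond]
            if not uniform:
                m = min(
                    len(spots),
                    max(3, int(round(config.sparse_subset_frac * len(spots)))),
                )
                spots = rng.choice(spots, size=m, replace=False)
            counts = rng.poisson(rate, size=len(spots))
            demand[(ct, cond)] = (spots, counts)
            need = int(counts.sum())
            have = len(pools[(ct, cond)])
            if need > have:
                shortfall[(ct, cond)] = (need, have)
    if shortfall:
        raise PoolShortfallError(shortfall)

    for t, ct in enumerate(cts):
        for cond in ("A", "B"):
            spots, counts = demand[(ct, cond)]
            pool = pools[(ct, cond)]
            offset = 0
            for s, k in zip(spots, counts):
                if k:
                    plan[int(s)].extend(pool[offset : offset + k].tolist())
                    n_cells[s, t] += k
                    offset += k

    cells_in_spot = {i: np.array(sorted(v), dtype=int) for i, v in plan.items()}
    return SpotAssignment(cells_in_spot, n_cells, cts, states)


def aggregate_counts(
    sc: SCDataset, assignment: SpotAssignment, layout: TissueLayout
) -> SpotDataset:
    """Sum assigned cells' transcriptomes per spot (stage ST-M).

    The returned dataset spans the full array; unoccupied (background)
    positions carry zero counts and zero composition.
    """
    all_pos = lattice_positions(layout.array_rows, layout.array_cols)
    pos_index = {tuple(p): i for i, p in enumerate(all_pos)}
    S = len(all_pos)
    G = sc.counts.shape[1]
    counts = np.zeros((S, G), dtype=np.int64)
    is_tissue = np.zeros(S, dtype=bool)
    condition = np.full(S, "", dtype=object)
    composition = np.zeros((S, len(assignment.cell_types)), dtype=np.int64)
    for occ_i, pos in enumerate(layout.occupied):
        i = pos_index[tuple(pos)]
        is_tissue[i] = True
        condition[i] = layout.condition[occ_i]
        composition[i] = assignment.n_cells[occ_i]
        cells = assignment.cells_in_spot.get(occ_i, np.empty(0, dtype=int))
        if len(cells):
            counts[i] = sc.counts[cells].sum(axis=0)
    return SpotDataset(
        counts,
        sc.genes,
        assignment.cell_types,
        all_pos,
        is_tissue,
        condition,
        composition,
        stage="ST-M",
    )
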