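"""Readers and writers for the standard on-disk formats.

Spot data follow 10x Visium conventions: a MatrixMarket genes × spots
matrix with ``genes.tsv`` / ``barcodes.tsv`` row/column ids and a
``tissue_positions.csv`` (barcode, in_tissue, array_row, array_col).
Composition, condition labels, and the stage tag — which real Visium
exports do not carry — live in sidecar files (``composition.tsv``
long-form and ``meta.json``). Round trips are lossless; in particular,
all-zero spots are preserved, never filtered: IO must not make analysis
decisions.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .singlecell import SCDataset
from .tissue import SpotDataset

__all__ = [
    "write_spot_dataset",
    "read_spot_dataset",
    "write_sc_dataset",
    "read_sc_dataset",
    "RunLog",
]


def write_spot_dataset(ds: SpotDataset, outdir: str | Path) -> Path:
    """Write a SpotDataset as MTX + positions + sidecars; returns the dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csc_matrix(ds.counts.T))
    (outdir / "genes.tsv").write_text("\n".join(map(str, ds.genes)) + "\n")
    barcodes = ds.barcodes
    (outdir / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")
    pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": ds.is_tissue.astype(int),
            "array_row": ds.positions[:, 0],
            "array_col": ds.positions[:, 1],
        }
    ).to_csv(outdir / "tissue_positions.csv", index=False)
    comp_rows = []
    for i, bc in enumerate(barcodes):
        for c, ct in enumerate(ds.cell_types):
            comp_rows.append(
                (bc, str(ct), int(ds.composition[i, c]), str(ds.condition[i]))
            )
    pd.DataFrame(
        comp_rows, columns=["spot_barcode", "cell_type", "n_cells", "condition"]
    ).to_csv(outdir / "composition.tsv", sep="\t", index=False)
    (outdir / "meta.json").write_text(
        json.dumps({"stage": ds.stage, "cell_types": [str(c) for c in ds.cell_types]})
    )
    return outdir


def read_spot_dataset(
    matrix_path: str | Path, positions_path: str | Path | None = None
) -> SpotDataset:
    """Read a SpotDataset written by :func:`write_spot_dataset`.

    ``matrix_path`` may be the dataset directory or the ``matrix.mtx``
    file; sibling files supply ids, positions, and sidecars. A barcode
    present in the matrix but missing from the positions table (or vice
    versa) is an error.
    """
    matrix_path = Path(matrix_path)
    outdir = matrix_path if matrix_path.is_dir() else matrix_path.parent
    mtx = outdir / "matrix.mtx" if matrix_path.is_dir() else matrix_path
    if positions_path is None:
        positions_path = outdir / "tissue_positions.csv"
    counts = np.asarray(spio.mmread(mtx).todense()).T  # spots x genes
    genes = np.array(
        (outdir / "genes.tsv").read_text().split(), dtype=object
    )
    barcodes = np.array(
        (outdir / "barcodes.tsv").read_text().split(), dtype=object
    )
    pos = pd.read_csv(positions_path)
    if set(pos["barcode"]) != set(barcodes) or len(pos) != len(barcodes):
        missing = set(barcodes) ^ set(pos["barcode"])
        raise ValueError(f"barcode mismatch between matrix and positions: {missing}")
    pos = pos.set_index("barcode").loc[barcodes]
    meta = json.loads((outdir / "meta.json").read_text())
    cell_types = np.array(meta["cell_types"], dtype=object)
    comp = pd.read_csv(outdir / "composition.tsv", sep="\t")
    comp_piv = comp.pivot(index="spot_barcode", columns="cell_type", values="n_cells")
    comp_piv = comp_piv.loc[barcodes, cell_types].to_numpy()
    cond = (
        comp.drop_duplicates("spot_barcode")
        .set_index("spot_barcode")
        .loc[barcodes, "condition"]
        .fillna("")
        .to_numpy(dtype=object)
    )
    return SpotDataset(
        counts.astype(np.int64),
        genes,
        cell_types,
        pos[["array_row", "array_col"]].to_numpy(),
        pos["in_tissue"].to_numpy().astype(bool),
        cond,
        comp_piv.astype(np.int64),
        stage=meta["stage"],
    )


def write_sc_dataset(sc: SCDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csc_matrix(sc.counts.T))
    (outdir / "genes.tsv").write_text("\n".join(map(str, sc.genes)) + "\n")
    pd.DataFrame(
        {
            "barcode": [f"cell_{i}" for i in range(sc.n_cells)],
            "cell_type": sc.cell_type,
            "condition": sc.condition,
        }
    ).to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return outdir


def read_sc_dataset(outdir: str | Path) -> SCDataset:
    outdir = Path(outdir)
    counts = np.asarray(spio.mmread(outdir / "matrix.mtx").todense()).T
    genes = np.array((outdir / "genes.tsv").read_text().split(), dtype=object)
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t")
    return SCDataset(
        counts.astype(np.int32),
        genes,
        cells["cell_type"].to_numpy(dtype=object),
        cells["condition"].to_numpy(dtype=object),
    )


@dataclass
class RunLog:
    """Append-only provenance log tying outputs to one config + seed."""

    path: Path
    entries: list = field(default_factory=list)

    def record(
        self,
        stage: str,
        seed: int,
        qc_passed: bool | None = None,
        files: list[str | Path] = (),
    ) -> None:
        entry = {
            "stage": stage,
            "seed": int(seed),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "qc_passed": qc_passed,
            "digests": {
                str(f): hashlib.sha256(Path(f).read_bytes()).hexdigest()[:16]
                for f in files
            },
        }
        self.entries.append(entry)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")
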