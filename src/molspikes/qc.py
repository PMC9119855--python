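"""Quality control of extracted spUMIs.

Three diagnostics: (1) per-cell minimum Hamming-distance profiles of spUMIs
against their within-cell neighbours and against a random background sample
from other cells — PCR/sequencing errors enrich within-cell minima at 1-2
substitutions while the background stays near the random expectation; (2) a
filter removing over-represented spUMIs (seen in too many cells or with too
many raw reads, both symptoms of contamination or highly amplified
artefacts); and (3) selection of the eligible-molecule pool (molecules seen
in exactly one cell with moderate 10-20x read coverage) used as ground truth
for counting evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collapse import encode_umis, packed_hamming


@dataclass
class DistanceProfile:
    """Minimum Hamming distances of each spUMI within its cell and to background."""

    within_cell_min_distances: list[int]
    background_min_distances: list[int]


def _min_distances(codes: np.ndarray, other: np.ndarray, length: int) -> list[int]:
    out = []
    for c in codes:
        d = packed_hamming(np.full(len(other), c, dtype=np.uint64), other, length)
        out.append(int(d.min()))
    return out


def distance_profile(
    records: pd.DataFrame,
    background_sample_size: int = 1000,
    seed: int = 0,
) -> dict[str, DistanceProfile]:
    """Per-cell minimum-distance profiles of spUMI sequences.

    For each spUMI in a cell: the minimum Hamming distance to any other spUMI
    of the same cell (empty when the cell holds a single spUMI) and to a
    seeded random sample of spUMIs from other cells, drawn without
    replacement.  Requires >= 2 cells.
    """
    cells = records["cell_barcode"].unique()
    if len(cells) < 2:
        raise ValueError("distance_profile requires spUMIs from at least 2 cells")
    length = len(records["spumi"].iloc[0])
    rng = np.random.default_rng(seed)
    by_cell = {c: list(g["spumi"]) for c, g in records.groupby("cell_barcode")}
    profiles: dict[str, DistanceProfile] = {}
    for cell in sorted(by_cell):
        own = by_cell[cell]
        codes = encode_umis(own)
        within: list[int] = []
        if len(own) > 1:
            for i, c in enumerate(codes):
                others = np.delete(codes, i)
                within.append(
                    int(packed_hamming(np.full(len(others), c, dtype=np.uint64), others, length).min())
                )
        pool = [s for other_cell, spumis in by_cell.items() if other_cell != cell for s in spumis]
        k = background_sample_size
        if len(pool) < k:
            warnings.warn(
                f"background for cell {cell} has only {len(pool)} spUMIs "
                f"(requested {k}); using all available"
            )
            k = len(pool)
        idx = rng.choice(len(pool), size=k, replace=False)
        background = encode_umis([pool[i] for i in idx])
        profiles[cell] = DistanceProfile(
            within_cell_min_distances=within,
            background_min_distances=_min_distances(codes, background, length),
        )
    return profiles


def filter_overrepresented(
    records: pd.DataFrame, max_cells: int, max_reads: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard spUMIs seen in > ``max_cells`` cells or with > ``max_reads`` raw reads.

    Both thresholds are strict (a spUMI in exactly ``max_cells`` cells is
    retained).  Read counts are raw sequencing reads summed dataset-wide.
    The filter is idempotent and order-independent.  Returns the filtered
    table and a removal report (spumi, n_cells, n_reads, reason).
    """
    key_cols = [c for c in ("spike", "barcode") if c in records.columns] + ["spumi"]
    if records.empty:
        return records.copy(), pd.DataFrame(columns=key_cols + ["n_cells", "n_reads", "reason"])
    stats = records.groupby(key_cols).agg(
        n_cells=("cell_barcode", "nunique"), n_reads=("read_count", "sum")
    )
    too_many_cells = stats["n_cells"] > max_cells
    too_many_reads = stats["n_reads"] > max_reads
    removed = stats[too_many_cells | too_many_reads].copy()
    removed["reason"] = np.where(
        too_many_cells[removed.index] & too_many_reads[removed.index],
        "cells+reads",
        np.where(too_many_cells[removed.index], "cells", "reads"),
    )
    bad = set(removed.index)
    keys = list(records[key_cols].itertuples(index=False, name=None))
    if len(key_cols) == 1:
        keys = [k[0] for k in keys]
        bad = {k if not isinstance(k, tuple) else k[0] for k in bad}
    mask = [k not in bad for k in keys]
    return records[mask].reset_index(drop=True), removed.reset_index()


def eligible_molecule_pool(records: pd.DataFrame) -> pd.DataFrame:
    """Molecules observed in exactly one cell with 10-20 total reads (inclusive).

    ``records`` is a corrected molecule table (cell_barcode, [spike,
    barcode,] spumi, read_count); the returned pool keeps one row per
    eligible molecule.
    """
    key_cols = [c for c in ("spike", "barcode") if c in records.columns] + ["spumi"]
    if records.empty:
        return records.copy()
    stats = records.groupby(key_cols).agg(
        n_cells=("cell_barcode", "nunique"), n_reads=("read_count", "sum")
    )
    ok = stats[(stats["n_cells"] == 1) & stats["n_reads"].between(10, 20)]
    good = set(ok.index)
    keys = list(records[key_cols].itertuples(index=False, name=None))
    if len(key_cols) == 1:
        keys = [k[0] for k in keys]
        good = {k if not isinstance(k, tuple) else k[0] for k in good}
    mask = [k in good for k in keys]
    return records[mask].reset_index(drop=True)
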