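"""Ground-truth counting-accuracy evaluation.

Molecules whose identity is known from their spUMI are sampled into in-silico
cells at defined expression levels, together with all of their sequencing
reads.  Counting a cell then reduces to deduplicating the library UMIs on
those reads, and the result can be compared to the exact number of sampled
molecules.  Percent counting error is observed/truth x 100, so 100% means
exact counting; the "inflation reference line" reads/truth x 100 is the null
of total counting failure in which every sequenced read is taken as a new
molecule (the signature of template-switching-oligo or primer carry-over
artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .collapse import ALGORITHMS, collapse, trim_umi


@dataclass
class ExpressionLevelDesign:
    """Target expression levels for in-silico cells.

    The two standard designs are 20 linearly spaced levels from 1 to 100
    molecules and 60 log-spaced levels from 1 to 1,000 molecules, each with
    100 in-silico cells per level.
    """

    levels: list[float]
    cells: int = 100
    spacing: str = "linear"
    seed: int = 0

    @classmethod
    def linear(cls, n_levels: int = 20, low: float = 1, high: float = 100,
               cells: int = 100, seed: int = 0) -> "ExpressionLevelDesign":
        return cls(list(np.linspace(low, high, n_levels)), cells, "linear", seed)

    @classmethod
    def log(cls, n_levels: int = 60, low: float = 1, high: float = 1000,
            cells: int = 100, seed: int = 0) -> "ExpressionLevelDesign":
        return cls(list(np.geomspace(low, high, n_levels)), cells, "log", seed)


@dataclass
class CountingError:
    """Observed vs ground-truth molecule count for one in-silico cell."""

    observed: int
    truth: int
    percent: float = field(init=False)

    def __post_init__(self) -> None:
        self.percent = 100.0 * self.observed / self.truth if self.truth else float("nan")


def draw_level_size(mean: float, rng: np.random.Generator) -> int:
    """Number of molecules for a cell at a level: round(N(mean, sqrt(mean))), clamped at 0."""
    if mean <= 0:
        raise ValueError("mean expression level must be positive")
    return max(0, int(round(rng.normal(mean, np.sqrt(mean)))))


def sample_ground_truth(
    pool: Mapping[str, Sequence[str]],
    design: ExpressionLevelDesign,
) -> dict[float, list[dict[str, list[str]]]]:
    """Sample molecules (with their reads) into in-silico cells per level.

    ``pool`` maps molecule ids to the list of library-UMI sequences of their
    reads.  For every level x cell, ``draw_level_size(level)`` molecules are
    sampled without replacement within the cell (molecules are re-usable
    across cells).  Returns {level: [cell dict of molecule -> reads, ...]}.
    """
    molecule_ids = sorted(pool)
    rng = np.random.default_rng(design.seed)
    out: dict[float, list[dict[str, list[str]]]] = {}
    for level in design.levels:
        cells = []
        for _ in range(design.cells):
            size = draw_level_size(level, rng)
            if size > len(molecule_ids):
                raise ValueError(
                    f"pool of {len(molecule_ids)} molecules exhausted at level {level}"
                )
            chosen = rng.choice(len(molecule_ids), size=size, replace=False)
            cells.append({molecule_ids[i]: list(pool[molecule_ids[i]]) for i in chosen})
        out[level] = cells
    return out


def evaluate_counting(
    sampled: dict[float, list[dict[str, list[str]]]],
    umi_length: int,
    mode: str = "adjacency",
    d: int = 1,
) -> pd.DataFrame:
    """Count each in-silico cell by collapsing its (trimmed) library UMIs.

    Library UMIs on all reads of a cell are trimmed to ``umi_length``,
    collapsed with the chosen algorithm at Hamming distance ``d`` (``d=0`` or
    ``mode='none'`` counts distinct UMIs uncorrected), and compared to the
    number of ground-truth molecules.  Returns a long-format table with
    level, cell, truth, observed, difference and percent.
    """
    if mode != "none" and mode not in ALGORITHMS:
        raise ValueError(f"unknown collapse mode {mode!r}")
    rows = []
    for level in sorted(sampled):
        for cell_idx, cell in enumerate(sampled[level]):
            truth = len(cell)
            counts: dict[str, int] = {}
            for reads in cell.values():
                for umi in reads:
                    counts[umi] = counts.get(umi, 0) + 1
            counts = trim_umi(counts, umi_length) if counts else {}
            if mode == "none" or d == 0:
                observed = len(counts)
            else:
                observed = collapse(counts, d, mode).n_molecules
            err = CountingError(observed=observed, truth=truth)
            rows.append(
                {
                    "level": level,
                    "cell": cell_idx,
                    "truth": truth,
                    "observed": observed,
                    "difference": observed - truth,
                    "percent": err.percent,
                }
            )
    return pd.DataFrame(rows)


def inflation_reference_line(reads_per_cell: int, truth: int) -> float:
    """Percent counting error if every sequenced read were a new molecule."""
    if truth == 0:
        return float("nan")
    return 100.0 * reads_per_cell / truth
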