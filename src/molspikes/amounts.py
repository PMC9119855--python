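"""Expected-molecule arithmetic for spike-in pools.

Converts a dispensed mass of spike RNA into an expected molecule count using
standard single-stranded RNA residue masses, the length and GC composition of
each species and the relative abundance (complexity) of the species in the
pool.  Also provides small counting-capacity helpers (UMI sequence-space
size, detection sensitivity).
"""

from __future__ import annotations

import pandas as pd

AVOGADRO = 6.02214076e23

# monophosphate residue masses of single-stranded RNA, g/mol
MASS_A = 329.2
MASS_C = 305.2
MASS_G = 345.2
MASS_U = 306.2
# one 5' triphosphate adds ~159 g/mol over the residue mass
TRIPHOSPHATE_5P = 159.0

#: Composition of the reference complex molecular-spike pool: 11 species with
#: their body length (nt, excluding the poly-A tail), GC content (%) and total
#: spUMI complexity (molecules), used as abundance weights.
COMPLEX_POOL_COMPOSITION = pd.DataFrame(
    {
        "name": [f"spike_{i}" for i in range(1, 12)],
        "length_nt": [2070, 1070, 570, 2070, 1070, 570, 3070, 2070, 1067, 568, 1096],
        "gc_percent": [58.5, 58.7, 54.7, 48.2, 49.3, 44.2, 39.3, 38.8, 39.4, 40.0, 49.1],
        "complexity": [
            1_746_869, 4_628_714, 8_735_160, 9_203_773, 12_828_533, 9_079_194,
            4_399_937, 7_130_428, 5_790_596, 8_121_606, 4_946_866,
        ],
    }
)


def umi_coding_capacity(length: int) -> int:
    """Number of distinct sequences a UMI of the given length can encode."""
    return 4 ** length


def detection_sensitivity(observed_molecules: float, expected_molecules: float) -> float:
    """Percent of expected molecules actually observed."""
    return 100.0 * observed_molecules / expected_molecules


def rna_molecular_weight(
    length_nt: int, gc_percent: float, polya_tail: int = 30
) -> float:
    """Molecular weight (g/mol) of one ssRNA species.

    A/U and G/C are assumed equimolar within their class over the sequence
    body; the poly-A tail and the 5' triphosphate are added on top.
    """
    gc = length_nt * gc_percent / 100.0
    at = length_nt - gc
    return gc / 2 * (MASS_G + MASS_C) + at / 2 * (MASS_A + MASS_U) + polya_tail * MASS_A + TRIPHOSPHATE_5P


def expected_molecules(
    mass_pg: float, composition: pd.DataFrame | None = None, polya_tail: int = 30
) -> float:
    """Expected number of molecules in ``mass_pg`` picograms of a spike pool.

    The pool's mean molecular weight is the complexity-weighted average over
    its species; the expected count is mass / mean MW x Avogadro.
    """
    if composition is None:
        composition = COMPLEX_POOL_COMPOSITION
    mws = [
        rna_molecular_weight(row.length_nt, row.gc_percent, polya_tail)
        for row in composition.itertuples()
    ]
    weights = composition["complexity"].astype(float)
    mean_mw = float((pd.Series(mws, index=composition.index) * weights).sum() / weights.sum())
    return mass_pg * 1e-12 / mean_mw * AVOGADRO
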