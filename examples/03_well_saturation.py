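"""Estimate the spike molecules captured in an empty well from a saturation fit.

An empty well (spike-ins, no cell) with 8,000 molecules is simulated at ~5
reads per molecule.  Reads are subsampled over a depth grid, spUMIs corrected
at Hamming distance 2 and distinct molecules counted; the asymptote of the
fitted model y = b0 + b1(1 - exp(-exp(c) x)) estimates the captured molecules
at sequencing saturation.
"""

import numpy as np

from molspikes import SimulationConfig, simulate
from molspikes.saturation import estimate_well_molecules, predict_saturation

n_true = 8000
truth = simulate(SimulationConfig(
    n_cells=1, molecules_per_cell=n_true, spumi_length=14,
    reads_per_molecule=("poisson", 5.0), per_base_error_rate=0.002, seed=3,
))
reads = [r.spumi_obs for mol in truth.cells[0].molecules for r in mol.reads]
depths = [int(v) for v in np.linspace(3000, len(reads), 12)]
fit, curve = estimate_well_molecules(reads, depths, seed=3)

print(curve.to_string(index=False))
print(f"\nfitted asymptote  : {fit.asymptote:,.0f} molecules (truth {n_true:,})")
print(f"relative error    : {abs(fit.asymptote - n_true) / n_true:.1%}")
y, frac = predict_saturation(fit, depths[len(depths) // 2])
print(f"at {depths[len(depths)//2]:,} reads the well is {frac:.0%} saturated ({y:,.0f} molecules seen)")
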