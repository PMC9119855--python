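"""Ground-truth counting evaluation: UMI length, error correction and inflation.

Molecules with known identity are sampled into in-silico cells at a fixed
expression level; their library UMIs are counted raw and after adjacency
collapse, at full length and trimmed.  Percent counting error is
observed/truth x 100, so 100 means exact counting: raw counts inflate with
per-base UMI errors, short UMIs undercount by collisions, and Hamming-1
collapse recovers accurate counts for 10-nt UMIs.
"""

from molspikes import ExpressionLevelDesign, SimulationConfig, simulate
from molspikes.counting import evaluate_counting, sample_ground_truth

truth = simulate(SimulationConfig(
    n_cells=1, molecules_per_cell=400, library_umi_length=10,
    reads_per_molecule=8, per_base_error_rate=0.01, seed=1,
))
pool = {
    f"mol{i}": [r.library_umi_obs for r in mol.reads]
    for i, mol in enumerate(truth.cells[0].molecules)
}
design = ExpressionLevelDesign([100.0], cells=20, seed=0)
sampled = sample_ground_truth(pool, design)

print(f"{'UMI length':>10} {'raw %':>8} {'adjacency d=1 %':>16} {'adjacency d=2 %':>16}")
for length in (10, 8, 6, 4):
    raw = evaluate_counting(sampled, length, mode="none", d=0)["percent"].mean()
    hd1 = evaluate_counting(sampled, length, mode="adjacency", d=1)["percent"].mean()
    hd2 = evaluate_counting(sampled, length, mode="adjacency", d=2)["percent"].mean()
    print(f"{length:>10} {raw:>8.1f} {hd1:>16.1f} {hd2:>16.1f}")

print("Longer UMIs inflate more without correction (more bases can mutate);")
print("4-nt UMIs undercount even raw (only 256 codes for ~100 molecules);")
print("collapse restores ~100% for lengths with enough coding capacity.")
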