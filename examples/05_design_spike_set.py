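"""Design a complex molecular-spike set: sequences, barcodes and manifest.

Candidate spike sequences are sampled at a target GC content, filtered for
homopolymer runs and ranked by local GC smoothness; 7-nt expression barcodes
are built greedily at pairwise Hamming distance >= 3 and arranged as a
twofold, 12-level duplicate titration on each sequence.
"""

import numpy as np

from molspikes.design import (
    assemble_complex_set,
    assign_titration_levels,
    design_barcodes,
    generate_candidate_sequences,
    rank_by_local_gc,
)

rng = np.random.default_rng(0)
candidates = generate_candidate_sequences(20, 500, gc=0.50, rng=rng)
ranked = rank_by_local_gc(candidates, window=100)
sequences = {f"spike{i + 1}": s for i, s in enumerate(ranked[:11])}

barcodes = design_barcodes(n=24, seed=0)
print(f"candidate sequences kept : {len(candidates)} (GC 50% +/- 1%, runs <= 4)")
print(f"barcodes designed        : {barcodes}")

bsets = {name: assign_titration_levels(barcodes) for name in sequences}
manifest = assemble_complex_set(sequences, bsets)
print(f"species in manifest      : {len(manifest)} "
      f"({manifest['sequence_id'].nunique()} sequences x {manifest['barcode'].nunique()} barcodes)")
print(f"abundance range          : "
      f"{manifest['relative_abundance'].min():.0f}x to {manifest['relative_abundance'].max():.0f}x "
      f"over {manifest['level'].nunique()} twofold levels")
print(manifest.head(4).to_string(index=False))
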