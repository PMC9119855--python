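import numpy as np
import pytest

from molspikes import SimulationConfig, simulate
from molspikes.reference import SpikeReference


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_ref():
    """A compact simple-design reference with known anchors and spUMI locus."""
    up = "ACGTACGTAACCGGTTACGT"
    down = "TTGGCCAATTGGCCAATTGG"
    pad5 = "GATTACA" * 4
    pad3 = "CATCATC" * 4
    seq = pad5 + up + "N" * 18 + down + pad3
    return SpikeReference(
        name="spike_test",
        sequence=seq,
        spumi_start=len(pad5) + len(up),
        spumi_length=18,
        upstream_anchor=up,
        downstream_anchor=down,
    )


@pytest.fixture
def complex_ref():
    """A complex-design reference: 7-nt barcode + 14N spUMI + 25-nt constant."""
    barcodes = ("AACCGGT", "TTGGCCA", "ACACACA", "GTGTGTG")
    pad5 = "ATGCATGCAT"
    constant = "ACGTTGCAACGGTTAACCGGATCCA"
    seq = pad5 + barcodes[0] + "N" * 14 + constant + "TGCAATTGCA"
    return SpikeReference(
        name="spike_complex",
        sequence=seq,
        spumi_start=len(pad5) + 7,
        spumi_length=14,
        upstream_anchor=pad5,
        downstream_anchor=constant,
        barcode_locus=len(pad5),
        barcodes=barcodes,
    )


@pytest.fixture
def clean_truth():
    """Small error-free simulation (ground truth for lossless round trips)."""
    config = SimulationConfig(
        n_cells=3, molecules_per_cell=25, reads_per_molecule=3, seed=7
    )
    return simulate(config)
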