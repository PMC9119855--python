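"""Synthetic ground-truth simulator for molecular-spike experiments.

Generates cells with a known number of spike molecules, each carrying a
uniform random spUMI and library UMI, amplifies every molecule into reads,
and injects the two error processes that corrupt UMI sequences in real
libraries:

* PCR errors — each molecule is amplified through a binary tree of
  ``pcr_cycles`` doublings; a substitution on an early branch is inherited by
  all descendant reads, which reproduces the within-cell enrichment of spUMIs
  one or two errors away from a true sequence.  The tree is never
  materialised: each read samples a random leaf and the per-branch mutations
  are derived from deterministic per-edge seeds, so reads sharing ancestry
  share mutations.
* sequencing errors — independent per-base substitutions on every read.

Two count-inflation failure modes can be switched on: ``new_umi_per_read``
stamps a fresh random library UMI on every read (the signature of oligo-dT
primer carry-over in direct-PCR protocols), and ``tso_priming`` does so for a
fraction of reads (residual template-switching oligo priming).  Fixtures can
be emitted as SAM (tagged reads embedding anchors + spUMI) plus truth tables
so every downstream analysis stage can be exercised end to end.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pysam

from .reference import SpikeReference

_BASES = "ACGT"


class ReadObservation(NamedTuple):
    """One simulated sequencing read of one molecule."""

    spumi_obs: str
    library_umi_obs: str
    umi_qualities: tuple[int, ...]


@dataclass
class MoleculeTruth:
    """One simulated spike molecule with its true identifiers and reads."""

    spumi: str
    library_umi: str
    reads: list[ReadObservation] = field(default_factory=list)


@dataclass
class CellTruth:
    cell_barcode: str
    molecules: list[MoleculeTruth] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return sum(len(m.reads) for m in self.molecules)


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    config: "SimulationConfig"
    reference: SpikeReference

    @property
    def n_molecules(self) -> int:
        return sum(len(c.molecules) for c in self.cells)

    def observed_spumi_counts(self, cell: CellTruth) -> dict[str, int]:
        counts: dict[str, int] = {}
        for mol in cell.molecules:
            for read in mol.reads:
                counts[read.spumi_obs] = counts.get(read.spumi_obs, 0) + 1
        return counts

    def observed_library_umi_counts(self, cell: CellTruth) -> dict[str, int]:
        counts: dict[str, int] = {}
        for mol in cell.molecules:
            for read in mol.reads:
                counts[read.library_umi_obs] = counts.get(read.library_umi_obs, 0) + 1
        return counts


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    ``reads_per_molecule`` is either an integer (constant) or a tuple
    ``("poisson", mean)`` / ``("nb", mean, dispersion)``.  ``inflation_mode``
    is one of ``none``, ``new_umi_per_read`` or ``tso_priming`` (the latter
    replacing the library UMI for ``tso_priming_fraction`` of reads).
    """

    n_cells: int = 10
    molecules_per_cell: int = 100
    spumi_length: int = 18
    library_umi_length: int = 10
    reads_per_molecule: object = ("poisson", 5.0)
    per_base_error_rate: float = 0.0
    pcr_cycles: int = 8
    per_cycle_error_rate: float = 0.0
    inflation_mode: str = "none"
    tso_priming_fraction: float = 0.0
    low_quality_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.per_base_error_rate, self.per_cycle_error_rate,
                  self.tso_priming_fraction, self.low_quality_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spumi_length <= 0 or self.library_umi_length < 0:
            raise ValueError("lengths must be positive")
        if self.inflation_mode not in ("none", "new_umi_per_read", "tso_priming"):
            raise ValueError(f"unknown inflation_mode {self.inflation_mode!r}")


def default_reference(spumi_length: int = 18, seed: int = 20) -> SpikeReference:
    """A compact simple-design spike reference with 20-nt anchors."""
    rng = np.random.default_rng(seed)
    up = "".join(rng.choice(list(_BASES), size=20))
    down = "".join(rng.choice(list(_BASES), size=20))
    pad5 = "".join(rng.choice(list(_BASES), size=30))
    pad3 = "".join(rng.choice(list(_BASES), size=30))
    seq = pad5 + up + "N" * spumi_length + down + pad3
    return SpikeReference(
        name="spike_sim",
        sequence=seq,
        spumi_start=len(pad5) + len(up),
        spumi_length=spumi_length,
        upstream_anchor=up,
        downstream_anchor=down,
    )


def _draw_reads(spec, rng: np.random.Generator) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    kind = spec[0]
    if kind == "poisson":
        return int(rng.poisson(spec[1]))
    if kind == "nb":
        mean, size = spec[1], spec[2]
        p = size / (size + mean)
        return int(rng.negative_binomial(size, p))
    raise ValueError(f"unknown reads_per_molecule spec {spec!r}")


def _mutate(seq: list[str], positions, rng: random.Random) -> None:
    for pos in positions:
        old = seq[pos]
        seq[pos] = rng.choice([b for b in _BASES if b != old])


def _pcr_mutations(
    molecule_seed: int, leaf: int, cycles: int, length: int, rate: float,
) -> list[tuple[int, random.Random]]:
    """Mutation events along one leaf's lineage, shared across reads via seeds."""
    events = []
    for t in range(1, cycles + 1):
        prefix = leaf >> (cycles - t)
        edge_rng = random.Random((molecule_seed << 34) ^ (t << 28) ^ prefix)
        k = sum(1 for _ in range(length) if edge_rng.random() < rate)
        if k:
            events.append((k, edge_rng))
    return events


def simulate(config: SimulationConfig, reference: Optional[SpikeReference] = None) -> GroundTruth:
    """Run one simulation, returning the full per-molecule ground truth."""
    rng = np.random.default_rng(config.seed)
    reference = reference or default_reference(config.spumi_length)
    sp_len = config.spumi_length
    lib_len = config.library_umi_length
    cells: list[CellTruth] = []
    n_leaves = 2 ** config.pcr_cycles
    pcr_on = config.per_cycle_error_rate > 0 and config.pcr_cycles > 0
    seq_err = config.per_base_error_rate
    for ci in range(config.n_cells):
        cell = CellTruth(cell_barcode=f"CELL{ci:04d}")
        for _ in range(config.molecules_per_cell):
            spumi = "".join(_BASES[b] for b in rng.integers(0, 4, size=sp_len))
            lib_umi = "".join(_BASES[b] for b in rng.integers(0, 4, size=lib_len))
            mol = MoleculeTruth(spumi=spumi, library_umi=lib_umi)
            n_reads = _draw_reads(config.reads_per_molecule, rng)
            mol_seed = int(rng.integers(0, 2 ** 31)) if pcr_on else 0
            for _ in range(n_reads):
                sp = list(spumi)
                lu = list(lib_umi)
                if pcr_on:
                    leaf = int(rng.integers(0, n_leaves))
                    for k, edge_rng in _pcr_mutations(
                        mol_seed, leaf, config.pcr_cycles, sp_len + lib_len,
                        config.per_cycle_error_rate,
                    ):
                        positions = edge_rng.sample(range(sp_len + lib_len), k)
                        for pos in positions:
                            target = sp if pos < sp_len else lu
                            idx = pos if pos < sp_len else pos - sp_len
                            old = target[idx]
                            target[idx] = edge_rng.choice([b for b in _BASES if b != old])
                if seq_err > 0:
                    for i in range(sp_len):
                        if rng.random() < seq_err:
                            sp[i] = _BASES[(rng.integers(1, 4) + _BASES.index(sp[i])) % 4]
                    for i in range(lib_len):
                        if rng.random() < seq_err:
                            lu[i] = _BASES[(rng.integers(1, 4) + _BASES.index(lu[i])) % 4]
                if config.inflation_mode == "new_umi_per_read" or (
                    config.inflation_mode == "tso_priming"
                    and rng.random() < config.tso_priming_fraction
                ):
                    lu = [_BASES[b] for b in rng.integers(0, 4, size=lib_len)]
                quals = tuple(
                    10 if config.low_quality_prob and rng.random() < config.low_quality_prob else 37
                    for _ in range(lib_len)
                )
                mol.reads.append(ReadObservation("".join(sp), "".join(lu), quals))
            cell.molecules.append(mol)
        cells.append(cell)
    return GroundTruth(cells=cells, config=config, reference=reference)


def titration_expected_counts(
    total_molecules: float = 33_378.0,
    sequences: int = 11,
    levels: int = 12,
    replicates: int = 2,
) -> np.ndarray:
    """Expected per-barcode molecule counts of a twofold titration spike set.

    The complex spike set arranges its barcodes as 12 expression levels in
    twofold steps, duplicated, across 11 sequences (264 barcodes).  Defaults
    scale the series so a well receives ~33,378 spike molecules in total.
    """
    per_level = sequences * replicates
    level_of_barcode = np.repeat(np.arange(1, levels + 1), per_level)
    base = total_molecules / (per_level * (2.0 ** levels - 1.0))
    return base * 2.0 ** (level_of_barcode - 1)


def expression_profile(
    n_genes: int = 3000,
    mean_total: float = 35_000.0,
    sigma: float = 2.55,
    seed: int = 0,
) -> np.ndarray:
    """A fixed per-gene expression-rate profile for simulated cells of one type.

    Gene rates are drawn once from a lognormal whose scale matches the spread
    the twofold titration spike set spans (a Poisson-lognormal fit to the
    titration's per-barcode counts gives sigma ~2.55); per-cell molecule
    counts are then Poisson realisations of this shared profile, as for
    biological replicates of one cell type.
    """
    rng = np.random.default_rng(seed)
    mu = np.log(mean_total / n_genes) - sigma ** 2 / 2.0
    return rng.lognormal(mu, sigma, size=n_genes)


def simulate_inflated_well(
    gene_rates: np.ndarray,
    rng: np.random.Generator,
    read_inflation: float = 5.0,
    spike_expected: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """One well with count inflation: true UMIs, inflated reads, spike counts.

    True per-gene molecule counts are Poisson draws from the shared profile;
    read counts are Poisson with ``read_inflation``-fold amplification (every
    read counted as a molecule, the total-counting-failure regime); spike
    barcode spUMI counts are Poisson draws from the titration expectation.
    """
    true_umis = rng.poisson(gene_rates)
    reads = rng.poisson(read_inflation * true_umis)
    if spike_expected is None:
        spike_expected = titration_expected_counts()
    spike_counts = rng.poisson(spike_expected)
    return {"true_umis": true_umis, "reads": reads, "spike_counts": spike_counts}


def emit_fixtures(truth: GroundTruth, outdir: str | Path, format: str = "SAM") -> dict[str, Path]:
    """Write simulated reads and truth tables to files.

    ``format='SAM'`` emits tagged alignments (BC/UB/UY tags; read sequence =
    upstream anchor + observed spUMI + downstream anchor) so the extraction
    module can run end to end; ``format='TSV'`` emits the read table only.
    A per-molecule truth table is written alongside in both cases.  Output is
    byte-identical for a fixed simulation seed.
    """
    if format not in ("SAM", "TSV"):
        raise ValueError(f"unsupported fixture format {format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = truth.reference
    paths: dict[str, Path] = {}

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("cell_barcode\tmolecule\tspumi\tlibrary_umi\tn_reads\n")
        for cell in truth.cells:
            for mi, mol in enumerate(cell.molecules):
                fh.write(
                    f"{cell.cell_barcode}\t{mi}\t{mol.spumi}\t{mol.library_umi}\t{len(mol.reads)}\n"
                )
    paths["truth"] = truth_path

    reads_path = outdir / "reads.tsv"
    with open(reads_path, "w") as fh:
        fh.write("cell_barcode\tmolecule\tspumi_obs\tlibrary_umi_obs\n")
        for cell in truth.cells:
            for mi, mol in enumerate(cell.molecules):
                for read in mol.reads:
                    fh.write(
                        f"{cell.cell_barcode}\t{mi}\t{read.spumi_obs}\t{read.library_umi_obs}\n"
                    )
    paths["reads"] = reads_path

    if format == "SAM":
        sam_path = outdir / "reads.sam"
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": ref.name, "LN": len(ref.sequence)}],
        }
        start = ref.upstream_anchor_start
        with pysam.AlignmentFile(str(sam_path), "wh", header=header) as fh:
            qi = 0
            for cell in truth.cells:
                for mol in cell.molecules:
                    for read in mol.reads:
                        seq = ref.upstream_anchor + read.spumi_obs + ref.downstream_anchor
                        aln = pysam.AlignedSegment(fh.header)
                        aln.query_name = f"read{qi:08d}"
                        aln.query_sequence = seq
                        aln.flag = 0
                        aln.reference_id = 0
                        aln.reference_start = start
                        aln.mapping_quality = 255
                        aln.cigarstring = f"{len(seq)}M"
                        aln.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                        tags = [("BC", cell.cell_barcode), ("UB", read.library_umi_obs)]
                        if read.library_umi_obs:
                            tags.append(
                                ("UY", "".join(chr(q + 33) for q in read.umi_qualities))
                            )
                        aln.tags = tags
                        fh.write(aln)
                        qi += 1
        paths["sam"] = sam_path
    return paths
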