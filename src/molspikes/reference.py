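"""Domain types for molecular-spike references, tagged reads and validated records.

A *molecular spike* is an in-vitro-transcribed RNA spike-in that carries a
built-in unique molecular identifier (the spike UMI, or spUMI) inside its
sequence.  The simple design embeds an 18-nt random stretch; the complex set
additionally carries a 7-nt expression barcode directly upstream of a 14-nt
spUMI, followed by a 25-nt constant region.  These types describe a spike
species, one aligned sequencing read carrying cell-barcode/UMI tags, and one
validated spUMI observation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq`` (0 for an empty sequence)."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")) / len(seq)


@dataclass(frozen=True)
class SpikeReference:
    """One spike species: sequence plus the coordinates of its spUMI locus.

    Offsets are 0-based, half-open.  ``upstream_anchor`` and
    ``downstream_anchor`` are the known sequences flanking the spUMI locus;
    for the complex design ``downstream_anchor`` is the 25-nt constant region
    directly downstream of the 14-nt spUMI and ``barcode_locus`` points at the
    7-nt expression barcode directly upstream of the spUMI.
    """

    name: str
    sequence: str
    spumi_start: int
    spumi_length: int
    upstream_anchor: str
    downstream_anchor: str
    barcode_locus: Optional[int] = None
    barcodes: Optional[tuple[str, ...]] = None
    length_nt: int = 0
    gc_percent: float = 0.0

    def __post_init__(self) -> None:
        if self.spumi_length <= 0:
            raise ValueError(f"spike {self.name}: spumi_length must be positive")
        if self.spumi_start + self.spumi_length > len(self.sequence):
            raise ValueError(f"spike {self.name}: spUMI locus extends past sequence end")
        if self.barcodes is not None:
            bcs = list(self.barcodes)
            if len(set(bcs)) != len(bcs):
                raise ValueError(f"spike {self.name}: duplicate expression barcodes")
            for i, a in enumerate(bcs):
                for b in bcs[i + 1 :]:
                    if sum(x != y for x, y in zip(a, b)) < 3:
                        raise ValueError(
                            f"spike {self.name}: barcodes {a}/{b} closer than Hamming 3"
                        )
        if not self.length_nt:
            object.__setattr__(self, "length_nt", len(self.sequence))
        if not self.gc_percent:
            object.__setattr__(self, "gc_percent", 100.0 * gc_fraction(self.sequence))

    @property
    def upstream_anchor_start(self) -> int:
        return self.spumi_start - len(self.upstream_anchor)

    @property
    def downstream_anchor_start(self) -> int:
        return self.spumi_start + self.spumi_length


@dataclass(frozen=True)
class TaggedRead:
    """One aligned read with its cell barcode and library-UMI tags.

    ``read_sequence`` is expected in reference orientation (the SAM
    convention); a read supplied with ``strand == '-'`` is reverse-complemented
    by the extraction step before anchor matching.  ``library_umi`` may be
    empty for UMI-free protocols.
    """

    cell_barcode: str
    library_umi: str
    library_umi_qualities: tuple[int, ...]
    read_sequence: str
    reference_name: str
    strand: str = "+"
    reference_start: int = 0
    query_name: str = ""


@dataclass(frozen=True)
class SpikeMoleculeRecord:
    """One validated spUMI observation (or aggregated molecule)."""

    cell_barcode: str
    spike_name: str
    spumi: str
    expression_barcode: Optional[str] = None
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


def load_spike_fasta(path: str | Path) -> dict[str, str]:
    """Read spike sequences from a FASTA file, keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_spike_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def load_structure_table(
    path: str | Path, sequences: dict[str, str]
) -> dict[str, SpikeReference]:
    """Read a spike structure table (TSV) and join it with FASTA sequences.

    Columns: name, spumi_start, spumi_length, upstream_anchor,
    downstream_anchor, and optionally barcode_locus and barcode_file (a text
    file with one 7-nt barcode per line, ranked by expected abundance).
    """
    refs: dict[str, SpikeReference] = {}
    path = Path(path)
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            name = row["name"]
            if name not in sequences:
                raise KeyError(f"structure table names unknown sequence {name!r}")
            barcode_locus = None
            barcodes = None
            if row.get("barcode_locus") not in (None, "", "NA"):
                barcode_locus = int(row["barcode_locus"])
                bc_file = path.parent / row["barcode_file"]
                barcodes = tuple(
                    ln.strip() for ln in open(bc_file) if ln.strip() and not ln.startswith("#")
                )
            refs[name] = SpikeReference(
                name=name,
                sequence=sequences[name],
                spumi_start=int(row["spumi_start"]),
                spumi_length=int(row["spumi_length"]),
                upstream_anchor=row["upstream_anchor"],
                downstream_anchor=row["downstream_anchor"],
                barcode_locus=barcode_locus,
                barcodes=barcodes,
            )
    return refs


def write_structure_table(
    path: str | Path, refs: list[SpikeReference], barcode_file: Optional[str] = None
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "name\tspumi_start\tspumi_length\tupstream_anchor\tdownstream_anchor"
            "\tbarcode_locus\tbarcode_file\n"
        )
        for r in refs:
            locus = "" if r.barcode_locus is None else str(r.barcode_locus)
            bcf = barcode_file or ""
            fh.write(
                f"{r.name}\t{r.spumi_start}\t{r.spumi_length}\t{r.upstream_anchor}"
                f"\t{r.downstream_anchor}\t{locus}\t{bcf if locus else ''}\n"
            )
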