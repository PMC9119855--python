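"""Extraction of validated spUMI records from tagged alignments.

Reads aligned to spike references are first passed through a library-UMI
base-quality filter, then the spUMI is located by matching the known anchor
sequences flanking its locus.  The simple (18N) design uses a sliding-window
Hamming search for both anchors; the complex design validates the 7-nt
expression barcode (Hamming <= 1, unique best hit), the presence of a 14-nt
spUMI and the 25-nt constant region downstream (Hamming <= 3).  Substitutions
only: a read whose indel changes the spUMI length is rejected, mirroring the
strict length requirement of the designs.  Every rejection carries exactly one
reason code and is tallied, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam

from .reference import (
    SpikeMoleculeRecord,
    SpikeReference,
    TaggedRead,
    reverse_complement,
)


class MalformedRecordError(ValueError):
    """A read whose UMI and quality string disagree in length."""


@dataclass(frozen=True)
class Rejection:
    """Why a read failed spUMI validation (one reason code per read)."""

    reason: str
    detail: str = ""


def filter_umi_quality(
    reads: Iterable[TaggedRead], phred_min: int = 20, max_low_bases: int = 3
) -> list[TaggedRead]:
    """Keep reads whose library UMI has <= ``max_low_bases`` bases below ``phred_min``.

    The threshold is strict: a UMI with exactly ``max_low_bases`` low-quality
    bases is retained.  Reads without a library UMI pass unchanged.  Order is
    preserved and the filter is idempotent.
    """
    kept = []
    for read in reads:
        if read.library_umi:
            quals = read.library_umi_qualities
            if len(quals) != len(read.library_umi):
                raise MalformedRecordError(
                    f"read {read.query_name or read.cell_barcode!r}: UMI length "
                    f"{len(read.library_umi)} != quality length {len(quals)}"
                )
            low = sum(1 for q in quals if q < phred_min)
            if low > max_low_bases:
                continue
        kept.append(read)
    return kept


def _best_anchor_position(
    seq: str, anchor: str, expected: int, window: int, max_mismatch: int
) -> Optional[int]:
    """Best sliding-window Hamming match of ``anchor`` near ``expected``.

    Scans expected +/- window; returns the start of the match with the fewest
    mismatches (<= max_mismatch), ties broken by proximity to the expected
    offset.  None if no position qualifies.
    """
    best: Optional[tuple[int, int, int]] = None  # (mismatches, |offset|, start)
    k = len(anchor)
    for delta in range(-window, window + 1):
        start = expected + delta
        if start < 0 or start + k > len(seq):
            continue
        mm = sum(a != b for a, b in zip(seq[start : start + k], anchor))
        if mm > max_mismatch:
            continue
        key = (mm, abs(delta), start)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def _oriented_sequence(read: TaggedRead) -> str:
    seq = read.read_sequence.upper()
    return reverse_complement(seq) if read.strand == "-" else seq


def extract_spumi(
    read: TaggedRead,
    ref: SpikeReference,
    max_anchor_mismatch: int = 2,
    search_window: int = 5,
) -> SpikeMoleculeRecord | Rejection:
    """Extract the spUMI of a simple-design spike read by anchor matching.

    Both anchors are located by best sliding-window Hamming match within
    ``search_window`` positions of the offset expected from the alignment
    coordinate; the substring between them is accepted as the spUMI only if
    its length equals the reference's spUMI length exactly.
    """
    seq = _oriented_sequence(read)
    expected_up = ref.upstream_anchor_start - read.reference_start
    up = _best_anchor_position(
        seq, ref.upstream_anchor, expected_up, search_window, max_anchor_mismatch
    )
    if up is None:
        return Rejection("anchor", "upstream anchor not found within mismatch budget")
    up_end = up + len(ref.upstream_anchor)
    down = _best_anchor_position(
        seq,
        ref.downstream_anchor,
        up_end + ref.spumi_length,
        search_window,
        max_anchor_mismatch,
    )
    if down is None:
        return Rejection("anchor", "downstream anchor not found within mismatch budget")
    spumi = seq[up_end:down]
    if len(spumi) != ref.spumi_length:
        return Rejection("length", f"spUMI length {len(spumi)} != {ref.spumi_length}")
    return SpikeMoleculeRecord(
        cell_barcode=read.cell_barcode, spike_name=ref.name, spumi=spumi
    )


def extract_complex_record(
    read: TaggedRead,
    ref: SpikeReference,
    max_barcode_mismatch: int = 1,
    max_constant_mismatch: int = 3,
) -> SpikeMoleculeRecord | Rejection:
    """Validate a complex-set read: barcode, 14-nt spUMI and constant region.

    Acceptance requires (1) the 7-nt expression barcode to match one known
    barcode within Hamming distance ``max_barcode_mismatch`` with a unique
    best hit, (2) a full-length spUMI between barcode and constant region and
    (3) the downstream constant region to match within
    ``max_constant_mismatch``.  The matched (not the observed) barcode is
    assigned to the record.
    """
    if ref.barcode_locus is None or not ref.barcodes:
        raise ValueError(f"spike {ref.name} carries no expression barcode set")
    seq = _oriented_sequence(read)
    bc_len = len(ref.barcodes[0])
    bc_start = ref.barcode_locus - read.reference_start
    if bc_start < 0 or bc_start + bc_len > len(seq):
        return Rejection("truncated", "read does not cover the barcode locus")
    observed_bc = seq[bc_start : bc_start + bc_len]
    dists = [sum(a != b for a, b in zip(observed_bc, bc)) for bc in ref.barcodes]
    best = min(dists)
    if best > max_barcode_mismatch:
        return Rejection("barcode", f"nearest barcode at Hamming {best}")
    if dists.count(best) > 1:
        return Rejection("ambiguous-barcode", f"{dists.count(best)} barcodes at Hamming {best}")
    matched_bc = ref.barcodes[dists.index(best)]
    spumi_start = bc_start + bc_len
    spumi = seq[spumi_start : spumi_start + ref.spumi_length]
    if len(spumi) < ref.spumi_length:
        return Rejection("length", "read truncated inside the spUMI")
    const = ref.downstream_anchor
    const_start = spumi_start + ref.spumi_length
    observed_const = seq[const_start : const_start + len(const)]
    if len(observed_const) < len(const):
        return Rejection("truncated", "read does not cover the constant region")
    mm = sum(a != b for a, b in zip(observed_const, const))
    if mm > max_constant_mismatch:
        return Rejection("constant", f"constant region at Hamming {mm}")
    return SpikeMoleculeRecord(
        cell_barcode=read.cell_barcode,
        spike_name=ref.name,
        spumi=spumi,
        expression_barcode=matched_bc,
    )


def aggregate_records(records: Iterable[SpikeMoleculeRecord]) -> pd.DataFrame:
    """Aggregate validated records into a per-cell (spike, barcode, spUMI) table.

    The ``read_count`` of each row equals the number of input records with the
    identical key; the column sum equals the number of input records.
    """
    rows = [
        {
            "cell_barcode": r.cell_barcode,
            "spike": r.spike_name,
            "barcode": r.expression_barcode or "",
            "spumi": r.spumi,
            "read_count": r.read_count,
        }
        for r in records
    ]
    if not rows:
        return pd.DataFrame(
            columns=["cell_barcode", "spike", "barcode", "spumi", "read_count"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["cell_barcode", "spike", "barcode", "spumi"], sort=True)["read_count"]
        .sum()
        .reset_index()
    )


def load_tagged_reads(
    path: str | Path,
    cell_tag: str = "BC",
    umi_tag: str = "UB",
    umi_quality_tag: str = "UY",
) -> Iterator[TaggedRead]:
    """Stream tagged reads from a SAM/BAM file via pysam.

    SAM stores SEQ in reference orientation, so no re-orientation is needed
    downstream.  UMI base qualities are taken from ``umi_quality_tag`` when
    present, else assumed high (Phred 37).
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            umi = aln.get_tag(umi_tag) if aln.has_tag(umi_tag) else ""
            if aln.has_tag(umi_quality_tag):
                quals = tuple(ord(c) - 33 for c in aln.get_tag(umi_quality_tag))
            else:
                quals = tuple([37] * len(umi))
            yield TaggedRead(
                cell_barcode=aln.get_tag(cell_tag) if aln.has_tag(cell_tag) else "",
                library_umi=umi,
                library_umi_qualities=quals,
                read_sequence=aln.query_sequence or "",
                reference_name=aln.reference_name or "",
                strand="+",  # SEQ is already reference-oriented in SAM
                reference_start=aln.reference_start,
                query_name=aln.query_name or "",
            )


def extract_from_alignments(
    reads: Iterable[TaggedRead],
    references: dict[str, SpikeReference],
    phred_min: int = 20,
    max_low_bases: int = 3,
    max_anchor_mismatch: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run quality filtering and spUMI extraction over a read stream.

    Returns the aggregated record table, a rejection summary (reason, count)
    and a read-level table (one row per validated read, retaining the
    library UMI so molecules can later be paired with their sequencing
    reads).  |validated| <= |reads|, and every read is either validated or
    assigned exactly one reason code.
    """
    tallies: dict[str, int] = {}
    records: list[SpikeMoleculeRecord] = []
    read_rows: list[dict] = []
    for read in reads:
        ref = references.get(read.reference_name)
        if ref is None:
            tallies["off-target"] = tallies.get("off-target", 0) + 1
            continue
        if not filter_umi_quality([read], phred_min, max_low_bases):
            tallies["low-quality-umi"] = tallies.get("low-quality-umi", 0) + 1
            continue
        if ref.barcodes:
            outcome = extract_complex_record(read, ref)
        else:
            outcome = extract_spumi(read, ref, max_anchor_mismatch)
        if isinstance(outcome, Rejection):
            tallies[outcome.reason] = tallies.get(outcome.reason, 0) + 1
        else:
            records.append(outcome)
            read_rows.append(
                {
                    "cell_barcode": outcome.cell_barcode,
                    "spike": outcome.spike_name,
                    "barcode": outcome.expression_barcode or "",
                    "spumi": outcome.spumi,
                    "library_umi": read.library_umi,
                }
            )
    summary = pd.DataFrame(sorted(tallies.items()), columns=["reason", "count"])
    read_level = pd.DataFrame(
        read_rows,
        columns=["cell_barcode", "spike", "barcode", "spumi", "library_umi"],
    )
    return aggregate_records(records), summary, read_level
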