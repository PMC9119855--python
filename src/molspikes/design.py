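"""Design of new molecular-spike sequences and expression-barcode sets.

Spike sequence candidates are random sequences constrained to a target GC
content (within 1%), free of homopolymer runs longer than four bases and
ranked by the smoothness of their local GC profile.  Expression barcodes are
7-mers chosen greedily so that every pair is separated by Hamming distance
>= 3 (allowing single-error correction during extraction), with homopolymer
runs capped at three bases and near-self-complementary sequences excluded;
the final set is ranked by closeness to 50% GC.  A complex set pairs each of
11 sequences with 24 barcodes arranged as a twofold titration over 12
expression levels in duplicate, yielding 264 distinct spike species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .collapse import encode_umis, packed_hamming
from .reference import gc_fraction, reverse_complement

_BASES = "ACGT"
_RUN5_RE = re.compile(r"A{5,}|C{5,}|G{5,}|T{5,}")
_RUN4_RE = re.compile(r"A{4,}|C{4,}|G{4,}|T{4,}")


@dataclass
class DesignSpec:
    """Parameters of a complex spike-set design."""

    lengths: tuple[int, ...] = (500, 1000, 2000, 3000)
    gc_targets: tuple[float, ...] = (0.40, 0.50, 0.60)
    gc_tolerance: float = 0.01
    max_homopolymer_seq: int = 4
    barcode_length: int = 7
    barcode_min_hd: int = 3
    barcode_max_homopolymer: int = 3
    titration_levels: int = 12
    replicates_per_level: int = 2
    seed: int = 0

    @property
    def barcodes_per_sequence(self) -> int:
        return self.titration_levels * self.replicates_per_level


@dataclass
class BarcodeSet:
    """An ordered set of expression barcodes with titration-level assignment."""

    barcodes: list[str]
    level_assignment: dict[str, tuple[int, int]] = field(default_factory=dict)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def generate_candidate_sequences(
    n: int, length: int, gc: float, rng: np.random.Generator, max_attempts: int = 10_000_000
) -> list[str]:
    """Random sequences of a given length and GC content.

    Bases are drawn with probabilities matching the target GC; candidates
    with homopolymer runs longer than four bases or with realised GC content
    more than 1% from the target are discarded and redrawn.
    """
    if length < 100:
        raise ValueError("sequence length must be >= 100")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    out: list[str] = []
    attempts = 0
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        seq = "".join(rng.choice(list(_BASES), size=length, p=probs))
        if _RUN5_RE.search(seq):
            continue
        if abs(gc_fraction(seq) - gc) > 0.01:
            continue
        out.append(seq)
    if len(out) < n:
        raise RuntimeError(f"only {len(out)}/{n} candidates found in {attempts} attempts")
    return out


def rank_by_local_gc(sequences: Sequence[str], window: int = 100) -> list[str]:
    """Rank sequences by least local GC variation (ascending sd of windowed GC).

    The window slides with stride 1; the rank key is the standard deviation
    of the per-window GC fractions.  Stable, so the ranking is invariant to
    the input ordering up to exact ties.
    """
    keyed = []
    for seq in sequences:
        if window >= len(seq):
            raise ValueError("window must be smaller than the sequence length")
        is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
        cum = np.concatenate([[0.0], np.cumsum(is_gc)])
        win_gc = (cum[window:] - cum[:-window]) / window
        keyed.append((float(np.std(win_gc)), seq))
    keyed.sort(key=lambda t: t[0])
    return [seq for _, seq in keyed]


def _is_near_self_complementary(seq: str) -> bool:
    # odd-length sequences can never equal their reverse complement exactly;
    # reject those within Hamming distance 1 of it
    rc = reverse_complement(seq)
    return sum(a != b for a, b in zip(seq, rc)) <= 1


def design_barcodes(
    n: Optional[int] = None,
    length: int = 7,
    min_hd: int = 3,
    max_homopolymer: int = 3,
    seed: Optional[int] = None,
) -> list[str]:
    """Greedy construction of a Hamming-separated expression-barcode set.

    Walks the full barcode space (lexicographically, or shuffled when a seed
    is given) and accepts a candidate iff it has no homopolymer run longer
    than ``max_homopolymer``, is not near-self-complementary, and is at
    Hamming distance >= ``min_hd`` from every accepted barcode.  The
    accepted set is then sorted by deviation from 50% GC (stable) and, when
    ``n`` is given, truncated to that size.
    """
    candidates = ["".join(p) for p in product(_BASES, repeat=length)]
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(candidates))
        candidates = [candidates[i] for i in order]
    accepted: list[str] = []
    accepted_codes = np.empty(0, dtype=np.uint64)
    for cand in candidates:
        if max_homopolymer_run(cand) > max_homopolymer:
            continue
        if _is_near_self_complementary(cand):
            continue
        code = encode_umis([cand])
        if len(accepted_codes) and int(
            packed_hamming(np.full(len(accepted_codes), code[0], dtype=np.uint64),
                           accepted_codes, length).min()
        ) < min_hd:
            continue
        accepted.append(cand)
        accepted_codes = np.append(accepted_codes, code)
    accepted.sort(key=lambda bc: abs(gc_fraction(bc) - 0.5))
    if n is not None:
        if len(accepted) < n:
            raise RuntimeError(
                f"could only construct {len(accepted)} barcodes (requested {n})"
            )
        accepted = accepted[:n]
    return accepted


def assign_titration_levels(
    barcodes: Sequence[str], levels: int = 12, replicates: int = 2
) -> BarcodeSet:
    """Assign barcodes to a twofold titration series (level k, replicate r)."""
    if len(barcodes) != levels * replicates:
        raise ValueError(f"need exactly {levels * replicates} barcodes")
    assignment = {
        bc: (i // replicates + 1, i % replicates + 1) for i, bc in enumerate(barcodes)
    }
    return BarcodeSet(barcodes=list(barcodes), level_assignment=assignment)


def assemble_complex_set(
    sequences: dict[str, str],
    barcode_sets: dict[str, BarcodeSet],
    base_abundance: float = 1.0,
) -> pd.DataFrame:
    """Combine designed sequences and barcode sets into a spike-set manifest.

    One species per (sequence, barcode); intended molar abundance of level k
    is 2**(k-1) x ``base_abundance``.  The canonical complex set is 11
    sequences x 24 barcodes = 264 species over 12 twofold levels.
    """
    rows = []
    for name in sequences:
        bset = barcode_sets[name]
        if len(set(bset.barcodes)) != len(bset.barcodes):
            raise ValueError(f"duplicate barcode within sequence {name}")
        for bc in bset.barcodes:
            level, replicate = bset.level_assignment[bc]
            rows.append(
                {
                    "name": f"{name}_L{level:02d}R{replicate}",
                    "sequence_id": name,
                    "barcode": bc,
                    "level": level,
                    "replicate": replicate,
                    "relative_abundance": base_abundance * 2 ** (level - 1),
                }
            )
    manifest = pd.DataFrame(rows)
    if manifest.duplicated(["sequence_id", "barcode"]).any():
        raise ValueError("duplicate (sequence, barcode) species in manifest")
    return manifest


def kmer_uniqueness_screen(
    sequence: str, host_kmers: set[str], k: int = 50
) -> bool:
    """Exact k-mer screen against a host k-mer set (both strands).

    Returns True (pass) iff no k-mer of the sequence or of its reverse
    complement occurs in ``host_kmers``.  The k of 50 mirrors typical short
    sequencing read lengths.
    """
    if not host_kmers:
        return True
    for strand in (sequence, reverse_complement(sequence)):
        for i in range(len(strand) - k + 1):
            if strand[i : i + k] in host_kmers:
                return False
    return True
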