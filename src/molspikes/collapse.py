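"""UMI error-correction: Hamming distances and the four network collapse algorithms.

PCR and sequencing introduce substitutions into UMI sequences, so the number
of distinct UMIs observed for a feature overestimates the number of molecules.
The network-based corrections implemented here repeatedly pick the most
abundant unassigned UMI as a representative and absorb its close neighbours:

* ``adjacency`` absorbs every unassigned UMI within Hamming distance ``d``;
* ``directional`` absorbs a neighbour only if it has strictly fewer than half
  the representative's reads;
* ``singleton`` absorbs a neighbour only if it was seen by exactly one read;
* ``cluster`` additionally follows chains of distance-``d`` links with
  non-increasing abundance, so a UMI two errors away can still be absorbed
  through an intermediate single-error UMI.

Ties in abundance are broken lexicographically (smallest UMI wins), and the
"most abundant" ordering always uses the original, pre-aggregation counts.
A brute-force oracle (:func:`collapse_oracle`) re-derives each algorithm by
explicit network enumeration and exists only to cross-check the
implementations in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd

ALGORITHMS = ("adjacency", "directional", "singleton", "cluster")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"hamming_distance requires equal lengths ({len(a)} != {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def umi_space(length: int) -> int:
    """Coding capacity of a UMI of the given length (4**length sequences)."""
    return 4 ** length


@dataclass
class CollapseResult:
    """Outcome of a UMI collapse.

    ``surviving`` maps each representative UMI to its aggregated read count;
    ``parent_of`` maps every input UMI to its representative (representatives
    map to themselves).  Total reads are conserved exactly.
    """

    surviving: Dict[str, int]
    parent_of: Dict[str, str]

    @property
    def n_molecules(self) -> int:
        return len(self.surviving)


def encode_umis(umis: Iterable[str]) -> np.ndarray:
    """Pack UMI strings into 2-bit-per-base uint64 codes (length <= 31)."""
    out = []
    for u in umis:
        code = 0
        for ch in u:
            code = (code << 2) | _BASE_CODE[ch]
        out.append(code)
    return np.asarray(out, dtype=np.uint64)


def _pair_symbol_mask(length: int) -> np.uint64:
    # one low bit per 2-bit symbol: 0b0101...01
    m = 0
    for _ in range(length):
        m = (m << 2) | 1
    return np.uint64(m)


def packed_hamming(codes_a: np.ndarray, codes_b: np.ndarray, length: int) -> np.ndarray:
    """Vectorised Hamming distance between arrays of packed codes."""
    x = np.bitwise_xor(codes_a, codes_b)
    sym = np.bitwise_or(x, np.right_shift(x, np.uint64(1))) & _pair_symbol_mask(length)
    return np.bitwise_count(sym)


def neighbor_pairs(codes: np.ndarray, length: int, d: int) -> list[tuple[int, int]]:
    """Indices of all pairs of distinct codes at Hamming distance <= d.

    Uses the position-mask partition: two length-L sequences are within
    Hamming distance d iff they agree outside some subset of d positions, so
    bucketing by every masked pattern over the C(L, d) subsets enumerates
    exactly the qualifying pairs.  Runs in O(C(L, d) * n log n).
    """
    n = len(codes)
    if n < 2 or d <= 0:
        return []
    if d >= length:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs: set[tuple[int, int]] = set()
    for subset in combinations(range(length), d):
        mask = np.uint64(0xFFFFFFFFFFFFFFFF)
        for pos in subset:
            shift = np.uint64(2 * (length - 1 - pos))
            mask &= ~(np.uint64(3) << shift)
        masked = codes & mask
        order = np.argsort(masked, kind="stable")
        sm = masked[order]
        boundaries = np.flatnonzero(sm[1:] != sm[:-1]) + 1
        start = 0
        for stop in list(boundaries) + [n]:
            if stop - start > 1:
                bucket = sorted(order[start:stop])
                for i, a in enumerate(bucket):
                    for b in bucket[i + 1 :]:
                        pairs.add((a, b))
            start = stop
    return sorted(pairs)


def _neighbor_map(umis: list[str], d: int) -> dict[str, list[str]]:
    length = len(umis[0])
    for u in umis:
        if len(u) != length:
            raise ValueError("all UMIs in a count map must have the same length")
    codes = encode_umis(umis)
    nbrs: dict[str, list[str]] = {u: [] for u in umis}
    for i, j in neighbor_pairs(codes, length, d):
        nbrs[umis[i]].append(umis[j])
        nbrs[umis[j]].append(umis[i])
    return nbrs


def _greedy_collapse(umis: Mapping[str, int], d: int, mode: str) -> CollapseResult:
    if mode not in ALGORITHMS:
        raise ValueError(f"unknown collapse mode {mode!r}")
    if not umis:
        return CollapseResult({}, {})
    for u, c in umis.items():
        if c < 1:
            raise ValueError(f"UMI {u} has non-positive count {c}")
    order = sorted(umis, key=lambda u: (-umis[u], u))
    if d <= 0:
        return CollapseResult(dict(umis), {u: u for u in umis})
    nbrs = _neighbor_map(order, d)
    parent: dict[str, str] = {}
    for rep in order:
        if rep in parent:
            continue
        parent[rep] = rep
        if mode == "cluster":
            # breadth-first through chains with non-increasing abundance
            frontier = [rep]
            while frontier:
                v = frontier.pop()
                for u in nbrs[v]:
                    if u not in parent and umis[u] <= umis[v]:
                        parent[u] = rep
                        frontier.append(u)
        else:
            for u in sorted(nbrs[rep]):
                if u in parent:
                    continue
                if mode == "adjacency":
                    absorb = True
                elif mode == "directional":
                    absorb = umis[u] < 0.5 * umis[rep]
                else:  # singleton
                    absorb = umis[u] == 1
                if absorb:
                    parent[u] = rep
    surviving: dict[str, int] = {}
    for u, rep in parent.items():
        surviving[rep] = surviving.get(rep, 0) + umis[u]
    return CollapseResult(surviving, parent)


def collapse_adjacency(umis: Mapping[str, int], d: int) -> CollapseResult:
    """Collapse all UMIs within Hamming distance ``d`` of each representative."""
    return _greedy_collapse(umis, d, "adjacency")


def collapse_directional(umis: Mapping[str, int], d: int) -> CollapseResult:
    """Adjacency, but absorb only neighbours with < 0.5x the representative's reads."""
    return _greedy_collapse(umis, d, "directional")


def collapse_singleton(umis: Mapping[str, int], d: int) -> CollapseResult:
    """Adjacency, but absorb only neighbours observed by exactly one read."""
    return _greedy_collapse(umis, d, "singleton")


def collapse_cluster(umis: Mapping[str, int], d: int) -> CollapseResult:
    """Transitive collapse through chains of distance-``d`` links."""
    return _greedy_collapse(umis, d, "cluster")


def collapse(umis: Mapping[str, int], d: int, mode: str) -> CollapseResult:
    """Dispatch to one of the four collapse algorithms by name."""
    return _greedy_collapse(umis, d, mode)


def collapse_oracle(umis: Mapping[str, int], d: int, mode: str) -> CollapseResult:
    """Naive re-derivation of each algorithm by explicit network enumeration.

    Independent of the production code path (full pairwise distance matrix via
    networkx, recursive absorption); guarded to <= 15 distinct UMIs.  Test
    support only.
    """
    import networkx as nx

    if len(umis) > 15:
        raise ValueError("collapse_oracle refuses more than 15 distinct UMIs")
    if mode not in ALGORITHMS:
        raise ValueError(f"unknown collapse mode {mode!r}")
    if not umis:
        return CollapseResult({}, {})
    nodes = list(umis)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a in nodes:
        for b in nodes:
            if a < b and sum(x != y for x, y in zip(a, b)) <= d and a != b and d > 0:
                g.add_edge(a, b)
    unassigned = set(nodes)
    parent: dict[str, str] = {}

    def rank(u: str):
        return (-umis[u], u)

    while unassigned:
        rep = min(unassigned, key=rank)
        unassigned.discard(rep)
        parent[rep] = rep

        def absorb_from(v: str) -> None:
            for u in sorted(g.neighbors(v)):
                if u not in unassigned:
                    continue
                if mode == "adjacency":
                    ok = True
                elif mode == "directional":
                    ok = umis[u] < 0.5 * umis[rep]
                elif mode == "singleton":
                    ok = umis[u] == 1
                else:  # cluster
                    ok = umis[u] <= umis[v]
                if ok:
                    unassigned.discard(u)
                    parent[u] = rep
                    if mode == "cluster":
                        absorb_from(u)

        absorb_from(rep)
    surviving: dict[str, int] = {}
    for u, rep in parent.items():
        surviving[rep] = surviving.get(rep, 0) + umis[u]
    return CollapseResult(surviving, parent)


def trim_umi(umis: Mapping[str, int], new_length: int) -> dict[str, int]:
    """Keep the first ``new_length`` (5') bases; merge counts of collided UMIs."""
    if not umis:
        return {}
    length = len(next(iter(umis)))
    if not 1 <= new_length <= length:
        raise ValueError(f"new_length must be in [1, {length}]")
    out: dict[str, int] = {}
    for u, c in umis.items():
        key = u[:new_length]
        out[key] = out.get(key, 0) + c
    return out


def collapsed_unique_count(codes: np.ndarray, length: int, d: int) -> int:
    """Number of surviving molecules after adjacency collapse of packed codes.

    Fast path used by depth-subsampling loops: ``codes`` is a per-read array
    of packed spUMI codes; duplicates are aggregated, the distance-<=d graph
    is built by the position-mask partition, and only nodes with neighbours
    enter the greedy loop (isolated nodes survive unconditionally).
    """
    if len(codes) == 0:
        return 0
    uniq, counts = np.unique(codes, return_counts=True)
    if d <= 0:
        return len(uniq)
    pairs = neighbor_pairs(uniq, length, d)
    if not pairs:
        return len(uniq)
    involved = sorted({i for p in pairs for i in p})
    nbrs: dict[int, list[int]] = {i: [] for i in involved}
    for i, j in pairs:
        nbrs[i].append(j)
        nbrs[j].append(i)
    order = sorted(involved, key=lambda i: (-counts[i], uniq[i]))
    assigned: set[int] = set()
    survivors = len(uniq) - len(involved)
    for rep in order:
        if rep in assigned:
            continue
        assigned.add(rep)
        survivors += 1
        for u in nbrs[rep]:
            assigned.add(u)
    return survivors


def correct_spumis(
    records: pd.DataFrame, d: int = 2, return_table: bool = False
) -> pd.DataFrame:
    """Adjacency-correct spUMIs within each cell barcode (and spike/barcode).

    ``records`` is a table with columns ``cell_barcode``, ``spumi``,
    ``read_count`` and optionally ``spike`` and ``barcode``; correction runs
    independently within each (cell, spike, barcode) group.

    Returns per-group unique molecule counts (column ``molecules``), or with
    ``return_table=True`` the corrected molecule table in which each surviving
    representative carries the aggregated read count of its error cloud.
    """
    group_cols = ["cell_barcode"] + [c for c in ("spike", "barcode") if c in records.columns]
    counts_rows = []
    table_rows = []
    if records.empty:
        cols = group_cols + (["spumi", "read_count"] if return_table else ["molecules"])
        return pd.DataFrame(columns=cols)
    for keys, grp in records.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        umis = grp.groupby("spumi")["read_count"].sum().to_dict()
        result = collapse_adjacency(umis, d)
        counts_rows.append(dict(zip(group_cols, keys), molecules=result.n_molecules))
        if return_table:
            for rep, cnt in sorted(result.surviving.items()):
                table_rows.append(dict(zip(group_cols, keys), spumi=rep, read_count=cnt))
    if return_table:
        return pd.DataFrame(table_rows)
    return pd.DataFrame(counts_rows)
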