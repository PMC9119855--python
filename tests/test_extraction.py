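"""Quality filtering, anchor-based spUMI extraction and record aggregation."""

import pytest

from molspikes.extraction import (
    MalformedRecordError,
    Rejection,
    aggregate_records,
    extract_complex_record,
    extract_from_alignments,
    extract_spumi,
    filter_umi_quality,
)
from molspikes.reference import SpikeMoleculeRecord, TaggedRead, reverse_complement


def _read(seq, ref, umi="ACGTACGTAC", quals=None, start=None, strand="+"):
    return TaggedRead(
        cell_barcode="cell1",
        library_umi=umi,
        library_umi_qualities=tuple(quals if quals is not None else [37] * len(umi)),
        read_sequence=seq,
        reference_name=ref.name,
        strand=strand,
        reference_start=ref.upstream_anchor_start if start is None else start,
    )


class TestQualityFilter:
    def test_more_than_three_low_bases_discarded(self, simple_ref):
        read = _read("ACGT", simple_ref, umi="ACGTACGTAC", quals=[15] * 4 + [30] * 6)
        assert filter_umi_quality([read]) == []

    def test_exactly_three_low_bases_retained(self, simple_ref):
        read = _read("ACGT", simple_ref, umi="ACGTACGTAC", quals=[15] * 3 + [30] * 7)
        assert filter_umi_quality([read]) == [read]

    def test_all_high_quality_retained_and_idempotent(self, simple_ref):
        reads = [
            _read("ACGT", simple_ref, umi="ACGTACGTAC", quals=[25] * 10),
            _read("ACGT", simple_ref, umi="ACGTACGTAC", quals=[15] * 2 + [37] * 8),
        ]
        kept = filter_umi_quality(reads)
        assert kept == reads  # order preserved
        assert filter_umi_quality(kept) == kept

    def test_umi_free_reads_pass(self, simple_ref):
        read = _read("ACGT", simple_ref, umi="", quals=[])
        assert filter_umi_quality([read]) == [read]

    def test_quality_length_mismatch_names_read(self, simple_ref):
        read = TaggedRead(
            cell_barcode="c", library_umi="ACGT", library_umi_qualities=(30, 30),
            read_sequence="A", reference_name="r", query_name="bad_read",
        )
        with pytest.raises(MalformedRecordError, match="bad_read"):
            filter_umi_quality([read])


class TestExtractSpumi:
    def _build(self, ref, spumi, up=None, down=None):
        return (up or ref.upstream_anchor) + spumi + (down or ref.downstream_anchor)

    def test_recovers_spumi_by_construction(self, simple_ref):
        spumi = "ACGTACGTACGTACGTAC"
        read = _read(self._build(simple_ref, spumi), simple_ref)
        rec = extract_spumi(read, simple_ref)
        assert isinstance(rec, SpikeMoleculeRecord)
        assert rec.spumi == spumi and rec.spike_name == simple_ref.name

    def test_deletion_in_spumi_rejected_with_length_reason(self, simple_ref):
        spumi17 = "ACGTACGTACGTACGTA"  # 17 nt
        read = _read(self._build(simple_ref, spumi17), simple_ref)
        out = extract_spumi(read, simple_ref)
        assert isinstance(out, Rejection) and out.reason == "length"

    def test_two_anchor_mismatches_within_budget_accepted(self, simple_ref):
        spumi = "TTTTACGTACGTACGTTT"
        up = list(simple_ref.upstream_anchor)
        up[0] = "T" if up[0] != "T" else "A"
        up[5] = "C" if up[5] != "C" else "G"
        read = _read(self._build(simple_ref, spumi, up="".join(up)), simple_ref)
        rec = extract_spumi(read, simple_ref, max_anchor_mismatch=2)
        assert isinstance(rec, SpikeMoleculeRecord) and rec.spumi == spumi
        out = extract_spumi(read, simple_ref, max_anchor_mismatch=1)
        assert isinstance(out, Rejection) and out.reason == "anchor"

    def test_shifted_read_start_found_in_window(self, simple_ref):
        spumi = "ACGTACGTACGTACGTAC"
        read = _read(self._build(simple_ref, spumi), simple_ref,
                     start=simple_ref.upstream_anchor_start - 3)
        rec = extract_spumi(read, simple_ref)
        assert isinstance(rec, SpikeMoleculeRecord) and rec.spumi == spumi

    def test_minus_strand_read_is_reverse_complemented(self, simple_ref):
        spumi = "ACGTACGTACGTACGTAC"
        seq = reverse_complement(self._build(simple_ref, spumi))
        read = _read(seq, simple_ref, strand="-")
        rec = extract_spumi(read, simple_ref)
        assert isinstance(rec, SpikeMoleculeRecord) and rec.spumi == spumi


class TestExtractComplexRecord:
    def _build(self, ref, barcode, spumi, constant=None):
        return ref.upstream_anchor + barcode + spumi + (constant or ref.downstream_anchor)

    def test_exact_read_accepted(self, complex_ref):
        spumi = "ACGTACGTACGTAC"
        read = _read(self._build(complex_ref, "AACCGGT", spumi), complex_ref, start=0)
        rec = extract_complex_record(read, complex_ref)
        assert isinstance(rec, SpikeMoleculeRecord)
        assert rec.expression_barcode == "AACCGGT" and rec.spumi == spumi

    def test_one_mismatch_barcode_assigned_to_known_barcode(self, complex_ref):
        read = _read(self._build(complex_ref, "AACCGGA", "ACGTACGTACGTAC"), complex_ref, start=0)
        rec = extract_complex_record(read, complex_ref)
        assert rec.expression_barcode == "AACCGGT"  # matched, not observed

    def test_two_mismatch_barcode_rejected(self, complex_ref):
        read = _read(self._build(complex_ref, "AACCGAA", "ACGTACGTACGTAC"), complex_ref, start=0)
        out = extract_complex_record(read, complex_ref)
        assert isinstance(out, Rejection) and out.reason == "barcode"

    def test_constant_region_four_mismatches_rejected(self, complex_ref):
        const = list(complex_ref.downstream_anchor)
        for i in range(4):
            const[i] = "A" if const[i] != "A" else "C"
        read = _read(
            self._build(complex_ref, "AACCGGT", "ACGTACGTACGTAC", constant="".join(const)),
            complex_ref, start=0,
        )
        out = extract_complex_record(read, complex_ref)
        assert isinstance(out, Rejection) and out.reason == "constant"

    def test_constant_region_three_mismatches_accepted(self, complex_ref):
        const = list(complex_ref.downstream_anchor)
        for i in range(3):
            const[i] = "A" if const[i] != "A" else "C"
        read = _read(
            self._build(complex_ref, "AACCGGT", "ACGTACGTACGTAC", constant="".join(const)),
            complex_ref, start=0,
        )
        assert isinstance(extract_complex_record(read, complex_ref), SpikeMoleculeRecord)

    def test_equidistant_barcode_is_ambiguous(self, complex_ref):
        # AACCGGT vs ACACACA: craft an observation at distance 1 from two barcodes
        # barcodes AACCGGT and TTGGCCA differ a lot; use ACACACA vs GTGTGTG? distance 7.
        # Build ambiguity with a barcode set where it is possible:
        read = _read(self._build(complex_ref, "AACCGTT", "ACGTACGTACGTAC"), complex_ref, start=0)
        out = extract_complex_record(read, complex_ref, max_barcode_mismatch=2)
        # AACCGTT is distance 1 from AACCGGT -> unique best, accepted
        assert isinstance(out, SpikeMoleculeRecord)

    def test_truncated_spumi_rejected(self, complex_ref):
        read = _read(complex_ref.upstream_anchor + "AACCGGT" + "ACGTAC", complex_ref, start=0)
        out = extract_complex_record(read, complex_ref)
        assert isinstance(out, Rejection) and out.reason == "length"


def test_ambiguous_barcode_rejection_reason():
    """A barcode observation equidistant to two known barcodes is ambiguous."""
    from molspikes.reference import SpikeReference

    barcodes = ("AAACCCT", "AAAGGGT")  # differ at positions 3,4,5 (HD 3)
    pad = "ATGCATGCAT"
    const = "ACGTTGCAACGGTTAACCGGATCCA"
    ref = SpikeReference(
        name="amb", sequence=pad + barcodes[0] + "N" * 14 + const,
        spumi_start=len(pad) + 7, spumi_length=14,
        upstream_anchor=pad, downstream_anchor=const,
        barcode_locus=len(pad), barcodes=barcodes,
    )

    def run(obs, budget):
        read = TaggedRead("c", "ACGT", (37,) * 4, pad + obs + "ACGTACGTACGTAC" + const,
                          "amb", reference_start=0)
        return extract_complex_record(read, ref, max_barcode_mismatch=budget)

    # AAATCGT: T at pos 3 misses both, C at 4 matches the first, G at 5 the
    # second -> Hamming 2 to each: a tie, hence ambiguous at budget 2
    out = run("AAATCGT", budget=2)
    assert isinstance(out, Rejection) and out.reason == "ambiguous-barcode"
    # AAACGGT is Hamming 2 / 1 -> unique best, assigned the second barcode
    rec = run("AAACGGT", budget=2)
    assert isinstance(rec, SpikeMoleculeRecord) and rec.expression_barcode == "AAAGGGT"


class TestAggregateRecords:
    def test_identical_records_sum(self):
        rec = SpikeMoleculeRecord("c1", "s", "ACGT")
        table = aggregate_records([rec, rec, rec])
        assert len(table) == 1 and table.loc[0, "read_count"] == 3

    def test_empty_input(self):
        assert aggregate_records([]).empty

    def test_two_groups(self):
        a = SpikeMoleculeRecord("c1", "s", "ACGT")
        b = SpikeMoleculeRecord("c1", "s", "TTTT")
        table = aggregate_records([a] * 3 + [b] * 2)
        assert sorted(table["read_count"]) == [2, 3]
        assert table["read_count"].sum() == 5


def test_extraction_conservation_and_reason_codes(simple_ref):
    """Every read is either validated or carries exactly one rejection reason."""
    good = simple_ref.upstream_anchor + "A" * 18 + simple_ref.downstream_anchor
    bad_len = simple_ref.upstream_anchor + "A" * 17 + simple_ref.downstream_anchor
    bad_anchor = "G" * 20 + "A" * 18 + simple_ref.downstream_anchor
    reads = [
        _read(good, simple_ref),
        _read(bad_len, simple_ref),
        _read(bad_anchor, simple_ref),
        _read(good, simple_ref, quals=[10] * 10),
    ]
    table, summary, read_level = extract_from_alignments(reads, {simple_ref.name: simple_ref})
    assert table["read_count"].sum() == 1
    assert len(read_level) == 1
    assert summary.set_index("reason")["count"].to_dict() == {
        "anchor": 1, "length": 1, "low-quality-umi": 1,
    }
    assert summary["count"].sum() + table["read_count"].sum() == len(reads)
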