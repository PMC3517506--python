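import numpy as np
import pandas as pd
import pytest

from tetermi.formats_io import DitagRecord, GeneModel, GenomicInterval, TE_FAMILIES
from tetermi.gene_annotation import (
    TTSRecord,
    associate_with_gene,
    classify_location,
    location_table_shares,
    summarize_location_table,
)
from tetermi.tts_discovery import cluster_3prime_ends

# Published location-by-family count grid for PET-characterized human TTS
# (counts as printed; shares in the source are integer-truncated percentages
# of the eight named family counts per row).
PUBLISHED_COUNTS = {
    "five_prime_utr": (3677, 696, [347, 52, 34, 113, 57, 17, 54, 22]),
    "internal": (46716, 6014, [2955, 162, 332, 842, 371, 110, 377, 158]),
    "three_prime_utr": (15491, 867, [267, 25, 69, 120, 60, 29, 101, 43]),
    "annotated": (16031, 1310, [291, 109, 102, 229, 123, 67, 150, 59]),
    "downstream": (2806, 804, [222, 70, 51, 141, 49, 45, 53, 33]),
}
PUBLISHED_SHARES = {
    "five_prime_utr": [49, 7, 4, 16, 8, 2, 7, 3],
    "internal": [55, 3, 6, 15, 6, 2, 7, 2],
    "three_prime_utr": [37, 3, 9, 16, 8, 4, 14, 6],
    "annotated": [25, 9, 9, 20, 10, 5, 13, 5],
    "downstream": [33, 10, 7, 21, 7, 6, 7, 4],
}


def published_counts_frame() -> pd.DataFrame:
    rows = {}
    for loc, (non_te, all_te, fams) in PUBLISHED_COUNTS.items():
        rows[loc] = [non_te, all_te, *fams]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["non_te", "all_te", *TE_FAMILIES]
    )
    df.loc["sum"] = df.sum(axis=0)
    return df


def _cluster_at(base, strand="+", n=5):
    (cl,) = cluster_3prime_ends([("chr1", base, strand)] * n)
    return cl


def _ditag(five, three, strand="+", ct="A"):
    return DitagRecord(("chr1", five, strand), ("chr1", three, strand), ct)


class TestAssociateWithGene:
    def test_promoter_linked_intronic_cluster_assigned(self, plus_gene):
        cl = _cluster_at(4000)
        ditags = [_ditag(plus_gene.annotated_tss, 4000) for _ in range(5)]
        assert associate_with_gene(cl, ditags, [plus_gene]) == "gplus"

    def test_six_kb_downstream_is_too_far(self, plus_gene):
        # annotated TTS at 11,999; 6 kb past it exceeds the 5 kb window
        cl = _cluster_at(plus_gene.annotated_tts + 6000)
        ditags = [_ditag(plus_gene.annotated_tss, plus_gene.annotated_tts + 6000)] * 5
        assert associate_with_gene(cl, ditags, [plus_gene]) is None

    def test_five_kb_downstream_is_accepted(self, plus_gene):
        cl = _cluster_at(plus_gene.annotated_tts + 5000)
        ditags = [_ditag(plus_gene.annotated_tss, plus_gene.annotated_tts + 5000)] * 5
        assert associate_with_gene(cl, ditags, [plus_gene]) == "gplus"

    def test_five_prime_ends_far_from_any_promoter(self, plus_gene):
        cl = _cluster_at(4000)
        ditags = [_ditag(plus_gene.annotated_tss + 10_000, 4000)] * 5
        assert associate_with_gene(cl, ditags, [plus_gene]) is None

    def test_plurality_decides_between_overlapping_genes(self, plus_gene):
        other = GeneModel(
            id="gother",
            locus=GenomicInterval("chr1", 2600, 13000, "+"),
            exon_blocks=((2600, 13000),),
        )
        cl = _cluster_at(8000)
        ditags = [_ditag(plus_gene.annotated_tss, 8000)] * 3 + [
            _ditag(other.annotated_tss, 8000)
        ] * 2
        assert associate_with_gene(cl, ditags, [plus_gene, other]) == "gplus"

    def test_minus_strand_downstream_window(self, minus_gene):
        # annotated TTS at 20,000; downstream means smaller coordinates
        cl = _cluster_at(minus_gene.annotated_tts - 4000, strand="-")
        ditags = [
            _ditag(minus_gene.annotated_tss, minus_gene.annotated_tts - 4000, "-")
        ] * 5
        assert associate_with_gene(cl, ditags, [minus_gene]) == "gminus"


class TestClassifyLocation:
    def test_peak_at_annotated_tts(self, plus_gene):
        assert classify_location(plus_gene.annotated_tts, plus_gene) == "annotated"

    def test_cluster_overlapping_annotated_tts(self, plus_gene):
        iv = GenomicInterval("chr1", plus_gene.annotated_tts - 10, plus_gene.annotated_tts + 1, "+")
        got = classify_location(plus_gene.annotated_tts - 5, plus_gene, cluster_interval=iv)
        assert got == "annotated"

    def test_intron_is_internal(self, plus_gene):
        assert classify_location(4000, plus_gene) == "internal"

    def test_two_kb_past_annotated_tts_is_downstream(self, plus_gene):
        assert classify_location(plus_gene.annotated_tts + 2000, plus_gene) == "downstream"

    def test_utr_classes_respect_cds_bounds(self, plus_gene):
        assert classify_location(2100, plus_gene) == "five_prime_utr"
        assert classify_location(10_000, plus_gene) == "three_prime_utr"
        # exonic but inside the CDS: internal
        assert classify_location(5100, plus_gene) == "internal"

    def test_minus_strand_utrs(self, minus_gene):
        assert classify_location(29_900, minus_gene) == "five_prime_utr"
        assert classify_location(21_000, minus_gene) == "three_prime_utr"
        assert classify_location(minus_gene.annotated_tts - 100, minus_gene) == "downstream"

    def test_gene_without_cds_has_no_utr_classes(self):
        g = GeneModel(
            id="gnc",
            locus=GenomicInterval("chr1", 0, 1000, "+"),
            exon_blocks=((0, 1000),),
        )
        assert classify_location(500, g) == "internal"

    def test_peak_past_downstream_limit_rejected(self, plus_gene):
        with pytest.raises(ValueError):
            classify_location(plus_gene.annotated_tts + 5001, plus_gene)


class TestLocationTable:
    def test_published_family_shares_reproduced_by_truncation(self):
        shares, _ = location_table_shares(published_counts_frame())
        for loc, expected in PUBLISHED_SHARES.items():
            assert list(shares.loc[loc]) == expected, loc
        # the sum row of the published grid is the column sum of the family cells
        assert list(shares.loc["sum"]) == [47, 4, 6, 16, 7, 3, 8, 3]

    def test_published_non_te_alternative_fraction(self):
        _, alt = location_table_shares(published_counts_frame())
        assert int(alt["non_te"] * 100) == 81

    def test_row_shares_sum_to_100_within_truncation_slack(self):
        shares, _ = location_table_shares(published_counts_frame())
        for loc in PUBLISHED_SHARES:
            assert 92 <= shares.loc[loc].sum() <= 100

    def test_single_record_cell(self):
        cl = _cluster_at(100)
        rec = TTSRecord(cluster=cl, gene="g", location_class="internal",
                        te="te1", te_family="Alu")
        counts = summarize_location_table([rec])
        assert counts.loc["internal", "Alu"] == 1
        assert counts.loc["internal", "all_te"] == 1
        shares, _ = location_table_shares(counts)
        assert shares.loc["internal", "Alu"] == 100

    def test_counts_from_records_split_te_and_non_te(self):
        recs = [
            TTSRecord(cluster=_cluster_at(100), gene="g", location_class="annotated"),
            TTSRecord(cluster=_cluster_at(500), gene="g", location_class="internal",
                      te="te1", te_family="L1"),
        ]
        counts = summarize_location_table(recs)
        assert counts.loc["annotated", "non_te"] == 1
        assert counts.loc["internal", "L1"] == 1
        assert counts.loc["sum", "all_te"] == 1
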