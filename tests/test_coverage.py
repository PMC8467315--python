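"""Depth profiles, region means, enrichment folds, read tallies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceoseq import (
    AlignmentRecord,
    LabeledInterval,
    depth_profile,
    enrichment_fold,
    filter_reads,
    genome_mean_depth,
    long_read_tally,
    region_depth_table,
    region_mean_depth,
)


def aln(read_id, start, end, q=20.0, chrom="c"):
    return AlignmentRecord(read_id, chrom, start, end, "+", q)


def test_quality_filter_keeps_boundary():
    records = [aln("a", 0, 10, 6.9), aln("b", 0, 10, 7.0), aln("c", 0, 10, 12.0)]
    kept = filter_reads(records, min_q=7)
    assert [a.read_id for a in kept] == ["b", "c"]


def test_quality_filter_zero_threshold_is_identity():
    records = [aln(str(i), 0, 10, q) for i, q in enumerate((0.0, 3.0, 50.0))]
    assert filter_reads(records, min_q=0) == records


@given(st.lists(st.floats(0, 30, allow_nan=False), max_size=30))
@settings(max_examples=100, derandomize=True)
def test_quality_filter_equals_comprehension(qs):
    records = [aln(str(i), 0, 10, q) for i, q in enumerate(qs)]
    assert filter_reads(records, 7) == [a for a in records if a.mean_q >= 7]


def test_depth_conservation_single_read():
    profile = depth_profile([aln("a", 0, 10)], {"c": 20})
    assert profile["c"].sum() == 10
    assert profile["c"][:10].tolist() == [1] * 10


def test_depth_linearity():
    one = depth_profile([aln("a", 3, 9)], {"c": 20})["c"]
    two = depth_profile([aln("a", 3, 9), aln("b", 3, 9)], {"c": 20})["c"]
    assert (two == 2 * one).all()


def test_depth_matches_naive_counting(rng):
    n = 500
    starts = rng.integers(0, n - 1, size=1000)
    ends = starts + rng.integers(1, 80, size=1000)
    ends = np.minimum(ends, n)
    records = [aln(str(i), int(s), int(e)) for i, (s, e) in enumerate(zip(starts, ends))]
    profile = depth_profile(records, {"c": n})["c"]
    naive = np.zeros(n, dtype=int)
    for s, e in zip(starts, ends):
        naive[s:e] += 1
    assert (profile == naive).all()


def test_depth_out_of_bounds_names_the_read():
    with pytest.raises(ValueError, match="badread"):
        depth_profile([aln("badread", 15, 25)], {"c": 20})


def test_genome_mean_depth_is_total_bases_over_length():
    records = [aln("a", 0, 10), aln("b", 5, 20)]
    profile = depth_profile(records, {"c": 50})
    assert genome_mean_depth(profile) == pytest.approx(25 / 50)


def test_region_mean_uniform_and_half():
    profile = {"c": np.array([5] * 10 + [0] * 10)}
    assert region_mean_depth(profile, LabeledInterval("r", "c", 1, 10)) == 5.0
    assert region_mean_depth(profile, LabeledInterval("r", "c", 1, 20)) == 2.5


def test_region_mean_matches_naive(rng):
    profile = {"c": rng.integers(0, 50, size=300)}
    region = LabeledInterval("r", "c", 40, 160)
    assert region_mean_depth(profile, region) == pytest.approx(profile["c"][39:160].mean())


def test_region_mean_rejects_empty_region():
    with pytest.raises(ValueError):
        region_mean_depth({"c": np.zeros(10)}, LabeledInterval("r", "c", 5, 4))


@pytest.mark.parametrize(
    "depth,genome,expected",
    [(87.07, 38, 2.29), (60.05, 38, 1.58), (80.12, 38, 2.11), (12.3, 12.3, 1.0)],
)
def test_enrichment_fold_published_arithmetic(depth, genome, expected):
    assert enrichment_fold(depth, genome) == expected


def test_enrichment_fold_rejects_nonpositive_genome_depth():
    with pytest.raises(ValueError):
        enrichment_fold(10.0, 0.0)


def test_long_read_tally_boundary_inclusive():
    region = LabeledInterval("t", "c", 1, 100_000)
    records = [
        aln("a", 0, 15_999),
        aln("b", 0, 16_000),
        aln("c", 10, 20_010),
        aln("far", 200, 17_000, chrom="other"),
    ]
    assert long_read_tally(records, region, 16_000) == 2
    assert long_read_tally([], region, 16_000) == 0


def test_long_read_tally_matches_brute_force(rng):
    region = LabeledInterval("t", "c", 1000, 3000)
    records = [
        aln(str(i), int(s), int(s) + int(l))
        for i, (s, l) in enumerate(
            zip(rng.integers(0, 5000, 200), rng.integers(1, 4000, 200))
        )
    ]
    expected = sum(
        1 for a in records if a.start < 3000 and a.end > 999 and a.length >= 1500
    )
    assert long_read_tally(records, region, 1500) == expected


def test_region_depth_table_layout():
    records = [aln("a", 0, 100, 20), aln("b", 0, 50, 3)]
    table = region_depth_table(
        records, [LabeledInterval("roi", "c", 1, 100)], {"c": 200}, min_q=7
    )
    row = table.iloc[0]
    # the q=3 read is filtered: 100 bases over a 200 bp genome
    assert row["average_depth"] == 1.0
    assert row["enrichment_fold"] == 2.0
    assert list(table.columns) == [
        "chromosome", "description", "start", "end", "average_depth", "enrichment_fold",
    ]
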