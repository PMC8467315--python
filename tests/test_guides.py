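"""Guide metrics, PAM scanning, off-target census, region derivation."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceoseq import (
    GuideRecord,
    at_percent,
    count_offtargets,
    define_enrichment_regions,
    gc_percent,
    published_fibh_guides,
    scan_pams,
)
from ceoseq.dna import iupac_to_regex, random_seq, revcomp

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


@pytest.mark.parametrize(
    "protospacer,expected",
    [
        ("TGTTACCGGGGTCTAGTGAC", 55),
        ("AGCTTGTTGTACAAAACTGC", 40),
        ("TATGAACCTATTGTAATTTAG", 24),
        ("TACCCTCATACCTCAAAGAAC", 43),
        ("AAAA", 0),
        ("GCGC", 100),
    ],
)
def test_gc_percent(protospacer, expected):
    assert gc_percent(protospacer) == expected


def test_gc_percent_rejects_non_acgt():
    with pytest.raises(ValueError):
        gc_percent("ACGN")
    with pytest.raises(ValueError):
        gc_percent("")


@given(dna)
@settings(max_examples=200, derandomize=True)
def test_gc_plus_at_is_100(s):
    assert gc_percent(s) + at_percent(s) == 100


def test_published_guides_match_printed_metrics():
    guides = published_fibh_guides()
    assert [g.gc_percent for g in guides] == [55, 40, 24, 43]
    assert [g.size for g in guides] == [20, 20, 21, 21]


def test_guide_record_site_span_covers_pam_plus_protospacer():
    for g in published_fibh_guides():
        assert abs(g.end - g.start) + 1 == g.size + len(g.pam)


def test_guide_record_rejects_bad_pam():
    with pytest.raises(ValueError):
        GuideRecord("x", "GGGG", "ACGTACGTACGTACGTACGT", "+", "c", 1, 24)


def test_scan_pams_single_constructed_site():
    genome = {"c": "AAATTTACCCCCCCCCCCCCCCCCCCCCAAA"}
    hits = [g for g in scan_pams(genome, spacer_len=20) if g.strand == "+"]
    assert len(hits) == 1
    assert hits[0].protospacer == "C" * 20
    assert hits[0].pam == "TTTA"


def test_scan_pams_strand_symmetry():
    fwd = "AAATTTACCCCCCCCCCCCCCCCCCCCCAAA"
    rev_hits = [g for g in scan_pams({"c": revcomp(fwd)}, spacer_len=20) if g.strand == "-"]
    assert len(rev_hits) == 1
    assert rev_hits[0].protospacer == "C" * 20
    # descending coordinates on the reverse strand
    assert rev_hits[0].start > rev_hits[0].end


def test_scan_pams_matches_regex_oracle(rng):
    seq = random_seq(10_000, rng, 0.5)
    n = len(seq)

    def oracle(L=21):
        out = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for m in re.finditer(f"(?=({iupac_to_regex('TTTV')}))", s):
                i = m.start()
                if i + 4 + L <= n:
                    out.add((strand, i, s[i + 4 : i + 4 + L]))
        return out

    got = {
        (g.strand, (g.start - 1) if g.strand == "+" else n - g.start, g.protospacer)
        for g in scan_pams({"x": seq})
    }
    assert got == oracle()


def brute_force_census(guide, genome, max_mm=3):
    counts = [0] * (max_mm + 1)
    pat = re.compile(iupac_to_regex(guide.pam_pattern))
    L, plen = len(guide.protospacer), len(guide.pam_pattern)
    own = (guide.chrom, guide.strand, guide.interval0())
    for chrom, seq in genome.items():
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(n - plen - L + 1):
                if not pat.fullmatch(s[i : i + plen]):
                    continue
                mm = sum(a != b for a, b in zip(s[i + plen : i + plen + L], guide.protospacer))
                if mm > max_mm:
                    continue
                iv = (i, i + plen + L) if strand == "+" else (n - (i + plen + L), n - i)
                if (chrom, strand, iv) == own:
                    continue
                counts[mm] += 1
    return tuple(counts)


def test_unique_guide_has_zero_census(rng):
    # a guide planted once in a random background reports (0, 0, 0, 0)
    proto = random_seq(21, rng, 0.5)
    background = random_seq(4000, rng, 0.5)
    seq = background[:2000] + "TTTA" + proto + background[2000:]
    genome = {"c": seq}
    guide = GuideRecord("g", "TTTA", proto, "+", "c", 2001, 2025)
    assert count_offtargets(guide, genome).as_tuple() == brute_force_census(guide, genome)


def test_planted_mm3_copy_is_counted(rng):
    proto = random_seq(21, rng, 0.5)
    mutated = list(proto)
    for k in (2, 9, 17):  # three protospacer mismatches
        mutated[k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[k]]
    seq = (
        random_seq(1500, rng, 0.5)
        + "TTTA" + proto
        + random_seq(1500, rng, 0.5)
        + "TTTG" + "".join(mutated)
        + random_seq(500, rng, 0.5)
    )
    genome = {"c": seq}
    guide = GuideRecord("g", "TTTA", proto, "+", "c", 1501, 1525)
    census = count_offtargets(guide, genome)
    oracle = brute_force_census(guide, genome)
    assert census.as_tuple() == oracle
    assert census.mm3 >= 1 and census.mm0 == 0


@given(st.integers(0, 10_000))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_offtarget_census_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    genome = {"c": random_seq(3000, rng, float(rng.uniform(0.3, 0.7)))}
    cands = scan_pams(genome, spacer_len=20)
    if not cands:
        return
    guide = cands[int(rng.integers(len(cands)))]
    assert count_offtargets(guide, genome).as_tuple() == brute_force_census(guide, genome)


def test_regions_from_published_guides_match_published_boundaries():
    guides = published_fibh_guides()
    regions = define_enrichment_regions(
        up_pair=[g for g in guides if "up" in g.name],
        down_pair=[g for g in guides if "down" in g.name],
    )
    assert (regions.target.start, regions.target.end) == (10_354_516, 10_372_477)
    assert (regions.upstream.start, regions.upstream.end) == (10_372_477, 10_372_871)
    assert (regions.downstream.start, regions.downstream.end) == (10_353_778, 10_354_516)


def _toy_guide(name, start, strand="+", size=20):
    end = start + size + 3 if strand == "+" else start - size - 3
    proto = "ACGT" * 5
    return GuideRecord(name, "TTTA", proto, strand, "chr", start, end)


def test_regions_toy_layout_spans_inner_boundaries():
    up = [_toy_guide("u1", 1000), _toy_guide("u2", 1500)]
    down = [_toy_guide("d1", 5000), _toy_guide("d2", 5400)]
    r = define_enrichment_regions(up, down)
    assert (r.target.start, r.target.end) == (1500, 5000)
    assert (r.upstream.start, r.upstream.end) == (1000, 1500)
    assert (r.downstream.start, r.downstream.end) == (5000, 5400)


@given(st.lists(st.integers(100, 10_000), min_size=4, max_size=4, unique=True))
@settings(max_examples=100, derandomize=True)
def test_regions_tile_without_gaps(starts):
    starts = sorted(starts)
    if starts[1] + 23 >= starts[2]:  # pairs must not interleave
        return
    up = [_toy_guide("u1", starts[0]), _toy_guide("u2", starts[1])]
    down = [_toy_guide("d1", starts[2]), _toy_guide("d2", starts[3])]
    r = define_enrichment_regions(up, down)
    ordered = sorted((r.downstream, r.target, r.upstream), key=lambda x: x.start)
    assert ordered[0].end == ordered[1].start
    assert ordered[1].end == ordered[2].start


def test_regions_reject_mixed_chromosomes():
    up = [_toy_guide("u1", 1000), _toy_guide("u2", 1500)]
    bad = GuideRecord("d1", "TTTA", "ACGT" * 5, "+", "other", 5000, 5023)
    with pytest.raises(ValueError):
        define_enrichment_regions(up, [bad, _toy_guide("d2", 5400)])


def test_regions_reject_interleaved_pairs():
    up = [_toy_guide("u1", 1000), _toy_guide("u2", 5100)]
    down = [_toy_guide("d1", 5000), _toy_guide("d2", 5400)]
    with pytest.raises(ValueError):
        define_enrichment_regions(up, down)
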