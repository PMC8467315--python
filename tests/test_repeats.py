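"""Motif census, CG enumeration, domain segmentation."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceoseq import MotifInstance, count_motifs, find_cg_sites, segment_domains
from ceoseq.dna import random_seq
from ceoseq.repeats import AMORPHOUS, C_TERMINAL, N_TERMINAL, REPETITIVE
from ceoseq.tables import FIBH_MOTIFS


def test_count_motifs_concatenated_copies():
    counts, instances = count_motifs("TGCTCCGTATC" * 3, {"motif-1": "TGCTCCGTATC"})
    assert counts["motif-1"] == 3
    assert [i.start for i in instances] == [0, 11, 22]


def test_count_motifs_absent_motif_is_zero():
    counts, instances = count_motifs("AAAAAAAA", {"m": "TGCTCCGTATC"})
    assert counts["m"] == 0 and instances == []


def test_count_motifs_counts_overlaps():
    counts, _ = count_motifs("ATATATA", {"m": "ATA"})
    assert counts["m"] == 3  # lookahead scan counts overlapping hits


def test_count_motifs_matches_regex_oracle(rng):
    motifs = {name: seq for name, (seq, _, _) in FIBH_MOTIFS.items()}
    seq = random_seq(2000, rng, 0.6) + "".join(
        m * 3 for m in list(motifs.values())[:4]
    ) + random_seq(500, rng, 0.6)
    counts, _ = count_motifs(seq, motifs)
    for name, m in motifs.items():
        assert counts[name] == len(re.findall(f"(?={m})", seq))


@pytest.mark.parametrize("seq,expected", [("ACGT", [1]), ("CGCG", [0, 2]), ("AAAA", [])])
def test_find_cg_sites_examples(seq, expected):
    assert find_cg_sites(seq) == expected


def test_each_published_motif_has_exactly_one_cg():
    for name, (seq, _, _) in FIBH_MOTIFS.items():
        assert len(find_cg_sites(seq)) == 1, name


@given(st.text(alphabet="ACGT", min_size=0, max_size=200))
@settings(max_examples=150, derandomize=True)
def test_find_cg_sites_matches_naive_scan(s):
    assert find_cg_sites(s) == [i for i in range(len(s) - 1) if s[i : i + 2] == "CG"]


def _clusters(layout, motif_len=11):
    """Build instances from (n_motifs, spacer) cluster layout; returns
    instances and total length."""
    instances, pos = [], 0
    for k, (n, spacer) in enumerate(layout):
        for _ in range(n):
            instances.append(MotifInstance("m", "c", pos, motif_len))
            pos += motif_len
        pos += spacer
    return instances, pos


def test_segment_twelve_clusters_gives_12R_11A():
    layout = [(30, 1000)] * 11 + [(30, 0)]
    instances, total = _clusters(layout)
    segments = segment_domains(instances, total)
    kinds = [s.kind for s in segments]
    assert kinds.count(REPETITIVE) == 12
    assert kinds.count(AMORPHOUS) == 11


def test_segment_uniform_dense_is_single_repetitive_block():
    instances, total = _clusters([(50, 0)])
    segments = segment_domains(instances, total + 100)
    reps = [s for s in segments if s.kind == REPETITIVE]
    assert len(reps) == 1
    assert reps[0].start == 0 and reps[0].end == 550
    assert [s.kind for s in segments if s.kind != REPETITIVE] == [C_TERMINAL]


def test_segment_no_instances_single_segment():
    segments = segment_domains([], 500)
    assert len(segments) == 1 and segments[0].length == 500


def test_segment_flanks_labeled_terminal():
    instances = [MotifInstance("m", "c", 400 + 11 * k, 11) for k in range(40)]
    segments = segment_domains(instances, 1500)
    assert segments[0].kind == N_TERMINAL and segments[0].start == 0
    assert segments[-1].kind == C_TERMINAL and segments[-1].end == 1500


@given(st.integers(2, 9), st.integers(300, 1200), st.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_segment_recovers_planted_cluster_count(n_clusters, spacer, seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    layout = [
        (int(rng.integers(20, 40)), spacer if k < n_clusters - 1 else 0)
        for k in range(n_clusters)
    ]
    instances, total = _clusters(layout)
    segments = segment_domains(instances, total)
    assert sum(1 for s in segments if s.kind == REPETITIVE) == n_clusters


def test_segmentation_invariant_to_instance_order(rng):
    layout = [(25, 800)] * 3 + [(25, 0)]
    instances, total = _clusters(layout)
    shuffled = list(instances)
    rng.shuffle(shuffled)
    assert segment_domains(instances, total) == segment_domains(shuffled, total)


def test_segments_tile_locus():
    layout = [(25, 700)] * 5 + [(25, 123)]
    instances, total = _clusters(layout)
    segments = segment_domains(instances, total)
    assert segments[0].start == 0 and segments[-1].end == total
    for a, b in zip(segments, segments[1:]):
        assert a.end == b.start
    # R and A alternate in the interior
    interior = [s.kind for s in segments if s.kind in (REPETITIVE, AMORPHOUS)]
    for a, b in zip(interior, interior[1:]):
        assert a != b
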