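import numpy as np
import pytest

from conftest import random_dna
from mitokit import (
    CircularGenome, DispersedRepeat, LongRead,
    select_candidates, apply_event, enumerate_conformations,
    build_junctions, score_read_support, classify_recombination_type,
    canonical_circular, revcomp, subsequence,
    find_dispersed_repeats,
)
from mitokit.recombination import Conformation, RecombRepeatPair


def _master(seq):
    return Conformation("C1", frozenset(), (seq,), is_major=True)


def _pair(label, orientation, a, b, genome, identity=1.0):
    repA = subsequence(genome, a[0], a[1], "+")
    masterB = subsequence(genome, b[0], b[1], "+")
    repB = revcomp(masterB) if orientation == "inverted" else masterB
    return RecombRepeatPair(label, orientation, identity, a, b, repA, repB, "", "", 50)


@pytest.fixture()
def inverted_toy(rng):
    """1 kb circle with identical inverted 60-mers at 101-160 and 501-560."""
    bg = random_dna(rng, 1000)
    rep = random_dna(rng, 60)
    s = list(bg)
    s[100:160] = list(rep)
    s[500:560] = list(revcomp(rep))
    genome = CircularGenome("toy", "".join(s))
    return genome, _pair("R1", "inverted", (101, 160), (501, 560), genome)


@pytest.fixture()
def direct_toy(rng):
    bg = random_dna(rng, 1000)
    rep = random_dna(rng, 60)
    s = list(bg)
    s[100:160] = list(rep)
    s[500:560] = list(rep)
    genome = CircularGenome("toy", "".join(s))
    return genome, _pair("R1", "direct", (101, 160), (501, 560), genome)


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------


def test_select_candidates_labels_and_orientations(toy_circle):
    """Repeats of 1561/534/461/150 bp: only the three >= 200 bp qualify,
    labelled R1-R3 by length with palindromic -> inverted, forward -> direct."""
    repeats = [
        DispersedRepeat("palindromic", 534, 3000, 3533, 7000, 7533, 0),
        DispersedRepeat("palindromic", 1561, 100, 1660, 4000, 5560, 0),
        DispersedRepeat("forward", 461, 8000, 8460, 9000, 9460, 0),
        DispersedRepeat("forward", 150, 200, 349, 600, 749, 0),
    ]
    genome = CircularGenome("m", random_dna(np.random.default_rng(2), 12_000))
    cands = select_candidates(repeats, genome, min_len=200, flank_len=100)
    assert [(c.label, c.orientation, c.length) for c in cands] == [
        ("R1", "inverted", 1561), ("R2", "inverted", 534), ("R3", "direct", 461),
    ]


def test_select_candidates_empty_and_overlapping(toy_circle):
    assert select_candidates([], toy_circle) == []
    overlapping = [DispersedRepeat("forward", 300, 101, 400, 301, 600, 0)]
    assert select_candidates(overlapping, toy_circle, min_len=200) == []


def test_planted_candidate_crs_exact(three_pair_study):
    """The CRS of a planted pair equals the repeat plus 1000 bp flanks."""
    genome, _, truth, _ = three_pair_study
    cands = select_candidates(find_dispersed_repeats(genome), genome)
    planted = max(truth.recomb_pairs, key=lambda p: p.end1 - p.start1)
    r1 = cands[0]
    assert (r1.copyA, r1.copyB) == ((planted.start1, planted.end1),
                                    (planted.start2, planted.end2))
    n = len(genome)
    expected = subsequence(genome, (planted.start1 - 1 - 1000) % n + 1,
                           (planted.end1 - 1 + 1000) % n + 1, "+")
    assert r1.crsA == expected


# ---------------------------------------------------------------------------
# event algebra
# ---------------------------------------------------------------------------


def test_inverted_event_reverse_complements_between_midpoints(inverted_toy):
    genome, pair = inverted_toy
    prod = apply_event(_master(genome.sequence), pair)
    assert len(prod.molecules) == 1 and prod.total_length == 1000
    m1, m2 = 100 + 30, 500 + 30
    expected = genome.sequence[:m1] + revcomp(genome.sequence[m1:m2]) + genome.sequence[m2:]
    assert canonical_circular(prod.molecules[0]) == canonical_circular(expected)


def test_inverted_event_is_involution(inverted_toy):
    genome, pair = inverted_toy
    start = _master(genome.sequence)
    twice = apply_event(apply_event(start, pair), pair)
    assert twice.canonical_key() == start.canonical_key()


def test_direct_event_fission_and_fusion(direct_toy):
    genome, pair = direct_toy
    start = _master(genome.sequence)
    fissioned = apply_event(start, pair)
    assert sorted(len(m) for m in fissioned.molecules) == [400, 600]
    assert fissioned.total_length == 1000
    refused = apply_event(fissioned, pair)
    assert len(refused.molecules) == 1
    assert refused.canonical_key() == start.canonical_key()


def test_event_inapplicable_when_copies_missing(rng):
    genome = CircularGenome("m", random_dna(rng, 800))
    ghost = RecombRepeatPair("R1", "direct", 1.0, (1, 60), (301, 360),
                             "A" * 60, "A" * 60, "", "", 50)
    assert apply_event(_master(genome.sequence), ghost) is None


# ---------------------------------------------------------------------------
# conformation enumeration
# ---------------------------------------------------------------------------


def test_enumerate_no_pairs(toy_circle):
    confs = enumerate_conformations(toy_circle, [])
    assert len(confs) == 1 and confs[0].label == "C1" and confs[0].is_major


def test_enumerate_one_direct_pair(direct_toy):
    genome, pair = direct_toy
    confs = enumerate_conformations(genome, [pair])
    assert len(confs) == 2
    assert len(confs[0].molecules) == 1 and len(confs[1].molecules) == 2
    assert all(c.total_length == 1000 for c in confs)


def test_enumerate_three_pairs_eight_conformations(three_pair_study):
    """Two inverted pairs and one direct pair enumerate 2^3 = 8 distinct
    conformations: the master plus seven minors, every one conserving bases."""
    genome, _, _, _ = three_pair_study
    cands = select_candidates(find_dispersed_repeats(genome), genome)
    assert len(cands) == 3
    confs = enumerate_conformations(genome, cands)
    reachable = [c for c in confs if c.reachable]
    assert len(reachable) == 8
    assert sum(1 for c in reachable if c.is_major) == 1
    assert all(c.duplicate_of is None for c in reachable)
    assert all(c.total_length == len(genome) for c in reachable)


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------


def test_direct_junctions_distinct_and_correct_lengths(rng):
    bg = random_dna(rng, 6000)
    rep = random_dna(rng, 200)
    s = list(bg)
    s[1500:1700] = list(rep)
    s[4000:4200] = list(rep)
    genome = CircularGenome("m", "".join(s))
    pair = _pair("R1", "direct", (1501, 1700), (4001, 4200), genome)
    jx = build_junctions(genome, pair, flank_len=1000)
    seqs = [jx.refA, jx.refB, jx.recA, jx.recB]
    assert all(len(q) == 2200 for q in seqs)
    assert len(set(seqs)) == 4


@pytest.mark.parametrize("kind", ["direct", "inverted"])
def test_recombinant_junctions_appear_in_event_product(kind, request):
    """Cross-module consistency: each recombinant junction occurs verbatim
    (up to strand) in the molecules of the conformation its event creates."""
    genome, pair = request.getfixturevalue(f"{kind}_toy")
    jx = build_junctions(genome, pair, flank_len=80)
    prod = apply_event(_master(genome.sequence), pair)
    haystack = [m + m for m in prod.molecules]
    for rec in (jx.recA, jx.recB):
        assert any(rec in h or revcomp(rec) in h for h in haystack)
    master_dbl = genome.sequence * 2
    assert jx.refA in master_dbl
    assert jx.refB in master_dbl or revcomp(jx.refB) in master_dbl


# ---------------------------------------------------------------------------
# read support
# ---------------------------------------------------------------------------


def test_reads_from_master_support_only_reference(inverted_toy):
    genome, pair = inverted_toy
    jx = build_junctions(genome, pair, flank_len=150)
    dbl = genome.sequence * 2
    reads = [LongRead(f"r{i}", dbl[i * 13 : i * 13 + 600]) for i in range(50)]
    res = score_read_support(jx, reads, min_span=100)
    assert res.counts["refA"] >= 1
    assert res.counts["recA"] == 0 and res.counts["recB"] == 0


def test_clipped_read_fails_span_rule(inverted_toy):
    """A read identical to recA but clipped 50 bp into the left flank cannot
    satisfy min_span=100 into both flanks."""
    genome, pair = inverted_toy
    jx = build_junctions(genome, pair, flank_len=150)
    lf, core, rf = jx.parts["recA"]
    clipped = jx.recA[lf - 50 : lf + core + 120]
    res = score_read_support(jx, [LongRead("clip", clipped)], min_span=100)
    assert all(v == 0 for v in res.counts.values())
    full = jx.recA[lf - 120 : lf + core + 120]
    res2 = score_read_support(jx, [LongRead("full", full)], min_span=100)
    assert res2.counts["recA"] == 1


def test_best_hit_assignment_is_exclusive(inverted_toy):
    genome, pair = inverted_toy
    jx = build_junctions(genome, pair, flank_len=150)
    lf, core, rf = jx.parts["refA"]
    probe_read = LongRead("r", jx.refA)
    res = score_read_support(jx, [probe_read], min_span=100)
    assert sum(res.counts.values()) == 1


# ---------------------------------------------------------------------------
# recombination-type taxonomy
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "identity,orientation,expected",
    [
        (1.0, "direct", ("identical", 1)),
        (1.0, "inverted", ("identical", 2)),
        (0.98, "inverted", ("non-identical", 6)),
        (0.98, "direct", ("non-identical", 3)),
    ],
)
def test_classify_recombination_type(identity, orientation, expected):
    pair = RecombRepeatPair("R1", orientation, identity, (1, 200), (1001, 1200),
                            "A" * 200, "A" * 200, "", "", 100)
    label = classify_recombination_type(pair)
    assert (label.identity_class, label.subtype) == expected
    assert label.orientation == orientation
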