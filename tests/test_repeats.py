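import numpy as np
import pytest

from brute import oracle_dispersed, tandem_window_exists
from conftest import random_dna
from mitokit import (
    CircularGenome, RepeatConfig,
    find_ssrs, find_tandem_repeats, find_dispersed_repeats, complement, revcomp,
)


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def test_ssr_threshold_boundary():
    recs = find_ssrs(CircularGenome("m", "C" + "A" * 10 + "C" + "G" * 30))
    a = next(r for r in recs if r.motif == "A")
    assert (a.copies, a.start, a.end) == (10, 2, 11)


def test_ssr_below_threshold_absent(rng):
    seq = random_dna(rng, 200)
    seq = seq[:90].replace("A", "C") + "A" * 9 + seq[99:].replace("A", "C")
    assert not [r for r in find_ssrs(CircularGenome("m", seq)) if r.motif == "A"]


def test_ssr_dimer_not_reported_as_monomers():
    recs = find_ssrs(CircularGenome("m", "G" + "AT" * 5 + "G"))
    assert len(recs) == 1
    r = recs[0]
    assert (r.motif, r.unit_len, r.copies, r.start, r.end) == ("AT", 2, 5, 2, 11)


def test_ssr_planted_recovery_exact(planted_feature_study):
    genome, _, truth, _ = planted_feature_study
    got = {(r.motif, r.start, r.end) for r in find_ssrs(genome)}
    for planted in truth.ssrs:
        assert (planted.motif, planted.start, planted.end) in got


def test_ssr_rotation_invariance(planted_feature_study):
    """SSR counts are invariant under rotation when no run spans the origin."""
    genome, _, truth, _ = planted_feature_study
    base = find_ssrs(genome)
    shift = 1001
    assert all(not (r.start <= shift < r.end) for r in base)
    rotated = CircularGenome("rot", genome.sequence[shift:] + genome.sequence[:shift])
    assert len(find_ssrs(rotated)) == len(base)


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------


def test_tandem_perfect_period_three():
    recs = find_tandem_repeats(CircularGenome("m", "TTAATAATAATT" + "G" * 40))
    assert any(r.period == 3 and r.copies >= 2 and r.identity == 1.0 for r in recs)


def test_tandem_planted_recovery(planted_feature_study):
    genome, _, truth, _ = planted_feature_study
    got = {(r.period, r.start, r.end) for r in find_tandem_repeats(genome)}
    for planted in truth.tandems:
        assert (len(planted.motif), planted.start, planted.end) in got
    # the 27x2 planted array spans 54 bases
    big = next(t for t in truth.tandems if len(t.motif) == 27)
    assert big.end - big.start + 1 == 54


def test_tandem_random_sequence_matches_brute_force(rng):
    """On a seeded random kilobase, the finder reports a span >= 20 tandem iff
    an exhaustive lag-correlation scan finds a qualifying window."""
    seq = random_dna(np.random.default_rng(20), 1000)
    cfg = RepeatConfig(tandem_max_period=50)
    finder_hit = any(
        r.end - r.start + 1 >= 20 for r in find_tandem_repeats(CircularGenome("m", seq), cfg)
    )
    brute_hit = tandem_window_exists(seq, 20, 50, 0.85)
    assert finder_hit == brute_hit


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------


def _plant(seq: str, pos: int, payload: str) -> str:
    return seq[:pos] + payload + seq[pos + len(payload):]


def _found_set(genome, cfg):
    return {
        (r.orientation, r.start1, r.end1, r.start2, r.end2, r.mismatches)
        for r in find_dispersed_repeats(genome, cfg)
    }


@pytest.mark.parametrize("mm", [0, 1, 2, 3, 4])
def test_dispersed_equals_brute_force_oracle(mm):
    """Seeded <=5 kb genome with planted pairs of all four orientation
    classes: the seed-and-extend finder reports exactly the maximal pair set
    of the all-diagonal brute-force oracle, for mismatch budgets 0-4."""
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 1500)
    src = random_dna(rng, 40)
    seq = _plant(seq, 100, src)
    seq = _plant(seq, 300, src)                   # forward
    seq = _plant(seq, 500, src[::-1])             # reverse
    seq = _plant(seq, 700, complement(src))       # complement
    seq = _plant(seq, 900, revcomp(src))          # palindromic
    cfg = RepeatConfig(dispersed_min_len=20, dispersed_max_mismatch=mm,
                       dispersed_max_report=10**9)
    assert _found_set(CircularGenome("m", seq), cfg) == oracle_dispersed(seq, 20, mm)


def test_dispersed_mismatch_boundary():
    """A 35 bp pair with exactly 3 mismatches is reported at budget 3; with a
    fourth mismatch (positions spread so no 30 bp sub-window survives) it is
    absent."""
    rng = np.random.default_rng(8)
    seq = random_dna(rng, 2000)
    src = random_dna(rng, 35)

    def mutate(s, positions):
        out = list(s)
        for p in positions:
            out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
        return "".join(out)

    cfg = RepeatConfig(dispersed_min_len=30, dispersed_max_mismatch=3)
    three = _plant(_plant(seq, 200, src), 900, mutate(src, [5, 17, 29]))
    hits = [r for r in find_dispersed_repeats(CircularGenome("m", three), cfg)
            if r.orientation == "forward" and r.length >= 30]
    assert any(r.start1 == 201 and r.start2 == 901 and r.mismatches == 3 for r in hits)

    four = _plant(_plant(seq, 200, src), 900, mutate(src, [5, 12, 19, 26]))
    hits4 = [r for r in find_dispersed_repeats(CircularGenome("m", four), cfg)
             if r.orientation == "forward" and r.length >= 30
             and r.start1 >= 195 and r.start1 <= 240]
    assert not hits4


def test_dispersed_planted_recovery_exact(planted_feature_study):
    genome, _, truth, _ = planted_feature_study
    got = _found_set(genome, RepeatConfig())
    for planted in truth.dispersed + truth.recomb_pairs:
        assert (planted.orientation, planted.start1, planted.end1,
                planted.start2, planted.end2, planted.mismatches) in got


def test_dispersed_reversal_symmetry():
    """Reversing the genome maps forward and palindromic hits onto mirrored
    coordinates of the same class."""
    rng = np.random.default_rng(13)
    seq = random_dna(rng, 2000)
    src = random_dna(rng, 45)
    pal = random_dna(rng, 45)
    seq = _plant(_plant(seq, 150, src), 800, src)             # forward pair
    seq = _plant(_plant(seq, 1200, pal), 1600, revcomp(pal))  # palindromic pair
    cfg = RepeatConfig(dispersed_min_len=30, dispersed_max_mismatch=0,
                       dispersed_max_report=10**9)
    n = len(seq)

    def mirror(rec):
        a1, a2 = n - rec.end1 + 1, n - rec.start1 + 1
        b1, b2 = n - rec.end2 + 1, n - rec.start2 + 1
        if (b1, b2) < (a1, a2):
            (a1, a2), (b1, b2) = (b1, b2), (a1, a2)
        return (rec.orientation, a1, a2, b1, b2, rec.mismatches)

    fwd = find_dispersed_repeats(CircularGenome("m", seq), cfg)
    rev = _found_set(CircularGenome("m", seq[::-1]), cfg)
    for rec in fwd:
        if rec.orientation in ("forward", "palindromic"):
            assert mirror(rec) in rev


def test_dispersed_cap_and_ordering():
    rng = np.random.default_rng(3)
    seq = random_dna(rng, 3000)
    src = random_dna(rng, 60)
    for pos in (100, 400, 700, 1000, 1300):
        seq = _plant(seq, pos, src)
    cfg = RepeatConfig(dispersed_min_len=30, dispersed_max_report=3)
    recs = find_dispersed_repeats(CircularGenome("m", seq), cfg)
    assert len(recs) == 3
    lengths = [r.length for r in recs]
    assert lengths == sorted(lengths, reverse=True)
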