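"""Repeat-mediated homologous recombination of circular mitogenomes.

Large dispersed repeats recombine plant mitochondrial DNA: an inverted pair on
one circle flips the segment between the copies; a direct pair on one circle
splits it into two circles (and, in reverse, fuses two circles carrying one
copy each).  Applying subsets of recombination-active pairs to the assembled
master circle enumerates the conformation space of the molecule; junction
sequences across each repeat copy and its flanks let long reads vote for the
reference (master) or recombinant arrangements.

Conventions
-----------
* Candidate pairs are repeats >= 200 bp (forward -> direct, palindromic ->
  inverted), labelled R1, R2, ... by decreasing length, each carried with its
  1000 bp flanking regions (the candidate recombination sequence, CRS).
* The crossover point inside a repeat copy is its midpoint; for non-identical
  copies the recombinant repeat takes copyA's left half and copyB's right half.
* A canonical circular form (the lexicographically least rotation of the
  lesser of sequence and reverse complement) makes conformation identity
  decidable.
* A read supports a junction when the junction probe (repeat plus at least
  ``min_span`` bases of both flanks) aligns within the read at >= 95%
  identity; each read is assigned to its best junction only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import edlib

from .genome import CircularGenome, LongRead, revcomp, subsequence
from .repeats import DispersedRepeat

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# canonical circular form
# ---------------------------------------------------------------------------


def least_rotation(s: str) -> str:
    """Lexicographically least rotation (Booth's algorithm, O(n))."""
    ss = s + s
    f = [-1] * len(ss)
    kk = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - kk - 1]
        while i != -1 and sj != ss[kk + i + 1]:
            if sj < ss[kk + i + 1]:
                kk = j - i - 1
            i = f[i]
        if sj != ss[kk + i + 1]:
            if sj < ss[kk]:
                kk = j
            f[j - kk] = -1
        else:
            f[j - kk] = i + 1
    return ss[kk : kk + len(s)]


def canonical_circular(s: str) -> str:
    """Canonical form of a circular molecule: least rotation of the lesser of
    the sequence and its reverse complement."""
    return min(least_rotation(s), least_rotation(revcomp(s)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecombRepeatPair:
    """A recombination-capable repeat pair with its CRS flanks."""

    label: str
    orientation: str                     # direct | inverted
    identity: float
    copyA: tuple[int, int]               # 1-based inclusive on the master
    copyB: tuple[int, int]
    repeatA: str                         # copyA on its own strand
    repeatB: str                         # copyB on the repeat strand
    crsA: str
    crsB: str
    flank_len: int = 1000

    @property
    def length(self) -> int:
        return len(self.repeatA)


@dataclass
class Conformation:
    """A multiset of circular molecules reachable by recombination events."""

    label: str
    event_set: frozenset[str]
    molecules: tuple[str, ...]
    is_major: bool = False
    reachable: bool = True
    duplicate_of: str | None = None

    def canonical_key(self) -> tuple[str, ...]:
        return tuple(sorted(canonical_circular(m) for m in self.molecules))

    @property
    def total_length(self) -> int:
        return sum(len(m) for m in self.molecules)


@dataclass(frozen=True)
class JunctionSet:
    """The four junction sequences of one pair: two reference, two recombinant.

    ``parts`` records (left flank, core, right flank) lengths per junction so
    scoring can slice a probe covering the core plus a span of each flank.
    """

    pair_label: str
    refA: str
    refB: str
    recA: str
    recB: str
    flank_len: int
    parts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def items(self):
        return (("refA", self.refA), ("refB", self.refB),
                ("recA", self.recA), ("recB", self.recB))


@dataclass
class ReadSupportResult:
    pair_label: str
    counts: dict[str, int]
    supporting_read_ids: dict[str, list[str]]
    min_similarity: float
    min_span: int


@dataclass(frozen=True)
class RecombTypeLabel:
    identity_class: str                  # identical | non-identical
    orientation: str                     # direct | inverted
    subtype: int


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

_ORIENT_MAP = {"forward": "direct", "palindromic": "inverted"}


def select_candidates(
    repeats: list[DispersedRepeat],
    genome: CircularGenome,
    min_len: int = 200,
    flank_len: int = 1000,
) -> list[RecombRepeatPair]:
    """Recombination-capable pairs: forward/palindromic repeats >= ``min_len``,
    labelled R1, R2, ... by descending length, with CRS flanks attached.
    Pairs whose copies overlap are skipped with a warning."""
    cands = [
        r
        for r in repeats
        if r.orientation in _ORIENT_MAP and r.length >= min_len
    ]
    cands.sort(key=lambda r: (-r.length, r.start1, r.start2))
    out: list[RecombRepeatPair] = []
    for r in cands:
        if r.end1 >= r.start2 and r.start1 <= r.end2:
            log.warning("candidate at (%d,%d)/(%d,%d) has overlapping copies; skipped",
                        r.start1, r.end1, r.start2, r.end2)
            continue
        orientation = _ORIENT_MAP[r.orientation]
        repA = subsequence(genome, r.start1, r.end1, "+")
        masterB = subsequence(genome, r.start2, r.end2, "+")
        repB = revcomp(masterB) if orientation == "inverted" else masterB
        n = len(genome)
        crsA = _with_flanks(genome, r.start1, r.end1, flank_len)
        crsB = _with_flanks(genome, r.start2, r.end2, flank_len)
        out.append(
            RecombRepeatPair(
                label=f"R{len(out) + 1}",
                orientation=orientation,
                identity=r.identity,
                copyA=(r.start1, r.end1),
                copyB=(r.start2, r.end2),
                repeatA=repA,
                repeatB=repB,
                crsA=crsA,
                crsB=crsB,
                flank_len=flank_len,
            )
        )
    return out


def _with_flanks(genome: CircularGenome, start: int, end: int, flank: int) -> str:
    n = len(genome)
    flank = min(flank, (n - (end - start + 1)) // 2)  # never wrap ambiguously
    s = (start - 1 - flank) % n + 1
    e = (end - 1 + flank) % n + 1
    return subsequence(genome, s, e, "+")


# ---------------------------------------------------------------------------
# event algebra
# ---------------------------------------------------------------------------


def _variants(pair: RecombRepeatPair) -> list[str]:
    """Exact repeat-core variants that can occur after any event subset:
    both originals plus the two midpoint-crossover hybrids (both index
    conventions, which differ for odd lengths)."""
    a, b = pair.repeatA, pair.repeatB
    L = len(a)
    h = L // 2
    vs = [a, b, a[:h] + b[h:], b[:h] + a[h:], a[:h] + b[L - h :], b[: L - h] + a[h:]]
    uniq: list[str] = []
    for v in vs:
        if v and v not in uniq:
            uniq.append(v)
    return uniq


def _find_occurrences(molecules: tuple[str, ...], variants: list[str]):
    """Locate repeat-core occurrences on circular molecules, both strands.

    Returns (mol_index, start0, strand, length) with start0 taken modulo the
    molecule length (occurrences may wrap the origin)."""
    occs = []
    seen: set[tuple[int, int]] = set()
    for mi, mol in enumerate(molecules):
        n = len(mol)
        dbl = mol + mol
        for v in variants:
            if len(v) > n:
                continue
            for strand, probe in (("+", v), ("-", revcomp(v))):
                start = 0
                while True:
                    p = dbl.find(probe, start)
                    if p == -1 or p >= n:
                        break
                    if (mi, p) not in seen:
                        seen.add((mi, p))
                        occs.append((mi, p, strand, len(v)))
                    start = p + 1
    return occs


def apply_event(conf: Conformation, pair: RecombRepeatPair) -> Conformation | None:
    """Apply one recombination event; returns None when the pair's copies
    cannot both be located on the conformation's molecules.

    Same molecule, opposite strands -> inversion of the inter-midpoint
    segment; same molecule, same strand -> fission into two circles;
    different molecules -> fusion into one circle.  Total length is conserved.
    """
    occs = _find_occurrences(conf.molecules, _variants(pair))
    if len(occs) != 2:
        return None
    (m1, p1, s1, l1), (m2, p2, s2, l2) = occs
    mols = list(conf.molecules)
    if m1 == m2:
        mol = mols[m1]
        n = len(mol)
        mid1 = (p1 + l1 // 2) % n
        mid2 = (p2 + l2 // 2) % n
        if mid1 > mid2:
            mid1, mid2, s1, s2 = mid2, mid1, s2, s1
        if s1 == s2:                               # fission
            c1 = mol[mid1:mid2]
            c2 = mol[mid2:] + mol[:mid1]
            new = [m for i, m in enumerate(mols) if i != m1] + [c1, c2]
        else:                                      # inversion
            new = list(mols)
            new[m1] = mol[:mid1] + revcomp(mol[mid1:mid2]) + mol[mid2:]
    else:                                          # fusion
        parts = []
        for mi, p, strand, l in ((m1, p1, s1, l1), (m2, p2, s2, l2)):
            mol = mols[mi]
            n = len(mol)
            if strand == "-":
                mol = revcomp(mol)
                p = (n - p - l) % n
            mid = (p + l // 2) % n
            parts.append(mol[mid:] + mol[:mid])
        fused = parts[0] + parts[1]
        new = [m for i, m in enumerate(mols) if i not in (m1, m2)] + [fused]
    return Conformation(
        label="",
        event_set=conf.event_set | {pair.label},
        molecules=tuple(new),
    )


def enumerate_conformations(
    genome: CircularGenome, pairs: list[RecombRepeatPair]
) -> list[Conformation]:
    """One conformation per subset of pairs, events applied in label order.

    C1 is the empty subset (the master circle, flagged major).  Subsets whose
    event chain becomes inapplicable are marked unreachable; conformations
    whose canonical molecule multiset duplicates an earlier one are flagged."""
    if len(pairs) > 12:
        raise ValueError("conformation enumeration limited to 12 pairs (2^k subsets)")
    pairs = sorted(pairs, key=lambda p: p.label)
    master = Conformation("C1", frozenset(), (genome.sequence,), is_major=True)
    out = [master]
    subsets = []
    for k in range(1, len(pairs) + 1):
        subsets.extend(itertools.combinations(pairs, k))
    seen: dict[tuple[str, ...], str] = {master.canonical_key(): "C1"}
    for subset in subsets:
        conf: Conformation | None = master
        for pair in subset:
            conf = apply_event(conf, pair)
            if conf is None:
                break
        label = f"C{len(out) + 1}"
        if conf is None:
            out.append(
                Conformation(label, frozenset(p.label for p in subset), (), reachable=False)
            )
            continue
        key = conf.canonical_key()
        dup = seen.get(key)
        if dup is None:
            seen[key] = label
        out.append(
            Conformation(label, conf.event_set, conf.molecules, duplicate_of=dup)
        )
    return out


# ---------------------------------------------------------------------------
# junctions and read support
# ---------------------------------------------------------------------------


def build_junctions(
    genome: CircularGenome, pair: RecombRepeatPair, flank_len: int = 1000
) -> JunctionSet:
    """The four junction sequences of a pair, written on copyA's strand.

    refA/refB reproduce the master locally; recA/recB are the two crossover
    products exchanging flanks (B-side flanks reverse-complemented for
    inverted pairs so all four sequences share one strand).  A flank running
    into the partner copy is truncated with a warning."""
    n = len(genome)
    (a1, a2), (b1, b2) = pair.copyA, pair.copyB
    gap_ab = (b1 - a2 - 1) % n
    gap_ba = (a1 - b2 - 1) % n
    f_right_a = min(flank_len, gap_ab)
    f_left_b = min(flank_len, gap_ab)
    f_left_a = min(flank_len, gap_ba)
    f_right_b = min(flank_len, gap_ba)
    if min(f_right_a, f_left_a) < flank_len:
        log.warning("pair %s: flanks truncated to fit between the copies", pair.label)

    lfA = subsequence(genome, (a1 - 1 - f_left_a) % n + 1, (a1 - 2) % n + 1, "+") if f_left_a else ""
    rfA = subsequence(genome, a2 % n + 1, (a2 + f_right_a - 1) % n + 1, "+") if f_right_a else ""
    lfB = subsequence(genome, (b1 - 1 - f_left_b) % n + 1, (b1 - 2) % n + 1, "+") if f_left_b else ""
    rfB = subsequence(genome, b2 % n + 1, (b2 + f_right_b - 1) % n + 1, "+") if f_right_b else ""

    A, B = pair.repeatA, pair.repeatB
    L = len(A)
    h = L // 2
    if pair.orientation == "direct":
        refA = lfA + A + rfA
        refB = lfB + B + rfB
        recA = lfA + A[:h] + B[h:] + rfB
        recB = lfB + B[:h] + A[h:] + rfA
        parts = {
            "refA": (len(lfA), L, len(rfA)),
            "refB": (len(lfB), L, len(rfB)),
            "recA": (len(lfA), L, len(rfB)),
            "recB": (len(lfB), L, len(rfA)),
        }
    else:
        # B-side written on the repeat strand: left flank = revcomp(rfB) etc.
        refA = lfA + A + rfA
        refB = revcomp(rfB) + B + revcomp(lfB)
        recA = lfA + A[:h] + B[L - h :] + revcomp(lfB)
        recB = revcomp(rfB) + B[: L - h] + A[h:] + rfA
        parts = {
            "refA": (len(lfA), L, len(rfA)),
            "refB": (len(rfB), L, len(lfB)),
            "recA": (len(lfA), 2 * h, len(lfB)),
            "recB": (len(rfB), 2 * (L - h), len(rfA)),
        }
    return JunctionSet(pair.label, refA, refB, recA, recB, flank_len, parts)


_JUNCTION_ORDER = ("refA", "refB", "recA", "recB")


def _identity_in_read(probe: str, read_seq: str) -> float:
    """Best infix-alignment identity of the probe within the read, either
    strand; identity = matching columns / alignment columns."""
    best = 0.0
    for target in (read_seq,):
        for q in (probe, revcomp(probe)):
            res = edlib.align(q, target, mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            cols = 0
            num = ""
            for ch in res["cigar"]:
                if ch.isdigit():
                    num += ch
                else:
                    cols += int(num)
                    num = ""
            if cols == 0:
                continue
            ident = (cols - res["editDistance"]) / cols
            best = max(best, ident)
    return best


def score_read_support(
    junctions: JunctionSet,
    reads: list[LongRead],
    min_similarity: float = 0.95,
    min_span: int = 100,
) -> ReadSupportResult:
    """Count reads supporting each junction of a pair.

    The probe for a junction is its core (the repeat, or the recombinant
    hybrid) plus ``min_span`` bases into both flanks; a read supports the
    junction when the whole probe aligns within the read at identity >=
    ``min_similarity``, and each read is assigned to its best junction only
    (ties resolved in the order refA, refB, recA, recB)."""
    probes: dict[str, str] = {}
    for name, seq in junctions.items():
        lf, core, rf = junctions.parts[name]
        span_l, span_r = min(min_span, lf), min(min_span, rf)
        probes[name] = seq[lf - span_l : lf + core + span_r]
    counts = {name: 0 for name in _JUNCTION_ORDER}
    supporters: dict[str, list[str]] = {name: [] for name in _JUNCTION_ORDER}
    for read in reads:
        best_name, best_ident = None, 0.0
        for name in _JUNCTION_ORDER:
            ident = _identity_in_read(probes[name], read.sequence)
            if ident > best_ident:
                best_name, best_ident = name, ident
        if best_name is not None and best_ident >= min_similarity:
            counts[best_name] += 1
            supporters[best_name].append(read.id)
    return ReadSupportResult(junctions.pair_label, counts, supporters, min_similarity, min_span)


def classify_recombination_type(pair: RecombRepeatPair) -> RecombTypeLabel:
    """Provisional recombination-type taxonomy.

    Identical copies admit two types (1 direct, 2 inverted).  Non-identical
    copies admit six, indexed here as orientation x recombinant-arrangement
    (AB-hybrid, BA-hybrid, both): a single reciprocal crossover yields both
    hybrids, so pairs classify as 3 (direct) or 6 (inverted).  The indexing is
    a documented convention of this package, not an established standard."""
    if pair.identity >= 1.0:
        return RecombTypeLabel("identical", pair.orientation,
                               1 if pair.orientation == "direct" else 2)
    return RecombTypeLabel("non-identical", pair.orientation,
                           3 if pair.orientation == "direct" else 6)
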