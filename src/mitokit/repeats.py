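"""Detection of the three repeat classes of plant mitogenomes.

* SSRs (microsatellites): maximal perfect runs of a 1-6 base unit above the
  MISA-style per-class copy thresholds (mono 10, di 5, tri 4, tetra/penta/hexa 3).
* Tandem repeats: a deterministic lag-correlation scan over periods, reporting
  runs that match themselves at lag *p* with >= 85% identity.
* Dispersed repeats: maximal repeat pairs in four orientation classes
  (forward, reverse, complement, palindromic) under a Hamming-mismatch budget,
  found by exact k-mer seeding (pigeonhole) and ungapped extension.  This
  reproduces the output contract of suffix-tree maximal-repeat finders
  (REPuter-style: Hamming distance 3, minimum length 30, top 5000 pairs).

Coordinates in all records are 1-based inclusive.  The genome is treated as
linear at its deposited origin; origin-spanning repeats can be sought by
re-running on a rotated copy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .genome import CircularGenome, complement

Orientation = Literal["forward", "reverse", "complement", "palindromic"]

ORIENTATIONS: tuple[Orientation, ...] = ("forward", "reverse", "complement", "palindromic")


@dataclass(frozen=True)
class SSRRecord:
    motif: str
    unit_len: int
    copies: int
    start: int
    end: int


@dataclass(frozen=True)
class TandemRepeat:
    period: int
    copies: float
    start: int
    end: int
    consensus: str
    identity: float


@dataclass(frozen=True, order=True)
class DispersedRepeat:
    """A maximal repeat pair; copy1 starts lexicographically before copy2."""

    orientation: Orientation
    length: int
    start1: int
    end1: int
    start2: int
    end2: int
    mismatches: int

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length


@dataclass
class RepeatConfig:
    """Detection thresholds; defaults follow standard organelle practice."""

    ssr_min_repeats: tuple[int, int, int, int, int, int] = (10, 5, 4, 3, 3, 3)
    dispersed_min_len: int = 30
    dispersed_max_mismatch: int = 3
    dispersed_max_report: int = 5000
    tandem_min_span: int = 9
    tandem_min_period: int = 2
    tandem_max_period: int = 100
    tandem_min_identity: float = 0.85

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.ssr_min_repeats):
            raise ValueError("SSR thresholds must be positive")
        if self.dispersed_min_len <= 0 or self.dispersed_max_mismatch < 0:
            raise ValueError("bad dispersed-repeat parameters")


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs(genome: CircularGenome, config: RepeatConfig | None = None) -> list[SSRRecord]:
    """Maximal perfect microsatellite runs meeting the per-class thresholds.

    A run whose unit is itself periodic (e.g. AA, ATAT) is reported only under
    its shortest unit; a trailing partial copy is trimmed so that
    ``end - start + 1 == unit_len * copies``.
    """
    config = config or RepeatConfig()
    s = genome.sequence
    n = len(s)
    out: list[SSRRecord] = []
    for u in range(1, 7):
        thr = config.ssr_min_repeats[u - 1]
        i = u
        while i < n:
            if s[i] == s[i - u]:
                run_start = i
                while i < n and s[i] == s[i - u]:
                    i += 1
                region_start = run_start - u          # 0-based repeat region start
                region_len = (i - run_start) + u
                copies = region_len // u
                motif = s[region_start : region_start + u]
                if copies >= thr and "N" not in motif and _is_primitive(motif):
                    out.append(
                        SSRRecord(
                            motif=motif,
                            unit_len=u,
                            copies=copies,
                            start=region_start + 1,
                            end=region_start + copies * u,
                        )
                    )
            else:
                i += 1
    out.sort(key=lambda r: (r.start, r.unit_len))
    return out


def find_tandem_repeats(
    genome: CircularGenome, config: RepeatConfig | None = None
) -> list[TandemRepeat]:
    """Lag-correlation tandem scan.

    For each period p, maximal stretches where the sequence matches itself at
    lag p with identity >= ``tandem_min_identity`` and total span >=
    ``max(tandem_min_span, 2p)`` are candidates; overlapping candidates of
    different periods are resolved to the highest identity, then the smallest
    period.  This is a deterministic stand-in for the output contract of
    stochastic tandem finders, not a reimplementation of their models.
    """
    config = config or RepeatConfig()
    s = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    n = len(s)
    candidates: list[TandemRepeat] = []
    for p in range(config.tandem_min_period, config.tandem_max_period + 1):
        if n < 2 * p:
            break
        m = s[p:] == s[:-p]
        trues = np.flatnonzero(m)
        if trues.size == 0:
            continue
        w = last = int(trues[0])
        matches = 1
        for pos in trues[1:].tolist():
            # would identity still hold after bridging the gap to this match?
            if (matches + 1) / (pos - w + 1) >= config.tandem_min_identity:
                matches += 1
                last = pos
            else:
                _close_tandem(candidates, genome.sequence, p, w, last, matches, config)
                w = last = pos
                matches = 1
        _close_tandem(candidates, genome.sequence, p, w, last, matches, config)
    # overlap resolution: highest identity first, then smallest period
    candidates.sort(key=lambda t: (-t.identity, t.period, t.start))
    accepted: list[TandemRepeat] = []
    for cand in candidates:
        if all(cand.end < a.start or cand.start > a.end for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda t: t.start)
    return accepted


def _close_tandem(
    out: list[TandemRepeat],
    seq: str,
    p: int,
    w: int,
    last: int,
    matches: int,
    config: RepeatConfig,
) -> None:
    span = (last - w + 1) + p
    if span < max(config.tandem_min_span, 2 * p):
        return
    identity = matches / (last - w + 1)
    consensus = seq[w : w + p]
    if "N" in consensus or not _is_primitive(consensus):
        return
    out.append(
        TandemRepeat(
            period=p,
            copies=round(span / p, 2),
            start=w + 1,
            end=last + p + 1,
            consensus=consensus,
            identity=identity,
        )
    )


# ---------------------------------------------------------------------------
# dispersed repeats: exact k-mer seeds + ungapped Hamming extension
# ---------------------------------------------------------------------------


def seed_length(min_len: int, max_mismatch: int) -> int:
    """Pigeonhole-safe seed size: any pair of length >= min_len with <=
    max_mismatch mismatches contains an exact run of this length."""
    return max(1, -(-(min_len - max_mismatch) // (max_mismatch + 1)))


def _kmer_index(s: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if "N" not in kmer:
            idx[kmer].append(i)
    return idx


def _maximal_windows_from_seed(
    match, lo: int, hi: int, s0: int, s1: int, budget: int
) -> list[tuple[int, int, int]]:
    """All maximal <=budget-mismatch windows containing the exact run [s0, s1].

    ``match(x)`` is the per-position pair-match predicate on domain [lo, hi].
    Returns (start, end, mismatches) triples, ends inclusive.
    """
    left: list[int] = []            # mismatch positions walking left, nearest first
    x = s0 - 1
    while x >= lo and len(left) <= budget:
        if not match(x):
            left.append(x)
        x -= 1
    right: list[int] = []
    x = s1 + 1
    while x <= hi and len(right) <= budget:
        if not match(x):
            right.append(x)
        x += 1
    r_real, s_real = len(left), len(right)
    lpad = left + [lo - 1] * (budget + 1 - r_real)
    rpad = right + [hi + 1] * (budget + 1 - s_real)
    t_lo, t_hi = max(0, budget - s_real), min(budget, r_real)
    raw = []
    if t_lo > t_hi:                  # whole domain fits inside the budget
        raw.append((lo, hi, r_real + s_real))
    else:
        for t in range(t_lo, t_hi + 1):
            start = lpad[t] + 1
            end = rpad[budget - t] - 1
            mism = min(t, r_real) + min(budget - t, s_real)
            raw.append((start, end, mism))
    # trim mismatching boundary columns: a repeat is reported by its matching
    # core, so coordinates are unambiguous across overlapping maximal windows
    windows = []
    for start, end, mism in raw:
        while start <= end and not match(start):
            start += 1
            mism -= 1
        while end >= start and not match(end):
            end -= 1
            mism -= 1
        if start <= end:
            windows.append((start, end, mism))
    return windows


def find_dispersed_repeats(
    genome: CircularGenome, config: RepeatConfig | None = None
) -> list[DispersedRepeat]:
    """Maximal dispersed repeat pairs of the four orientation classes.

    Orientation semantics for a pair (copy1, copy2): forward — copy2 equals
    copy1; reverse — copy2 is copy1 reversed; complement — copy2 is copy1
    complemented in place; palindromic — copy2 is the reverse complement.
    Maximality: extending the pair by one base on either side would exceed the
    mismatch budget or leave the genome; reported coordinates are the matching
    core of each maximal window (mismatching boundary columns trimmed), so the
    same physical repeat is one record.  Each unordered pair is reported once;
    pairs whose copies overlap by more than half their length (tandem-like)
    are dropped; output is sorted longest first and capped at
    ``dispersed_max_report``.
    """
    config = config or RepeatConfig()
    g = genome.sequence
    n = len(g)
    min_len, mm = config.dispersed_min_len, config.dispersed_max_mismatch
    if n < 2 * min_len:
        return []
    k = seed_length(min_len, mm)
    found: dict[tuple, DispersedRepeat] = {}

    def emit(orientation: Orientation, windows, pair_coords) -> None:
        for start, end, mism in windows:
            length = end - start + 1
            if length < min_len:
                continue
            (a1, a2), (b1, b2) = pair_coords(start, end)
            if (a1, a2) == (b1, b2):
                continue
            overlap = min(a2, b2) - max(a1, b1) + 1
            if overlap > 0.5 * length:
                continue
            if (b1, b2) < (a1, a2):
                (a1, a2), (b1, b2) = (b1, b2), (a1, a2)
            key = (orientation, a1, a2, b1, b2)
            if key not in found:
                found[key] = DispersedRepeat(
                    orientation, length, a1 + 1, a2 + 1, b1 + 1, b2 + 1, mism
                )

    gi = _kmer_index(g, k)

    # forward / complement: diagonal classes (copy2 = copy1 shifted by d)
    for orientation, second in (("forward", g), ("complement", complement(g))):
        seen_seeds: set[tuple[int, int]] = set()
        if orientation == "forward":
            pair_iter = (
                (ps[i], ps[j])
                for ps in gi.values()
                for i in range(len(ps))
                for j in range(i + 1, len(ps))
            )
        else:
            idx2 = _kmer_index(second, k)
            pair_iter = (
                (x, u)
                for kmer, xs in gi.items()
                if kmer in idx2
                for x in xs
                for u in idx2[kmer]
                if u > x
            )
        for x, u in pair_iter:
            d = u - x
            if (d, x) in seen_seeds:
                continue
            seen_seeds.add((d, x))
            lo, hi = 0, n - d - 1
            windows = _maximal_windows_from_seed(
                lambda y: g[y + d] == second[y], lo, hi, x, x + k - 1, mm
            )
            emit(
                orientation,  # type: ignore[arg-type]
                windows,
                lambda s_, e_, d=d: ((s_, e_), (s_ + d, e_ + d)),
            )

    # reverse / palindromic: anti-diagonal classes (copy2 mirrors copy1)
    for orientation, second in (("reverse", g[::-1]), ("palindromic", complement(g)[::-1])):
        idx2 = _kmer_index(second, k)
        seen_seeds = set()
        for kmer, xs in gi.items():
            ys = idx2.get(kmer)
            if not ys:
                continue
            for x in xs:
                for y in ys:
                    c = n + x - y
                    lo, hi = max(0, c - n), (c - 2) // 2
                    if x < lo or x + k - 1 > hi:
                        continue
                    if (c, x) in seen_seeds:
                        continue
                    seen_seeds.add((c, x))
                    windows = _maximal_windows_from_seed(
                        lambda z: second[n - c + z] == g[z], lo, hi, x, x + k - 1, mm
                    )
                    emit(
                        orientation,  # type: ignore[arg-type]
                        windows,
                        lambda s_, e_, c=c: ((s_, e_), (c - 1 - e_, c - 1 - s_)),
                    )

    out = sorted(
        found.values(), key=lambda r: (-r.length, r.start1, r.start2, r.orientation)
    )
    return out[: config.dispersed_max_report]


def repeats_to_frame(records: list) -> pd.DataFrame:
    """Uniform tabular export for any repeat record list."""
    return pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__") else
                         {f: getattr(r, f) for f in r.__dataclass_fields__}
                         for r in records])
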