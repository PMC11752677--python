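"""Independent brute-force oracles used by the tests.

The dispersed-repeat oracle scans every diagonal and anti-diagonal of the
genome directly (no seeding, no k-mer index), enumerating maximal
bounded-mismatch windows from the full mismatch-position list, then applies
the same reporting conventions as the production finder (matching-core trim,
half-domain arms, 50% overlap filter, unordered-pair dedup).
"""

from __future__ import annotations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "X"}


def oracle_dispersed(seq: str, min_len: int, mm: int) -> set[tuple]:
    n = len(seq)
    found: set[tuple] = set()

    def add(orientation, start, end, pair, mism):
        length = end - start + 1
        if length < min_len:
            return
        (a1, a2), (b1, b2) = pair
        if (a1, a2) == (b1, b2):
            return
        if min(a2, b2) - max(a1, b1) + 1 > 0.5 * length:
            return
        if (b1, b2) < (a1, a2):
            (a1, a2), (b1, b2) = (b1, b2), (a1, a2)
        found.add((orientation, a1 + 1, a2 + 1, b1 + 1, b2 + 1, mism))

    def scan(orientation, match, lo, hi, coords):
        if hi - lo + 1 < min_len:
            return
        mis_positions = [x for x in range(lo, hi + 1) if not match(x)]
        pad = [lo - 1] + mis_positions + [hi + 1] * (mm + 1)
        for i in range(len(mis_positions) + 1):
            start, end = pad[i] + 1, pad[i + mm + 1] - 1
            if end - start + 1 < min_len:
                continue
            k = sum(1 for x in mis_positions if start <= x <= end)
            while start <= end and not match(start):
                start += 1
                k -= 1
            while end >= start and not match(end):
                end -= 1
                k -= 1
            if start <= end:
                add(orientation, start, end, coords(start, end), k)

    for d in range(1, n):
        scan("forward", lambda x, d=d: seq[x + d] == seq[x], 0, n - d - 1,
             lambda s, e, d=d: ((s, e), (s + d, e + d)))
        scan("complement", lambda x, d=d: seq[x + d] == COMP[seq[x]], 0, n - d - 1,
             lambda s, e, d=d: ((s, e), (s + d, e + d)))
    for c in range(2, 2 * n):
        lo, hi = max(0, c - n), (c - 2) // 2
        scan("reverse", lambda x, c=c: seq[c - 1 - x] == seq[x], lo, hi,
             lambda s, e, c=c: ((s, e), (c - 1 - e, c - 1 - s)))
        scan("palindromic", lambda x, c=c: seq[c - 1 - x] == COMP[seq[x]], lo, hi,
             lambda s, e, c=c: ((s, e), (c - 1 - e, c - 1 - s)))
    return found


def tandem_window_exists(seq: str, min_span: int, max_period: int,
                         min_identity: float) -> bool:
    """Naive check: does any lag-p window of span >= min_span reach the
    identity threshold?  (cumulative-sum scan over all starts)."""
    import numpy as np

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    for p in range(2, max_period + 1):
        if n < min_span or n < 2 * p:
            continue
        m = (arr[p:] == arr[:-p]).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(m)])
        min_run = max(min_span, 2 * p) - p
        for start in range(0, len(m) - min_run + 1):
            lens = np.arange(min_run, len(m) - start + 1)
            matches = cs[start + lens] - cs[start]
            if np.any(matches / lens >= min_identity):
                return True
    return False
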