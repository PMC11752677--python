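"""Intracellularly transferred DNA: MTPTs and NUMTs.

Plant mitogenomes accumulate plastome-derived insertions (MTPTs) and share
sequence with the nuclear genome (NUMTs).  Both are detected as significant
local alignments between a recipient and a donor genome (E-value <= 1e-5,
span >= 30 bp, BLASTN), labelled by descending length; each alignment is one
fragment — overlapping hits are deliberately not merged, so fragment counts
and contained-gene lists can coexist in the same bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._blast import blastn
from .genome import CircularGenome, Feature


@dataclass(frozen=True)
class HomologyFragment:
    """One donor->recipient alignment; coordinates 1-based inclusive, donor
    coordinates given on the plus strand with ``strand`` recording
    orientation."""

    label: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    length: int
    identity: float              # percent
    evalue: float
    strand: str
    donor_id: str = ""


@dataclass
class TransferSummary:
    fragment_count: int
    total_bases: int
    pct_of_recipient: float
    pct_of_donor: float
    complete_genes: list[str] = field(default_factory=list)


def find_homologous_fragments(
    recipient: CircularGenome,
    donor: CircularGenome,
    evalue_cutoff: float = 1e-5,
    min_len: int = 30,
    label_prefix: str = "MTPT",
) -> list[HomologyFragment]:
    """Significant recipient/donor local alignments, longest first.

    When recipient and donor are the same sequence, the trivial full-length
    self-alignment is excluded.
    """
    hits = blastn(
        [(recipient.id or "recipient", recipient.sequence)],
        [(donor.id or "donor", donor.sequence)],
        evalue=evalue_cutoff,
    )
    self_compare = recipient.sequence == donor.sequence
    frags = []
    for h in hits:
        if h.evalue > evalue_cutoff or h.length < min_len:
            continue
        if self_compare and (h.qstart, h.qend) == tuple(sorted((h.sstart, h.send))) \
                and h.length >= len(recipient):
            continue
        s_lo, s_hi = sorted((h.sstart, h.send))
        frags.append((h.qstart, h.qend, s_lo, s_hi, h.length, h.pident, h.evalue, h.strand))
    frags.sort(key=lambda f: (-f[4], f[0], f[2]))
    return [
        HomologyFragment(f"{label_prefix}{i + 1}", *f, donor_id=donor.id)
        for i, f in enumerate(frags)
    ]


def find_homologous_fragments_multi(
    recipient: CircularGenome,
    donors: list[CircularGenome],
    evalue_cutoff: float = 1e-5,
    min_len: int = 30,
    label_prefix: str = "NUMT",
) -> list[HomologyFragment]:
    """Same search against a multi-record donor assembly (e.g. nuclear
    chromosomes); per-record donor coordinates, labels global by length."""
    raw: list[HomologyFragment] = []
    for donor in donors:
        raw.extend(
            find_homologous_fragments(recipient, donor, evalue_cutoff, min_len, "TMP")
        )
    raw.sort(key=lambda f: (-f.length, f.q_start, f.s_start))
    return [
        HomologyFragment(f"{label_prefix}{i + 1}", f.q_start, f.q_end, f.s_start,
                         f.s_end, f.length, f.identity, f.evalue, f.strand, f.donor_id)
        for i, f in enumerate(raw)
    ]


def annotate_complete_genes(
    fragments: list[HomologyFragment], donor_features: list[Feature]
) -> list[tuple[str, str, bool]]:
    """Genes overlapping each fragment on donor coordinates; ``complete`` when
    every exon part lies inside the fragment's donor span."""
    out = []
    for frag in fragments:
        for feat in donor_features:
            overlaps = any(s <= frag.s_end and e >= frag.s_start for s, e in feat.parts)
            if not overlaps:
                continue
            complete = all(
                frag.s_start <= s and e <= frag.s_end for s, e in feat.parts
            )
            out.append((frag.label, feat.gene, complete))
    return out


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e + 1:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + cur_e - cur_s + 1


def summarize_transfer(
    fragments: list[HomologyFragment],
    recipient_len: int,
    donor_len: int,
    annotations: list[tuple[str, str, bool]] | None = None,
) -> TransferSummary:
    """Union of recipient intervals and its share of both genomes (2 dp)."""
    union_q = _interval_union([(f.q_start, f.q_end) for f in fragments])
    union_s = _interval_union([(f.s_start, f.s_end) for f in fragments])
    complete = sorted({g for _, g, c in (annotations or []) if c})
    return TransferSummary(
        fragment_count=len(fragments),
        total_bases=union_q,
        pct_of_recipient=round(100.0 * union_q / recipient_len, 2),
        pct_of_donor=round(100.0 * union_s / donor_len, 2),
        complete_genes=complete,
    )


def fragments_to_frame(fragments: list[HomologyFragment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": f.label, "recipient_start": f.q_start, "recipient_end": f.q_end,
                "donor_start": f.s_start, "donor_end": f.s_end, "length": f.length,
                "identity_pct": f.identity, "evalue": f.evalue, "strand": f.strand,
                "donor": f.donor_id,
            }
            for f in fragments
        ]
    )
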