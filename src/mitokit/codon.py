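"""Codon counting and relative synonymous codon usage (RSCU).

RSCU for codon *c* in a synonymous family *F* is the observed count divided by
the count expected under uniform usage within the family:

    RSCU(c) = count(c) * |F| / sum_{c' in F} count(c')

so a value of 1 means no bias, values above 1 a preferred codon.  Plant
mitochondria translate with the standard genetic code; the three stop codons
are treated as one synonymous family by default so that stop-codon bias (a
commonly reported quantity for organelle gene sets) is defined.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

RNA_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("UCAG", repeat=3)
)


def _families(code_table: str, include_stops: bool) -> dict[str, tuple[str, ...]]:
    """Map amino acid (one-letter, '*' for stop) -> its RNA codon family."""
    if code_table != "standard":
        try:
            table = CodonTable.unambiguous_rna_by_name[code_table]
        except KeyError as exc:
            raise ValueError(f"unknown genetic code table: {code_table!r}") from exc
    else:
        table = CodonTable.unambiguous_rna_by_id[1]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    if include_stops:
        fams["*"] = list(table.stop_codons)
    return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


def count_codons(coding_seqs: list[str]) -> dict[str, int]:
    """Count codons over a set of coding sequences, reported as RNA codons.

    Sequences must have length divisible by 3 (guaranteed upstream by PCG
    extraction trimming).  Codons containing N are skipped with a warning.
    """
    counts = {c: 0 for c in RNA_CODONS}
    skipped = 0
    for seq in coding_seqs:
        if len(seq) % 3:
            raise ValueError(f"coding sequence length {len(seq)} not divisible by 3")
        rna = seq.upper().replace("T", "U")
        for i in range(0, len(rna), 3):
            codon = rna[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            elif "N" in codon:
                skipped += 1
            else:
                raise ValueError(f"invalid codon {codon!r}")
    if skipped:
        warnings.warn(f"skipped {skipped} codon(s) containing N")
    return counts


@dataclass
class CodonUsageTable:
    """Codon counts with per-codon RSCU over a chosen genetic code."""

    counts: dict[str, int]
    rscu: dict[str, float]
    code_table: str = "standard"
    include_stops: bool = True
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: codon, amino acid (3-letter), count, RSCU (2 dp)."""
        rows = []
        for aa, fam in sorted(self.families.items()):
            name = "Ter" if aa == "*" else seq3(aa)
            for codon in fam:
                rows.append(
                    {
                        "codon": codon,
                        "amino_acid": name,
                        "count": self.counts[codon],
                        "rscu": round(self.rscu[codon], 2),
                    }
                )
        return pd.DataFrame(rows)


def compute_rscu(
    counts: dict[str, int],
    code_table: str = "standard",
    include_stops: bool = True,
) -> CodonUsageTable:
    """RSCU per codon; families with zero total get 0 for every member."""
    fams = _families(code_table, include_stops)
    rscu = {c: 0.0 for c in RNA_CODONS}
    for fam in fams.values():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            continue
        for c in fam:
            rscu[c] = counts.get(c, 0) * len(fam) / total
    return CodonUsageTable(dict(counts), rscu, code_table, include_stops, fams)


def rank_amino_acids(
    counts: dict[str, int], code_table: str = "standard"
) -> list[tuple[str, int]]:
    """Amino acids by total codon count, descending; ties alphabetical by
    three-letter code.  Stops are not amino acids and are excluded; zero-count
    amino acids are omitted."""
    fams = _families(code_table, include_stops=False)
    totals = []
    for aa, fam in fams.items():
        total = sum(counts.get(c, 0) for c in fam)
        if total > 0:
            totals.append((seq3(aa), total))
    totals.sort(key=lambda t: (-t[1], t[0]))
    return totals
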