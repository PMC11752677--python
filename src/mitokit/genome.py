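"""Sequence, annotation and read I/O with circular-coordinate arithmetic.

All coordinates in this package are 1-based and inclusive, matching the
convention of published organelle-genome coordinates.  A circular genome
supports extraction across the origin by giving ``start > end``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC = set("ACGTNRYSWKMBDHV")

Strand = Literal["+", "-"]
Topology = Literal["circular", "linear"]


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Complement without reversal (used for the 'complement' repeat class)."""
    return seq.translate(_COMPLEMENT)


@dataclass(frozen=True)
class CircularGenome:
    """A single DNA molecule with circular or linear topology.

    ``sequence`` is uppercase A/C/G/T/N; positions are 1-based inclusive.
    """

    id: str
    sequence: str
    topology: Topology = "circular"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in genome {self.id}: {sorted(bad)}")
        if not self.sequence:
            raise ValueError(f"empty sequence for genome {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_content(self) -> float:
        """Fraction of G+C over A/C/G/T (N excluded from the denominator)."""
        s = self.sequence
        acgt = sum(s.count(b) for b in "ACGT")
        return (s.count("G") + s.count("C")) / acgt if acgt else 0.0

    def base_composition(self) -> dict[str, float]:
        """Per-base percentages of A, T, C, G over the full length."""
        n = len(self.sequence)
        return {b: 100.0 * self.sequence.count(b) / n for b in "ATCG"}


@dataclass(frozen=True)
class Feature:
    """A gene model: ordered exon parts on 1-based inclusive coordinates."""

    gene: str
    kind: Literal["PCG", "tRNA", "rRNA", "other"]
    strand: Strand
    parts: tuple[tuple[int, int], ...]
    copy_index: int = 1

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"feature {self.gene} has no parts")

    @property
    def start(self) -> int:
        return self.parts[0][0]


@dataclass(frozen=True)
class LongRead:
    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty read {self.id}")


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in record {record_id}: {sorted(bad)}")
    ambiguous = set(seq) - set("ACGTN")
    if ambiguous:
        warnings.warn(
            f"record {record_id}: IUPAC ambiguity codes {sorted(ambiguous)} replaced by N"
        )
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return "fasta"
    if first.startswith("LOCUS"):
        return "genbank"
    raise ValueError(f"cannot determine format of {path} (expected FASTA or GenBank)")


def read_genome(path: str | Path, topology: Topology = "circular") -> CircularGenome:
    """Read a single-record FASTA or GenBank flat file as a genome.

    Multi-record files are rejected; the sequence is uppercased and IUPAC
    ambiguity codes outside A/C/G/T/N become N with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(path, _sniff_format(path)))
    if len(records) != 1:
        raise ValueError(f"{path} holds {len(records)} records; exactly one expected")
    rec = records[0]
    if len(rec.seq) == 0:
        raise ValueError(f"empty record in {path}")
    return CircularGenome(rec.id, _clean_sequence(str(rec.seq), rec.id), topology)


def write_genome(genome: CircularGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


_KINDS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def _features_from_genbank(path: Path) -> list[Feature]:
    rec = next(SeqIO.parse(path, "genbank"))
    out: list[Feature] = []
    for feat in rec.features:
        kind = _KINDS.get(feat.type)
        if kind is None:
            continue
        gene = feat.qualifiers.get("gene", feat.qualifiers.get("product", ["?"]))[0]
        strand = "-" if feat.location.strand == -1 else "+"
        parts = tuple(
            (int(p.start) + 1, int(p.end)) for p in sorted(feat.location.parts, key=lambda p: p.start)
        )
        out.append(Feature(gene, kind, strand, parts))
    return _assign_copy_indices(out)


def _features_from_table(path: Path) -> list[Feature]:
    """6-column TSV/CSV gene model: gene, kind, strand, part-starts, part-ends, copy.

    Part lists are ';'-separated; copy is optional (defaults assigned by order).
    """
    out: list[Feature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene"):
                continue
            cols = line.split("\t") if "\t" in line else line.split(",")
            if len(cols) < 5:
                raise ValueError(f"{path}:{ln}: expected >=5 columns, got {len(cols)}")
            gene, kind, strand = cols[0], cols[1], cols[2]
            starts = [int(x) for x in cols[3].split(";")]
            ends = [int(x) for x in cols[4].split(";")]
            if len(starts) != len(ends):
                raise ValueError(f"{path}:{ln}: part-start/part-end count mismatch")
            for s, e in zip(starts, ends):
                if e < s:
                    raise ValueError(f"{path}:{ln}: end {e} < start {s} on a part")
            copy = int(cols[5]) if len(cols) > 5 and cols[5].strip() else 0
            out.append(
                Feature(gene, kind, strand, tuple(zip(starts, ends)), copy or 1)  # type: ignore[arg-type]
            )
    return _assign_copy_indices(out)


def _assign_copy_indices(features: list[Feature]) -> list[Feature]:
    seen: dict[str, int] = {}
    out = []
    for f in features:
        seen[f.gene] = seen.get(f.gene, 0) + 1
        out.append(Feature(f.gene, f.kind, f.strand, f.parts, seen[f.gene]))
    return out


def read_features(path: str | Path) -> list[Feature]:
    """Read gene models from a GenBank flat file or the 6-column table dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("LOCUS"):
        return _features_from_genbank(path)
    return _features_from_table(path)


def write_features(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tkind\tstrand\tpart_starts\tpart_ends\tcopy\n")
        for f in features:
            fh.write(
                f"{f.gene}\t{f.kind}\t{f.strand}\t"
                f"{';'.join(str(s) for s, _ in f.parts)}\t"
                f"{';'.join(str(e) for _, e in f.parts)}\t{f.copy_index}\n"
            )


def read_fastq(path: str | Path) -> list[LongRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations.get("phred_quality", ()))
        reads.append(LongRead(rec.id, str(rec.seq).upper(), quals or None))
    return reads


def write_fastq(reads: Iterable[LongRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities or (30,) * len(r.sequence)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qstr}\n")


def subsequence(genome: CircularGenome, start: int, end: int, strand: Strand = "+") -> str:
    """Extract bases ``start..end`` (1-based inclusive); ``start > end`` wraps a
    circular genome through the origin; minus strand returns the reverse
    complement of the plus-strand extraction."""
    n = len(genome)
    if not (1 <= start <= n and 1 <= end <= n):
        raise IndexError(f"coordinates ({start},{end}) out of range 1..{n}")
    if start <= end:
        seg = genome.sequence[start - 1 : end]
    else:
        if genome.topology != "circular":
            raise ValueError("origin-wrapping extraction requested on a linear genome")
        seg = genome.sequence[start - 1 :] + genome.sequence[:end]
    return revcomp(seg) if strand == "-" else seg


def extract_pcg_sequences(
    genome: CircularGenome, features: Iterable[Feature]
) -> dict[str, str]:
    """Concatenate exon parts of protein-coding genes into coding sequences.

    Keys are ``gene`` or ``gene.copyN`` for multi-copy genes.  Parts are joined
    in annotation order, reverse-complemented for minus-strand genes; a trailing
    partial codon is trimmed with a warning (plant mitochondrial annotations
    include edited and exceptional genes; non-AUG starts are accepted).
    """
    out: dict[str, str] = {}
    for f in features:
        if f.kind != "PCG":
            continue
        seq = "".join(subsequence(genome, s, e, "+") for s, e in f.parts)
        if f.strand == "-":
            seq = revcomp(seq)
        if len(seq) % 3:
            log.warning(
                "PCG %s length %d not divisible by 3; trimming %d trailing base(s)",
                f.gene, len(seq), len(seq) % 3,
            )
            seq = seq[: len(seq) - len(seq) % 3]
        key = f.gene if f.copy_index == 1 else f"{f.gene}.copy{f.copy_index}"
        out[key] = seq
    return out


def translate(seq: str, table: int = 1) -> str:
    """Translate a coding sequence (convenience wrapper, standard code)."""
    return str(Seq(seq).translate(table=table))
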