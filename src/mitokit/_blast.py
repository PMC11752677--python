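"""Thin wrapper around the NCBI BLASTN command line used for homology search.

`blastn -task blastn` (word size 11, match/mismatch +1/-2) is run in
query/subject mode with low-complexity filtering off, so results are
deterministic functions of the input sequences and thresholds.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

_FIELDS = "qseqid sseqid qstart qend sstart send length pident evalue bitscore"


@dataclass(frozen=True)
class BlastHit:
    qseqid: str
    sseqid: str
    qstart: int
    qend: int
    sstart: int
    send: int
    length: int
    pident: float
    evalue: float
    bitscore: float

    @property
    def strand(self) -> str:
        return "-" if self.sstart > self.send else "+"


def _write_fasta(records: Sequence[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def blastn(
    query: Sequence[tuple[str, str]],
    subject: Sequence[tuple[str, str]],
    evalue: float = 10.0,
    task: str = "blastn",
) -> list[BlastHit]:
    """All local alignments of query records against subject records."""
    if shutil.which("blastn") is None:
        raise RuntimeError("blastn executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath, spath = Path(tmp, "q.fa"), Path(tmp, "s.fa")
        _write_fasta(query, qpath)
        _write_fasta(subject, spath)
        proc = subprocess.run(
            [
                "blastn", "-task", task,
                "-query", str(qpath), "-subject", str(spath),
                "-evalue", str(evalue),
                "-dust", "no", "-soft_masking", "false",
                "-outfmt", f"6 {_FIELDS}",
            ],
            capture_output=True, text=True, check=True,
        )
    hits = []
    for line in proc.stdout.splitlines():
        c = line.split("\t")
        hits.append(
            BlastHit(
                c[0], c[1], int(c[2]), int(c[3]), int(c[4]), int(c[5]),
                int(c[6]), float(c[7]), float(c[8]), float(c[9]),
            )
        )
    return hits
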