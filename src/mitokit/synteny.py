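"""Pairwise mitogenome collinearity and shared-PCG matrix export.

Collinear blocks are local alignments >= 500 bp between two mitogenomes
(inverted when the strands differ); block order differences between genomes
reveal rearrangement.  The shared-PCG matrix takes the intersection of
protein-coding gene names across genomes and exports per-gene sequences plus
a concatenated supermatrix with a partition table for external alignment and
tree building — multiple sequence alignment and phylogenetics themselves are
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._blast import blastn
from .genome import CircularGenome, Feature, extract_pcg_sequences

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CollinearBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str             # same | inverted
    length: int
    identity: float              # percent


@dataclass
class SharedGeneMatrix:
    genes: list[str]                            # alphabetical concatenation order
    sequences: dict[str, dict[str, str]]        # species -> gene -> CDS

    def concatenated(self) -> dict[str, str]:
        return {
            sp: "".join(seqs[g] for g in self.genes) for sp, seqs in self.sequences.items()
        }


def find_collinear_blocks(
    a: CircularGenome, b: CircularGenome, min_block: int = 500
) -> list[CollinearBlock]:
    """Local alignments of span >= ``min_block`` between two genomes,
    sorted by position on genome a."""
    a_id = a.id or "a"
    b_id = b.id if (b.id and b.id != a.id) else "b"
    hits = blastn([(a_id, a.sequence)], [(b_id, b.sequence)])
    blocks = []
    for h in hits:
        if h.length < min_block:
            continue
        b_lo, b_hi = sorted((h.sstart, h.send))
        blocks.append(
            CollinearBlock(
                h.qstart, h.qend, b_lo, b_hi,
                "inverted" if h.strand == "-" else "same",
                h.length, h.pident,
            )
        )
    blocks.sort(key=lambda blk: (blk.a_start, blk.b_start))
    return blocks


def extract_shared_pcgs(
    genomes: list[CircularGenome], features: list[list[Feature]]
) -> SharedGeneMatrix:
    """Intersection of PCG names across genomes, first copy by coordinate.

    Raises on an empty intersection; duplicated genes (two copies of atp1 and
    the like) contribute their first copy with a logged warning."""
    if len(genomes) < 2:
        raise ValueError("at least two genomes required")
    per_species: dict[str, dict[str, str]] = {}
    name_sets = []
    for genome, feats in zip(genomes, features):
        pcgs = sorted(
            (f for f in feats if f.kind == "PCG"), key=lambda f: (f.gene, f.start)
        )
        chosen: dict[str, Feature] = {}
        for f in pcgs:
            if f.gene in chosen:
                log.warning("%s: gene %s duplicated; first copy by coordinate used",
                            genome.id, f.gene)
                continue
            chosen[f.gene] = f
        firsts = [Feature(f.gene, f.kind, f.strand, f.parts, 1) for f in chosen.values()]
        seqs = extract_pcg_sequences(genome, firsts)
        per_species[genome.id] = {g: seqs[g] for g in chosen if g in seqs}
        name_sets.append(set(chosen))
    shared = sorted(set.intersection(*name_sets))
    if not shared:
        raise ValueError("empty intersection: no PCG shared by all genomes")
    return SharedGeneMatrix(
        genes=shared,
        sequences={sp: {g: seqs[g] for g in shared} for sp, seqs in per_species.items()},
    )


def write_supermatrix(matrix: SharedGeneMatrix, outdir: str | Path) -> None:
    """Per-gene FASTAs, concatenated supermatrix FASTA, and a RAxML-style
    partition table fixing the (alphabetical) gene order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes_dir = outdir / "genes"
    genes_dir.mkdir(exist_ok=True)
    for gene in matrix.genes:
        with open(genes_dir / f"{gene}.fasta", "w") as fh:
            for sp, seqs in matrix.sequences.items():
                fh.write(f">{sp}\n{seqs[gene]}\n")
    concat = matrix.concatenated()
    with open(outdir / "supermatrix.fasta", "w") as fh:
        for sp, seq in concat.items():
            fh.write(f">{sp}\n{seq}\n")
    # partition bounds follow the first species' gene lengths
    first = next(iter(matrix.sequences.values()))
    with open(outdir / "partitions.txt", "w") as fh:
        pos = 1
        for gene in matrix.genes:
            end = pos + len(first[gene]) - 1
            fh.write(f"DNA, {gene} = {pos}-{end}\n")
            pos = end + 1


def blocks_to_frame(blocks: list[CollinearBlock]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in blocks])
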