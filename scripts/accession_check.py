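#!/usr/bin/env python
"""Reproduce the published *Rubus idaeus* mitogenome statistics from locally
downloaded records.

This script needs data the repository does not ship: download the mitogenome
GenBank record PP003260 (with its feature table) and the plastome record
OR698909 (FASTA or GenBank), e.g. via NCBI efetch, then run

    python scripts/accession_check.py --mito PP003260.gb --plastome OR698909.fasta

It recomputes, on the real records: genome length and GC / base composition,
SSR count at MISA thresholds, the longest palindromic and forward dispersed
repeats with their positions, RSCU of the annotated PCGs (including the stop
codon UAA), MTPT fragment count and transferred totals at E <= 1e-5, and the
total dispersed-repeat count under the REPuter-style parameter profile
(Hamming distance 3, minimum 30 bp, top 5000).  Counts that depend on the
maximality definition of the repeat engine (the dispersed total) are printed
with that caveat.  The dispersed scan of a ~440 kb genome takes a few minutes
on one CPU.
"""

from __future__ import annotations

import argparse

from mitokit import (
    RepeatConfig, compute_rscu, count_codons, extract_pcg_sequences,
    find_dispersed_repeats, find_homologous_fragments, find_ssrs,
    read_features, read_genome, summarize_transfer,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--mito", required=True,
                        help="PP003260 GenBank flat file (sequence + features)")
    parser.add_argument("--plastome", required=True,
                        help="OR698909 FASTA or GenBank flat file")
    args = parser.parse_args()

    mito = read_genome(args.mito, topology="circular")
    print(f"mitogenome length: {len(mito):,} bp")
    print(f"GC content: {100 * mito.gc_content():.1f}%")
    comp = mito.base_composition()
    print("base composition:", ", ".join(f"{b} {p:.2f}%" for b, p in comp.items()))

    features = read_features(args.mito)
    pcgs = [f for f in features if f.kind == "PCG"]
    print(f"annotated PCGs: {len(pcgs)}")
    seqs = extract_pcg_sequences(mito, pcgs)
    table = compute_rscu(count_codons(list(seqs.values())))
    print(f"RSCU(UAA) over PCGs: {table.rscu['UAA']:.2f}")

    ssrs = find_ssrs(mito)
    print(f"SSRs at MISA thresholds (no compound merging): {len(ssrs)}")

    cfg = RepeatConfig()
    dispersed = find_dispersed_repeats(mito, cfg)
    print(f"dispersed repeat pairs (engine-dependent maximality): {len(dispersed)}")
    for orientation in ("palindromic", "forward"):
        best = next((r for r in dispersed if r.orientation == orientation), None)
        if best:
            print(f"longest {orientation}: {best.length} bp at "
                  f"{best.start1:,}-{best.end1:,} / {best.start2:,}-{best.end2:,}")

    plastome = read_genome(args.plastome, topology="circular")
    print(f"plastome length: {len(plastome):,} bp")
    frags = find_homologous_fragments(mito, plastome)
    summary = summarize_transfer(frags, len(mito), len(plastome))
    print(f"MTPT fragments (E <= 1e-5, >= 30 bp): {len(frags)}")
    print(f"homologous total: {summary.total_bases:,} bp = "
          f"{summary.pct_of_recipient}% of the mitogenome, "
          f"{summary.pct_of_donor}% of the plastome")


if __name__ == "__main__":
    main()
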