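import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitokit import (
    CircularGenome, Feature,
    read_genome, write_genome, read_features, write_features,
    subsequence, extract_pcg_sequences, revcomp,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@pytest.mark.parametrize(
    "seq,start,end,strand,expected",
    [
        ("ACGTAC", 2, 4, "+", "CGT"),
        ("ACGTAC", 5, 2, "+", "ACAC"),          # wrap through the origin
        ("ACGTAC", 2, 4, "-", "ACG"),           # revcomp of CGT
        ("ACGTAC", 1, 6, "+", "ACGTAC"),
        ("ACGTAC", 6, 6, "+", "C"),
    ],
)
def test_subsequence(seq, start, end, strand, expected):
    g = CircularGenome("m", seq)
    assert subsequence(g, start, end, strand) == expected


def test_subsequence_errors():
    g = CircularGenome("m", "ACGTAC", topology="linear")
    with pytest.raises(ValueError):
        subsequence(g, 5, 2, "+")               # wrap on a linear genome
    with pytest.raises(IndexError):
        subsequence(g, 0, 3, "+")
    with pytest.raises(IndexError):
        subsequence(CircularGenome("m", "ACGT"), 1, 9, "+")


@settings(derandomize=True, max_examples=50)
@given(dna)
def test_revcomp_involution_and_full_extraction(seq):
    g = CircularGenome("m", seq)
    assert subsequence(g, 1, len(seq), "+") == seq
    assert revcomp(revcomp(seq)) == seq


@settings(derandomize=True, max_examples=50)
@given(dna, st.integers(1, 200), st.integers(1, 200))
def test_wrap_equals_doubled_string(seq, start, end):
    """Extraction across the origin equals the same slice on the doubled
    string at shifted coordinates."""
    n = len(seq)
    start, end = (start - 1) % n + 1, (end - 1) % n + 1
    g = CircularGenome("m", seq)
    length = (end - start) % n + 1
    assert subsequence(g, start, end, "+") == (seq + seq)[start - 1 : start - 1 + length]


def test_fasta_round_trip(tmp_path):
    g = CircularGenome("mito1", "ACGTN" * 20)
    path = tmp_path / "g.fasta"
    write_genome(g, path)
    back = read_genome(path, topology="circular")
    assert back.id == g.id and back.sequence == g.sequence


def test_read_genome_case_fold_and_errors(tmp_path):
    p = tmp_path / "l.fa"
    p.write_text(">m\nacgt\n")
    assert read_genome(p).sequence == "ACGT"
    multi = tmp_path / "two.fa"
    multi.write_text(">a\nACGT\n>b\nACGT\n")
    with pytest.raises(ValueError, match="records"):
        read_genome(multi)
    bad = tmp_path / "bad.fa"
    bad.write_text(">m\nACGZ\n")
    with pytest.raises(ValueError, match="non-IUPAC"):
        read_genome(bad)
    with pytest.raises(FileNotFoundError):
        read_genome(tmp_path / "absent.fa")


def test_ambiguity_codes_become_n(tmp_path):
    p = tmp_path / "amb.fa"
    p.write_text(">m\nACGRYT\n")
    with pytest.warns(UserWarning, match="ambiguity"):
        g = read_genome(p)
    assert g.sequence == "ACGNNT"


def test_feature_table_round_trip(tmp_path):
    path = tmp_path / "f.tsv"
    path.write_text(
        "gene\tkind\tstrand\tpart_starts\tpart_ends\tcopy\n"
        "cox1\tPCG\t+\t1000\t2583\t1\n"
        "nad5\tPCG\t-\t10;30\t20;40\t1\n"
        "atp1\tPCG\t+\t50\t70\t1\n"
        "atp1\tPCG\t+\t90\t110\t1\n"
    )
    feats = read_features(path)
    assert feats[0] == Feature("cox1", "PCG", "+", ((1000, 2583),), 1)
    assert feats[1].parts == ((10, 20), (30, 40)) and feats[1].strand == "-"
    # duplicate gene names get incrementing copy indices
    assert [f.copy_index for f in feats if f.gene == "atp1"] == [1, 2]
    out = tmp_path / "w.tsv"
    write_features(feats, out)
    assert read_features(out) == feats


def test_feature_table_rejects_reversed_part(tmp_path):
    path = tmp_path / "f.tsv"
    path.write_text("cox1\tPCG\t+\t200\t100\t1\n")
    with pytest.raises(ValueError, match="end"):
        read_features(path)


GENBANK = """LOCUS       toy                61 bp    DNA     circular PLN 01-JAN-2024
FEATURES             Location/Qualifiers
     CDS             complement(join(10..20,30..40))
                     /gene="nad1"
     tRNA            5..7
                     /gene="trnM"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 a
//
"""


def test_genbank_join_location(tmp_path):
    path = tmp_path / "toy.gb"
    path.write_text(GENBANK)
    feats = read_features(path)
    cds = next(f for f in feats if f.gene == "nad1")
    assert cds.kind == "PCG" and cds.strand == "-"
    assert cds.parts == ((10, 20), (30, 40))
    assert next(f for f in feats if f.gene == "trnM").kind == "tRNA"


def test_extract_pcg_sequences(toy_circle, caplog):
    g = toy_circle
    plus = Feature("g1", "PCG", "+", ((11, 19),))
    assert extract_pcg_sequences(g, [plus])["g1"] == subsequence(g, 11, 19, "+")
    # two-part minus-strand gene: revcomp of the concatenated parts
    minus = Feature("g2", "PCG", "-", ((101, 109), (121, 126)))
    expected = revcomp(subsequence(g, 101, 109, "+") + subsequence(g, 121, 126, "+"))
    assert extract_pcg_sequences(g, [minus])["g2"] == expected
    # trailing partial codon trimmed with a warning, non-PCG ignored
    import logging
    with caplog.at_level(logging.WARNING):
        seqs = extract_pcg_sequences(
            g, [Feature("g3", "PCG", "+", ((1, 10),)), Feature("t", "tRNA", "+", ((1, 9),))]
        )
    assert len(seqs["g3"]) == 9 and "t" not in seqs
    assert any("divisible" in r.message for r in caplog.records)


def test_planted_gene_recovered(planted_feature_study):
    genome, features, truth, config = planted_feature_study
    # re-plant a study with genes to compare against generator truth
    from mitokit import SimulationConfig, GeneSpec, generate_genome
    cfg = SimulationConfig(genome_len=20_000, seed=5,
                           genes=[GeneSpec("cox1", 300, "+"), GeneSpec("nad5", 303, "-")])
    g, feats, tr = generate_genome(cfg)
    seqs = extract_pcg_sequences(g, feats)
    assert set(seqs) == {"cox1", "nad5"}
    for name, seq in seqs.items():
        assert seq.startswith("ATG") and seq.endswith("TAA")
        assert len(seq) == next(s.length for s in cfg.genes if s.name == name)
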