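"""Synthetic circular mitogenomes with planted ground truth, and long-read
simulation from conformation mixtures.

The generator emulates the statistics of a mid-sized plant mitogenome
(circular, 44.1% GC by default) carrying planted microsatellites, tandem
repeats, dispersed repeat pairs of all four orientation classes (including
recombination-active pairs >= 200 bp), plastome-derived insertions with a
donor genome, and simple gene models.  Every planted feature is recorded in a
:class:`SyntheticTruth` manifest precise enough to score finder recall and
coordinates exactly.

Planted repeats are bordered by short divergence guards (forced mismatching
columns in the partner flanks, period-breaking bases around SSR/tandem runs)
so that the planted coordinates are exactly the matching-core coordinates a
maximal-repeat finder reports; without guards, chance flank matches would
extend every maximal window a few bases past the planted interval.

All randomness in a run flows from one seeded generator, so identical
configurations produce byte-identical genomes and FASTQ output.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome import CircularGenome, Feature, LongRead, revcomp, complement
from .recombination import Conformation

log = logging.getLogger(__name__)

_GUARD = 8          # forced-divergence columns flanking every planted repeat
_BASES = np.array(list("ACGT"))

_SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA", "ATG")
]


@dataclass(frozen=True)
class SSRSpec:
    motif: str
    copies: int


@dataclass(frozen=True)
class TandemSpec:
    period: int
    copies: int


@dataclass(frozen=True)
class DispersedSpec:
    length: int
    orientation: str                  # forward | reverse | complement | palindromic
    mismatches: int = 0


@dataclass(frozen=True)
class RecombPairSpec:
    length: int                       # >= 200 for recombination-active pairs
    orientation: str                  # direct | inverted
    identity: float = 1.0


@dataclass(frozen=True)
class TransferSpec:
    length: int
    identity: float = 1.0


@dataclass(frozen=True)
class GeneSpec:
    name: str
    length: int                       # coding length incl. start/stop, multiple of 3
    strand: str = "+"
    kind: str = "PCG"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Defaults give a 50 kb circle at the GC content typical of Rosaceae
    mitogenomes, with the three-pair recombination layout (two inverted, one
    direct, all >= 200 bp) used throughout the tests, a plastome-like 30 kb
    donor, and desk-scale Nanopore-like reads (log-normal lengths around
    8 kb, 5%% errors at substitutions:insertions:deletions = 2:1:1).
    """

    genome_len: int = 50_000
    gc_content: float = 0.441
    seed: int = 0
    ssrs: list[SSRSpec] = field(default_factory=list)
    tandems: list[TandemSpec] = field(default_factory=list)
    dispersed: list[DispersedSpec] = field(default_factory=list)
    recomb_pairs: list[RecombPairSpec] = field(default_factory=list)
    transfers: list[TransferSpec] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)
    donor_len: int = 30_000
    codon_weights: dict[str, float] | None = None
    read_count: int = 1000
    read_len_mean: float = 8000.0
    read_len_sigma: float = 0.4       # log-units
    read_error_rate: float = 0.05
    mixture_weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if self.mixture_weights and abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for s in self.ssrs:
            if not 1 <= len(s.motif) <= 6:
                raise ValueError("SSR motif unit length must be 1-6")
        for r in self.recomb_pairs:
            if r.orientation not in ("direct", "inverted"):
                raise ValueError("recomb pair orientation must be direct|inverted")


@dataclass(frozen=True)
class PlantedPair:
    orientation: str                  # dispersed-repeat orientation class
    start1: int
    end1: int
    start2: int
    end2: int
    mismatches: int


@dataclass(frozen=True)
class PlantedInterval:
    kind: str
    start: int
    end: int
    motif: str
    copies: float


@dataclass(frozen=True)
class PlantedTransfer:
    r_start: int
    r_end: int
    d_start: int
    d_end: int
    identity: float


@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    conformation: str
    molecule: int
    strand: str
    start: int                        # 1-based on the molecule
    length: int


@dataclass
class SyntheticTruth:
    """Manifest of every planted feature and simulation parameter."""

    config: SimulationConfig
    ssrs: list[PlantedInterval] = field(default_factory=list)
    tandems: list[PlantedInterval] = field(default_factory=list)
    dispersed: list[PlantedPair] = field(default_factory=list)
    recomb_pairs: list[PlantedPair] = field(default_factory=list)
    transfers: list[PlantedTransfer] = field(default_factory=list)
    genes: list[Feature] = field(default_factory=list)
    donor: CircularGenome | None = None
    reads: list[ReadOrigin] = field(default_factory=list)

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tdetail\n")
            for cat in ("ssrs", "tandems", "dispersed", "recomb_pairs", "transfers"):
                for item in getattr(self, cat):
                    fh.write(f"{cat}\t{asdict(item)}\n")
            for read in self.reads:
                fh.write(f"read\t{asdict(read)}\n")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=n, p=p)


class _Placer:
    """Non-overlapping interval allocation with guard margins."""

    def __init__(self, rng: np.random.Generator, n: int, margin: int = _GUARD + 4):
        self.rng = rng
        self.n = n
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def place(self, length: int) -> int:
        """A 0-based start such that [start-margin, start+length+margin) is free."""
        for _ in range(2000):
            start = int(self.rng.integers(self.margin, self.n - length - self.margin))
            lo, hi = start - self.margin, start + length + self.margin
            if all(hi <= s or lo >= e for s, e in self.taken):
                self.taken.append((lo, hi))
                return start
        raise ValueError("could not place a planted feature; genome too crowded")


def _mutate(rng: np.random.Generator, seq: str, k: int) -> tuple[str, list[int]]:
    """Substitute exactly k distinct positions with a different base."""
    arr = list(seq)
    positions = sorted(rng.choice(len(seq), size=k, replace=False).tolist()) if k else []
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[int(rng.integers(3))]
    return "".join(arr), positions


def _force_differ(arr: list[str], pos: int, other: str, rng: np.random.Generator) -> None:
    if 0 <= pos < len(arr) and arr[pos] == other:
        choices = [b for b in "ACGT" if b != other]
        arr[pos] = choices[int(rng.integers(3))]


_PAIR_TRANSFORM = {
    "forward": lambda s: s,
    "reverse": lambda s: s[::-1],
    "complement": complement,
    "palindromic": revcomp,
}


def generate_genome(
    config: SimulationConfig,
) -> tuple[CircularGenome, list[Feature], SyntheticTruth]:
    """Build the synthetic master circle, its gene models, and the truth.

    Background bases are i.i.d. at the configured GC; every planted feature
    is written at recorded coordinates with divergence guards; identical
    configurations produce identical sequences.
    """
    rng = np.random.default_rng(config.seed)
    n = config.genome_len
    arr = _random_bases(rng, n, config.gc_content).tolist()
    placer = _Placer(rng, n)
    truth = SyntheticTruth(config=config)
    features: list[Feature] = []

    for spec in config.ssrs:
        u = len(spec.motif)
        payload = spec.motif * spec.copies
        st = placer.place(len(payload))
        arr[st : st + len(payload)] = list(payload)
        _force_differ(arr, st - 1, spec.motif[u - 1], rng)
        _force_differ(arr, st + len(payload), spec.motif[0], rng)
        truth.ssrs.append(
            PlantedInterval("ssr", st + 1, st + len(payload), spec.motif, spec.copies)
        )

    for spec in config.tandems:
        # the unit must not hide a shorter-period array of its own, or the
        # overlap resolution of the finder would report the sub-period call
        unit = "".join(_random_bases(rng, spec.period, config.gc_content))
        while not (_primitive(unit) and _no_internal_tandem(unit)):
            unit = "".join(_random_bases(rng, spec.period, config.gc_content))
        payload = unit * spec.copies
        st = placer.place(len(payload))
        arr[st : st + len(payload)] = list(payload)
        en = st + len(payload) - 1
        for j in range(_GUARD):
            _force_differ(arr, st - 1 - j, arr[st - 1 - j + spec.period], rng)
            _force_differ(arr, en + 1 + j, arr[en + 1 + j - spec.period], rng)
        truth.tandems.append(
            PlantedInterval("tandem", st + 1, en + 1, unit, float(spec.copies))
        )

    pair_specs = [(s.length, s.orientation, s.mismatches, "dispersed") for s in config.dispersed]
    for s in config.recomb_pairs:
        orient = "forward" if s.orientation == "direct" else "palindromic"
        mism = round((1 - s.identity) * s.length)
        pair_specs.append((s.length, orient, mism, "recomb"))
    for length, orientation, mism, bucket in pair_specs:
        copy1 = "".join(_random_bases(rng, length, config.gc_content))
        transformed = _PAIR_TRANSFORM[orientation](copy1)
        copy2, _ = _mutate(rng, transformed, mism)
        p1 = placer.place(length)
        p2 = placer.place(length)
        if p2 < p1:
            p1, p2 = p2, p1
        arr[p1 : p1 + length] = list(copy1)
        arr[p2 : p2 + length] = list(copy2)
        _plant_pair_guards(arr, p1, p2, length, orientation, rng)
        planted = PlantedPair(orientation, p1 + 1, p1 + length, p2 + 1, p2 + length, mism)
        getattr(truth, "dispersed" if bucket == "dispersed" else "recomb_pairs").append(planted)

    donor = None
    if config.transfers:
        donor_arr = _random_bases(rng, config.donor_len, config.gc_content).tolist()
        donor_placer = _Placer(rng, config.donor_len)
        for spec in config.transfers:
            d_start = donor_placer.place(spec.length)
            segment = "".join(donor_arr[d_start : d_start + spec.length])
            mism = round((1 - spec.identity) * spec.length)
            mutated, _ = _mutate(rng, segment, mism)
            r_start = placer.place(spec.length)
            arr[r_start : r_start + spec.length] = list(mutated)
            truth.transfers.append(
                PlantedTransfer(
                    r_start + 1, r_start + spec.length,
                    d_start + 1, d_start + spec.length, spec.identity,
                )
            )
        donor = CircularGenome("synthetic_donor", "".join(donor_arr), "circular")
        truth.donor = donor

    for spec in config.genes:
        if spec.length % 3 or spec.length < 9:
            raise ValueError(f"gene {spec.name}: length must be a multiple of 3, >= 9")
        n_codons = spec.length // 3 - 2
        codons = _draw_codons(rng, n_codons, config.codon_weights)
        coding = "ATG" + "".join(codons) + "TAA"
        st = placer.place(spec.length)
        placed = revcomp(coding) if spec.strand == "-" else coding
        arr[st : st + spec.length] = list(placed)
        feat = Feature(spec.name, spec.kind, spec.strand, ((st + 1, st + spec.length),))  # type: ignore[arg-type]
        features.append(feat)
        truth.genes.append(feat)

    genome = CircularGenome("synthetic_mito", "".join(arr), "circular")
    return genome, features, truth


def _no_internal_tandem(unit: str, min_span: int = 9, min_identity: float = 0.85) -> bool:
    """True when no sub-period lag window inside the repeated unit reaches
    tandem-call thresholds (span >= max(min_span, 2p), identity >= 85%)."""
    s = unit * 3
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    for p in range(1, len(unit)):
        m = (arr[p:] == arr[:-p]).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(m)])
        min_run = max(min_span, 2 * p) - p
        if min_run <= 0 or len(m) < min_run:
            continue
        for start in range(0, len(m) - min_run + 1):
            lens = np.arange(min_run, len(m) - start + 1)
            if np.any((cs[start + lens] - cs[start]) / lens >= min_identity):
                return False
    return True


def _primitive(motif: str) -> bool:
    return all(
        not (len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d))
        for d in range(1, len(motif))
    )


def _draw_codons(rng, k: int, weights: dict[str, float] | None) -> list[str]:
    if weights:
        codons = sorted(weights)
        p = np.array([weights[c] for c in codons], dtype=float)
        p /= p.sum()
        return [codons[i] for i in rng.choice(len(codons), size=k, p=p)]
    return [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=k)]


def _plant_pair_guards(
    arr: list[str], p1: int, p2: int, length: int, orientation: str, rng
) -> None:
    """Force pair-mismatch columns just outside both planted copies, per the
    orientation class's extension geometry, so the planted interval is the
    exact matching core of its maximal window."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for j in range(_GUARD):
        if orientation in ("forward", "complement"):
            left1, left2 = p1 - 1 - j, p2 - 1 - j
            right1, right2 = p1 + length + j, p2 + length + j
        else:                                  # reverse / palindromic mirror
            left1, left2 = p1 - 1 - j, p2 + length + j
            right1, right2 = p1 + length + j, p2 - 1 - j
        for a, b in ((left1, left2), (right1, right2)):
            if 0 <= a < len(arr) and 0 <= b < len(arr):
                partner = arr[a]
                if orientation in ("complement", "palindromic"):
                    partner = comp[partner]
                _force_differ(arr, b, partner, rng)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    conformations: list[Conformation],
    config: SimulationConfig,
) -> tuple[list[LongRead], SyntheticTruth]:
    """Sample reads from a weighted mixture of conformations.

    Each read picks a conformation by mixture weight, a molecule by
    length-proportional probability, a uniform circular start and strand, and
    a log-normal length (truncated at the molecule length with a warning);
    substitution/insertion/deletion errors are applied at the configured rate
    in a 2:1:1 split.  Error rate 0 leaves every read an exact substring of
    the doubled molecule or its reverse complement.
    """
    if len(config.mixture_weights) != len(conformations):
        raise ValueError("mixture weights must match the conformation count")
    rng = np.random.default_rng(config.seed + 1)
    mu = float(np.log(config.read_len_mean))
    reads: list[LongRead] = []
    truth = SyntheticTruth(config=config)
    truncated = 0
    for i in range(config.read_count):
        ci = int(rng.choice(len(conformations), p=config.mixture_weights))
        conf = conformations[ci]
        lengths = np.array([len(m) for m in conf.molecules], dtype=float)
        mi = int(rng.choice(len(conf.molecules), p=lengths / lengths.sum()))
        mol = conf.molecules[mi]
        n = len(mol)
        length = int(round(rng.lognormal(mu, config.read_len_sigma)))
        length = max(50, length)
        if length > n:
            truncated += 1
            length = n
        start = int(rng.integers(0, n))
        raw = (mol + mol)[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = revcomp(raw)
        seq = _apply_errors(rng, raw, config.read_error_rate)
        rid = f"read{i:06d}"
        reads.append(LongRead(rid, seq))
        truth.reads.append(ReadOrigin(rid, conf.label, mi, strand, start + 1, length))
    if truncated:
        log.warning("%d read(s) longer than their molecule were truncated", truncated)
    return reads, truth


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    n_err = rng.binomial(n, rate)
    if n_err == 0:
        return seq
    positions = np.sort(rng.choice(n, size=n_err, replace=False))
    kinds = rng.choice(3, size=n_err, p=[0.5, 0.25, 0.25])   # sub, ins, del
    out = []
    prev = 0
    for pos, kind in zip(positions.tolist(), kinds.tolist()):
        out.append(seq[prev:pos])
        base = seq[pos]
        if kind == 0:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(3))])
        elif kind == 1:
            out.append(base + str(_BASES[int(rng.integers(4))]))
        # kind == 2: deletion, emit nothing
        prev = pos + 1
    out.append(seq[prev:])
    return "".join(out)
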