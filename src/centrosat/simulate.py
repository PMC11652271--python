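"""Synthetic centromere generator with planted ground truth.

Real alpha-satellite arrays are tandem runs of ~171-bp monomers: monomers of
one centromere share roughly 50-90% identity with each other, while copies of
the same higher-order repeat (HOR) unit share 95-100% identity.  The
generator emulates exactly that structure — a monomer set at a target
cross-identity, HOR units concatenated from a monomer pattern with per-base
mutations, optional locally nested subunit expansions, diploid samples built
from two allelic arrays, and HiFi-like 10-25 kb reads at a stated fold
coverage — and records the planted truth so every downstream stage can be
scored by parameter recovery.

Every function is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import SequenceRecord, reverse_complement, sequence_identity

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class NestingEvent:
    """A locally nested subunit expansion planted inside HOR units.

    ``subpattern`` must occur contiguously in the parent pattern; in every
    affected unit, ``extra_copies`` additional copies of it are spliced in
    immediately after its first occurrence.  ``locus`` is the fractional
    interval of the array (by unit index) that carries the expansion.
    """

    subpattern: tuple[int, ...]
    extra_copies: int = 1
    locus: tuple[float, float] = (0.4, 0.6)


@dataclass
class SimSpec:
    """Parameters of a synthetic centromere cohort.

    Defaults mirror the biology the generator emulates: 171-bp monomers,
    cross-monomer identity inside the 50-90% band, per-base substitution rate
    1% so HOR-unit copies share ~95-100% identity, HiFi-like 10-25 kb reads.
    """

    n_monomers: int = 5
    monomer_length: int = 171
    cross_identity: float = 0.70
    mutation_rate: float = 0.01
    indels: bool = False
    pattern: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_units: int = 200
    nesting: list[NestingEvent] = field(default_factory=list)
    flank_length: int = 50_000
    coverage: float = 30.0
    read_range: tuple[int, int] = (10_000, 25_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        lo, hi = self.read_range
        if not (1_000 <= lo <= hi <= 100_000):
            raise ValueError("read_range must lie within [1 kb, 100 kb]")


@dataclass
class UnitTruth:
    """One planted HOR unit: array interval, token content, expanded length."""

    index: int
    start: int
    end: int
    tokens: tuple[int, ...]


@dataclass
class ArrayTruth:
    monomers: dict[int, str]
    pattern: tuple[int, ...]
    units: list[UnitTruth]
    nesting: list[NestingEvent]

    @property
    def unit_count(self) -> int:
        return len(self.units)


@dataclass
class ReadTruth:
    source: str
    start: int
    end: int
    strand: str


@dataclass
class CohortSample:
    sample_id: str
    population: str
    genotype: str  # "AA" | "BB" | "AB"
    coverage: float
    hor_counts: dict[str, float]  # read-derived raw counts r_{j,k}
    reads: list[SequenceRecord] | None = None
    read_truth: list[ReadTruth] | None = None


def _rng(spec: SimSpec, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((spec.seed + salt) % (2**31))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator, indels: bool = False) -> str:
    """Per-base substitutions at ``rate``; optional indels at the same rate."""
    if rate <= 0:
        return seq
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    mask = rng.random(codes.size) < rate
    if mask.any():
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=int(mask.sum()))
        codes[mask] = (codes[mask] + shift) % 4
    out = _BASES[codes].tobytes().decode()
    if indels:
        chars = list(out)
        for pos in np.nonzero(rng.random(len(chars)) < rate)[0][::-1]:
            if rng.random() < 0.5:
                chars.pop(pos)
            else:
                chars.insert(pos, _BASES[rng.integers(0, 4)].tobytes().decode())
        out = "".join(chars)
    return out


def gen_monomers(spec: SimSpec, rng: np.random.Generator | None = None) -> tuple[dict[int, str], np.ndarray]:
    """Generate a monomer set at the spec's pairwise cross-identity target.

    A base monomer is sampled uniformly; each monomer is then derived from the
    base by substituting a calibrated number of positions so that the expected
    pairwise identity equals ``spec.cross_identity``.  Returns the monomer
    dict (ids 1..n) and the realized pairwise identity matrix.
    """
    if spec.n_monomers < 1:
        raise ValueError("need at least one monomer")
    rng = _rng(spec, 1) if rng is None else rng
    L = spec.monomer_length
    d = 1.0 - spec.cross_identity
    # two monomers mutated independently from the base at per-position rate p
    # differ at an expected fraction 2p(1-p) + (2/3)p^2 of positions
    disc = 4.0 - (16.0 / 3.0) * d
    if disc < 0:
        raise ValueError(f"cross-identity target {spec.cross_identity} unreachable")
    p = (3.0 / 8.0) * (2.0 - math.sqrt(disc))
    n_mut = int(round(p * L))
    if spec.n_monomers > 1 and n_mut == 0 and spec.cross_identity < 1.0:
        n_mut = 1
    base = _random_dna(rng, L)
    monomers: dict[int, str] = {}
    for mid in range(1, spec.n_monomers + 1):
        codes = _CODE[np.frombuffer(base.encode(), dtype=np.uint8)].copy()
        pos = rng.choice(L, size=n_mut, replace=False)
        codes[pos] = (codes[pos] + rng.integers(1, 4, size=n_mut)) % 4
        monomers[mid] = _BASES[codes].tobytes().decode()
    ids = sorted(monomers)
    ident = np.ones((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                ident[i, j] = ident[j, i] = sequence_identity(monomers[a], monomers[b])
    return monomers, ident


def _unit_token_lists(spec: SimSpec) -> list[tuple[int, ...]]:
    """Token content of every planted unit, after splicing nesting events."""
    units = [tuple(spec.pattern) for _ in range(spec.n_units)]
    for ev in spec.nesting:
        sub = tuple(ev.subpattern)
        k = len(sub)
        pat = tuple(spec.pattern)
        at = next(
            (i for i in range(len(pat) - k + 1) if pat[i : i + k] == sub), None
        )
        if at is None:
            raise ValueError(f"nesting subpattern {sub} not contiguous in pattern {pat}")
        lo = int(ev.locus[0] * spec.n_units)
        hi = int(ev.locus[1] * spec.n_units)
        for u in range(lo, hi):
            units[u] = pat[: at + k] + sub * ev.extra_copies + pat[at + k :]
    return units


def gen_array(
    spec: SimSpec,
    monomers: dict[int, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, ArrayTruth]:
    """Concatenate HOR units per the spec's pattern, with per-base mutations.

    Nesting events splice extra subpattern copies into the affected units.
    The truth records every unit's interval and token content.
    """
    rng = _rng(spec, 2) if rng is None else rng
    if monomers is None:
        monomers, _ = gen_monomers(spec, rng)
    missing = set(spec.pattern) - set(monomers)
    if missing:
        raise ValueError(f"pattern uses undefined monomer ids {sorted(missing)}")
    parts: list[str] = []
    units: list[UnitTruth] = []
    offset = 0
    for idx, tokens in enumerate(_unit_token_lists(spec)):
        unit_seq = "".join(monomers[t] for t in tokens)
        unit_seq = _mutate(unit_seq, spec.mutation_rate, rng, spec.indels)
        units.append(UnitTruth(idx, offset, offset + len(unit_seq), tokens))
        parts.append(unit_seq)
        offset += len(unit_seq)
    truth = ArrayTruth(monomers=monomers, pattern=tuple(spec.pattern), units=units, nesting=list(spec.nesting))
    return "".join(parts), truth


def gen_reads(
    haplotypes: list[tuple[str, str]],
    coverage: float,
    read_range: tuple[int, int] = (10_000, 25_000),
    rng: np.random.Generator | None = None,
    seed: int = 0,
    materialize: bool = True,
) -> tuple[list[SequenceRecord], list[ReadTruth]]:
    """Sample reads to the stated fold coverage; exactly half reverse-complemented.

    ``haplotypes`` are (name, sequence) pairs; reads are drawn uniformly over
    total bases, with lengths uniform in ``read_range`` (clipped to the source
    length).  Per-read truth records source, interval and strand.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    lo, hi = read_range
    lengths = np.array([len(s) for _, s in haplotypes], dtype=float)
    if lengths.sum() == 0:
        return [], []
    target = coverage * lengths.sum()
    probs = lengths / lengths.sum()
    reads: list[SequenceRecord] = []
    truth: list[ReadTruth] = []
    total = 0.0
    i = 0
    while total < target:
        h = int(rng.choice(len(haplotypes), p=probs))
        name, seq = haplotypes[h]
        rl = int(rng.integers(lo, hi + 1))
        rl = min(rl, len(seq))
        start = int(rng.integers(0, len(seq) - rl + 1))
        truth.append(ReadTruth(name, start, start + rl, "+"))
        total += rl
        i += 1
    # reverse-complement exactly half of the set
    order = rng.permutation(len(truth))
    for j in order[: len(truth) // 2]:
        truth[j].strand = "-"
    if materialize:
        seqs = {name: seq for name, seq in haplotypes}
        for j, t in enumerate(truth):
            sub = seqs[t.source][t.start : t.end]
            if t.strand == "-":
                sub = reverse_complement(sub)
            reads.append(SequenceRecord(id=f"read_{j}", bases=sub, description=f"{t.source}:{t.start}-{t.end}({t.strand})"))
    return reads, truth


def gen_chromosome(
    spec: SimSpec,
    name: str = "chr1",
    rng: np.random.Generator | None = None,
) -> tuple[SequenceRecord, tuple[int, int], ArrayTruth]:
    """One chromosome: random flank + satellite array + random flank.

    Returns the record, the satellite interval in chromosome coordinates, and
    the array truth.  Flanks give classifier training a source of negatives.
    """
    rng = _rng(spec, 3) if rng is None else rng
    array, truth = gen_array(spec, rng=rng)
    left = _random_dna(rng, spec.flank_length)
    right = _random_dna(rng, spec.flank_length)
    rec = SequenceRecord(id=name, bases=left + array + right)
    return rec, (len(left), len(left) + len(array)), truth


def _count_covered_units(
    unit_starts: np.ndarray, unit_ends: np.ndarray, read_truth: list[ReadTruth], source: str
) -> int:
    """Total planted units fully contained in sampled reads from ``source``.

    This is the raw count an annotator would report from those reads: every
    read contributes each unit it fully contains, so overlapping reads count
    units repeatedly — which is exactly why downstream counts are normalized
    by coverage.
    """
    n = 0
    for t in read_truth:
        if t.source != source:
            continue
        lo = int(np.searchsorted(unit_starts, t.start, side="left"))
        hi = int(np.searchsorted(unit_ends, t.end, side="right"))
        if hi > lo:
            n += hi - lo
    return n


def gen_cohort(
    spec_a: SimSpec,
    spec_b: SimSpec,
    genotypes: list[str],
    populations: list[str] | None = None,
    coverage: float = 10.0,
    read_range: tuple[int, int] = (10_000, 25_000),
    seed: int = 0,
    materialize_reads: bool = False,
) -> tuple[list[CohortSample], dict[str, ArrayTruth]]:
    """Diploid cohort over one locus with two allelic arrays A and B.

    AA/BB samples carry two copies of one allele's array, AB one of each.
    Reads are sampled per sample at ``coverage`` over the diploid locus; each
    sample's HOR counts are derived from the sampled read intervals (units
    fully contained in reads), mirroring read-based annotation output.
    """
    rng = np.random.default_rng(seed % (2**31))
    arr_a, truth_a = gen_array(spec_a, rng=np.random.default_rng((seed + 11) % (2**31)))
    arr_b, truth_b = gen_array(spec_b, rng=np.random.default_rng((seed + 13) % (2**31)))
    arrays = {"A": (arr_a, truth_a), "B": (arr_b, truth_b)}
    starts = {k: np.array([u.start for u in t.units]) for k, (_, t) in arrays.items()}
    ends = {k: np.array([u.end for u in t.units]) for k, (_, t) in arrays.items()}
    if populations is None:
        populations = ["pop0"] * len(genotypes)
    samples: list[CohortSample] = []
    for s, (gt, pop) in enumerate(zip(genotypes, populations)):
        if gt not in ("AA", "BB", "AB"):
            raise ValueError(f"genotype {gt!r} not in AA/BB/AB")
        haps = [(f"hap1_{gt[0]}", arrays[gt[0]][0]), (f"hap2_{gt[1]}", arrays[gt[1]][0])]
        reads, rtruth = gen_reads(
            haps, coverage, read_range, rng=np.random.default_rng((seed + 1000 + s) % (2**31)),
            materialize=materialize_reads,
        )
        counts: dict[str, float] = {"A": 0.0, "B": 0.0}
        for hap_name, _ in haps:
            allele = hap_name[-1]
            counts[allele] += _count_covered_units(starts[allele], ends[allele], rtruth, hap_name)
        samples.append(
            CohortSample(
                sample_id=f"S{s:03d}",
                population=pop,
                genotype=gt,
                coverage=coverage,
                hor_counts=counts,
                reads=reads if materialize_reads else None,
                read_truth=rtruth,
            )
        )
    return samples, {"A": truth_a, "B": truth_b}
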