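"""Locate alpha-satellite regions in an assembly and build satellite arrays.

The ~171-bp alpha-satellite template is scanned against each chromosome on
both strands with a windowed infix aligner (an aligner-agnostic contract; an
adapter ingests externally produced hit tables).  Hits closer than 5 kb are
merged into candidate regions, merged regions shorter than 10 kb are
discarded, and the surviving regions of a chromosome are concatenated — in
coordinate order, minus-strand regions reverse-complemented into plus
orientation — into its satellite array.  Junction offsets ("break" track)
and a provenance map back to assembly coordinates are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .core_io import GenomicInterval, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

MERGE_GAP = 5_000  # hits closer than this merge into one region
MIN_REGION = 10_000  # merged regions shorter than this are discarded
DEFAULT_IDENTITY_FLOOR = 0.70


@dataclass
class TemplateHit:
    interval: GenomicInterval
    identity: float
    strand: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


@dataclass
class SatelliteArray:
    """Concatenated alpha-satellite regions of one chromosome.

    ``junctions`` are the offsets in concatenated coordinates where regions
    abut (the "break" track); ``regions`` keep assembly coordinates and the
    orientation each region was spliced in with.
    """

    chrom: str
    regions: list[GenomicInterval]
    sequence: str
    junctions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(len(r) for r in self.regions)
        if total != len(self.sequence):
            raise ValueError("region lengths do not sum to sequence length")
        if len(self.junctions) != max(len(self.regions) - 1, 0):
            raise ValueError("junction count must be region count - 1")

    def to_assembly_coord(self, offset: int) -> tuple[int, str]:
        """Map a concatenated offset to (assembly coordinate, strand)."""
        if not 0 <= offset < len(self.sequence):
            raise IndexError(offset)
        base = 0
        for region in self.regions:
            if offset < base + len(region):
                within = offset - base
                if region.strand == "+":
                    return region.start + within, "+"
                return region.end - 1 - within, "-"
            base += len(region)
        raise IndexError(offset)  # pragma: no cover

    def to_array_coord(self, position: int) -> int:
        """Map an assembly coordinate inside some region to the array offset."""
        base = 0
        for region in self.regions:
            if region.start <= position < region.end:
                if region.strand == "+":
                    return base + (position - region.start)
                return base + (region.end - 1 - position)
            base += len(region)
        raise IndexError(position)


def scan_template_hits(
    assembly: list[SequenceRecord],
    template: SequenceRecord | str,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    window_factor: float = 2.0,
) -> list[TemplateHit]:
    """Scan the template against both strands of every record.

    Windowed infix alignment: windows of ``window_factor * len(template)``
    advanced by half a template length; a window whose best infix alignment
    of the template reaches the identity floor yields a hit at the aligned
    interval.  Exact tandem tracts therefore produce overlapping/abutting
    hits covering the tract.
    """
    tseq = template.sequence if hasattr(template, "sequence") else (
        template.bases if isinstance(template, SequenceRecord) else str(template)
    )
    m = len(tseq)
    max_dist = int((1.0 - identity_floor) * m)
    win = max(int(window_factor * m), m + max_dist)
    step = max(m // 2, 1)
    hits: list[TemplateHit] = []
    queries = {"+": tseq, "-": reverse_complement(tseq)}
    for rec in assembly:
        n = len(rec.bases)
        for start in range(0, max(n - m + 1, 1), step):
            chunk = rec.bases[start : start + win]
            if len(chunk) < m // 2:
                continue
            for strand, q in queries.items():
                res = edlib.align(q, chunk, mode="HW", task="locations", k=max_dist)
                if res["editDistance"] < 0:
                    continue
                identity = 1.0 - res["editDistance"] / m
                s, e = res["locations"][0]
                hits.append(
                    TemplateHit(
                        GenomicInterval(rec.id, start + s, start + e + 1, strand=strand),
                        identity=identity,
                        strand=strand,
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end))
    return hits


def read_hit_table(path: str | Path) -> list[TemplateHit]:
    """Adapter for externally produced hit tables.

    Tab-separated columns: chrom, start, end, identity (0-1 or percent),
    strand.  Lines starting with ``#`` are ignored.
    """
    hits: list[TemplateHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, ident, strand = line.split("\t")[:5]
            identity = float(ident)
            if identity > 1.0:
                identity /= 100.0
            hits.append(
                TemplateHit(
                    GenomicInterval(chrom, int(start), int(end), strand=strand),
                    identity=identity,
                    strand=strand,
                )
            )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end))
    return hits


def merge_hits(
    hits: list[TemplateHit],
    merge_gap: int = MERGE_GAP,
    min_region: int = MIN_REGION,
) -> list[GenomicInterval]:
    """Merge hits with inter-hit gap < ``merge_gap``; drop regions < ``min_region``.

    The strand of a merged region is the majority strand of its hits
    (ties resolve to ``+``).  Idempotent.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end))
    merged: list[GenomicInterval] = []
    cur = ordered[0].interval
    plus = 1 if ordered[0].strand == "+" else 0
    minus = 1 - plus

    def flush(iv: GenomicInterval, n_plus: int, n_minus: int) -> None:
        if len(iv) >= min_region:
            strand = "+" if n_plus >= n_minus else "-"
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, strand=strand, name="satellite"))

    for hit in ordered[1:]:
        iv = hit.interval
        if iv.chrom == cur.chrom and iv.start - cur.end < merge_gap:
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end), strand=cur.strand)
            plus += hit.strand == "+"
            minus += hit.strand == "-"
        else:
            flush(cur, plus, minus)
            cur = iv
            plus = 1 if hit.strand == "+" else 0
            minus = 1 - plus
    flush(cur, plus, minus)
    return merged


def build_satellite_array(
    assembly: list[SequenceRecord], regions: list[GenomicInterval], chrom: str
) -> SatelliteArray:
    """Concatenate a chromosome's satellite regions into one array.

    Regions are taken in coordinate order; minus-strand regions are
    reverse-complemented so the array is uniformly plus-oriented (orientation
    retained in the region list for back-mapping).
    """
    seq_by_id = {rec.id: rec.bases for rec in assembly}
    if chrom not in seq_by_id:
        raise ValueError(f"chromosome {chrom!r} not in assembly")
    chrom_seq = seq_by_id[chrom]
    mine = sorted((r for r in regions if r.chrom == chrom), key=lambda r: r.start)
    for a, b in zip(mine, mine[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping regions {a} and {b}")
    parts: list[str] = []
    junctions: list[int] = []
    offset = 0
    for region in mine:
        if region.end > len(chrom_seq):
            raise ValueError(f"region {region} exceeds chromosome bounds ({len(chrom_seq)} bp)")
        sub = chrom_seq[region.start : region.end]
        if region.strand == "-":
            sub = reverse_complement(sub)
        if parts:
            junctions.append(offset)
        parts.append(sub)
        offset += len(sub)
    return SatelliteArray(chrom=chrom, regions=mine, sequence="".join(parts), junctions=junctions)
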