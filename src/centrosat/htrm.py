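"""Hierarchical tandem repeat mining (HTRM) over monomer sequences.

A higher-order repeat (HOR) is an ordered run of distinct monomers that
itself repeats in tandem.  Given a monomer-id sequence, HTRM finds maximal
local tandem runs, compresses each run into a single symbol, and re-mines the
reduced sequence recursively.  Runs found at inner levels become locally
nested subunits (LN-HORs, written with the ``(subpattern)xN`` notation, e.g.
``(1-2)x4-5-6-4-3``); runs surviving at the top level are the HOR units
themselves.

Shifted or reversed units describe the same HOR (a rotation of the unit is
just a different phase of the same tandem array; a reversal is the minus
strand), so patterns are canonicalized to the lexicographically minimal
rotation over the unit and its reversal, e.g. 1-2-3-4, 4-1-2-3, 3-4-1-2,
2-3-4-1 and 4-3-2-1 all name one HOR.

Naming follows "R + rank + L + unit-monomer-length" within a sample and
"M + rank + L + unit-monomer-length" after cross-sample aggregation, with
rank assigned by descending total repeat count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .decomposer import UNKNOWN, MonomerSequence

DEFAULT_MAX_UNIT = 40


@dataclass
class CompressedSymbol:
    """A compressed tandem subunit: ``subpattern`` repeated ``count`` times."""

    subpattern: tuple[int, ...]
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"compressed symbol count must be >= 1, got {self.count}")
        if not self.subpattern:
            raise ValueError("empty subpattern")


@dataclass
class UnitOccurrence:
    """One located HOR unit: token span and its expanded monomer length."""

    start: int
    end: int
    expanded_length: int


@dataclass
class HORPattern:
    """A mined HOR: canonical unit, nesting notation, and occurrence tally."""

    canonical: tuple[int, ...]
    unit: tuple[int, ...]
    nested: str | None = None
    name: str | None = None
    repeat_count: int = 0
    top_level: bool = False
    occurrences: list[UnitOccurrence] = field(default_factory=list)

    @property
    def L(self) -> int:
        """Unit monomer length (nested subunits counted once)."""
        return len(self.canonical)


@dataclass
class HORAnnotation:
    """Per-source located HOR units plus token coverage bookkeeping."""

    source_id: str
    units: list[tuple[UnitOccurrence, tuple[int, ...]]]  # (occurrence, canonical)
    n_tokens: int
    n_unknown: int

    @property
    def covered_tokens(self) -> int:
        return sum(occ.end - occ.start for occ, _ in self.units)

    @property
    def coverage(self) -> float:
        return self.covered_tokens / self.n_tokens if self.n_tokens else 0.0


# ---------------------------------------------------------------------------
# canonicalization and expansion


def canonicalize_pattern(unit: tuple[int, ...]) -> tuple[int, ...]:
    """Lexicographically minimal rotation over the unit and its reversal."""
    unit = tuple(unit)
    if not unit:
        raise ValueError("empty unit")
    candidates = []
    for seq in (unit, unit[::-1]):
        candidates.extend(seq[i:] + seq[:i] for i in range(len(seq)))
    return min(candidates)


def expand_pattern(compressed: list[int | CompressedSymbol]) -> tuple[tuple[int, ...], int]:
    """Flatten a compressed monomer pattern; returns (flat tuple, monomer count)."""
    flat: list[int] = []
    for sym in compressed:
        if isinstance(sym, CompressedSymbol):
            flat.extend(sym.subpattern * sym.count)
        else:
            flat.append(int(sym))
    return tuple(flat), len(flat)


_PAT_TOKEN = re.compile(r"\((?P<sub>[\d\-]+)\)x(?P<count>\d+)|(?P<id>\d+)")


def parse_pattern(text: str) -> list[int | CompressedSymbol]:
    """Parse compressed-pattern notation like ``(1-2)x4-5-6-4-3``."""
    out: list[int | CompressedSymbol] = []
    pos = 0
    for m in _PAT_TOKEN.finditer(text):
        if m.group("id") is not None:
            out.append(int(m.group("id")))
        else:
            sub = tuple(int(x) for x in m.group("sub").split("-"))
            out.append(CompressedSymbol(sub, int(m.group("count"))))
        pos = m.end()
    if not out:
        raise ValueError(f"cannot parse pattern {text!r}")
    return out


# ---------------------------------------------------------------------------
# tandem-run detection


def find_tandem_runs(tokens: list, max_unit: int = DEFAULT_MAX_UNIT) -> list[tuple[int, tuple, int]]:
    """All maximal tandem runs (start, unit, count>=2) with unit length <= max_unit.

    A run is maximal when it cannot be extended by one unit on either side.
    Tokens are compared by equality; any hashable token type is accepted.
    """
    if max_unit < 1:
        raise ValueError("max_unit must be >= 1")
    seq = list(tokens)
    n = len(seq)
    runs: list[tuple[int, tuple, int]] = []
    for u in range(1, min(max_unit, n // 2) + 1):
        for start in range(n - 2 * u + 1):
            unit = seq[start : start + u]
            if start >= u and seq[start - u : start] == unit:
                continue  # left-extendable: not the maximal start
            if seq[start + u : start + 2 * u] != unit:
                continue
            count = 2
            while seq[start + count * u : start + (count + 1) * u] == unit:
                count += 1
            runs.append((start, tuple(unit), count))
    return runs


# ---------------------------------------------------------------------------
# recursive mining


class _Sym:
    """Internal mining symbol: a monomer, an unknown token, or a compressed run."""

    __slots__ = ("kind", "start", "end", "exp_len", "unit_syms", "count", "rep_occs")

    def __init__(self, kind, start, end, exp_len, unit_syms=None, count=0, rep_occs=None):
        self.kind = kind  # hashable; compressed symbols compare by collapsed unit
        self.start = start
        self.end = end
        self.exp_len = exp_len
        self.unit_syms = unit_syms  # list[_Sym] of the first repetition (runs only)
        self.count = count
        self.rep_occs = rep_occs  # list[UnitOccurrence] per repetition (runs only)

    @property
    def is_run(self) -> bool:
        return self.unit_syms is not None


def _collapsed(sym: _Sym) -> tuple[int, ...]:
    """Flat monomer tuple of a symbol with nested runs collapsed to one copy."""
    if not sym.is_run:
        return (sym.kind[1],)
    out: list[int] = []
    for s in sym.unit_syms:
        out.extend(_collapsed(s))
    return tuple(out)


def _notation(sym: _Sym) -> str:
    """Compressed notation of a run symbol, e.g. ``(1-2)x4-5-6-4-3``."""
    parts = []
    for s in sym.unit_syms:
        if s.is_run:
            inner = "-".join(str(x) for x in _collapsed(s))
            parts.append(f"({inner})x{s.count}")
        else:
            parts.append(str(s.kind[1]))
    return "-".join(parts)


def _compress_run(symbols: list[_Sym], start: int, u: int, count: int) -> _Sym:
    block = symbols[start : start + u * count]
    rep_occs = []
    for r in range(count):
        rep = block[r * u : (r + 1) * u]
        rep_occs.append(UnitOccurrence(rep[0].start, rep[-1].end, sum(s.exp_len for s in rep)))
    unit_syms = block[:u]
    collapsed = []
    for s in unit_syms:
        collapsed.extend(_collapsed(s))
    return _Sym(
        kind=("r", tuple(collapsed)),
        start=block[0].start,
        end=block[-1].end,
        exp_len=sum(s.exp_len for s in block),
        unit_syms=unit_syms,
        count=count,
        rep_occs=rep_occs,
    )


def htrm_mine(
    tokens: MonomerSequence | list,
    max_unit: int = DEFAULT_MAX_UNIT,
    source_id: str | None = None,
) -> tuple[list[HORPattern], HORAnnotation]:
    """Mine HORs by recursive tandem-run compression.

    At each level all maximal runs over the current symbols are found;
    shortest-unit runs are compressed first (ties: larger token coverage,
    then leftmost), runs are replaced by single symbols, and mining repeats
    until no runs remain.  Compressed symbols with the same collapsed unit
    compare equal regardless of copy number, so nesting-count variants (the
    12/16/20-mor forms of one HOR) stay inside a single run.

    Unknown tokens never match any unit position and therefore terminate
    runs.  Returns the mined patterns (top-level HORs plus nested subunit
    patterns) and a located annotation for the top-level units.
    """
    if isinstance(tokens, MonomerSequence):
        source = source_id or tokens.source_id
        raw = tokens.tokens
    else:
        source = source_id or "."
        raw = list(tokens)
    n_unknown = sum(1 for t in raw if t == UNKNOWN)
    symbols: list[_Sym] = []
    for i, t in enumerate(raw):
        kind = ("u", i) if t == UNKNOWN else ("m", int(t))
        symbols.append(_Sym(kind, i, i + 1, 1))

    created: list[_Sym] = []
    while True:
        kinds = [s.kind for s in symbols]
        runs = find_tandem_runs(kinds, max_unit)
        if not runs:
            break
        # innermost-first: compress only the shortest-unit runs this level
        min_u = min(len(r[1]) for r in runs)
        runs = [r for r in runs if len(r[1]) == min_u]
        runs.sort(key=lambda r: (len(r[1]), -(len(r[1]) * r[2]), r[0]))
        taken: list[tuple[int, int, int]] = []  # (start, u, count), non-overlapping
        occupied: list[tuple[int, int]] = []
        for start, unit, count in runs:
            end = start + len(unit) * count
            if any(not (end <= a or start >= b) for a, b in occupied):
                continue
            taken.append((start, len(unit), count))
            occupied.append((start, end))
        unit_kind_seqs: set[tuple] = set()
        for start, u, count in sorted(taken, reverse=True):
            unit_kind_seqs.add(tuple(s.kind for s in symbols[start : start + u]))
            rep = _compress_run(symbols, start, u, count)
            created.append(rep)
            symbols[start : start + u * count] = [rep]
        # Wrap literal single occurrences of subpatterns compressed at this
        # level as count-1 symbols, so nesting-count variants including x1
        # (e.g. the 12-mor form next to 16/20-mors) unify in later runs.
        if unit_kind_seqs:
            seqs = sorted(unit_kind_seqs, key=len, reverse=True)
            i = 0
            while i < len(symbols):
                for ks in seqs:
                    u = len(ks)
                    if tuple(s.kind for s in symbols[i : i + u]) == ks:
                        rep = _compress_run(symbols, i, u, 1)
                        created.append(rep)
                        symbols[i : i + u] = [rep]
                        break
                i += 1

    top_level = {id(s) for s in symbols if s.is_run}
    by_canon: dict[tuple[int, ...], HORPattern] = {}
    best_inner: dict[tuple[int, ...], int] = {}
    for rep in created:
        flat = _collapsed(rep)
        canon = canonicalize_pattern(flat)
        pat = by_canon.get(canon)
        if pat is None:
            pat = HORPattern(canonical=canon, unit=flat, nested=None)
            by_canon[canon] = pat
            best_inner[canon] = -1
        pat.repeat_count += rep.count
        pat.occurrences.extend(rep.rep_occs)
        inner = max((s.count for s in rep.unit_syms if s.is_run), default=0)
        if inner > best_inner[canon]:
            best_inner[canon] = inner
            pat.nested = _notation(rep) if inner > 0 else None
        if id(rep) in top_level:
            pat.top_level = True
    # a pattern is locally nested only if a subunit actually expands somewhere
    for canon, pat in by_canon.items():
        exp_lengths = {occ.expanded_length for occ in pat.occurrences}
        if best_inner[canon] < 2 and len(exp_lengths) <= 1:
            pat.nested = None

    ann_units: list[tuple[UnitOccurrence, tuple[int, ...]]] = []
    for s in symbols:
        if s.is_run:
            canon = canonicalize_pattern(_collapsed(s))
            ann_units.extend((occ, canon) for occ in s.rep_occs)
    ann_units.sort(key=lambda x: x[0].start)
    annotation = HORAnnotation(source, ann_units, n_tokens=len(raw), n_unknown=n_unknown)
    return list(by_canon.values()), annotation


# ---------------------------------------------------------------------------
# naming


def name_hors(
    patterns: list[HORPattern],
    scope: str = "per_sample",
    chrom: str | None = None,
) -> list[HORPattern]:
    """Assign "R+rank+L+len" (per sample) or "M+rank+L+len" (aggregated) names.

    Patterns are ranked by descending repeat count; ties break by smaller
    unit length, then by canonical tuple order.  With ``chrom`` given, names
    are prefixed ``{chrom}_`` as used in cross-chromosome reports.
    """
    if scope not in ("per_sample", "aggregated"):
        raise ValueError(f"unknown scope {scope!r}")
    prefix = "R" if scope == "per_sample" else "M"
    ranked = sorted(patterns, key=lambda p: (-p.repeat_count, p.L, p.canonical))
    for rank, pat in enumerate(ranked, start=1):
        pat.name = f"{prefix}{rank}L{pat.L}"
        if chrom:
            pat.name = f"{chrom}_{pat.name}"
    return ranked
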