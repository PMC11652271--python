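"""Monomer decomposition: template tiling, labeling, and template inference.

A satellite array (or alpha-satellite read) is a near-tandem run of ~171-bp
monomers.  Decomposition proceeds in two steps:

1. **Block decomposition** — tile the sequence into consecutive blocks, each
   aligned to the ~171-bp alpha-satellite template, choosing block boundaries
   that minimize the total edit cost.  This is a global dynamic program over
   (sequence position x template position) with a "restart" transition that
   closes one block and opens the next at zero cost; it is equivalent to
   minimizing ``sum_i lev(s[b_i:b_{i+1}], template)`` over all tilings.

2. **Monomer labeling** — score each block against every chromosome-specific
   monomer template with the identity ``1 - ed(block, monomer) /
   max(l_block, l_monomer)`` and label it with the arg-max template id;
   blocks whose best identity falls below 90% become ``unknown`` tokens
   (transposable elements or other interjected sequence).

Monomer templates themselves can be inferred from an array by community
detection on the block-identity graph; each community is represented by the
member with the lowest summed edit distance to the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit

from .core_io import edit_distance, sequence_identity

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"

#: blocks below this identity against every template become ``unknown``
UNKNOWN_IDENTITY_CUTOFF = 0.90

_CODE = np.full(256, 4, dtype=np.uint8)  # 4 encodes N / anything ambiguous
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class Block:
    """One tiling block: a candidate monomer occurrence."""

    source_id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MonomerTemplate:
    """A chromosome-specific monomer template sequence (id >= 1)."""

    id: int
    sequence: str
    chrom: str = "."

    def __post_init__(self) -> None:
        if not 120 <= len(self.sequence) <= 250:
            raise ValueError(
                f"monomer template {self.id}: length {len(self.sequence)} outside [120, 250] bp"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MonomerSequence:
    """Ordered monomer tokens decoded from one source's blocks."""

    source_id: str
    tokens: list[int | str]  # monomer ids, or UNKNOWN
    starts: list[int]
    ends: list[int]
    identities: list[float]

    def __len__(self) -> int:
        return len(self.tokens)


@njit(cache=True)
def _tile_dp(s: np.ndarray, t: np.ndarray):  # pragma: no cover - jitted
    """Min-total-edit tiling of s into consecutive blocks vs template t.

    Returns (total_cost, block_boundaries).  D[i][j] = cheapest way to spend
    i sequence chars ending inside a block that has consumed j template
    chars; D[i][0] additionally allows closing the previous block at i.
    Two passes per row resolve the (i, 0) <- (i, m) restart without cycles
    (an empty block costs m > 0, so it can never improve a row).
    """
    n = s.size
    m = t.size
    INF = np.int64(1 << 60)
    prev = np.empty(m + 1, dtype=np.int64)
    cur = np.empty(m + 1, dtype=np.int64)
    prev_s = np.empty(m + 1, dtype=np.int64)  # seq index where current block started
    cur_s = np.empty(m + 1, dtype=np.int64)
    best = np.empty(n + 1, dtype=np.int64)  # best tiling cost of s[:i]
    last_start = np.empty(n + 1, dtype=np.int64)  # start of the optimal last block
    for j in range(m + 1):
        prev[j] = j  # delete template prefix at the start of the first block
        prev_s[j] = 0
    best[0] = 0
    last_start[0] = 0
    for i in range(1, n + 1):
        sc = s[i - 1]
        # pass 1: restart value at (i, 0) not yet known
        cur[0] = prev[0] + 1
        cur_s[0] = prev_s[0]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if sc == t[j - 1] and sc < 4 else 1)
            v = sub
            vs = prev_s[j - 1]
            if prev[j] + 1 < v:
                v = prev[j] + 1
                vs = prev_s[j]
            if cur[j - 1] + 1 < v:
                v = cur[j - 1] + 1
                vs = cur_s[j - 1]
            cur[j] = v
            cur_s[j] = vs
        best[i] = cur[m]
        last_start[i] = cur_s[m]
        # pass 2: allow a new block to open at i (template-prefix deletions)
        if best[i] < cur[0]:
            cur[0] = best[i]
            cur_s[0] = i
            for j in range(1, m + 1):
                if cur[j - 1] + 1 < cur[j]:
                    cur[j] = cur[j - 1] + 1
                    cur_s[j] = cur_s[j - 1]
        prev, cur = cur, prev
        prev_s, cur_s = cur_s, prev_s
    # traceback over block boundaries
    bounds = []
    p = n
    while p > 0:
        q = last_start[p]
        if q >= p:  # degenerate empty block; cannot happen for positive costs
            q = 0
        bounds.append(p)
        p = q
    bounds.append(0)
    return best[n], bounds[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def orient_to_template(sequence: str, template: MonomerTemplate | str) -> tuple[str, str]:
    """Return (strand, plus-oriented sequence) relative to the template.

    Reads come off either strand; decomposition and labeling assume plus
    orientation, so the strand whose best infix template alignment is
    cheaper wins.  Ties keep the input orientation.
    """
    import edlib

    from .core_io import reverse_complement

    tseq = template.sequence if isinstance(template, MonomerTemplate) else template
    fwd = edlib.align(tseq, sequence, mode="HW", task="distance")["editDistance"]
    rc = reverse_complement(sequence)
    rev = edlib.align(tseq, rc, mode="HW", task="distance")["editDistance"]
    if rev < fwd:
        return "-", rc
    return "+", sequence


def decompose_blocks(sequence: str, template: MonomerTemplate | str, source_id: str = ".") -> list[Block]:
    """Tile ``sequence`` into blocks by minimum-total-edit alignment to the template.

    Block lengths drift around the template length as indels require.  A
    sequence shorter than the template yields a single block (with a warning).
    """
    tseq = template.sequence if isinstance(template, MonomerTemplate) else template
    if not sequence:
        logger.warning("%s: empty sequence, no blocks", source_id)
        return []
    if len(sequence) < len(tseq):
        logger.warning(
            "%s: sequence (%d bp) shorter than template (%d bp); emitting single block",
            source_id, len(sequence), len(tseq),
        )
        return [Block(source_id, 0, len(sequence), sequence)]
    _, bounds = _tile_dp(_encode(sequence), _encode(tseq))
    return [
        Block(source_id, a, b, sequence[a:b])
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]


def label_monomers(blocks: list[Block], templates: list[MonomerTemplate]) -> MonomerSequence:
    """Label each block with its best-identity monomer template (Eq.-1 identity).

    Identity is ``1 - ed(block, monomer) / max(l_block, l_monomer)``; the
    arg-max template id wins, ties broken by lowest id, and a best identity
    below :data:`UNKNOWN_IDENTITY_CUTOFF` yields the ``unknown`` token.
    """
    if not templates:
        raise ValueError("need at least one monomer template")
    source = blocks[0].source_id if blocks else "."
    tokens: list[int | str] = []
    idents: list[float] = []
    by_id = sorted(templates, key=lambda t: t.id)
    for blk in blocks:
        best_id: int | str = UNKNOWN
        best = -1.0
        for tpl in by_id:
            ident = sequence_identity(blk.sequence, tpl.sequence)
            if ident > best:
                best = ident
                best_id = tpl.id
        if best < UNKNOWN_IDENTITY_CUTOFF:
            best_id = UNKNOWN
        tokens.append(best_id)
        idents.append(best)
    return MonomerSequence(
        source_id=source,
        tokens=tokens,
        starts=[b.start for b in blocks],
        ends=[b.end for b in blocks],
        identities=idents,
    )


def infer_monomer_templates(
    blocks: list[Block],
    seed: int = 0,
    identity_threshold: float = 0.90,
    resolution: float = 1.0,
    max_blocks: int = 400,
    chrom: str = ".",
) -> list[MonomerTemplate]:
    """Infer monomer templates by community detection on the block-identity graph.

    Blocks become nodes; edges (weighted by identity) connect pairs above
    ``identity_threshold``.  Louvain communities are each represented by the
    member minimizing the summed edit distance to the rest of its community.
    Template ids are assigned 1..k in order of first appearance along the
    source.  For large inputs a seeded subsample of ``max_blocks`` blocks is
    used.
    """
    if not blocks:
        raise ValueError("no blocks to infer templates from")
    if len(blocks) == 1:
        return [MonomerTemplate(1, blocks[0].sequence, chrom)]
    rng = np.random.default_rng(seed)
    idx = np.arange(len(blocks))
    if len(blocks) > max_blocks:
        idx = np.sort(rng.choice(len(blocks), size=max_blocks, replace=False))
    sub = [blocks[i] for i in idx]
    n = len(sub)
    dist = np.zeros((n, n))
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(sub[i].sequence, sub[j].sequence)
            dist[i, j] = dist[j, i] = d
            ident = 1.0 - d / max(len(sub[i].sequence), len(sub[j].sequence))
            if ident >= identity_threshold:
                graph.add_edge(i, j, weight=ident)
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=int(seed)
    )
    # representative = member with lowest summed edit distance to its community
    reps: list[tuple[int, str]] = []
    for comm in communities:
        members = sorted(comm)
        if len(members) == 1:
            reps.append((members[0], sub[members[0]].sequence))
            continue
        sums = dist[np.ix_(members, members)].sum(axis=1)
        best = members[int(np.argmin(sums))]
        reps.append((best, sub[best].sequence))
    # number templates by first appearance of their community along the source
    first = {
        r_idx: min(members)
        for (r_idx, _), members in zip(reps, (sorted(c) for c in communities))
    }
    reps.sort(key=lambda r: first[r[0]])
    kept = [seq for _, seq in reps if 120 <= len(seq) <= 250]
    if len(kept) < len(reps):
        logger.warning(
            "%s: dropped %d community representatives outside the 120-250 bp monomer band",
            chrom, len(reps) - len(kept),
        )
    return [MonomerTemplate(k + 1, seq, chrom) for k, seq in enumerate(kept)]
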