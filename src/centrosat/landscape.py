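"""Structure-level analyses of HOR arrays across assemblies.

* **Cross-landscape HOR clustering** — all DNA sequences of a target HOR
  unit (the largest monomer pattern the landscapes' primary HORs share) are
  summarized against their consensus as 0-1 difference vectors and k-means
  clustered; the smallest k whose clusters associate with the landscapes is
  chosen.  Shared vs landscape-specific clusters expose which layer of an
  array expanded recently.

* **Ancestral HOR reconstruction** — monomers from another chromosome of the
  same suprachromosomal family serve as the outgroup.  They are grouped by
  cutting a neighbor-joining distance tree, per-group consensuses become the
  ancestral monomers, target monomers map to their nearest ancestral
  monomer, and the ancestral HOR sequence is assembled by substitution.

* **Recent-expansion track** — in a sliding window of 10 HOR units (1-unit
  slide), the number of unit pairs with exactly identical DNA; recent
  tandem expansions show up as blocks of high exact-match counts.

* **Monomer-pattern length distributions** — histograms of per-unit expanded
  monomer lengths (the 10/12/16/20-mor spectrum of locally nested HORs) and
  per-sample ratio vectors for grouping samples by nesting level.

Alignment here is intentionally self-contained: a medoid-seeded projection
consensus and unit-cost global pairwise alignments; adapters accept
externally computed alignments in aligned FASTA.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from skbio import DistanceMatrix
from skbio.tree import nj
from sklearn.cluster import KMeans

from .core_io import edit_distance, sequence_identity

logger = logging.getLogger(__name__)

EXPANSION_WINDOW = 10


# ---------------------------------------------------------------------------
# consensus and 0-1 encoding


def _pairwise_alignment(query: str, target: str) -> tuple[str, str]:
    """Global unit-cost alignment; returns (aligned query, aligned target)."""
    res = edlib.align(query, target, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    return nice["query_aligned"], nice["target_aligned"]


def consensus_sequence(sequences: list[str]) -> str:
    """Majority-rule consensus from a medoid-seeded projection alignment.

    The medoid (minimum summed edit distance) provides the coordinate
    system; every sequence is globally aligned to it and votes per medoid
    column (the most common base at every position wins; a gap majority
    deletes the column).
    """
    if not sequences:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        return sequences[0]
    n = len(sequences)
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(sequences[i], sequences[j])
            sums[i] += d
            sums[j] += d
    medoid = sequences[int(np.argmin(sums))]
    counts = [Counter() for _ in range(len(medoid))]
    for seq in sequences:
        qa, ta = _pairwise_alignment(seq, medoid)
        col = 0
        for qc, tc in zip(qa, ta):
            if tc == "-":
                continue  # insertion relative to the medoid: no column
            counts[col][qc] += 1
            col += 1
    out = []
    for c in counts:
        base, _ = max(c.items(), key=lambda kv: (kv[1], kv[0] != "-", kv[0]))
        if base != "-":
            out.append(base)
    return "".join(out)


def unit_vector(unit: str, consensus: str) -> np.ndarray:
    """0-1 difference vector of a unit against the consensus.

    One entry per consensus position: 0 where the aligned unit base matches,
    1 for a substitution or a deletion.  Insertions in the unit have no
    consensus column and are dropped.
    """
    qa, ta = _pairwise_alignment(unit, consensus)
    vec = np.empty(len(consensus), dtype=np.int8)
    col = 0
    for qc, tc in zip(qa, ta):
        if tc == "-":
            continue
        vec[col] = 0 if qc == tc else 1
        col += 1
    return vec


# ---------------------------------------------------------------------------
# cross-landscape clustering


@dataclass
class LandscapeClusterResult:
    k: int
    assignments: pd.Series  # unit id -> "R0", "R1", ...
    consensus: str
    cluster_consensus: dict[str, str]
    composition: pd.DataFrame  # landscape x cluster counts
    association: float  # Cramer's V of cluster vs landscape


def cluster_units_cross_landscape(
    units_by_landscape: dict[str, list[str]],
    k: int | str = "auto",
    seed: int = 0,
    association_threshold: float = 0.3,
    k_range: tuple[int, int] = (2, 6),
) -> LandscapeClusterResult:
    """k-means clustering of HOR-unit 0-1 vectors across landscapes.

    With ``k="auto"`` the smallest k in ``k_range`` whose cluster-landscape
    association (Cramer's V from the chi-square statistic) exceeds
    ``association_threshold`` is chosen (falling back to the best-associated
    k).  Cluster ids R0, R1, ... are ordered by descending cluster size.
    """
    unit_ids, landscapes, seqs = [], [], []
    for land, units in sorted(units_by_landscape.items()):
        for i, u in enumerate(units):
            unit_ids.append(f"{land}:{i}")
            landscapes.append(land)
            seqs.append(u)
    if len(set(landscapes)) < 1 or not seqs:
        raise ValueError("no units")
    cons = consensus_sequence(seqs)
    vectors = np.stack([unit_vector(s, cons) for s in seqs])
    if not vectors.any():
        raise ValueError("degenerate input: all units identical to the consensus")

    def fit(k_: int) -> tuple[np.ndarray, float]:
        if len(seqs) < k_:
            raise ValueError(f"fewer units ({len(seqs)}) than clusters ({k_})")
        km = KMeans(n_clusters=k_, random_state=seed, n_init=10)
        lab = km.fit_predict(vectors)
        tab = pd.crosstab(pd.Series(lab), pd.Series(landscapes))
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            return lab, 0.0
        chi2 = chi2_contingency(tab.to_numpy())[0]
        v = np.sqrt(chi2 / (len(lab) * (min(tab.shape) - 1)))
        return lab, float(v)

    if k == "auto":
        best = None
        chosen = None
        for k_ in range(k_range[0], min(k_range[1], len(seqs)) + 1):
            lab, v = fit(k_)
            if best is None or v > best[2]:
                best = (k_, lab, v)
            if v > association_threshold:
                chosen = (k_, lab, v)
                break
        k_, labels, assoc = chosen if chosen is not None else best
    else:
        labels, assoc = fit(int(k))
        k_ = int(k)

    # name clusters by descending size (ties: first appearance)
    sizes = Counter(labels.tolist())
    order = sorted(sizes, key=lambda c: (-sizes[c], list(labels).index(c)))
    name_of = {c: f"R{i}" for i, c in enumerate(order)}
    named = [name_of[c] for c in labels]
    assignments = pd.Series(named, index=unit_ids, name="cluster")
    cluster_consensus = {
        name: consensus_sequence([s for s, nm in zip(seqs, named) if nm == name])
        for name in sorted(set(named))
    }
    composition = pd.crosstab(pd.Series(landscapes, index=unit_ids), assignments)
    return LandscapeClusterResult(
        k=k_,
        assignments=assignments,
        consensus=cons,
        cluster_consensus=cluster_consensus,
        composition=composition,
        association=assoc,
    )


# ---------------------------------------------------------------------------
# ancestral HOR reconstruction


@dataclass
class AncestralHOR:
    ancestral_monomers: dict[str, str]  # group id -> consensus
    correspondence: dict[int, str | None]  # target monomer id -> group id (None = ambiguous)
    ambiguous: list[int]
    sequence: str  # ancestral HOR DNA
    identity_matrix: pd.DataFrame


def _nj_groups(sequences: list[str], n_groups: int) -> list[list[int]]:
    """Group sequences by deleting the longest edges of a neighbor-joining tree."""
    n = len(sequences)
    if n_groups >= n:
        return [[i] for i in range(n)]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = edit_distance(sequences[i], sequences[j])
    ids = [f"m{i}" for i in range(n)]
    tree = nj(DistanceMatrix(dm, ids))
    g = nx.Graph()
    for node in tree.traverse(include_self=True):
        for child in node.children:
            length = child.length if child.length is not None else 0.0
            g.add_edge(id(node), id(child), weight=max(length, 0.0), child=child)
    edges = sorted(g.edges(data=True), key=lambda e: -e[2]["weight"])
    removed = 0
    for a, b, data in edges:
        if removed >= n_groups - 1:
            break
        g.remove_edge(a, b)
        if nx.number_connected_components(g) > removed + 1:
            removed += 1
        else:
            g.add_edge(a, b, **data)
    leaves = {id(tip): int(tip.name[1:]) for tip in tree.tips()}
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(leaves[x] for x in comp if x in leaves)
        if members:
            groups.append(members)
    groups.sort(key=lambda m: m[0])
    return groups


def reconstruct_ancestral_hor(
    target_monomers: dict[int, str],
    target_pattern: tuple[int, ...],
    outgroup_monomers: list[str],
    n_groups: int,
    cluster_consensus: dict[str, str] | None = None,
) -> AncestralHOR:
    """Reconstruct the ancestral HOR sequence from outgroup monomers.

    Outgroup monomers are cut into ``n_groups`` groups on a neighbor-joining
    tree; per-group consensuses are the ancestral monomers.  Each target
    monomer consensus maps to its nearest ancestral monomer (an exact
    distance tie is flagged as ambiguous, not silently assigned).  The
    ancestral HOR is the target pattern with every monomer substituted by
    its ancestral counterpart; the identity matrix compares it (and the
    ancestral monomset) with any supplied cluster consensuses.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    groups = _nj_groups(outgroup_monomers, n_groups)
    ancestral = {
        f"A{gi}": consensus_sequence([outgroup_monomers[i] for i in members])
        for gi, members in enumerate(groups)
    }
    correspondence: dict[int, str | None] = {}
    ambiguous: list[int] = []
    for mid, seq in sorted(target_monomers.items()):
        dists = {g: edit_distance(seq, a) for g, a in ancestral.items()}
        best = min(dists.values())
        winners = sorted(g for g, d in dists.items() if d == best)
        if len(winners) > 1:
            correspondence[mid] = None
            ambiguous.append(mid)
            logger.warning("target monomer %d equally close to groups %s", mid, winners)
        else:
            correspondence[mid] = winners[0]
    missing = [m for m in target_pattern if correspondence.get(m) is None]
    if missing:
        raise ValueError(f"ancestral correspondence unresolved for monomers {sorted(set(missing))}")
    sequence = "".join(ancestral[correspondence[m]] for m in target_pattern)
    others = dict(cluster_consensus or {})
    names = ["ancestral"] + sorted(others)
    seqs = {"ancestral": sequence, **others}
    mat = pd.DataFrame(
        [[sequence_identity(seqs[a], seqs[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return AncestralHOR(
        ancestral_monomers=ancestral,
        correspondence=correspondence,
        ambiguous=ambiguous,
        sequence=sequence,
        identity_matrix=mat,
    )


# ---------------------------------------------------------------------------
# recent-expansion track and length distributions


def recent_expansion_track(
    units: list[str], window: int = EXPANSION_WINDOW, slide: int = 1
) -> list[int]:
    """Exactly matching unit-pair count per sliding window of HOR units.

    Reported at window starts.  Fewer units than one window yields an empty
    track (with a warning).
    """
    if len(units) < window:
        logger.warning("only %d units (< window %d): empty track", len(units), window)
        return []
    track = []
    for start in range(0, len(units) - window + 1, slide):
        chunk = units[start : start + window]
        pairs = sum(
            1
            for i in range(window)
            for j in range(i + 1, window)
            if chunk[i] == chunk[j]
        )
        track.append(pairs)
    return track


@dataclass
class LengthDistribution:
    histogram: dict[int, int]
    peak: int
    ratios: dict[int, float] = field(default_factory=dict)
    remainder: float = 0.0


def mp_length_distribution(
    expanded_lengths: list[int], tracked_lengths: list[int] | None = None
) -> LengthDistribution:
    """Histogram of per-unit expanded monomer lengths with the modal peak.

    ``tracked_lengths`` (e.g. the 12/16/20-mor spectrum) selects the lengths
    whose occurrence ratios form the per-sample ratio vector; ratios sum to
    1 together with the remainder.
    """
    if not expanded_lengths:
        raise ValueError("no units")
    hist = Counter(expanded_lengths)
    peak = max(hist, key=lambda l: (hist[l], -l))
    total = sum(hist.values())
    ratios: dict[int, float] = {}
    if tracked_lengths:
        ratios = {l: hist.get(l, 0) / total for l in tracked_lengths}
    remainder = 1.0 - sum(ratios.values())
    return LengthDistribution(histogram=dict(sorted(hist.items())), peak=peak, ratios=ratios, remainder=remainder)


def group_samples_by_ratios(
    ratio_vectors: dict[str, list[float]], n_groups: int, seed: int = 0
) -> pd.Series:
    """k-means grouping of per-sample MP-length ratio vectors."""
    samples = sorted(ratio_vectors)
    x = np.array([ratio_vectors[s] for s in samples], dtype=float)
    km = KMeans(n_clusters=n_groups, random_state=seed, n_init=10)
    labels = km.fit_predict(x)
    return pd.Series([f"G{l}" for l in labels], index=samples, name="group")
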