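"""Cross-sample HOR bookkeeping and population statistics.

Per sample k with sequencing fold-coverage c_k:

* estimated HOR array size of chromosome i:  s_{i,k} = l_{i,k} / c_k, where
  l_{i,k} is the total length of that sample's HOR-carrying reads;
* n-number of HOR j:  n_{j,k} = r_{j,k} / c_k, where r_{j,k} is the raw HOR
  unit count reported by annotation.

Rare HORs — those that never reach 10% of their chromosome's HOR content in
any sample — are excluded.  For the remainder the mean fold change
mf_{j,k} = n_{j,k} / avgn_j is computed (avgn_j the cross-sample mean) and a
HOR whose mf dispersion std_j exceeds 0.5 is flagged as a variable HOR
(v-HOR).

Centromere genotypes come from hierarchical clustering of per-sample
n-number vectors on one chromosome's v-HORs: two or three clusters (chosen
by silhouette), with a cluster called heterozygous (AB) when its per-HOR
means approximate the pairwise mean of the other two clusters' means — the
``mean(C0+C1) ~ C2`` relation of a diploid locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import binomtest, mannwhitneyu
from sklearn.metrics import silhouette_score

from .htrm import HORPattern, canonicalize_pattern

logger = logging.getLogger(__name__)

RARE_FRACTION = 0.1
VHOR_STD_CUTOFF = 0.5
HET_TOLERANCE = 0.2


@dataclass
class SampleQuant:
    """Per-sample HOR quantities: coverage-normalized counts and array sizes."""

    sample_id: str
    coverage: float
    population: str = "other"
    hor_counts: dict[str, float] = field(default_factory=dict)  # raw r_{j,k}
    hor_chrom: dict[str, str] = field(default_factory=dict)
    hor_read_length: dict[str, float] = field(default_factory=dict)  # l_{i,k} per chrom

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def n_numbers(self) -> dict[str, float]:
        return {j: r / self.coverage for j, r in self.hor_counts.items()}

    @property
    def estimated_sizes(self) -> dict[str, float]:
        return {i: l / self.coverage for i, l in self.hor_read_length.items()}


def quantify_sample(
    sample_id: str,
    coverage: float,
    hor_counts: dict[str, float],
    hor_chrom: dict[str, str] | None = None,
    hor_read_length: dict[str, float] | None = None,
    population: str = "other",
) -> SampleQuant:
    """Build a :class:`SampleQuant` from annotation output and coverage."""
    return SampleQuant(
        sample_id=sample_id,
        coverage=coverage,
        population=population,
        hor_counts=dict(hor_counts),
        hor_chrom=dict(hor_chrom or {}),
        hor_read_length=dict(hor_read_length or {}),
    )


@dataclass
class HORCatalog:
    """Aggregated cross-sample HOR patterns with M-names."""

    patterns: list[HORPattern]
    name_map: dict[tuple[str, tuple[int, ...]], str]  # (sample, canonical) -> M-name
    chrom_of: dict[str, str] = field(default_factory=dict)


def aggregate_hors(
    per_sample: dict[str, list[HORPattern]],
    chrom: str | None = None,
) -> HORCatalog:
    """Merge identical canonical patterns across samples and assign M-names.

    Patterns are ranked by total repeat count across all samples; each
    sample's per-sample (R-) pattern maps to its aggregated M-name, so
    assembly-derived names can be matched with read-derived names.
    """
    totals: dict[tuple[int, ...], HORPattern] = {}
    for sample, patterns in per_sample.items():
        for pat in patterns:
            canon = canonicalize_pattern(pat.canonical)
            agg = totals.get(canon)
            if agg is None:
                agg = HORPattern(canonical=canon, unit=pat.unit, nested=pat.nested)
                totals[canon] = agg
            agg.repeat_count += pat.repeat_count
            if pat.nested and not agg.nested:
                agg.nested = pat.nested
    ranked = sorted(totals.values(), key=lambda p: (-p.repeat_count, p.L, p.canonical))
    for rank, pat in enumerate(ranked, start=1):
        pat.name = f"M{rank}L{pat.L}"
        if chrom:
            pat.name = f"{chrom}_{pat.name}"
    by_canon = {p.canonical: p.name for p in ranked}
    name_map = {
        (sample, canonicalize_pattern(p.canonical)): by_canon[canonicalize_pattern(p.canonical)]
        for sample, pats in per_sample.items()
        for p in pats
    }
    return HORCatalog(
        patterns=ranked,
        name_map=name_map,
        chrom_of={p.name: chrom or "." for p in ranked},
    )


def n_number_table(quants: list[SampleQuant]) -> pd.DataFrame:
    """n-number matrix, HOR x sample (missing HORs are 0)."""
    data = {q.sample_id: q.n_numbers for q in quants}
    return pd.DataFrame(data).fillna(0.0).sort_index()


def filter_rare_hors(quants: list[SampleQuant]) -> list[str]:
    """HORs retained after the rare-HOR exclusion rule.

    A HOR j is excluded iff in *every* sample its n-number stays below 10%
    of the summed n-numbers of all HORs on its chromosome; i.e. it is
    retained iff it reaches >= 10% of its chromosome's HOR content in at
    least one sample.
    """
    table = n_number_table(quants)
    chrom_of: dict[str, str] = {}
    for q in quants:
        chrom_of.update(q.hor_chrom)
    retained: list[str] = []
    for hor in table.index:
        chrom = chrom_of.get(hor, ".")
        siblings = [h for h in table.index if chrom_of.get(h, ".") == chrom]
        chrom_total = table.loc[siblings].sum(axis=0)
        if (table.loc[hor] >= RARE_FRACTION * chrom_total).any():
            retained.append(hor)
    return retained


@dataclass
class FoldChangeTable:
    mean_fold_change: pd.DataFrame  # HOR x sample mf_{j,k}
    avg_n: pd.Series  # avgn_j
    std: pd.Series  # std_j of mf over samples
    vhor: pd.Series  # std_j > 0.5
    std_mode: str = "population"


def call_vhors(
    quants: list[SampleQuant],
    retained: list[str] | None = None,
    std_mode: str = "population",
) -> FoldChangeTable:
    """Mean fold change per HOR/sample and the std_j > 0.5 v-HOR flag.

    ``std_mode`` selects population (divide by n) or sample (n-1) standard
    deviation; the choice is echoed in the result.
    """
    if len(quants) < 2:
        raise ValueError("need at least two samples")
    if std_mode not in ("population", "sample"):
        raise ValueError(f"unknown std_mode {std_mode!r}")
    table = n_number_table(quants)
    if retained is not None:
        table = table.loc[[h for h in retained if h in table.index]]
    avg = table.mean(axis=1)
    zero = avg[avg == 0].index
    if len(zero):
        logger.warning("dropping HORs with zero mean n-number: %s", list(zero))
        table = table.drop(index=zero)
        avg = avg.drop(index=zero)
    mf = table.div(avg, axis=0)
    ddof = 0 if std_mode == "population" else 1
    std = mf.std(axis=1, ddof=ddof)
    return FoldChangeTable(
        mean_fold_change=mf,
        avg_n=avg,
        std=std,
        vhor=std > VHOR_STD_CUTOFF,
        std_mode=std_mode,
    )


@dataclass
class GenotypeClustering:
    chrom: str
    labels: pd.Series  # sample -> "C0"/"C1"/"C2"
    zygosity: dict[str, str]  # cluster -> "AA"/"BB"/"AB"
    cluster_means: pd.DataFrame  # HOR x cluster
    k: int
    population_frequencies: pd.DataFrame | None = None


def cluster_genotypes(
    table: pd.DataFrame,
    chrom: str = ".",
    populations: dict[str, str] | None = None,
    het_tolerance: float = HET_TOLERANCE,
) -> GenotypeClustering:
    """Cluster samples into centromere genotypes from one chromosome's v-HOR n-numbers.

    ``table`` is HOR x sample.  Samples are Ward-clustered on z-scored
    n-numbers; k in {2, 3} is chosen by silhouette.  With k = 3, a cluster
    is called heterozygous (AB) when for every HOR its mean n-number is
    within ``het_tolerance`` (relative) of the pairwise mean of the other
    two clusters' means; the homozygous clusters are called AA/BB.
    Cluster ids C0/C1 are the homozygotes (ordered by descending mean of the
    first HOR), the heterozygote (if any) is the last cluster.
    """
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples to cluster genotypes")
    x = table.T.to_numpy(dtype=float)  # samples x HORs
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    link = linkage(z, method="ward")
    best_k, best_sil, best_labels = 2, -np.inf, None
    for k in (2, 3):
        labels = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(labels)) < k:
            continue
        sil = silhouette_score(z, labels)
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    labels = best_labels
    k = best_k
    clusters = [np.nonzero(labels == c)[0] for c in np.unique(labels)]
    means = np.stack([x[idx].mean(axis=0) for idx in clusters], axis=1)  # HORs x k

    het_idx: int | None = None
    if k == 3:
        candidates = []
        for c in range(3):
            others = [o for o in range(3) if o != c]
            pair_mean = means[:, others].mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(means[:, c] - pair_mean) / np.where(pair_mean == 0, np.nan, pair_mean)
            rel = np.nan_to_num(rel, nan=np.inf)
            if (rel <= het_tolerance).all():
                candidates.append((float(rel.max()), c))
        if candidates:
            het_idx = min(candidates)[1]

    # order homozygote clusters by descending mean of the first HOR
    homo = [c for c in range(k) if c != het_idx]
    homo.sort(key=lambda c: -means[0, c])
    order = homo + ([het_idx] if het_idx is not None else [])
    if het_idx is None and k == 3:
        order = sorted(range(3), key=lambda c: -means[0, c])
    name_of = {cluster: f"C{pos}" for pos, cluster in enumerate(order)}
    zygosity = {}
    for pos, cluster in enumerate(order):
        if cluster == het_idx:
            zygosity[name_of[cluster]] = "AB"
        else:
            zygosity[name_of[cluster]] = "AA" if pos == 0 else "BB"
    if k == 2:
        zygosity = {name_of[order[0]]: "AA", name_of[order[1]]: "BB"}

    sample_labels = pd.Series(
        [name_of[int(np.nonzero([i in idx for idx in clusters])[0][0])] for i in range(x.shape[0])],
        index=table.columns,
        name="cluster",
    )
    cluster_means = pd.DataFrame(
        {name_of[c]: means[:, c] for c in range(k)}, index=table.index
    ).reindex(sorted(name_of.values()), axis=1)

    pop_freq = None
    if populations:
        df = pd.DataFrame({"cluster": sample_labels, "population": pd.Series(populations)})
        pop_freq = (
            df.groupby(["population", "cluster"]).size().unstack(fill_value=0)
        )
        pop_freq = pop_freq.div(pop_freq.sum(axis=1), axis=0)
    return GenotypeClustering(
        chrom=chrom,
        labels=sample_labels,
        zygosity=zygosity,
        cluster_means=cluster_means,
        k=k,
        population_frequencies=pop_freq,
    )


def allele_frequency(genotypes: list[str], allele: str = "B") -> float:
    """Allele frequency from diploid genotype calls (AA/BB/AB), as a fraction."""
    if not genotypes:
        raise ValueError("no genotypes")
    count = 0
    for gt in genotypes:
        if gt not in ("AA", "BB", "AB"):
            raise ValueError(f"bad genotype {gt!r}")
        count += gt.count(allele)
    return count / (2 * len(genotypes))


def compare_populations(
    design: str,
    group_a: list[float] | None = None,
    group_b: list[float] | None = None,
    k: int | None = None,
    n: int | None = None,
    p0: float | None = None,
    alternative: str = "two-sided",
):
    """The two population tests used for HOR comparisons.

    ``design="wilcoxon"``: two-sided (by default) Wilcoxon rank-sum test of
    two groups of n-numbers.  ``design="binomial"``: one-sided binomial test
    of ``k`` successes in ``n`` trials against null proportion ``p0``
    (``alternative`` "greater" gives P(X >= k), "less" gives P(X <= k)).
    Returns the scipy result object (``.pvalue`` attribute).
    """
    if design == "wilcoxon":
        if not group_a or not group_b:
            raise ValueError("wilcoxon requires two non-empty groups")
        return mannwhitneyu(group_a, group_b, alternative=alternative)
    if design == "binomial":
        if k is None or n is None or p0 is None:
            raise ValueError("binomial requires k, n and p0")
        if alternative == "two-sided":
            alternative = "greater"
        return binomtest(k, n, p0, alternative=alternative)
    raise ValueError(f"unknown design {design!r}")
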