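# Methods

## The problem and the model

Human centromeres are built from ~171-bp **alpha-satellite monomers**.
Monomers within one centromere typically share only 50–90% sequence
identity with each other, but ordered runs of distinct monomers — **higher
order repeat (HOR) units** — repeat in tandem with 95–100% identity between
copies. A HOR is therefore naturally described at two levels: a *monomer
pattern* (an ordered tuple of monomer identifiers, e.g. `1-2-3-4-5`) and
the DNA realization of each unit. Subunits of a HOR can themselves expand
in tandem inside the parent unit (**locally nested HORs**, written
`(1-2)x4-5-6-4-3`), which is a major mode of centromere evolution.

`centrosat` annotates HORs from two kinds of input — long HiFi-like reads
(10–25 kb) and chromosome-level assemblies — quantifies HOR content across
samples and populations, and analyzes array structure ("landscapes") across
assemblies. A synthetic-data module generates arrays, diploid cohorts and
reads with planted ground truth so that every stage is tested by parameter
recovery.

## Pipeline stages

### Read classification (`read_classifier`)

Each read is summarized by the frequencies of its canonical 5-mers. A 5-mer
and its reverse complement share one feature; at odd k there are no
palindromes, so exactly 1024/2 = 512 features exist. Counts are divided by
read length; windows containing `N` are skipped. By construction the
feature vector of a read equals that of its reverse complement, so
classification is strand-invariant — important because reads come off
either strand.

Training reads are simulated from an annotated reference: per replicate
round (10 rounds), an equal number of 10–25 kb fragments per chromosome
from its satellite arrays, with exactly half of all positives
reverse-complemented; negatives are equally many fragments sampled outside
the arrays (fragments touching an array are rejected and resampled). Both
stages project features onto principal components retaining > 95% of
variance and classify with a support-vector machine. The kernel and
regularization are not externally prescribed; the package defaults to a
linear kernel with C = 1 (exposed in the API) for reproducibility and
speed in a 512-dimensional, nearly linearly separable feature space.
Reads shorter than 10 kb are still classified at inference time; the
10–25 kb band constrains training only.

### Array building (`array_builder`)

The alpha-satellite template is scanned against both strands of each
chromosome with a windowed infix aligner (edlib): windows of twice the
template length, advanced by half a template length, with a configurable
identity floor (default 70% — low enough to admit monomers diverged to the
50–90% band, high enough to reject random sequence, whose expected infix
identity is ≈ 55%). An adapter ingests externally produced hit tables, so
any aligner can be substituted. Hits with an inter-hit gap < 5 kb are
merged; merged regions shorter than 10 kb are discarded. The 10-kb rule is
applied per merged region (the natural reading when regions are produced
one merge at a time). Surviving regions are concatenated in coordinate
order into the chromosome's satellite array; minus-strand regions are
reverse-complemented so the array is uniformly plus-oriented, with
orientation kept in the region list and junction offsets recorded as the
"break" track.

### Monomer decomposition (`decomposer`)

Block decomposition is a global dynamic program over (sequence position ×
template position) with unit edit costs and a restart transition that
closes one block and opens the next at zero cost. It minimizes
`Σ_i lev(s[b_i : b_{i+1}], template)` over all tilings — an equivalent
contract to published tandem-decomposition tools, implemented directly
(numba-jitted, O(n·m) time, two-row memory with block-start propagation so
only boundaries are traced back). An independent tiling oracle
(`B[i] = min_j B[j] + lev(s[j:i], t)`) verifies total costs in the tests.

Each block is scored against every monomer template with

```
identity(block, monomer) = 1 − ed(s_block, s_monomer) / max(l_block, l_monomer)
```

and labeled with the arg-max template id (ties to the lowest id). A best
identity below 90% yields the token `unknown` (transposable elements or
other interjected sequence). Note the printed form of this identity in the
source literature reads `ed/max(l)`, which cannot be the quantity whose
"largest" value is taken or thresholded at "below 90%"; the subtraction
from 1 is the internally consistent reading and is what is implemented.

Monomer templates can be inferred from an array: blocks become nodes of a
graph with edges weighted by pairwise identity above a threshold (default
90%), Louvain communities are found (seeded), and each community is
represented by the member with the lowest summed edit distance to the rest.
Template ids are assigned 1..k in order of first appearance along the
array, matching the `1-2-3-…` pattern notation. For large arrays a seeded
subsample of blocks (default 400) bounds the quadratic distance matrix.
The community-detection resolution is exposed in the API without claiming
an external default.

Reads of unknown orientation are normalized with `orient_to_template`
(cheaper infix alignment of the template against the read vs its reverse
complement) before decomposition.

### HOR mining (`htrm`)

Mining is recursive tandem-run compression over the monomer-token
sequence:

1. find all maximal tandem runs (unit length 1..40 by default, repeat
   count ≥ 2);
2. compress only the shortest-unit runs at each level (ties: larger token
   coverage, then leftmost), replacing each run by a single symbol;
3. additionally wrap literal single occurrences of subpatterns compressed
   at that level as count-1 symbols, so nesting-count variants — the
   12/16/20-mor forms of one HOR, i.e. `base-(sub)x1 / x2 / x3` — compare
   equal and join a single parent run;
4. repeat until no runs remain.

Compressed symbols compare equal when their collapsed units (nested
subunits counted once) are equal, regardless of copy number. `unknown`
tokens are unique symbols and therefore terminate runs without resetting
pattern tallies. Every compressed run contributes to a pattern keyed by
the canonical form of its collapsed unit: the lexicographically minimal
rotation over the unit and its reversal, so shifted and reversed units
(`1-2-3-4`, `4-1-2-3`, `3-4-1-2`, `2-3-4-1`, `4-3-2-1`) name one HOR.
Nested subunits tally their own pattern as well, including count-1
occurrences inside parents — which is why a nested dimer can legitimately
out-count its parent HOR, as observed in real centromere annotations.

Naming: patterns sorted by descending repeat count (ties: smaller unit
length, then canonical tuple order — an artifact convention), named
`R{rank}L{length}` per sample and `M{rank}L{length}` after cross-sample
aggregation, with an optional `{chrom}_` prefix. `L` counts nested
subunits once; per-occurrence expanded monomer lengths (10/12/16/20-mors)
are recorded separately.

### Quantification (`quantify`)

With per-sample fold coverage `c_k`:

* estimated array size of chromosome i: `s_{i,k} = l_{i,k} / c_k`
  (`l_{i,k}` = total length of that sample's HOR-carrying reads);
* n-number of HOR j: `n_{j,k} = r_{j,k} / c_k` (raw annotated unit count).

Coverage is required user metadata (a helper can estimate it as total read
bases / stated genome size). A HOR is excluded as *rare* iff in every
sample its n-number stays strictly below 10% of the summed n-numbers of
all HORs on its chromosome. For retained HORs, the mean fold change
`mf_{j,k} = n_{j,k} / avgn_j` is computed and a HOR with dispersion
`std_j > 0.5` is a **v-HOR**. The standard deviation defaults to the
population form (divide by n), switchable to the sample form; the choice
is echoed in the output.

Genotype clustering on one chromosome's v-HORs: Ward linkage on z-scored
per-sample n-number vectors, k ∈ {2, 3} by silhouette. With k = 3, a
cluster is called heterozygous (AB) when for every HOR its mean n-number
lies within 20% (configurable) of the pairwise mean of the other two
clusters' means — the diploid `mean(C0+C1) ≈ C2` relation; the remaining
clusters are the homozygotes. Which homozygote is "A" is arbitrary up to
relabeling. Population tests: two-sided Wilcoxon rank-sum
(`scipy.stats.mannwhitneyu`) for n-number group comparisons, one-sided
binomial (`scipy.stats.binomtest`) for genotype proportions; raw p-values
are reported (no multiple-testing correction by default).

### Landscape analyses (`landscape`)

*Cross-landscape clustering.* The target HOR is the largest monomer
pattern shared by the landscapes' primary HORs. A consensus is built by a
medoid-seeded projection alignment (every unit globally aligned to the
medoid; majority base per medoid column, gap-majority columns dropped) —
a deliberately self-contained stand-in for an external MSA tool, adequate
for near-identical HOR units. Each unit is encoded as a 0–1 vector over
consensus positions (substitutions and deletions count 1; unit insertions
have no consensus column and are dropped) and k-means clustered (seeded).
For k = auto, the smallest k in [2, 6] whose cluster–landscape association
(Cramér's V from the chi-square statistic, default threshold 0.3) suffices
is chosen, falling back to the best-associated k.

*Ancestral reconstruction.* Outgroup monomers (from another chromosome of
the same suprachromosomal family) are grouped by deleting the g−1 longest
edges of a neighbor-joining tree on their edit-distance matrix; g is a
required parameter (per-family group counts are not tabulated upstream).
Per-group consensuses are the ancestral monomers. Each target monomer maps
to its nearest ancestral monomer by edit distance (an exact tie is flagged
and reconstruction refuses rather than guessing); the ancestral HOR is the
target pattern with monomers substituted. Identities against cluster
consensuses use the same `1 − ed/max(l)` measure.

*Recent-expansion track.* In each sliding window of 10 HOR units (1-unit
slide), the number of unit pairs whose DNA matches exactly, reported at
the window start. The alternative reading (number of units having at
least one exact twin) is a trivial variation of the same pair comparison
and was not implemented separately.

*Length distributions.* Histograms of per-unit expanded monomer lengths,
with modal peak and per-sample ratio vectors over tracked lengths (e.g.
12/16/20) for k-means grouping of samples by nesting level.

## Synthetic data (`simulate`)

The generator emulates the structure the pipeline targets, with defaults
fixed at the biologically stated conditions:

| parameter | default | rationale |
|---|---|---|
| monomer length | 171 bp | alpha-satellite unit size |
| cross-monomer identity | 0.70 | middle of the 50–90% band |
| per-base substitution rate | 0.01 | HOR copies at ~98% identity, inside the 95–100% band |
| read length | uniform 10–25 kb | HiFi-like |
| coverage | 30× | typical high-coverage HiFi sampling |
| flank length | 50 kb | non-satellite context for classifier negatives |

Monomers are derived from one random base monomer by substituting a
calibrated number of positions: two monomers independently mutated at
per-position rate p differ at an expected fraction `2p(1−p) + (2/3)p²`,
solved for the identity target. Arrays concatenate units of the stated
pattern with independent per-base substitutions (indels behind a flag at
the same rate — substitution-only keeps unit-length truth crisp; indel
mode exists to stress the decomposer). Nesting events splice extra copies
of a subpattern into units within a fractional locus of the array. Reads
are drawn uniformly over bases to a stated fold coverage with exactly half
reverse-complemented. Diploid cohorts place two allelic arrays at one
locus (AA/BB carry two copies of one allele, AB one of each); per-sample
HOR counts are derived from the sampled read intervals (every unit fully
contained in a read counts once per read), which is exactly the raw count
a read annotator produces and why counts are normalized by coverage.

What the generator does *not* emulate: sequencing error profiles (reads
are exact substrings), array-scale mutational gradients (layered
expansion), segmental duplications or non-alpha satellite families in the
flanks, and pericentromeric repeat context. Passing recovery tests
therefore demonstrates correctness of the algorithms under idealized
HiFi-like conditions, not performance on raw sequencing data.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; BED on disk.
* `N` is excluded from k-mer windows and never matches in edit distance
  (not even another `N`), implemented by sentinel remapping before
  alignment — conservative and deterministic.
* Label ties break to the lowest template id; naming ties to smaller L,
  then canonical tuple order; k-means and Louvain are seeded; silhouette
  decides k = 2 vs 3 for genotypes.
* Degenerate inputs: sequences shorter than the template yield a single
  block with a warning; a single block is its own monomer template;
  all-`unknown` token input mines to an empty pattern list; fewer than 4
  samples refuse genotype clustering; all-identical units refuse 0–1
  clustering (zero-variance).

## Problem sizes used in the tests

Population-scale cohorts (hundreds of samples, chromosome-scale arrays)
are not simulated; the suite runs on sizes chosen to exercise every code path
while completing quickly: arrays of 150–500 units (0.1–1 Mb), cohorts of
8–30 diploid samples, three-chromosome genomes with 40-kb flanks, and
training sets of a few hundred simulated reads. All recovery criteria
(pattern identity, ≥ 95% unit coverage, ≥ 95% classification and genotype
accuracy) are met at these sizes; the algorithms are linear or
near-linear in array length except the quadratic pairwise stages, which
are bounded by seeded subsampling.

## Known limitations

* The mining recursion is deterministic but greedy at run selection;
  pathological token sequences with many overlapping maximal runs may
  compress differently than an exhaustive optimum.
* The medoid-projection consensus is not a full progressive MSA; for
  units more diverged than HOR copies normally are (< ~90% identity) an
  external alignment should be supplied via the adapters.
* Read-level HOR counting attributes units to reads independently, so
  boundary units spanning read ends are undercounted by a factor
  ≈ (1 − unit/read length); at 10–25 kb reads and ≤ 2 kb units this is a
  few percent and cancels in fold-change comparisons.
* The genotype heterozygote call assumes exactly one heterozygous cluster;
  loci with more than two segregating array alleles are reported as their
  best 2/3-cluster approximation.
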