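"""Two-stage alpha-satellite read classifier (alpha vs non-alpha, then chromosome).

Long reads drawn from centromeric satellite arrays have a distinctive k-mer
composition.  Each read is summarized by the frequencies of its 512 canonical
5-mers — a 5-mer and its reverse complement share one feature (1024/2 = 512;
no palindromes exist at odd k), so the feature vector of a read equals that
of its reverse complement and strand never matters.  Counts are normalized by
read length.

Training reads are simulated from an annotated reference: positives are
10-25 kb fragments of the satellite arrays (half reverse-complemented, equal
numbers per chromosome, ten replicate rounds), negatives are equally many
fragments sampled outside the arrays.  Both stages reduce the feature matrix
with PCA retaining > 95% of variance and classify with a linear-kernel SVM;
stage 1 separates Alpha from Non-Alpha, stage 2 assigns chromosomes to
stage-1 positives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .core_io import GenomicInterval, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

KMER_K = 5
N_FEATURES = 512
ALPHA, NON_ALPHA = "Alpha", "Non-Alpha"

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _canonical_tables() -> tuple[np.ndarray, np.ndarray]:
    codes = np.arange(4**KMER_K)
    digits = np.stack([(codes // 4**p) % 4 for p in range(KMER_K)], axis=1)  # low->high
    # digit p is the (K-1-p)-th base; the reverse complement swaps base order
    # and complements, so digit p of rc(k) is 3 minus digit (K-1-p) of k
    rc = np.zeros_like(codes)
    for p in range(KMER_K):
        rc += (3 - digits[:, KMER_K - 1 - p]) * 4**p
    canon = np.minimum(codes, rc)
    uniq = np.unique(canon)
    feat_index = np.full(4**KMER_K, -1, dtype=np.int64)
    feat_index[uniq] = np.arange(uniq.size)
    return canon, feat_index


_CANON, _FEAT_INDEX = _canonical_tables()
assert int(np.unique(_CANON).size) == N_FEATURES


@dataclass
class LabeledRead:
    read: SequenceRecord
    label: str  # ALPHA / NON_ALPHA at stage 1; chromosome name at stage 2
    chrom: str | None = None


@dataclass
class ClassifierModel:
    """One stage of the classifier: PCA projection + linear SVM."""

    stage: str  # "alpha_vs_non" | "chromosome"
    pca: PCA
    svm: SVC
    labels: list[str]

    @property
    def explained_variance(self) -> float:
        return float(self.pca.explained_variance_ratio_.sum())


def featurize_read(seq: str) -> np.ndarray:
    """Canonical 5-mer frequency vector of one read (length-normalized)."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.size < KMER_K:
        raise ValueError("read shorter than k")
    kmer = np.zeros(codes.size - KMER_K + 1, dtype=np.int64)
    valid = np.ones_like(kmer, dtype=bool)
    for p in range(KMER_K):
        window = codes[p : p + kmer.size]
        kmer = kmer * 4 + window
        valid &= window < 4  # windows containing N are skipped
    counts = np.bincount(_FEAT_INDEX[_CANON[kmer[valid]]], minlength=N_FEATURES)
    return counts.astype(np.float64) / len(seq)


def featurize(reads: list[SequenceRecord]) -> tuple[np.ndarray, list[str]]:
    """Feature matrix (reads x 512) plus the row ids; short reads are skipped."""
    rows, ids = [], []
    for rec in reads:
        if len(rec.bases) < KMER_K:
            logger.warning("read %s shorter than %d bp: skipped", rec.id, KMER_K)
            continue
        rows.append(featurize_read(rec.bases))
        ids.append(rec.id)
    if not rows:
        return np.empty((0, N_FEATURES)), []
    return np.vstack(rows), ids


def simulate_training_reads(
    reference: list[SequenceRecord],
    satellite_bed: list[GenomicInterval],
    seed: int,
    reads_per_chrom: int = 20,
    n_replicates: int = 10,
    read_range: tuple[int, int] = (10_000, 25_000),
) -> list[LabeledRead]:
    """Simulate the labeled training set from an annotated reference.

    Positives: per replicate round, an equal number of fragments per
    chromosome from its satellite intervals, lengths uniform in
    ``read_range``; exactly half of all positives are reverse-complemented.
    Negatives: the same total count, sampled outside satellite intervals
    (fragments touching a satellite region are rejected and resampled).
    """
    rng = np.random.default_rng(seed)
    lo, hi = read_range
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in satellite_bed:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    seqs = {rec.id: rec.bases for rec in reference}
    positives: list[LabeledRead] = []
    for rep in range(n_replicates):
        for chrom in sorted(by_chrom):
            ivs = [iv for iv in by_chrom[chrom] if len(iv) >= lo]
            if not ivs:
                logger.warning("chromosome %s: satellite regions all < %d bp, skipped", chrom, lo)
                continue
            weights = np.array([len(iv) for iv in ivs], dtype=float)
            weights /= weights.sum()
            for r in range(reads_per_chrom):
                iv = ivs[int(rng.choice(len(ivs), p=weights))]
                rl = int(rng.integers(lo, min(hi, len(iv)) + 1))
                start = iv.start + int(rng.integers(0, len(iv) - rl + 1))
                frag = seqs[chrom][start:start + rl]
                rec = SequenceRecord(id=f"pos_{rep}_{chrom}_{r}", bases=frag)
                positives.append(LabeledRead(rec, ALPHA, chrom=chrom))
    # reverse-complement exactly half of the positive set
    flip = rng.permutation(len(positives))[: len(positives) // 2]
    for i in flip:
        rec = positives[i].read
        positives[i].read = SequenceRecord(id=rec.id, bases=reverse_complement(rec.bases))
    # negatives: outside satellite regions, same total count
    negatives: list[LabeledRead] = []
    chroms = sorted(seqs)
    lengths = np.array([len(seqs[c]) for c in chroms], dtype=float)
    attempts = 0
    while len(negatives) < len(positives) and attempts < 100 * max(1, len(positives)):
        attempts += 1
        c = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        L = len(seqs[c])
        if L < lo:
            continue
        rl = int(rng.integers(lo, min(hi, L) + 1))
        start = int(rng.integers(0, L - rl + 1))
        if any(start < iv.end and start + rl > iv.start for iv in by_chrom.get(c, [])):
            continue  # touches a satellite region: reject and resample
        rec = SequenceRecord(id=f"neg_{len(negatives)}_{c}", bases=seqs[c][start:start + rl])
        negatives.append(LabeledRead(rec, NON_ALPHA))
    if len(negatives) < len(positives):
        logger.warning("only %d/%d negatives could be sampled", len(negatives), len(positives))
    return positives + negatives


def _fit_stage(x: np.ndarray, y: list[str], stage: str, seed: int, svm_c: float) -> ClassifierModel:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"stage {stage}: need >= 2 classes, got {list(classes)}")
    thin = classes[counts < 2]
    if thin.size:
        raise ValueError(f"stage {stage}: classes with < 2 examples: {list(thin)}")
    pca = PCA(n_components=0.95, svd_solver="full", random_state=seed)
    z = pca.fit_transform(x)
    svm = SVC(kernel="linear", C=svm_c, random_state=seed)
    svm.fit(z, y)
    return ClassifierModel(stage=stage, pca=pca, svm=svm, labels=sorted(classes.tolist()))


def train_two_stage(
    training: list[LabeledRead], seed: int = 0, svm_c: float = 1.0
) -> tuple[ClassifierModel, ClassifierModel]:
    """Train stage-1 (Alpha/Non-Alpha) and stage-2 (chromosome) models."""
    x, ids = featurize([lr.read for lr in training])
    kept = set(ids)
    labeled = [lr for lr in training if lr.read.id in kept]
    y1 = [lr.label if lr.label == NON_ALPHA else ALPHA for lr in labeled]
    stage1 = _fit_stage(x, y1, "alpha_vs_non", seed, svm_c)
    alpha_rows = [i for i, lr in enumerate(labeled) if lr.label != NON_ALPHA]
    y2 = [labeled[i].chrom or labeled[i].label for i in alpha_rows]
    stage2 = _fit_stage(x[alpha_rows], y2, "chromosome", seed, svm_c)
    return stage1, stage2


def classify_reads(
    reads: list[SequenceRecord], models: tuple[ClassifierModel, ClassifierModel]
) -> list[LabeledRead]:
    """Classify reads: stage 1 gates alpha status, stage 2 assigns chromosomes."""
    stage1, stage2 = models
    x, ids = featurize(reads)
    by_id = {rec.id: rec for rec in reads}
    out: list[LabeledRead] = []
    if x.shape[0] == 0:
        return out
    if x.shape[1] != stage1.pca.n_features_in_:
        raise ValueError("feature dimension mismatch with trained model")
    lab1 = stage1.svm.predict(stage1.pca.transform(x))
    alpha_idx = np.nonzero(lab1 == ALPHA)[0]
    chrom_of = {}
    if alpha_idx.size:
        lab2 = stage2.svm.predict(stage2.pca.transform(x[alpha_idx]))
        chrom_of = {ids[i]: c for i, c in zip(alpha_idx, lab2)}
    for rid, l1 in zip(ids, lab1):
        if l1 == ALPHA:
            out.append(LabeledRead(by_id[rid], ALPHA, chrom=chrom_of[rid]))
        else:
            out.append(LabeledRead(by_id[rid], NON_ALPHA))
    return out


def save_models(models: tuple[ClassifierModel, ClassifierModel], model_dir: str | Path) -> None:
    """Persist both stages plus a small manifest into a model directory."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    stage1, stage2 = models
    joblib.dump(stage1, model_dir / "stage1.joblib")
    joblib.dump(stage2, model_dir / "stage2.joblib")
    manifest = {
        "format_version": 1,
        "n_features": N_FEATURES,
        "stage1_labels": stage1.labels,
        "stage2_labels": stage2.labels,
        "stage1_explained_variance": stage1.explained_variance,
        "stage2_explained_variance": stage2.explained_variance,
    }
    (model_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_models(model_dir: str | Path) -> tuple[ClassifierModel, ClassifierModel]:
    model_dir = Path(model_dir)
    return (
        joblib.load(model_dir / "stage1.joblib"),
        joblib.load(model_dir / "stage2.joblib"),
    )
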