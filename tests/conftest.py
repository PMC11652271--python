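"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (full DP tables,
exhaustive enumerations) kept separate from the library code they check.
"""

from __future__ import annotations

import numpy as np
import pytest

BASES = "ACGT"


def levenshtein_oracle(a: str, b: str) -> int:
    """Quadratic DP Levenshtein with unit costs; N matches nothing."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    dp[:, 0] = np.arange(n + 1)
    dp[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            same = a[i - 1] == b[j - 1] and a[i - 1] != "N"
            dp[i, j] = min(
                dp[i - 1, j - 1] + (0 if same else 1),
                dp[i - 1, j] + 1,
                dp[i, j - 1] + 1,
            )
    return int(dp[n, m])


def tandem_runs_oracle(tokens: list, max_unit: int) -> set[tuple[int, tuple, int]]:
    """Definition-checking enumeration of all maximal tandem runs."""
    n = len(tokens)
    runs = set()
    for u in range(1, max_unit + 1):
        for start in range(n):
            unit = tuple(tokens[start : start + u])
            if len(unit) < u:
                continue
            count = 0
            while tuple(tokens[start + count * u : start + (count + 1) * u]) == unit:
                count += 1
            if count < 2:
                continue
            if start >= u and tuple(tokens[start - u : start]) == unit:
                continue  # extendable left
            runs.add((start, unit, count))
    return runs


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def mutate_positions(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = BASES[(BASES.index(chars[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_chrom_genome():
    """Three synthetic chromosomes with distinct monomer sets, plus satellite BED."""
    from centrosat.core_io import GenomicInterval
    from centrosat.simulate import SimSpec, gen_chromosome

    records, bed, truths = [], [], {}
    for i, name in enumerate(["chr1", "chr2", "chr3"]):
        spec = SimSpec(
            n_monomers=4,
            pattern=(1, 2, 3, 4),
            n_units=180,
            flank_length=40_000,
            mutation_rate=0.01,
            seed=100 + i,
        )
        rec, (start, end), truth = gen_chromosome(spec, name=name)
        records.append(rec)
        bed.append(GenomicInterval(name, start, end, name="satellite"))
        truths[name] = truth
    return records, bed, truths


@pytest.fixture(scope="session")
def trained_models(three_chrom_genome):
    from centrosat.read_classifier import simulate_training_reads, train_two_stage

    records, bed, _ = three_chrom_genome
    training = simulate_training_reads(records, bed, seed=1, reads_per_chrom=10)
    models = train_two_stage(training, seed=2)
    return models, training
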