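"""Cross-landscape clustering, ancestral reconstruction, expansion track, lengths."""

from collections import Counter

import numpy as np
import pytest

from centrosat.landscape import (
    cluster_units_cross_landscape,
    consensus_sequence,
    group_samples_by_ratios,
    mp_length_distribution,
    recent_expansion_track,
    reconstruct_ancestral_hor,
    unit_vector,
)

from conftest import mutate_positions, random_dna


def _family(rng, base, n, noise=0.005):
    out = []
    for _ in range(n):
        k = int(np.round(rng.binomial(len(base), noise)))
        out.append(mutate_positions(base, list(rng.choice(len(base), size=k, replace=False)), rng))
    return out


class TestConsensus:
    def test_majority_rule_example(self):
        assert consensus_sequence(["ACGT", "ACGA", "ACGA"]) == "ACGA"

    def test_single_sequence(self):
        assert consensus_sequence(["ACGT"]) == "ACGT"

    def test_recovers_base_from_noisy_family(self, rng):
        base = random_dna(rng, 300)
        fam = _family(rng, base, 20, noise=0.01)
        assert consensus_sequence(fam) == base


class TestUnitVector:
    def test_zero_iff_equal(self, rng):
        cons = random_dna(rng, 150)
        assert not unit_vector(cons, cons).any()
        other = mutate_positions(cons, [10, 70], rng)
        vec = unit_vector(other, cons)
        assert vec.sum() == 2 and len(vec) == 150

    def test_deletion_counts_as_difference(self, rng):
        cons = random_dna(rng, 100)
        unit = cons[:50] + cons[52:]
        assert unit_vector(unit, cons).sum() >= 2


class TestCrossLandscapeClustering:
    @pytest.fixture(scope="class")
    def planted(self):
        rng = np.random.default_rng(5)
        base = random_dna(rng, 200)
        variant = mutate_positions(base, list(range(0, 200, 20)), rng)  # 10 fixed diffs
        return {
            "L1": _family(rng, base, 15),
            "L2": _family(rng, variant, 15),
        }, base, variant

    def test_two_families_perfectly_separated(self, planted):
        units, *_ = planted
        res = cluster_units_cross_landscape(units, k=2, seed=0)
        comp = res.composition
        # purity 1.0: each landscape maps to exactly one cluster
        assert (comp.gt(0).sum(axis=1) == 1).all()
        assert res.association > 0.9

    def test_auto_k_picks_two(self, planted):
        units, *_ = planted
        res = cluster_units_cross_landscape(units, k="auto", seed=0, association_threshold=0.5)
        assert res.k == 2

    def test_reproducible_with_seed(self, planted):
        units, *_ = planted
        a = cluster_units_cross_landscape(units, k=2, seed=3)
        b = cluster_units_cross_landscape(units, k=2, seed=3)
        assert a.assignments.equals(b.assignments)

    def test_cluster_consensuses_match_planted(self, planted):
        units, base, variant = planted
        res = cluster_units_cross_landscape(units, k=2, seed=0)
        recovered = set(res.cluster_consensus.values())
        assert recovered == {base, variant}

    def test_degenerate_identical_units_refused(self, rng):
        u = random_dna(rng, 100)
        with pytest.raises(ValueError):
            cluster_units_cross_landscape({"L1": [u] * 6, "L2": [u] * 6}, k=2)


class TestAncestralReconstruction:
    def test_noiseless_group_recovery(self, rng):
        g = [random_dna(rng, 171) for _ in range(3)]
        outgroup = [g[0]] * 4 + [g[1]] * 4 + [g[2]] * 4
        anc = reconstruct_ancestral_hor({1: g[0], 2: g[1], 3: g[2]}, (1, 2, 3), outgroup, 3)
        assert set(anc.ancestral_monomers.values()) == set(g)
        assert anc.sequence == "".join(
            anc.ancestral_monomers[anc.correspondence[m]] for m in (1, 2, 3)
        )

    def test_mutated_targets_map_to_generative_ancestors(self, rng):
        ancestors = [random_dna(rng, 171) for _ in range(3)]
        outgroup = []
        for a in ancestors:
            outgroup += _family(rng, a, 5, noise=0.02)
        # target monomers: ancestors mutated 5%
        targets = {
            i + 1: mutate_positions(a, list(rng.choice(171, size=9, replace=False)), rng)
            for i, a in enumerate(ancestors)
        }
        anc = reconstruct_ancestral_hor(targets, (1, 2, 3, 2), outgroup, 3)
        for i, a in enumerate(ancestors):
            group = anc.correspondence[i + 1]
            # the inferred ancestral monomer for this target is (near) its true ancestor
            from centrosat.core_io import edit_distance

            assert edit_distance(anc.ancestral_monomers[group], a) <= 5

    def test_identity_matrix_diagonal(self, rng):
        g = [random_dna(rng, 171) for _ in range(2)]
        anc = reconstruct_ancestral_hor(
            {1: g[0], 2: g[1]},
            (1, 2),
            [g[0]] * 3 + [g[1]] * 3,
            2,
            cluster_consensus={"R0": g[0] + g[1]},
        )
        assert np.allclose(np.diag(anc.identity_matrix.to_numpy()), 1.0)
        assert anc.identity_matrix.loc["ancestral", "R0"] == pytest.approx(1.0)

    def test_ambiguous_correspondence_flagged(self, rng):
        seq = random_dna(rng, 171)
        anc1 = mutate_positions(seq, [0], rng)
        anc2 = mutate_positions(seq, [1], rng)
        # target at edit distance 1 from both group consensuses: a tie
        with pytest.raises(ValueError, match="unresolved"):
            reconstruct_ancestral_hor({1: seq}, (1,), [anc1] * 3 + [anc2] * 3, 2)


class TestExpansionTrack:
    def test_all_identical_units(self):
        assert recent_expansion_track(["U"] * 10) == [45]

    def test_all_distinct_units(self):
        assert recent_expansion_track([f"u{i}" for i in range(10)]) == [0]

    def test_matches_pair_count_identity(self, rng):
        # independent tally: sum over value multiplicities of C(c, 2)
        units = [f"u{int(x)}" for x in rng.integers(0, 4, 60)]
        track = recent_expansion_track(units)
        for start, got in enumerate(track):
            counts = Counter(units[start : start + 10])
            expected = sum(c * (c - 1) // 2 for c in counts.values())
            assert got == expected

    def test_short_input_empty(self):
        assert recent_expansion_track(["a"] * 5) == []


class TestLengthDistribution:
    def test_single_peak(self):
        dist = mp_length_distribution([12] * 30)
        assert dist.peak == 12 and dist.histogram == {12: 30}

    def test_mixture_ratios(self):
        lengths = [10] * 70 + [12] * 30
        dist = mp_length_distribution(lengths, tracked_lengths=[10, 12])
        assert dist.peak == 10
        assert dist.ratios == {10: pytest.approx(0.7), 12: pytest.approx(0.3)}
        assert dist.remainder == pytest.approx(0.0)

    def test_ratios_plus_remainder_sum_to_one(self, rng):
        lengths = list(rng.choice([12, 16, 20, 24], size=100))
        dist = mp_length_distribution(lengths, tracked_lengths=[12, 16, 20])
        assert sum(dist.ratios.values()) + dist.remainder == pytest.approx(1.0)

    def test_ratio_grouping(self):
        vectors = {
            "s1": [0.9, 0.05, 0.05],
            "s2": [0.85, 0.1, 0.05],
            "s3": [0.1, 0.8, 0.1],
            "s4": [0.05, 0.85, 0.1],
        }
        groups = group_samples_by_ratios(vectors, n_groups=2, seed=0)
        assert groups["s1"] == groups["s2"]
        assert groups["s3"] == groups["s4"]
        assert groups["s1"] != groups["s3"]
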