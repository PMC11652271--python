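"""Coverage-normalized HOR quantities, rare-HOR filtering, v-HORs, genotypes, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from centrosat.htrm import HORPattern, htrm_mine, name_hors
from centrosat.quantify import (
    aggregate_hors,
    allele_frequency,
    call_vhors,
    cluster_genotypes,
    compare_populations,
    filter_rare_hors,
    n_number_table,
    quantify_sample,
)
from centrosat.simulate import SimSpec, gen_cohort


def _quant(sample, coverage, counts, chrom="chr5", population="other"):
    return quantify_sample(
        sample, coverage, counts, {h: chrom for h in counts}, population=population
    )


class TestSampleQuant:
    def test_n_number_direct(self):
        q = _quant("s1", 20.0, {"H1": 100})
        assert q.n_numbers["H1"] == 5.0

    def test_estimated_size_direct(self):
        q = quantify_sample("s1", 20.0, {}, hor_read_length={"chr5": 60e6})
        assert q.estimated_sizes["chr5"] == pytest.approx(3e6)

    def test_scale_invariance_in_coverage(self):
        a = _quant("a", 10.0, {"H1": 50, "H2": 10})
        b = _quant("b", 20.0, {"H1": 100, "H2": 20})
        assert a.n_numbers == b.n_numbers

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            _quant("s", 0.0, {})


class TestAggregate:
    def test_same_canonical_merges_across_samples(self):
        per_sample = {}
        for s, rot in [("a", 0), ("b", 1), ("c", 2)]:
            unit = (1, 2, 3, 4)
            unit = unit[rot:] + unit[:rot]
            patterns, _ = htrm_mine(list(unit) * 10)
            per_sample[s] = name_hors(patterns)
        catalog = aggregate_hors(per_sample, chrom="5")
        assert len(catalog.patterns) == 1
        assert catalog.patterns[0].repeat_count == 30  # conservation of counts
        names = {catalog.name_map[(s, (1, 2, 3, 4))] for s in "abc"}
        assert names == {"5_M1L4"}

    def test_m_name_ranks_by_total_count(self):
        p_big = HORPattern(canonical=(1, 2), unit=(1, 2), repeat_count=100)
        p_small = HORPattern(canonical=(3, 4, 5), unit=(3, 4, 5), repeat_count=10)
        catalog = aggregate_hors({"s": [p_small, p_big]})
        assert catalog.patterns[0].name == "M1L2"
        assert catalog.patterns[1].name == "M2L3"


class TestRareFilter:
    def test_dominant_and_rare(self):
        quants = [_quant(f"s{k}", 1.0, {"H1": 9.5, "H2": 0.5}) for k in range(3)]
        assert filter_rare_hors(quants) == ["H1"]

    def test_exactly_ten_percent_is_retained(self):
        # the exclusion inequality is strict: reaching 10% keeps the HOR
        quants = [_quant(f"s{k}", 1.0, {"H1": 9, "H2": 1}) for k in range(3)]
        assert filter_rare_hors(quants) == ["H1", "H2"]

    def test_existential_clause_keeps_spiky_hor(self):
        quants = [_quant(f"s{k}", 1.0, {"H1": 95, "H2": 5}) for k in range(3)]
        quants.append(_quant("s3", 1.0, {"H1": 70, "H2": 30}))
        assert "H2" in filter_rare_hors(quants)

    def test_single_hor_chromosome_always_retained(self):
        quants = [_quant("s0", 1.0, {"solo": 2})]
        assert filter_rare_hors(quants) == ["solo"]

    def test_matches_bruteforce_eq4(self, rng):
        for _ in range(20):
            n_hors = int(rng.integers(1, 6))
            n_samples = int(rng.integers(1, 10))
            hors = [f"H{j}" for j in range(n_hors)]
            table = rng.random((n_hors, n_samples)) * 10
            quants = [
                _quant(f"s{k}", 1.0, {h: float(table[j, k]) for j, h in enumerate(hors)})
                for k in range(n_samples)
            ]
            got = set(filter_rare_hors(quants))
            expected = set()
            for j, h in enumerate(hors):
                excluded = all(
                    table[j, k] < 0.1 * table[:, k].sum() for k in range(n_samples)
                )
                if not excluded:
                    expected.add(h)
            assert got == expected


class TestVHors:
    def test_constant_hor_not_variable(self):
        quants = [_quant(f"s{k}", 1.0, {"H1": 7.0}) for k in range(5)]
        fc = call_vhors(quants)
        assert (fc.mean_fold_change.loc["H1"] == 1.0).all()
        assert fc.std["H1"] == 0.0 and not fc.vhor["H1"]

    def test_two_sample_case_both_std_modes(self):
        quants = [_quant("a", 1.0, {"H": 1.0}), _quant("b", 1.0, {"H": 3.0})]
        pop = call_vhors(quants, std_mode="population")
        assert list(pop.mean_fold_change.loc["H"]) == [0.5, 1.5]
        assert pop.std["H"] == pytest.approx(0.5)
        assert not pop.vhor["H"]  # strict > 0.5
        samp = call_vhors(quants, std_mode="sample")
        assert samp.std["H"] == pytest.approx(np.sqrt(0.5))
        assert samp.vhor["H"]

    def test_scale_invariance(self, rng):
        base = rng.random(6) * 5 + 0.1
        q1 = [_quant(f"s{k}", 1.0, {"H": float(v)}) for k, v in enumerate(base)]
        q2 = [_quant(f"s{k}", 1.0, {"H": float(3 * v)}) for k, v in enumerate(base)]
        a, b = call_vhors(q1), call_vhors(q2)
        assert np.allclose(a.mean_fold_change.loc["H"], b.mean_fold_change.loc["H"])
        assert a.std["H"] == pytest.approx(b.std["H"])

    def test_mean_fold_change_averages_to_one(self, rng):
        quants = [
            _quant(f"s{k}", 1.0, {f"H{j}": float(rng.random() * 9 + 0.5) for j in range(4)})
            for k in range(8)
        ]
        fc = call_vhors(quants)
        assert np.allclose(fc.mean_fold_change.mean(axis=1), 1.0, atol=1e-9)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            call_vhors([_quant("only", 1.0, {"H": 1.0})])


class TestGenotypeClustering:
    @pytest.fixture(scope="class")
    def cohort_table(self):
        gts = ["AA"] * 8 + ["BB"] * 8 + ["AB"] * 14
        pops = (["AFR"] * 10 + ["EAS"] * 20)[: len(gts)]
        spec_a = SimSpec(pattern=(1, 2, 3, 4, 5), n_units=100, seed=7)
        spec_b = SimSpec(n_monomers=8, pattern=(1, 2, 3, 4, 5, 6, 7, 8), n_units=80, seed=8)
        samples, _ = gen_cohort(spec_a, spec_b, gts, populations=pops, coverage=8.0, seed=3)
        quants = [
            _quant(s.sample_id, s.coverage, s.hor_counts, population=s.population)
            for s in samples
        ]
        truth = {s.sample_id: s.genotype for s in samples}
        pops_map = {s.sample_id: s.population for s in samples}
        return n_number_table(quants), truth, pops_map

    def test_three_clusters_with_het_called(self, cohort_table):
        table, truth, pops = cohort_table
        res = cluster_genotypes(table, chrom="chr5", populations=pops)
        assert res.k == 3
        assert "AB" in res.zygosity.values()
        pred = {s: res.zygosity[c] for s, c in res.labels.items()}
        # zygosity is defined up to which homozygote is called A vs B
        accs = []
        for swap in (False, True):
            mapping = {"AA": "BB", "BB": "AA", "AB": "AB"} if swap else {}
            accs.append(
                np.mean([mapping.get(pred[s], pred[s]) == truth[s] for s in truth])
            )
        assert max(accs) >= 0.95
        assert res.population_frequencies is not None
        assert np.allclose(res.population_frequencies.sum(axis=1), 1.0)

    def test_het_means_match_pairwise_mean_of_homs(self, cohort_table):
        table, _, _ = cohort_table
        res = cluster_genotypes(table, chrom="chr5")
        het = [c for c, z in res.zygosity.items() if z == "AB"]
        assert len(het) == 1
        homs = [c for c in res.cluster_means.columns if c != het[0]]
        pair_mean = res.cluster_means[homs].mean(axis=1)
        rel = (res.cluster_means[het[0]] - pair_mean).abs() / pair_mean
        assert (rel <= 0.2).all()

    def test_two_cluster_cohort_has_no_het(self):
        gts = ["AA"] * 6 + ["BB"] * 6
        spec_a = SimSpec(pattern=(1, 2, 3, 4, 5), n_units=100, seed=17)
        spec_b = SimSpec(n_monomers=8, pattern=(1, 2, 3, 4, 5, 6, 7, 8), n_units=80, seed=18)
        samples, _ = gen_cohort(spec_a, spec_b, gts, coverage=8.0, seed=19)
        quants = [_quant(s.sample_id, s.coverage, s.hor_counts) for s in samples]
        res = cluster_genotypes(n_number_table(quants))
        assert res.k == 2
        assert set(res.zygosity.values()) == {"AA", "BB"}

    def test_sample_order_invariance(self, cohort_table):
        table, _, _ = cohort_table
        res1 = cluster_genotypes(table)
        shuffled = table[table.columns[::-1]]
        res2 = cluster_genotypes(shuffled)
        assert res1.labels.sort_index().equals(res2.labels.sort_index())

    def test_too_few_samples_refused(self):
        table = pd.DataFrame(np.ones((2, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            cluster_genotypes(table)


class TestPopulationComparisons:
    def test_wilcoxon_identical_groups(self):
        res = compare_populations("wilcoxon", group_a=[1, 2, 3, 4], group_b=[1, 2, 3, 4])
        assert res.pvalue == pytest.approx(1.0)

    def test_wilcoxon_shifted_groups_small_p(self, rng):
        a = list(rng.normal(10, 1, 20))
        b = list(rng.normal(13, 1, 20))
        res = compare_populations("wilcoxon", group_a=a, group_b=b)
        assert res.pvalue < 1e-4

    def test_binomial_closed_form(self):
        res = compare_populations("binomial", k=10, n=10, p0=0.5, alternative="greater")
        assert res.pvalue == pytest.approx(0.5**10)

    def test_binomial_matches_mass_summation(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 40))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.1, 0.9))
            res = compare_populations("binomial", k=k, n=n, p0=p0, alternative="greater")
            direct = sum(
                comb(n, x, exact=True) * p0**x * (1 - p0) ** (n - x) for x in range(k, n + 1)
            )
            assert res.pvalue == pytest.approx(float(direct), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_populations("wilcoxon", group_a=[], group_b=[1.0])


class TestAlleleFrequency:
    def test_chr17_style_arithmetic(self):
        gts = ["BB"] * 20 + ["AB"] * 19 + ["AA"] * 23  # 59 B alleles of 124
        assert round(100 * allele_frequency(gts, "B"), 1) == 47.6

    def test_bad_genotype(self):
        with pytest.raises(ValueError):
            allele_frequency(["AC"])
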