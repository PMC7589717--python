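import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polydiff.diversity import (
    allele_frequencies,
    diversity_summary,
    infer_ploidy,
    ld_fisher,
    pic,
)
from tests.conftest import make_dataset
from tests.oracles import fisher_two_sided


class TestAlleleFrequencies:
    def test_presence_counting(self):
        ds = make_dataset({
            "i1": ("A", {"L1": {100}}),
            "i2": ("A", {"L1": {100, 102}}),
        })
        freqs = allele_frequencies(ds)["L1"]
        assert freqs == {100: pytest.approx(2 / 3), 102: pytest.approx(1 / 3)}

    def test_monomorphic(self):
        ds = make_dataset({"i1": ("A", {"L1": {100}}), "i2": ("A", {"L1": {100}})})
        assert allele_frequencies(ds)["L1"] == {100: 1.0}

    def test_order_invariance(self, sim_dataset):
        base = allele_frequencies(sim_dataset)
        shuffled = make_dataset(
            {
                ind: (sim_dataset.population_of[ind],
                      {l: set(sim_dataset.genotypes[ind][l].sizes)
                       for l in sim_dataset.locus_names})
                for ind in reversed(sim_dataset.individuals)
            },
            loci=sim_dataset.loci,
        )
        assert allele_frequencies(shuffled) == base


class TestPic:
    @pytest.mark.parametrize(
        "freqs,expected",
        [({100: 1.0}, 0.0), ({1: 0.5, 2: 0.5}, 0.5), ({1: 0.5, 2: 0.3, 3: 0.2}, 0.62)],
    )
    def test_values(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected)

    def test_rejects_non_normalized(self):
        with pytest.raises(ValueError):
            pic({1: 0.5, 2: 0.6})


class TestDiversitySummary:
    def test_polymorphic_fraction(self):
        # 2 of 3 loci polymorphic in A -> P = 66.67
        ds = make_dataset({
            "i1": ("A", {"L1": {100, 102}, "L2": {200}, "L3": {300, 302}}),
            "i2": ("A", {"L1": {100}, "L2": {200}, "L3": {300}}),
            "j1": ("B", {"L1": {104}, "L2": {200}, "L3": {304}}),
            "j2": ("B", {"L1": {104, 106}, "L2": {202}, "L3": {304}}),
        })
        summary = diversity_summary(ds)
        assert summary.per_population.loc["A", "P"] == pytest.approx(100 * 2 / 3)

    def test_single_allele_individuals_have_zero_ho(self):
        ds = make_dataset({
            "i1": ("A", {"L1": {100}}), "i2": ("A", {"L1": {102}}),
            "j1": ("B", {"L1": {104}}), "j2": ("B", {"L1": {104}}),
        })
        summary = diversity_summary(ds)
        assert (summary.per_population["H_O"] == 0).all()

    def test_two_equifrequent_alleles(self):
        ds = make_dataset({"i1": ("A", {"L1": {100}}), "i2": ("A", {"L1": {102}})})
        summary = diversity_summary(ds)
        assert summary.per_population.loc["A", "A"] == 2
        assert summary.per_population.loc["A", "H_E"] == pytest.approx(0.5)

    def test_rarefaction_monotone_and_bounded(self, sim_dataset):
        richness = []
        for g in (2, 4, 6):
            summary = diversity_summary(sim_dataset, rarefaction_g=g)
            richness.append(summary.per_population["A_R"])
        assert (richness[0] <= richness[1] + 1e-12).all()
        assert (richness[1] <= richness[2] + 1e-12).all()
        final = diversity_summary(sim_dataset)
        assert (final.per_population["A_R"] <= final.per_population["A"] + 1e-12).all()

    def test_oversized_rarefaction_rejected(self, sim_dataset):
        with pytest.raises(ValueError):
            diversity_summary(sim_dataset, rarefaction_g=10_000)

    def test_removing_monomorphic_locus_keeps_he(self):
        rows = {
            "i1": ("A", {"L1": {100, 102}, "L2": {200}}),
            "i2": ("A", {"L1": {100}, "L2": {200}}),
        }
        with_mono = diversity_summary(make_dataset(rows))
        without = diversity_summary(make_dataset({
            ind: (pop, {"L1": geno["L1"]}) for ind, (pop, geno) in rows.items()
        }))
        # H_E of the remaining locus is unchanged; P changes
        he_l1 = 1 - (2 / 3) ** 2 - (1 / 3) ** 2
        assert without.per_population.loc["A", "H_E"] == pytest.approx(he_l1)
        assert with_mono.per_population.loc["A", "P"] == pytest.approx(50.0)
        assert without.per_population.loc["A", "P"] == pytest.approx(100.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(shift=st.integers(min_value=-40, max_value=40))
    def test_he_invariant_under_allele_relabeling(self, shift):
        ds = make_dataset({
            "i1": ("A", {"L1": {100, 102}}), "i2": ("A", {"L1": {104}}),
            "j1": ("B", {"L1": {100}}), "j2": ("B", {"L1": {106, 108}}),
        })
        shifted = make_dataset({
            ind: (pop, {"L1": {a + 2 * shift for a in ds.genotypes[ind]["L1"].sizes}})
            for ind, (pop, _) in {
                i: (ds.population_of[i], None) for i in ds.individuals
            }.items()
        })
        a = diversity_summary(ds).per_population["H_E"]
        b = diversity_summary(shifted).per_population["H_E"]
        assert np.allclose(a, b)


class TestInferPloidy:
    @pytest.mark.parametrize("k,label", [(1, "diploid"), (2, "diploid"),
                                         (3, "tetraploid"), (4, "tetraploid"),
                                         (5, "hexaploid"), (6, "hexaploid")])
    def test_labels(self, k, label):
        sizes = set(range(100, 100 + 2 * k, 2))
        ds = make_dataset({"i1": ("A", {"L1": sizes}), "i2": ("A", {"L1": {100}})})
        assert infer_ploidy(ds) == label

    def test_population_scope(self, sim_dataset):
        assert infer_ploidy(sim_dataset, "QN1") == "diploid"

    def test_all_missing_rejected(self):
        ds = make_dataset({"i1": ("A", {"L1": set()}), "i2": ("A", {"L1": set()})})
        with pytest.raises(ValueError):
            infer_ploidy(ds)


class TestLdFisher:
    def test_exact_value_balanced_association(self):
        # presence patterns give table (5,0,0,5): p = 2/C(10,5)
        rows = {}
        for k in range(5):
            rows[f"p{k}"] = ("A", {"L1": {100}, "L2": {200}})
            rows[f"q{k}"] = ("A", {"L1": {102}, "L2": {202}})
        p = ld_fisher(make_dataset(rows), "L1", "L2")
        assert p == pytest.approx(2 / 252, abs=1e-5)

    def test_perfect_association_is_significant(self):
        rows = {}
        for k in range(10):
            rows[f"p{k}"] = ("A", {"L1": {100}, "L2": {200}})
            rows[f"q{k}"] = ("A", {"L1": {102}, "L2": {202}})
        assert ld_fisher(make_dataset(rows), "L1", "L2") < 0.001

    def test_matches_hypergeometric_oracle(self, sim_dataset):
        from polydiff.diversity import _locus_counts

        loci = sim_dataset.locus_names
        for la, lb in [(loci[0], loci[1]), (loci[1], loci[2])]:
            both = [i for i in sim_dataset.individuals
                    if not sim_dataset.genotypes[i][la].missing
                    and not sim_dataset.genotypes[i][lb].missing]
            major = {}
            for loc in (la, lb):
                counts = _locus_counts(sim_dataset, loc, both)
                major[loc] = min(sorted(counts), key=lambda a: (-counts[a], a))
            af = [major[la] in sim_dataset.genotypes[i][la].sizes for i in both]
            bf = [major[lb] in sim_dataset.genotypes[i][lb].sizes for i in both]
            table = [
                [sum(a and b for a, b in zip(af, bf)), sum(a and not b for a, b in zip(af, bf))],
                [sum(b and not a for a, b in zip(af, bf)), sum(not a and not b for a, b in zip(af, bf))],
            ]
            expected = fisher_two_sided(table)
            assert ld_fisher(sim_dataset, la, lb) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_margin_warns(self):
        rows = {f"i{k}": ("A", {"L1": {100}, "L2": {200 + 2 * (k % 2)}}) for k in range(6)}
        with pytest.warns(UserWarning, match="degenerate"):
            assert ld_fisher(make_dataset(rows), "L1", "L2") == 1.0

    def test_null_uniformity(self):
        # independent presence patterns -> approximately uniform p-values
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            rows = {}
            for k in range(30):
                a = {100} if rng.random() < 0.5 else {102}
                b = {200} if rng.random() < 0.5 else {202}
                rows[f"i{k}"] = ("A", {"L1": a, "L2": b})
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals.append(ld_fisher(make_dataset(rows), "L1", "L2"))
        # Fisher p is conservative; check no excess of small p-values
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.07
        assert np.mean(pvals) > 0.3
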