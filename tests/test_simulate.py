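"""The synthetic complex generator: drift, founding, plastids, reads."""

import numpy as np
import pytest

from allokin.containers import MISSING
from allokin.simulate import (
    SpeciesTreeSpec,
    default_species_tree,
    derive_allotetraploid_plastid,
    found_allotetraploid,
    simulate_complex,
    simulate_diploid_genotypes,
    simulate_parent_frequencies,
    simulate_plastid_haplotypes,
    simulate_reads,
)


def two_taxon_tree(c: float) -> SpeciesTreeSpec:
    return SpeciesTreeSpec(
        taxa=["X", "Y"], clade={"X": "left", "Y": "right"},
        parent={"X": "root", "Y": "root"}, drift={"X": c, "Y": c})


class TestParentFrequencies:
    def test_same_seed_bit_identical(self):
        tree = default_species_tree()
        a = simulate_parent_frequencies(tree, 500, 42)
        b = simulate_parent_frequencies(tree, 500, 42)
        assert np.array_equal(a.values, b.values)

    def test_zero_drift_limit_shares_frequencies(self):
        ft = simulate_parent_frequencies(two_taxon_tree(1e-12), 2000, 3)
        np.testing.assert_allclose(ft["X"], ft["Y"], atol=1e-4)

    def test_drift_coefficient_recovered_by_moment_estimate(self):
        """Sibling differentiation matches the Balding–Nichols c.

        Brute-force moment estimate from the sampled frequencies:
        c_hat = mean((p1-p2)^2 / 2) / mean(pbar qbar + (p1-p2)^2 / 4),
        which has expectation c for two sibling taxa.
        """
        c = 0.1
        ft = simulate_parent_frequencies(two_taxon_tree(c), 50_000, 9)
        p1, p2 = ft["X"], ft["Y"]
        pbar = (p1 + p2) / 2
        num = np.mean((p1 - p2) ** 2 / 2)
        den = np.mean(pbar * (1 - pbar) + (p1 - p2) ** 2 / 4)
        assert num / den == pytest.approx(c, abs=0.01)

    def test_invalid_drift_names_branch(self):
        with pytest.raises(ValueError, match="X"):
            two_taxon_tree(1.5)

    def test_disconnected_tree_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTreeSpec(taxa=["X"], clade={"X": "l"},
                            parent={"X": "ghost"}, drift={"X": 0.1})


class TestDiploidGenotypes:
    def _freqs(self, p, n_loci):
        tree = two_taxon_tree(0.1)
        ft = simulate_parent_frequencies(tree, n_loci, 1)
        ft.values[:] = p
        return ft

    def test_full_inbreeding_all_homozygous(self):
        dm = simulate_diploid_genotypes(self._freqs(0.4, 500), "X", 10, 1.0, 2)
        assert np.all((dm.G == 0) | (dm.G == 2))

    @pytest.mark.parametrize("f_is,expected", [(0.0, 0.5), (0.5, 0.25)])
    def test_heterozygosity_tracks_inbreeding(self, f_is, expected):
        # closed form: 2 p (1-p) (1 - F) at p = 0.5
        dm = simulate_diploid_genotypes(self._freqs(0.5, 10_000), "X", 4,
                                        f_is, 3)
        het = (dm.G == 1).mean()
        assert het == pytest.approx(expected, abs=0.02)

    def test_unknown_taxon_named_in_error(self):
        with pytest.raises(KeyError, match="nope"):
            simulate_diploid_genotypes(self._freqs(0.5, 10), "nope", 2, 0.0, 1)


class TestFoundAllotetraploid:
    def setup_method(self):
        self.tree = default_species_tree()
        self.ft = simulate_parent_frequencies(self.tree, 10_000, 5)

    def test_age_zero_matches_founding_mixture(self):
        dm, row = found_allotetraploid(self.ft, "A1", "B1", 200, 0, 0.0, 6)
        exp = (self.ft["A1"] + self.ft["B1"]) / 2
        obs = dm.G.mean(axis=1) / 4
        assert np.mean(obs - exp) == pytest.approx(0.0, abs=0.005)
        np.testing.assert_allclose(obs, exp, atol=0.2)

    def test_no_mutation_no_new_sites(self):
        dm, row = found_allotetraploid(self.ft, "A1", "B1", 5, 500, 0.0, 7)
        assert row["n_denovo"] == 0
        assert dm.n_sites == self.ft.n_loci

    def test_same_clade_parents_rejected_unless_allowed(self):
        with pytest.raises(ValueError, match="clade"):
            found_allotetraploid(self.ft, "A1", "A2", 5, 0, 0.0, 8,
                                 tree=self.tree)
        dm, _ = found_allotetraploid(self.ft, "A1", "A2", 5, 0, 0.0, 8,
                                     tree=self.tree, allow_same_clade=True)
        assert dm.n_samples == 5

    def test_older_lineage_has_more_private_derived_sites(self):
        wins = 0
        for seed in range(20):
            _, young = found_allotetraploid(
                self.ft, "A1", "B1", 5, 100, 1e-6, 100 + seed,
                invariant_sites=50_000)
            _, old = found_allotetraploid(
                self.ft, "A1", "B1", 5, 10_000, 1e-6, 200 + seed,
                invariant_sites=50_000)
            wins += old["n_denovo"] > young["n_denovo"]
        assert wins >= 19  # >= 95% of 20 seeds

    def test_private_site_count_monotone_in_age_expectation(self):
        ages = [0, 200, 2000, 20_000]
        means = []
        for age in ages:
            counts = [found_allotetraploid(self.ft, "A1", "B1", 2, age,
                                           1e-5, 300 + s)[1]["n_denovo"]
                      for s in range(5)]
            means.append(np.mean(counts))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_tetrasomic_mode_pools_subgenomes(self):
        dm, _ = found_allotetraploid(self.ft, "A1", "B1", 500, 0, 0.0, 9,
                                     inheritance="tetrasomic")
        exp = (self.ft["A1"] + self.ft["B1"]) / 2
        obs = dm.G.mean(axis=1) / 4
        assert np.mean(obs - exp) == pytest.approx(0.0, abs=0.005)
        # polysomic segregation: dosage variance is Binomial(4, p), larger
        # than the disomic Binomial(2,pm)+Binomial(2,pp) at unequal freqs
        with pytest.raises(ValueError):
            found_allotetraploid(self.ft, "A1", "B1", 5, 0, 0.0, 9,
                                 inheritance="hexasomic")

    def test_wf_and_beta_drift_agree_in_moments(self):
        """Per-generation resampling and the Beta endpoint match in
        mean and give comparable spread at matched c."""
        rng_a = np.random.default_rng(1)
        rng_b = np.random.default_rng(2)
        from allokin.simulate import drift_frequency
        p0 = np.full(4000, 0.3)
        age, ne = 200, 500
        f_wf = drift_frequency(rng_a, p0, age, ne, mode="wf")
        f_bn = drift_frequency(rng_b, p0, age, ne, mode="beta")
        assert f_wf.mean() == pytest.approx(f_bn.mean(), abs=0.01)
        assert f_wf.std() == pytest.approx(f_bn.std(), rel=0.15)


class TestPlastid:
    def setup_method(self):
        self.tree = default_species_tree()
        self.haps = simulate_plastid_haplotypes(self.tree, 200, 0.05, 4)

    def test_zero_divergence_identical_to_maternal(self):
        hap = derive_allotetraploid_plastid(self.haps, "A1", 0.0, 5)
        assert np.array_equal(hap, self.haps["A1"])

    def test_copy_closer_to_maternal_than_paternal(self):
        for seed in range(20):
            hap = derive_allotetraploid_plastid(self.haps, "A1", 1e-3,
                                                50 + seed)
            d_mat = (hap != self.haps["A1"]).sum()
            d_pat = (hap != self.haps["B1"]).sum()
            assert d_mat < d_pat

    def test_determinism(self):
        a = simulate_plastid_haplotypes(self.tree, 100, 0.05, 9)
        b = simulate_plastid_haplotypes(self.tree, 100, 0.05, 9)
        assert all(np.array_equal(a[t], b[t]) for t in a)


class TestSimulateReads:
    def _dm(self, g, m, L=2000):
        import pandas as pd
        from allokin.containers import DosageMatrix
        sites = pd.DataFrame({"contig": [f"c{k}" for k in range(L)], "pos": 1,
                              "ref": "A", "alt": "T", "qual": np.nan})
        return DosageMatrix(sites=sites, samples=["i"],
                            G=np.full((L, 1), g, dtype=np.int16),
                            ploidy=np.array([m], dtype=np.int16))

    def test_reference_dosage_negligible_derived_reads(self):
        vt = simulate_reads(self._dm(0, 4), depth=50, base_q=300, seed=1)
        assert vt.D.sum() == 0

    def test_full_dosage_read_fraction_near_one_minus_eps(self):
        vt = simulate_reads(self._dm(4, 4, L=10_000), depth=30, base_q=20,
                            seed=2)
        frac = vt.D.sum() / vt.N.sum()
        se = np.sqrt(0.01 * 0.99 / vt.N.sum())
        assert abs(frac - 0.99) < 3 * se

    def test_mean_depth_matches_poisson_rate(self):
        vt = simulate_reads(self._dm(2, 4, L=10_000), depth=100, base_q=30,
                            seed=3)
        assert vt.N.mean() == pytest.approx(100, abs=1.0)

    def test_zero_depth_cells_missing(self):
        vt = simulate_reads(self._dm(2, 4), depth=1.0, base_q=30, seed=4)
        assert np.all(vt.missing[vt.N == 0])


class TestFullComplex:
    def test_bit_identical_reruns(self, small_config):
        a = simulate_complex(small_config, seed=21)
        b = simulate_complex(small_config, seed=21)
        assert np.array_equal(a.dosages.G, b.dosages.G)
        assert np.array_equal(a.reads.N, b.reads.N)
        assert np.array_equal(a.reads.D, b.reads.D)
        assert np.array_equal(a.plastid.G, b.plastid.G)
        assert a.truth.equals(b.truth)

    def test_truth_covers_every_allotetraploid(self, small_complex):
        sc = small_complex
        assert set(sc.truth["taxon"]) == set(sc.groups.allotetraploid_taxa)
        assert (sc.truth["age"] >= 0).all()

    def test_dosages_respect_ploidy(self, small_complex):
        sc = small_complex
        ok = sc.dosages.G != MISSING
        assert np.all(sc.dosages.G[ok] <= sc.dosages.ploidy[None, :]
                      .repeat(sc.dosages.n_sites, 0)[ok])

    def test_mutation_rate_bounds_enforced(self, small_config):
        import dataclasses
        bad = dataclasses.replace(small_config, mu_sim=1e-3)
        with pytest.raises(ValueError, match="mu_sim"):
            simulate_complex(bad, seed=1)
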