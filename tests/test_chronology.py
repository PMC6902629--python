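"""Private-allele counting, age ranking and clock calibration."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from allokin.chronology import (
    CalibrationParams,
    age_rank,
    calibrate_node_age,
    private_alleles,
)
from allokin.containers import MISSING, DosageMatrix, GroupMap


def family_dm(blocks, ploidy=4):
    """Build a dosage matrix from {taxon: (n_sites x n_ind) arrays}."""
    mats = [np.asarray(b, dtype=np.int16) for b in blocks.values()]
    L = mats[0].shape[0]
    samples, cols = [], []
    ind_taxon = {}
    for taxon, b in zip(blocks, mats):
        for i in range(b.shape[1]):
            name = f"{taxon}_{i}"
            samples.append(name)
            ind_taxon[name] = taxon
        cols.append(b)
    G = np.hstack(cols)
    sites = pd.DataFrame({"contig": [f"c{k}" for k in range(L)], "pos": 1,
                          "ref": "A", "alt": "T", "qual": np.nan})
    dm = DosageMatrix(sites=sites, samples=samples, G=G,
                      ploidy=np.full(len(samples), ploidy, dtype=np.int16))
    gm = GroupMap(individual_taxon=ind_taxon,
                  taxon_role={t: "allotetraploid" for t in blocks},
                  taxon_family={t: "fam" for t in blocks})
    return dm, gm


def brute_force_private(dm, gm, family):
    """Set-algebra oracle: per-taxon observed (site, state) sets."""
    observed = {}
    for taxon in family:
        states = set()
        cols = [dm.samples.index(s) for s in gm.individuals_of(taxon)]
        for l, i in product(range(dm.n_sites), cols):
            g = dm.G[l, i]
            if g == MISSING:
                continue
            if g >= 1:
                states.add((l, "derived"))
            if g < dm.ploidy[i]:
                states.add((l, "ref"))
        observed[taxon] = states
    out = {}
    for taxon in family:
        union_sibs = set()
        for sib in family:
            if sib != taxon:
                union_sibs |= observed[sib]
        out[taxon] = len(observed[taxon] - union_sibs)
    return out


class TestPrivateAlleles:
    def test_toy_family_matches_set_algebra_oracle(self):
        # 2 taxa x 2 individuals x 6 sites, mixed dosages with missing
        blocks = {
            "P": [[0, 0], [4, 4], [2, 1], [0, MISSING], [3, 2], [0, 0]],
            "Q": [[0, 1], [4, 4], [0, 0], [4, 4], [MISSING, 4], [0, 0]],
        }
        dm, gm = family_dm(blocks)
        report = private_alleles(dm, gm, ["P", "Q"])
        oracle = brute_force_private(dm, gm, ["P", "Q"])
        for _, row in report.iterrows():
            assert row["raw"] == oracle[row["taxon"]]
            assert row["corrected"] == row["raw"] * (row["n"] + 1) / row["n"]

    def test_subset_taxon_has_zero_privates(self):
        blocks = {"P": [[1, 1], [2, 2], [0, 0]],
                  "Q": [[1, 0], [2, 4], [0, 3]]}
        dm, gm = family_dm(blocks)
        report = private_alleles(dm, gm, ["P", "Q"]).set_index("taxon")
        assert report.loc["P", "raw"] == 0
        assert report.loc["P", "corrected"] == 0

    @pytest.mark.parametrize("raw,n,expected", [(10, 4, 12.5), (3, 1, 6.0)])
    def test_small_sample_correction_factor(self, raw, n, expected):
        assert raw * (n + 1) / n == expected  # the documented correction

    def test_singleton_family_rejected(self):
        blocks = {"P": [[1, 1]]}
        dm, gm = family_dm(blocks)
        with pytest.raises(ValueError, match="sibling"):
            private_alleles(dm, gm, ["P"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_families_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        blocks = {t: rng.integers(0, 5, size=(30, rng.integers(1, 4)))
                  for t in ["P", "Q", "R"]}
        for b in blocks.values():
            b[rng.random(b.shape) < 0.15] = MISSING
        dm, gm = family_dm(blocks)
        report = private_alleles(dm, gm, list(blocks)).set_index("taxon")
        oracle = brute_force_private(dm, gm, list(blocks))
        for t, raw in oracle.items():
            assert report.loc[t, "raw"] == raw

    def test_relabelling_and_order_invariance(self):
        rng = np.random.default_rng(9)
        blocks = {t: rng.integers(0, 5, size=(25, 2)) for t in ["P", "Q", "R"]}
        dm, gm = family_dm(blocks)
        a = private_alleles(dm, gm, ["P", "Q", "R"]).set_index("taxon")
        b = private_alleles(dm, gm, ["R", "P", "Q"]).set_index("taxon")
        assert (a["raw"].sort_index() == b["raw"].sort_index()).all()

    def test_adding_individual_never_increases_counts(self):
        """More sampled alleles can only shrink private counts."""
        rng = np.random.default_rng(10)
        base = {t: rng.integers(0, 5, size=(40, 2)) for t in ["P", "Q"]}
        extra = np.column_stack([base["Q"], rng.integers(0, 5, size=40)])
        dm1, gm1 = family_dm(base)
        dm2, gm2 = family_dm({"P": base["P"], "Q": extra})
        r1 = private_alleles(dm1, gm1, ["P", "Q"]).set_index("taxon")
        r2 = private_alleles(dm2, gm2, ["P", "Q"]).set_index("taxon")
        assert r2.loc["P", "raw"] <= r1.loc["P", "raw"]


class TestAgeRank:
    def test_ranking_sorts_by_corrected_count(self):
        report = pd.DataFrame({
            "taxon": ["A", "B", "C"], "raw": [100, 10, 55],
            "n": [5, 5, 5], "corrected": [120.0, 12.0, 66.0]})
        ranking, corr = age_rank(report)
        assert list(ranking["taxon"]) == ["A", "C", "B"]
        assert corr.empty

    def test_constructed_linear_anticorrelation(self):
        from allokin.containers import RelatednessMatrix
        taxa = ["A", "B", "C", "D"]
        counts = np.array([10.0, 20.0, 30.0, 40.0])
        report = pd.DataFrame({"taxon": taxa, "raw": counts.astype(int),
                               "n": 5, "corrected": counts})
        samples = [f"{t}_0" for t in taxa] + ["par_0"]
        vals = np.zeros((5, 5))
        # mean relatedness to parent proportional to (1 - count)
        for i, c in enumerate(counts):
            vals[i, 4] = vals[4, i] = 1 - c / 50
        rm = RelatednessMatrix(samples=samples, values=vals)
        gm = GroupMap(
            individual_taxon={f"{t}_0": t for t in taxa} | {"par_0": "par"},
            taxon_role={t: "allotetraploid" for t in taxa}
            | {"par": "candidate_parent"},
            taxon_clade={"par": "west"})
        _, corr = age_rank(report, rm, gm, parent_taxa=["par"])
        assert corr.iloc[0]["pearson_r"] == pytest.approx(-1.0)
        assert corr.iloc[0]["spearman_rho"] == pytest.approx(-1.0)

    def test_two_taxa_suppresses_correlations(self):
        report = pd.DataFrame({"taxon": ["A", "B"], "raw": [5, 10],
                               "n": [2, 2], "corrected": [7.5, 15.0]})
        ranking, corr = age_rank(report)
        assert list(ranking["taxon"]) == ["B", "A"]
        assert corr.empty


class TestCalibration:
    def test_zero_branch_zero_years(self):
        params = CalibrationParams(S=100, L=1000)
        assert calibrate_node_age(0.0, params) == 0.0

    def test_worked_example(self):
        params = CalibrationParams(mu=7e-9, gen_time=5.8, S=2000, L=200_000)
        years = calibrate_node_age(0.01, params)
        assert years == pytest.approx(0.01 * 0.01 / 7e-9 * 5.8, abs=1e-6)
        assert abs(years - 82857.14) < 1.0

    def test_defaults_are_the_standard_plant_clock(self):
        params = CalibrationParams(S=1, L=1)
        assert params.mu == 7e-9
        assert params.gen_time == 5.8

    def test_linearity_and_rate_inversion(self):
        p1 = CalibrationParams(mu=7e-9, gen_time=5.8, S=500, L=5000)
        base = calibrate_node_age(0.02, p1)
        assert calibrate_node_age(0.04, p1) == pytest.approx(2 * base)
        p2 = CalibrationParams(mu=14e-9, gen_time=5.8, S=500, L=5000)
        assert calibrate_node_age(0.02, p2) == pytest.approx(base / 2)
        p3 = CalibrationParams(mu=7e-9, gen_time=11.6, S=500, L=5000)
        assert calibrate_node_age(0.02, p3) == pytest.approx(2 * base)

    def test_no_rescale_flag(self):
        params = CalibrationParams(mu=7e-9, gen_time=5.8, S=2000, L=200_000)
        assert calibrate_node_age(0.0001, params, rescale=False) == \
            pytest.approx(calibrate_node_age(0.01, params))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CalibrationParams(S=10, L=5)
        with pytest.raises(ValueError):
            CalibrationParams(mu=0.0)
        params = CalibrationParams(S=1, L=2)
        with pytest.raises(ValueError):
            calibrate_node_age(-0.1, params)
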