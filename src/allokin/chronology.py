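"""Relative dating of sibling allotetraploids from private alleles.

Within one sibling family (allotetraploids sharing a parental pair),
each taxon's private alleles — allele states observed in that taxon and
in no sibling — accumulate with time since origin, so the corrected
count ranks the siblings by relative age.  The raw count is corrected
for sample size by the factor (n + 1) / n, n being the number of
individuals in the group.  A separate closed form converts species-tree
branch lengths (substitutions per variable site) into years via a
per-generation mutation rate and a generation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, DosageMatrix, GroupMap, RelatednessMatrix

log = logging.getLogger(__name__)

#: mutation rate reported for Arabidopsis, substitutions/site/generation
DEFAULT_MU = 7e-9
#: average generation time (years) used for the focal orchid genus
DEFAULT_GEN_TIME = 5.8


@dataclass
class CalibrationParams:
    """Clock parameters for converting branch lengths to years.

    mu: substitutions/site/generation; gen_time: years/generation;
    S: number of polymorphic sites in the call set; L: total length of
    investigated sites the call set derives from (S <= L).
    """

    mu: float = DEFAULT_MU
    gen_time: float = DEFAULT_GEN_TIME
    S: int = 1
    L: int = 1

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gen_time <= 0 or self.S <= 0 or self.L <= 0:
            raise ValueError("all calibration parameters must be positive")
        if self.S > self.L:
            raise ValueError("polymorphic sites S cannot exceed total length L")


def _observed_states(dm: DosageMatrix, cols: Sequence[int]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per site: is the derived / the reference allele observed in ``cols``?

    An allele counts as observed when at least one non-missing
    individual carries at least one copy; missing genotypes contribute
    no observation.
    """
    G = dm.G[:, cols]
    m = dm.ploidy[cols][None, :]
    obs = G != MISSING
    derived = np.any(obs & (G >= 1), axis=1)
    ref = np.any(obs & (G < m), axis=1)
    return derived, ref


def private_alleles(dm: DosageMatrix, gm: GroupMap,
                    family: Sequence[str]) -> pd.DataFrame:
    """Private-allele counts for each taxon of one sibling family.

    For every taxon, counts (site, allele-state) pairs observed in that
    taxon and unobserved in every sibling of the family, then applies
    the small-sample correction (n + 1)/n with n the taxon's sample
    size.  Requires at least two taxa — against whom else would an
    allele be private?
    """
    family = list(family)
    if len(family) < 2:
        raise ValueError(
            "a sibling family needs >= 2 allotetraploid taxa for the "
            "private-allele comparison; add the sibling lineages")
    obs_d, obs_r = {}, {}
    n_ind = {}
    for taxon in family:
        inds = [s for s in gm.individuals_of(taxon) if s in dm.samples]
        if not inds:
            raise ValueError(f"no genotyped individuals for taxon {taxon!r}")
        cols = [dm.samples.index(s) for s in inds]
        obs_d[taxon], obs_r[taxon] = _observed_states(dm, cols)
        n_ind[taxon] = len(cols)
    rows = []
    for taxon in family:
        sibs = [t for t in family if t != taxon]
        sib_d = np.any([obs_d[t] for t in sibs], axis=0)
        sib_r = np.any([obs_r[t] for t in sibs], axis=0)
        raw = int(np.sum(obs_d[taxon] & ~sib_d) + np.sum(obs_r[taxon] & ~sib_r))
        n = n_ind[taxon]
        rows.append({
            "taxon": taxon,
            "raw": raw,
            "n": n,
            "corrected": raw * (n + 1) / n,
            "family": gm.taxon_family.get(taxon, ""),
        })
    return pd.DataFrame(rows)


def age_rank(
    report: pd.DataFrame,
    rm: RelatednessMatrix | None = None,
    gm: GroupMap | None = None,
    parent_taxa: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank a sibling family by corrected private-allele count.

    More private alleles = relatively older.  With >= 3 taxa and a
    relatedness matrix, also reports Pearson and Spearman correlations
    (with p-values) between corrected counts and each taxon's mean
    relatedness to every parent taxon in ``parent_taxa``.
    """
    ranking = report.sort_values(["corrected", "taxon"],
                                 ascending=[False, True]).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    corr_rows = []
    if rm is not None and gm is not None and len(report) >= 3:
        if parent_taxa is None:
            parent_taxa = gm.candidate_taxa
        counts = report.set_index("taxon")["corrected"]
        for par in parent_taxa:
            par_inds = [s for s in gm.individuals_of(par) if s in rm.samples]
            if not par_inds:
                continue
            means = []
            for taxon in report["taxon"]:
                tet_inds = [s for s in gm.individuals_of(taxon)
                            if s in rm.samples]
                block = rm.submatrix(tet_inds, par_inds)
                vals = block[np.isfinite(block)]
                means.append(vals.mean() if vals.size else np.nan)
            means = np.asarray(means)
            okm = np.isfinite(means)
            if okm.sum() < 3:
                continue
            x = counts.to_numpy()[okm]
            y = means[okm]
            pear = stats.pearsonr(x, y)
            spear = stats.spearmanr(x, y)
            corr_rows.append({
                "parent": par,
                "pearson_r": float(pear.statistic),
                "pearson_p": float(pear.pvalue),
                "spearman_rho": float(spear.statistic),
                "spearman_p": float(spear.pvalue),
                "n": int(okm.sum()),
            })
    elif len(report) < 3:
        log.info("fewer than 3 taxa: correlations suppressed")
    return ranking, pd.DataFrame(
        corr_rows, columns=["parent", "pearson_r", "pearson_p",
                            "spearman_rho", "spearman_p", "n"])


def calibrate_node_age(branch_length: float, params: CalibrationParams,
                       rescale: bool = True) -> float:
    """Convert a branch length into years under a strict clock.

    ``branch_length`` is in substitutions per *variable* site; the
    fraction S/L rescales it to substitutions per investigated site,
    division by mu converts to generations, and gen_time to years:

        age_years = branch_length * (S/L) / mu * gen_time

    With ``rescale=False`` the branch length is taken as already
    per-site.  Linear in branch length and in generation time; doubling
    mu halves the age exactly.
    """
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    scale = params.S / params.L if rescale else 1.0
    return branch_length * scale / params.mu * params.gen_time
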