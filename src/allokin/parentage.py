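"""Maximum-affiliation parentage and maternal-parent assignment.

Each allotetraploid taxon is assigned one parent per parental clade:
the candidate taxon whose individuals show the highest mean relatedness
to the allotetraploid's individuals.  A Mann–Whitney–Wilcoxon rank-sum
test compares the top candidate's relatedness distribution with the
runner-up's; when the difference is not significant the pair is flagged
statistically indistinguishable (the maximum is still reported).  The
maternal parent is the chosen parent with the higher plastid
relatedness, plastids being maternally inherited.

The pairwise relatedness values entering the rank-sum test share
individuals and are therefore not independent; the report carries a
pseudo-replication caveat flag, and ``subsample="per_tet"`` averages to
one observation per allotetraploid individual instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GroupMap, RelatednessMatrix

log = logging.getLogger(__name__)

#: switch point below which the rank-sum p-value is computed exactly
EXACT_N_MAX = 8


@dataclass
class CandidateProfile:
    """Relatedness distribution of one allotetraploid group to one candidate."""

    candidate: str
    values: np.ndarray
    n_tet: int
    n_candidate: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values.size else np.nan

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.values.size else np.nan


def affiliation_profile(
    rm: RelatednessMatrix,
    gm: GroupMap,
    tet: str,
    subsample: str = "all_pairs",
) -> dict[str, CandidateProfile]:
    """Relatedness distributions of ``tet`` to every candidate taxon.

    ``subsample="all_pairs"`` returns every tet-individual x
    candidate-individual value (the distribution shown in the violin
    plots); ``"per_tet"`` collapses to one mean per tet individual,
    removing within-test pseudo-replication.
    """
    if gm.taxon_role.get(tet) != "allotetraploid":
        raise ValueError(f"{tet!r} is not an allotetraploid taxon")
    tet_inds = [s for s in gm.individuals_of(tet) if s in rm.samples]
    out: dict[str, CandidateProfile] = {}
    for cand in gm.candidate_taxa:
        cand_inds = [s for s in gm.individuals_of(cand) if s in rm.samples]
        block = rm.submatrix(tet_inds, cand_inds)
        if subsample == "per_tet":
            with np.errstate(invalid="ignore"):
                vals = np.nanmean(block, axis=1)
            vals = vals[np.isfinite(vals)]
        else:
            vals = block[np.isfinite(block)]
        if vals.size == 0:
            log.warning("no usable relatedness pairs between %s and %s",
                        tet, cand)
        out[cand] = CandidateProfile(candidate=cand, values=np.sort(vals),
                                     n_tet=len(tet_inds),
                                     n_candidate=len(cand_inds))
    return out


def wilcoxon_rank_sum(xs: Sequence[float], ys: Sequence[float]
                      ) -> tuple[float, float]:
    """Two-sided Mann–Whitney–Wilcoxon U test.

    Exact p by enumeration of rank assignments when the smaller sample
    has at most 8 observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xs, ys])
    has_ties = len(np.unique(pooled)) < pooled.size
    if min(xs.size, ys.size) <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class ParentageRow:
    """Parentage call for one allotetraploid taxon."""

    tet: str
    parents: dict[str, str]  # clade -> chosen candidate taxon
    runner_up: dict[str, str | None]
    p_value: dict[str, float]  # top vs runner-up, NaN when single candidate
    u_stat: dict[str, float]
    indistinguishable: dict[str, bool]
    candidate_summary: pd.DataFrame  # candidate, clade, mean, median, n
    maternal: str | None = None
    maternal_margin: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def parent_pair(self) -> tuple[str, ...]:
        return tuple(sorted(self.parents.values()))


def assign_parents(
    profiles: Mapping[str, CandidateProfile],
    gm: GroupMap,
    tet: str,
    alpha: float = 0.05,
    statistic: str = "mean",
) -> ParentageRow:
    """Choose the maximum-affiliation parent in each parental clade.

    ``statistic`` ("mean" or "median") defines how "highest
    relatedness" is summarized; both are reported.  The chosen parent
    is always the argmax — a non-significant top-vs-runner-up test only
    raises the ``indistinguishable`` flag.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    summary_rows = []
    parents: dict[str, str] = {}
    runner: dict[str, str | None] = {}
    pvals: dict[str, float] = {}
    ustat: dict[str, float] = {}
    indist: dict[str, bool] = {}
    flags: list[str] = ["pseudo-replicated pairs in rank-sum test"]
    for clade in gm.clades:
        cands = [c for c in gm.candidates_in_clade(clade)
                 if c in profiles and profiles[c].values.size > 0]
        for c in gm.candidates_in_clade(clade):
            prof = profiles.get(c)
            summary_rows.append({
                "candidate": c, "clade": clade,
                "mean": prof.mean if prof else np.nan,
                "median": prof.median if prof else np.nan,
                "n_pairs": int(prof.values.size) if prof else 0,
            })
            if prof is None or prof.values.size == 0:
                flags.append(f"candidate {c} absent (no usable pairs)")
        if not cands:
            raise ValueError(f"no usable candidate in clade {clade!r} for {tet!r}")
        score = {c: getattr(profiles[c], statistic) for c in cands}
        order = sorted(cands, key=lambda c: (-score[c], c))
        top = order[0]
        parents[clade] = top
        if len(order) == 1:
            runner[clade] = None
            pvals[clade] = np.nan
            ustat[clade] = np.nan
            indist[clade] = False
        else:
            second = order[1]
            runner[clade] = second
            u, p = wilcoxon_rank_sum(profiles[top].values,
                                     profiles[second].values)
            ustat[clade], pvals[clade] = u, p
            indist[clade] = bool(p >= alpha)
            if indist[clade]:
                flags.append(
                    f"{top} and {second} statistically indistinguishable "
                    f"in clade {clade} (p={p:.3g})")
    return ParentageRow(
        tet=tet, parents=parents, runner_up=runner, p_value=pvals,
        u_stat=ustat, indistinguishable=indist,
        candidate_summary=pd.DataFrame(summary_rows), flags=flags)


def assign_maternal(
    plastid_rm: RelatednessMatrix,
    gm: GroupMap,
    tet: str,
    parents: Sequence[str],
    use_sharing: bool = True,
) -> tuple[str | None, float]:
    """Maternal parent = the chosen parent with highest plastid similarity.

    Ranks the two chosen parent taxa by mean plastid similarity to the
    allotetraploid's individuals (allele-sharing fraction by default,
    falling back to the plastid relatedness values).  Returns
    ``(maternal taxon or None, margin)``.
    """
    tet_inds = [s for s in gm.individuals_of(tet) if s in plastid_rm.samples]
    if not tet_inds:
        return None, np.nan
    mat = plastid_rm.sharing if (use_sharing and plastid_rm.sharing is not None) \
        else plastid_rm.values
    tmp = RelatednessMatrix(samples=plastid_rm.samples, values=(mat + mat.T) / 2)
    means = {}
    for par in parents:
        par_inds = [s for s in gm.individuals_of(par) if s in plastid_rm.samples]
        if not par_inds:
            log.warning("no plastid data for parent taxon %s", par)
            return None, np.nan
        block = tmp.submatrix(tet_inds, par_inds)
        vals = block[np.isfinite(block)]
        if vals.size == 0:
            return None, np.nan
        means[par] = float(vals.mean())
    order = sorted(means, key=lambda t: (-means[t], t))
    margin = means[order[0]] - means[order[1]] if len(order) > 1 else np.nan
    return order[0], margin


def parentage_report(
    rm: RelatednessMatrix,
    plastid_rm: RelatednessMatrix | None,
    gm: GroupMap,
    alpha: float = 0.05,
    statistic: str = "mean",
    subsample: str = "all_pairs",
    bh_correct: bool = False,
) -> list[ParentageRow]:
    """Run affiliation, parent choice and maternal assignment for every group.

    ``bh_correct=True`` applies a Benjamini–Hochberg adjustment to the
    top-vs-runner-up p-values across all groups and clades before the
    indistinguishability flags are set (off by default).
    """
    rows = []
    for tet in gm.allotetraploid_taxa:
        profiles = affiliation_profile(rm, gm, tet, subsample=subsample)
        row = assign_parents(profiles, gm, tet, alpha=alpha, statistic=statistic)
        if plastid_rm is not None:
            maternal, margin = assign_maternal(
                plastid_rm, gm, tet, list(row.parents.values()))
            row.maternal = maternal
            row.maternal_margin = margin
            if maternal is None:
                row.flags.append("maternal parent undetermined (plastid data missing)")
        rows.append(row)
    if bh_correct:
        keyed = [(row, clade) for row in rows for clade in row.p_value
                 if np.isfinite(row.p_value[clade])]
        if keyed:
            raw_p = [row.p_value[clade] for row, clade in keyed]
            adjusted = stats.false_discovery_control(raw_p, method="bh")
            for (row, clade), p_adj in zip(keyed, adjusted):
                row.p_value[clade] = float(min(p_adj, 1.0))
                row.indistinguishable[clade] = bool(p_adj >= alpha)
    return rows


def report_frame(rows: Sequence[ParentageRow], gm: GroupMap) -> pd.DataFrame:
    """Flatten parentage rows to one TSV-ready record per allotetraploid."""
    recs = []
    for row in rows:
        rec: dict[str, object] = {"tet": row.tet}
        for clade in gm.clades:
            rec[f"parent_{clade}"] = row.parents.get(clade)
            rec[f"runner_up_{clade}"] = row.runner_up.get(clade)
            rec[f"p_{clade}"] = row.p_value.get(clade)
            rec[f"indistinguishable_{clade}"] = row.indistinguishable.get(clade)
        rec["maternal"] = row.maternal
        rec["maternal_margin"] = row.maternal_margin
        rec["flags"] = "; ".join(row.flags)
        recs.append(rec)
    return pd.DataFrame(recs)
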