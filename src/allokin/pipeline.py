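"""End-to-end orchestration: simulate → filter → call → relatedness →
parentage → chronology, with one config, one seed and a machine-readable
run report.

Every stage writes its artifacts under the output directory and appends
an entry to the report; reruns with identical config and seed produce
byte-identical reports and VCFs (stage RNG streams are spawned from the
global seed in a fixed order, and the report serializer rounds floats
to six significant digits with sorted keys).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    ALLOTETRAPLOID,
    CANDIDATE_PARENT,
    DosageMatrix,
    GroupMap,
    VariantTable,
    load_ploidy_map,
)
from .chronology import age_rank, private_alleles
from .dosage import call_matrix
from .filtering import filter_variants, intersect_callsets
from .kinship import (
    allele_frequencies,
    individual_inbreeding,
    pairwise_relatedness,
    plastid_relatedness,
)
from .parentage import parentage_report, report_frame
from .simulate import SimulationConfig, simulate_complex, write_complex
from .vcfio import read_vcf, write_vcf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: either a simulation config or input VCF paths."""

    outdir: str = "allokin_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    diploid_vcf: str | None = None
    tetraploid_vcf: str | None = None
    plastid_vcf: str | None = None
    ploidy_map: str | None = None
    group_map: str | None = None
    min_qual: float = 100.0
    min_dp: int = 5
    min_call_rate: float = 0.5
    l_min: int = 100
    plastid_l_min: int = 1
    alpha: float = 0.05
    statistic: str = "mean"

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_vcf = self.diploid_vcf is not None or self.tetraploid_vcf is not None
        if has_sim == has_vcf:
            raise ValueError(
                "exactly one of {simulation config, input VCFs} must be set")
        if not has_sim:
            for name in ("diploid_vcf", "tetraploid_vcf", "ploidy_map",
                         "group_map"):
                if getattr(self, name) is None:
                    raise ValueError(f"VCF-mode run requires {name}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            from .simulate import AllotetraploidSpec
            tets = [AllotetraploidSpec(**t) for t in sim.pop("tets", [])]
            cfg.simulation = SimulationConfig(tets=tets, **sim)
        return cfg


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return None
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


@dataclass
class AnalysisResult:
    """In-memory results of the analysis stages (no file I/O)."""

    dosages: DosageMatrix
    relatedness: "object"
    plastid_relatedness: "object | None"
    filter_reports: dict
    parentage_rows: list
    families: dict  # family id -> {"ranking": DataFrame, "correlations": DataFrame}
    inferred_groups: GroupMap


def analyze(
    vt_dip: VariantTable,
    vt_tet: VariantTable,
    vt_plastid: VariantTable | None,
    ploidy: dict,
    groups: GroupMap,
    cfg: RunConfig | None = None,
) -> AnalysisResult:
    """Filter, intersect, call, relate, assign parentage and rank ages.

    The computational core of :func:`run_pipeline`, usable directly on
    in-memory tables (e.g. straight from the simulator).
    """
    cfg = cfg or RunConfig(simulation=SimulationConfig())
    vt_dip_f, rep_d = filter_variants(vt_dip, cfg.min_call_rate,
                                      cfg.min_qual, cfg.min_dp)
    vt_tet_f, rep_t = filter_variants(vt_tet, cfg.min_call_rate,
                                      cfg.min_qual, cfg.min_dp)
    vt_dip_i, vt_tet_i = intersect_callsets(vt_dip_f, vt_tet_f)

    dm_dip, _ = call_matrix(vt_dip_i, ploidy)
    dm_tet, _ = call_matrix(vt_tet_i, ploidy)
    dm = DosageMatrix(
        sites=dm_dip.sites.copy(),
        samples=dm_dip.samples + dm_tet.samples,
        G=np.hstack([dm_dip.G, dm_tet.G]),
        ploidy=np.concatenate([dm_dip.ploidy, dm_tet.ploidy]),
    )

    panel = [s for t in groups.candidate_taxa for s in groups.individuals_of(t)
             if s in dm.samples]
    freqs = allele_frequencies(dm, panel)
    rm = pairwise_relatedness(dm, freqs, l_min=cfg.l_min)
    prm = None
    if vt_plastid is not None:
        vt_pl_f, _ = filter_variants(vt_plastid, cfg.min_call_rate,
                                     cfg.min_qual, cfg.min_dp)
        dm_pl, _ = call_matrix(vt_pl_f, {s: 1 for s in vt_pl_f.samples})
        prm = plastid_relatedness(dm_pl, l_min=cfg.plastid_l_min)

    rows = []
    families: dict = {}
    inferred = groups
    if groups.allotetraploid_taxa:
        rows = parentage_report(rm, prm, groups, alpha=cfg.alpha,
                                statistic=cfg.statistic)
        inferred = GroupMap(
            individual_taxon=dict(groups.individual_taxon),
            taxon_role=dict(groups.taxon_role),
            taxon_clade=dict(groups.taxon_clade),
            taxon_family={row.tet: "x".join(row.parent_pair) for row in rows},
        )
        for family, members in sorted(inferred.families().items()):
            if len(members) < 2:
                families[family] = None  # singleton: comparison undefined
                continue
            tet_dm = dm.take_samples(
                [s for t in members for s in inferred.individuals_of(t)
                 if s in dm.samples])
            pa = private_alleles(tet_dm, inferred, members)
            ranking, corr = age_rank(pa, rm, inferred,
                                     parent_taxa=sorted(set(family.split("x"))))
            families[family] = {"ranking": ranking, "correlations": corr}
    return AnalysisResult(
        dosages=dm, relatedness=rm, plastid_relatedness=prm,
        filter_reports={"diploid": rep_d, "tetraploid": rep_t,
                        "shared_sites": vt_dip_i.n_sites},
        parentage_rows=rows, families=families, inferred_groups=inferred)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "parameters": _round_floats({
            k: v for k, v in asdict(cfg).items() if k != "simulation"}),
    }
    t0 = time.time()

    # -- stage 1: obtain inputs -----------------------------------------
    if cfg.simulation is not None:
        sc = simulate_complex(cfg.simulation, seed=cfg.seed)
        paths = write_complex(sc, outdir / "simulated")
        ploidy = sc.ploidy
        groups = sc.groups
        diploids = [s for s in sc.reads.samples if ploidy[s] == 2]
        tetraploids = [s for s in sc.reads.samples if ploidy[s] == 4]
        vt_dip = sc.reads.take_samples(diploids)
        vt_tet = sc.reads.take_samples(tetraploids)
        vt_plastid = sc.plastid_reads
        report["stages"]["simulate"] = {
            "status": "ok",
            "n_sites": sc.reads.n_sites,
            "n_individuals": sc.reads.n_samples,
            "n_allotetraploids": len(sc.config.tets),
            "outputs": {k: str(v) for k, v in paths.items()},
        }
    else:
        ploidy = load_ploidy_map(cfg.ploidy_map)
        groups = GroupMap.from_tsv(cfg.group_map)
        vt_dip, _ = read_vcf(cfg.diploid_vcf, ploidy)
        vt_tet, _ = read_vcf(cfg.tetraploid_vcf, ploidy)
        vt_plastid = None
        if cfg.plastid_vcf:
            vt_plastid, _ = read_vcf(cfg.plastid_vcf,
                                     {s: 1 for s in ploidy})
        report["stages"]["load"] = {
            "status": "ok",
            "diploid_sites": vt_dip.n_sites,
            "tetraploid_sites": vt_tet.n_sites,
        }
    log.info("inputs ready (%.1fs)", time.time() - t0)

    # -- stages 2-6: the analysis core ----------------------------------
    res = analyze(vt_dip, vt_tet, vt_plastid, ploidy, groups, cfg)
    rep_d = res.filter_reports["diploid"]
    rep_t = res.filter_reports["tetraploid"]
    rep_d.to_frame().to_csv(outdir / "filter_report_diploid.tsv",
                            sep="\t", index=False)
    rep_t.to_frame().to_csv(outdir / "filter_report_tetraploid.tsv",
                            sep="\t", index=False)
    report["stages"]["filter"] = {
        "status": "ok",
        "diploid": asdict(rep_d),
        "tetraploid": asdict(rep_t),
        "shared_sites": res.filter_reports["shared_sites"],
    }

    dm = res.dosages
    dm.to_tsv(outdir / "dosages.tsv")
    report["stages"]["call"] = {
        "status": "ok",
        "called_fraction": float((dm.G != -1).mean()) if dm.G.size else 0.0,
    }

    rm = res.relatedness
    rm.to_tsv(outdir / "relatedness.tsv")
    dip_cand = [s for t in groups.candidate_taxa
                for s in groups.individuals_of(t)
                if s in dm.samples and ploidy[s] == 2]
    if dip_cand:
        fdf = individual_inbreeding(dm.take_samples(dip_cand))
        fdf.to_csv(outdir / "inbreeding.tsv", sep="\t", index=False,
                   float_format="%.6g")
    if res.plastid_relatedness is not None:
        res.plastid_relatedness.to_tsv(outdir / "plastid_relatedness.tsv")
    report["stages"]["relatedness"] = {
        "status": "ok",
        "plastid": res.plastid_relatedness is not None,
    }
    log.info("relatedness done (%.1fs)", time.time() - t0)

    if not groups.allotetraploid_taxa:
        report["stages"]["parentage"] = {"status": "skipped",
                                         "reason": "no allotetraploid taxa"}
        report["stages"]["chronology"] = {"status": "skipped",
                                          "reason": "no allotetraploid taxa"}
        _write_report(report, outdir)
        return report

    rows = res.parentage_rows
    frame = report_frame(rows, groups)
    frame.to_csv(outdir / "parentage.tsv", sep="\t", index=False,
                 float_format="%.6g")
    report["stages"]["parentage"] = {
        "status": "ok",
        "groups": {
            row.tet: {
                "parents": dict(sorted(row.parents.items())),
                "parent_pair": list(row.parent_pair),
                "maternal": row.maternal,
                "maternal_margin": row.maternal_margin,
                "p_values": dict(sorted(row.p_value.items())),
                "indistinguishable": dict(sorted(row.indistinguishable.items())),
            }
            for row in rows
        },
    }
    log.info("parentage assigned (%.1fs)", time.time() - t0)

    chron: dict = {}
    rank_frames = []
    for family, result in sorted(res.families.items()):
        if result is None:
            chron[family] = {"status": "skipped", "reason": "singleton family"}
            continue
        ranking, corr = result["ranking"], result["correlations"]
        rank_frames.append(ranking.assign(family=family))
        chron[family] = {
            "status": "ok",
            "ranking": ranking[["taxon", "raw", "n", "corrected",
                                "rank"]].to_dict("records"),
            "correlations": corr.to_dict("records"),
        }
    if rank_frames:
        pd.concat(rank_frames, ignore_index=True).to_csv(
            outdir / "private_alleles.tsv", sep="\t", index=False,
            float_format="%.6g")
    report["stages"]["chronology"] = {"status": "ok", "families": chron}
    log.info("chronology done (%.1fs)", time.time() - t0)

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    path = outdir / "run_report.json"
    path.write_text(json.dumps(_round_floats(report), indent=2,
                               sort_keys=True) + "\n")
    log.info("report written to %s", path)
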