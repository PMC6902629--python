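"""VCF 4.2 input/output.

Reading goes through :mod:`cyvcf2` (htslib).  Writing uses a small
deterministic text writer: given the same table and dosages it produces
byte-identical files, which the pipeline's reproducibility contract
relies on.  Genotypes are written unphased with the derived-allele
dosage encoded as the number of ``1`` alleles (e.g. tetraploid dosage 2
is ``0/0/1/1``); ``AD`` and ``DP`` carry the derived/total read counts
and the per-site error probability is stored in ``INFO/EPS``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, DosageMatrix, VariantTable, ploidy_vector

_HEADER = """\
##fileformat=VCFv4.2
##source=allokin
##INFO=<ID=EPS,Number=1,Type=Float,Description="Per-site sequencing error probability">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele (ref,alt)">
"""


def _gt_string(dosage: int, m: int) -> str:
    if dosage == MISSING:
        return "/".join(["."] * m)
    return "/".join(["0"] * (m - dosage) + ["1"] * dosage)


def write_vcf(
    vt: VariantTable,
    path: str | Path,
    ploidy: Mapping[str, int],
    dosages: DosageMatrix | None = None,
) -> None:
    """Write a :class:`VariantTable` (and optional refined dosages) as VCF 4.2.

    When ``dosages`` is omitted every GT is emitted as missing; read
    evidence (AD/DP) is written either way.
    """
    pv = ploidy_vector(ploidy, vt.samples)
    if dosages is not None:
        if dosages.samples != vt.samples or dosages.n_sites != vt.n_sites:
            raise ValueError("dosage matrix does not match the variant table")
    contigs = list(dict.fromkeys(vt.sites["contig"]))
    lines = [_HEADER]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples) + "\n")
    sites = vt.sites
    for l in range(vt.n_sites):
        qual = sites.at[l, "qual"]
        qual_s = "." if pd.isna(qual) else f"{float(qual):g}"
        fields = [
            str(sites.at[l, "contig"]),
            str(int(sites.at[l, "pos"])),
            ".",
            str(sites.at[l, "ref"]),
            str(sites.at[l, "alt"]),
            qual_s,
            "PASS",
            f"EPS={vt.eps[l]:.8g}",
            "GT:DP:AD",
        ]
        cells = []
        for i in range(vt.n_samples):
            m = int(pv[i])
            if dosages is None or vt.missing[l, i]:
                g = MISSING
            else:
                g = int(dosages.G[l, i])
            n, d = int(vt.N[l, i]), int(vt.D[l, i])
            cells.append(f"{_gt_string(g, m)}:{n}:{n - d},{d}")
        lines.append("\t".join(fields + cells) + "\n")
    Path(path).write_text("".join(lines))


def read_vcf(path: str | Path, ploidy: Mapping[str, int] | None = None
             ) -> tuple[VariantTable, DosageMatrix | None]:
    """Read a VCF into a :class:`VariantTable` (plus dosages if GTs are called).

    ``D`` is taken from the first ALT column of ``AD``; the per-site
    error comes from ``INFO/EPS`` (0 when absent).  If ``ploidy`` is
    given and the file carries non-missing genotypes, a
    :class:`DosageMatrix` with the derived-allele counts is returned as
    the second element.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, eps_l, N_l, D_l, miss_l, G_l = [], [], [], [], [], []
    any_gt = False
    for v in vcf:
        alt = ",".join(v.ALT) if v.ALT else "."
        rows.append({"contig": v.CHROM, "pos": v.POS, "ref": v.REF,
                     "alt": alt, "qual": v.QUAL if v.QUAL is not None else np.nan})
        eps_l.append(float(v.INFO.get("EPS", 0.0)))
        dp = v.format("DP")
        ad = v.format("AD")
        if dp is None:
            n = np.zeros(len(samples), dtype=np.int64)
        else:
            n = dp.reshape(len(samples)).astype(np.int64)
            n[n < 0] = 0
        if ad is None:
            d = np.zeros(len(samples), dtype=np.int64)
        else:
            d = ad[:, 1].astype(np.int64)
            d[d < 0] = 0
        g = np.full(len(samples), MISSING, dtype=np.int16)
        for i, alleles in enumerate(v.genotypes):
            calls = alleles[:-1]
            if calls and all(a >= 0 for a in calls):
                g[i] = sum(1 for a in calls if a > 0)
                any_gt = True
        N_l.append(n)
        D_l.append(np.minimum(d, n))
        G_l.append(g)
    vcf.close()
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "qual"])
    if not rows:
        vt = VariantTable(sites=sites, samples=samples,
                          N=np.zeros((0, len(samples))),
                          D=np.zeros((0, len(samples))),
                          eps=np.zeros(0),
                          missing=np.zeros((0, len(samples)), dtype=bool))
        return vt, None
    N = np.vstack(N_l)
    G = np.vstack(G_l)
    # Files written without refined genotypes carry all-missing GTs; in
    # that case genotype missingness is defined by depth alone.
    if any_gt:
        missing = (G == MISSING) | (N == 0)
    else:
        missing = N == 0
    vt = VariantTable(
        sites=sites,
        samples=samples,
        N=N,
        D=np.vstack(D_l),
        eps=np.asarray(eps_l),
        missing=missing,
    )
    dm = None
    if any_gt and ploidy is not None:
        dm = DosageMatrix(sites=sites.copy(), samples=samples, G=G,
                          ploidy=ploidy_vector(ploidy, samples))
    return vt, dm
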