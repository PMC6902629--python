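"""Dosage-based relatedness across ploidies, plus per-individual inbreeding.

The central quantity is a product-moment coancestry over standardized
dosage fractions.  For individuals X, Y with ploidies u, v, dosages
x_l, y_l and reference-panel frequencies p_l,

    theta_XY = sum_l (x_l/u - p_l)(y_l/v - p_l) / sum_l p_l (1 - p_l)

over loci co-typed in both individuals and polymorphic in the panel,
and relatedness is r = 2 theta, the ploidy-scale conversion on which a
non-inbred diploid parent–offspring pair has expectation 0.5 and
self-relatedness 1.  Because dosages enter as fractions of ploidy, the
same estimator serves haploid plastid data (u = v = 1), diploids,
and tetraploids in one matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, DosageMatrix, FrequencyTable, RelatednessMatrix

log = logging.getLogger(__name__)

#: minimum co-typed loci for a pair before the estimate is reported
DEFAULT_L_MIN = 100


@dataclass
class FrequencyPanel:
    """Panel allele frequencies with usability flags.

    ``usable`` marks loci with at least two observed allele copies;
    loci fixed in the panel (p in {0, 1}) are additionally excluded by
    the relatedness estimator, where they carry no information and the
    denominator term vanishes.
    """

    p: np.ndarray
    n_copies: np.ndarray
    usable: np.ndarray

    @property
    def polymorphic(self) -> np.ndarray:
        return self.usable & (self.p > 0) & (self.p < 1)


def allele_frequencies(dm: DosageMatrix, panel: Sequence[str] | None = None
                       ) -> FrequencyPanel:
    """Ploidy-weighted derived-allele frequencies over a panel.

    ``p_l = sum_i g_il / sum_i m_i`` across non-missing panel members;
    sites with fewer than two observed allele copies are flagged
    unusable.
    """
    if panel is None:
        panel = dm.samples
    if len(panel) == 0:
        raise ValueError("frequency panel must be non-empty")
    sub = dm.take_samples(list(panel))
    G = sub.G.astype(float)
    obs = sub.G != MISSING
    G[~obs] = 0.0
    copies = (obs * sub.ploidy[None, :].astype(float)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, G.sum(axis=1) / np.maximum(copies, 1), np.nan)
    usable = copies >= 2
    if not usable.all():
        log.info("%d sites unusable for frequencies (<2 allele copies)",
                 int((~usable).sum()))
    return FrequencyPanel(p=p, n_copies=copies, usable=usable)


def pairwise_relatedness(
    dm: DosageMatrix,
    freqs: FrequencyPanel | np.ndarray,
    l_min: int = DEFAULT_L_MIN,
) -> RelatednessMatrix:
    """Product-moment relatedness matrix over all individuals in ``dm``.

    ``freqs`` is a :class:`FrequencyPanel` (from
    :func:`allele_frequencies`) or a raw frequency vector.  Pairs with
    fewer than ``l_min`` co-typed usable loci are reported as NaN.
    """
    if isinstance(freqs, FrequencyPanel):
        p = freqs.p
        ok = freqs.polymorphic
    else:
        p = np.asarray(freqs, dtype=float)
        ok = np.isfinite(p) & (p > 0) & (p < 1)
    if p.shape != (dm.n_sites,):
        raise ValueError("frequency vector length must match site count")

    obs = (dm.G != MISSING) & ok[:, None]
    X = dm.G.astype(float) / dm.ploidy[None, :].astype(float)
    Z = np.where(obs, X - p[:, None], 0.0)
    M = obs.astype(float)
    pq = np.where(ok, p * (1.0 - p), 0.0)

    num = Z.T @ Z
    den = (M * pq[:, None]).T @ M
    counts = (M.T @ M).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = 2.0 * num / den
    r[counts < l_min] = np.nan
    r = (r + r.T) / 2.0  # exact symmetry against floating-point order effects
    return RelatednessMatrix(samples=list(dm.samples), values=r,
                             estimator="product-moment (r = 2*theta)",
                             n_loci=counts)


def individual_inbreeding(
    dm: DosageMatrix,
    freqs: FrequencyPanel | None = None,
) -> pd.DataFrame:
    """Method-of-moments inbreeding F per diploid individual.

    Over each diploid's non-missing polymorphic loci,

        F_i = (O_hom - E_hom) / (L_i - E_hom),

    with E_hom = sum_l [1 - 2 p_l (1-p_l) A_l/(A_l - 1)] and A_l the
    number of allele copies observed at locus l — the small-sample
    corrected expected homozygosity.  F is a relative measure on the
    variable loci of the call set, spanning -1 (max outcrossing) to +1
    (max inbreeding); individuals whose denominator is non-positive get
    NaN and a flag.
    """
    if np.any(dm.ploidy != 2):
        raise ValueError("inbreeding F is defined here for diploids only")
    if freqs is None:
        freqs = allele_frequencies(dm)
    p = freqs.p
    A = freqs.n_copies
    ok = freqs.usable & (p > 0) & (p < 1) & (A > 1)
    rows = []
    for i, s in enumerate(dm.samples):
        use = ok & (dm.G[:, i] != MISSING)
        L = int(use.sum())
        g = dm.G[use, i]
        o_hom = int(np.sum((g == 0) | (g == 2)))
        e_hom = float(np.sum(1.0 - 2.0 * p[use] * (1 - p[use])
                             * (A[use] / (A[use] - 1.0))))
        denom = L - e_hom
        if denom <= 0:
            rows.append({"sample": s, "F": np.nan, "n_loci": L,
                         "flag": "undefined"})
        else:
            rows.append({"sample": s, "F": (o_hom - e_hom) / denom,
                         "n_loci": L, "flag": ""})
    return pd.DataFrame(rows)


def plastid_relatedness(
    ph: DosageMatrix,
    freqs: FrequencyPanel | np.ndarray | None = None,
    l_min: int = 1,
) -> RelatednessMatrix:
    """Relatedness and allele sharing over haploid plastid haplotypes.

    The same product-moment estimator with u = v = 1, plus the raw
    allele-sharing fraction per pair (fraction of co-typed sites with
    identical alleles), which is what maternal-parent assignment
    ultimately ranks.
    """
    if np.any(ph.ploidy != 1):
        raise ValueError("plastid haplotypes must be haploid (ploidy 1)")
    if freqs is None:
        freqs = allele_frequencies(ph)
    rm = pairwise_relatedness(ph, freqs, l_min=l_min)

    obs = ph.G != MISSING
    X = ph.G.astype(float)
    eq = np.zeros((ph.n_samples, ph.n_samples))
    cnt = (obs.astype(float).T @ obs.astype(float))
    # pairwise identity: sum over sites of 1[x==y] restricted to co-typed
    match = ((X * obs).T @ (X * obs)) + (((1 - X) * obs).T @ ((1 - X) * obs))
    with np.errstate(invalid="ignore", divide="ignore"):
        eq = np.where(cnt > 0, match / cnt, np.nan)
    rm.sharing = eq
    return rm


def plot_relatedness_heatmap(rm: RelatednessMatrix, path,
                             include_diagonal: bool = False) -> None:
    """Square heatmap of the relatedness matrix (diagonal blanked by default)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = rm.values.copy()
    if not include_diagonal:
        np.fill_diagonal(vals, np.nan)
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(vals, cmap="viridis")
    ax.set_xticks(range(len(rm.samples)))
    ax.set_yticks(range(len(rm.samples)))
    ax.set_xticklabels(rm.samples, rotation=90, fontsize=5)
    ax.set_yticklabels(rm.samples, fontsize=5)
    fig.colorbar(im, ax=ax, label="relatedness")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
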