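"""Ploidy-aware empirical-Bayes allele-dosage calling.

For an individual of ploidy ``m`` carrying ``g`` derived-allele copies,
a read supports the derived allele with probability

    p_g = (g/m) (1 - eps) + (1 - g/m) eps,

where ``eps`` is the per-site sequencing-error probability.  With a
flat prior over the ``m + 1`` dosages, the posterior is simply the
normalized vector of binomial likelihoods

    P(g | D, N) ∝ Binom(D; N, p_g),

which is evaluated exactly (in log space) — the dosage state space is
small enough that no sampling is required.  The MAP dosage ties break
toward the smaller ``g`` for determinism.  In the one degenerate case —
``eps = 0`` with reads of both alleles, so every dosage has likelihood
exactly zero — the log-space floor leaves the flat prior unchanged and
the cell posterior is uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .containers import MISSING, DosageMatrix, VariantTable, ploidy_vector

log = logging.getLogger(__name__)

SUPPORTED_PLOIDIES = (1, 2, 4)

#: floor on log-likelihoods, generous for read depths in the hundreds
LOG_FLOOR = -745.0  # ~ log(smallest normal double)

#: cap applied to per-site error estimates, keeping eps strictly below 0.5
EPS_CAP = 0.5 - 1e-9


@dataclass
class DosagePosterior:
    """Flat-prior dosage posteriors for one call set.

    ``probs[l, i, g]`` is the posterior probability that individual
    ``i`` carries ``g`` derived copies at site ``l``; entries with
    ``g`` above the individual's ploidy are NaN.  Missing cells carry a
    uniform posterior and ``missing=True``.
    """

    probs: np.ndarray  # (n_sites, n_samples, max_ploidy + 1)
    map_dosage: np.ndarray  # (n_sites, n_samples), MISSING where no data
    missing: np.ndarray
    ploidy: np.ndarray


def per_site_error(base_qualities: Sequence[float]) -> float:
    """Mean error probability implied by the Phred scores of covering reads.

    ``eps = mean(10^(-Q/10))``, capped just below 0.5 so the
    derived/reference symmetry of the read model never degenerates.
    """
    q = np.asarray(base_qualities, dtype=float)
    if q.size == 0:
        raise ValueError("a variant site must have at least one covering read")
    if np.any(q < 2):
        raise ValueError("Phred scores below 2 are not meaningful here")
    return float(min(np.mean(10.0 ** (-q / 10.0)), EPS_CAP))


def _log_binom_pmf(D: np.ndarray, N: np.ndarray, p: np.ndarray) -> np.ndarray:
    """log Binomial(D; N, p) with exact handling of p in {0, 1}."""
    D = np.asarray(D, dtype=float)
    N = np.asarray(N, dtype=float)
    p = np.asarray(p, dtype=float)
    coef = gammaln(N + 1) - gammaln(D + 1) - gammaln(N - D + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(D > 0, D * np.log(p), 0.0)
        term2 = np.where(N - D > 0, (N - D) * np.log1p(-p), 0.0)
    out = coef + term1 + term2
    out = np.where(np.isnan(out), -np.inf, out)
    return np.maximum(out, LOG_FLOOR)


def dosage_posterior(N: int, D: int, m: int, eps: float
                     ) -> tuple[np.ndarray, int, bool]:
    """Posterior over dosages for a single genotype cell.

    Returns ``(posterior over g in 0..m, MAP dosage, missing)``; with
    ``N == 0`` the posterior is uniform and the cell is missing.
    """
    if not (0 <= D <= N):
        raise ValueError("require 0 <= D <= N")
    if m not in SUPPORTED_PLOIDIES:
        raise ValueError(f"unsupported ploidy {m}; supported: {SUPPORTED_PLOIDIES}")
    if not (0 <= eps < 0.5):
        raise ValueError("eps must lie in [0, 0.5)")
    if N == 0:
        return np.full(m + 1, 1.0 / (m + 1)), MISSING, True
    g = np.arange(m + 1)
    p_g = (g / m) * (1 - eps) + (1 - g / m) * eps
    logL = _log_binom_pmf(np.full(m + 1, D), np.full(m + 1, N), p_g)
    post = np.exp(logL - logsumexp(logL))
    post /= post.sum()
    return post, int(np.argmax(post)), False


def call_matrix(vt: VariantTable, ploidy: Mapping[str, int]
                ) -> tuple[DosageMatrix, DosagePosterior]:
    """MAP dosages and posteriors for every cell of a filtered table.

    Cells are grouped by ploidy and evaluated vectorized; ties in the
    MAP break toward the smaller dosage (``argmax`` takes the first
    maximum).
    """
    pv = ploidy_vector(ploidy, vt.samples)
    bad = [s for s, m in zip(vt.samples, pv) if m not in SUPPORTED_PLOIDIES]
    if bad:
        raise ValueError(f"unsupported ploidy for individuals {bad}; "
                         f"supported ploidies: {SUPPORTED_PLOIDIES}")
    max_m = int(pv.max()) if len(pv) else 2
    ns, ni = vt.n_sites, vt.n_samples
    probs = np.full((ns, ni, max_m + 1), np.nan)
    G = np.full((ns, ni), MISSING, dtype=np.int16)
    eps = np.clip(vt.eps, 0.0, EPS_CAP)[:, None]

    for m in sorted(set(int(x) for x in pv)):
        cols = np.flatnonzero(pv == m)
        N = vt.N[:, cols]
        D = vt.D[:, cols]
        logL = np.empty((ns, len(cols), m + 1))
        for g in range(m + 1):
            p_g = (g / m) * (1 - eps) + (1 - g / m) * eps
            logL[:, :, g] = _log_binom_pmf(D, N, np.broadcast_to(p_g, N.shape))
        post = np.exp(logL - logsumexp(logL, axis=2, keepdims=True))
        post /= post.sum(axis=2, keepdims=True)
        miss = vt.missing[:, cols] | (N == 0)
        post[miss] = 1.0 / (m + 1)
        g_map = np.argmax(post, axis=2).astype(np.int16)
        g_map[miss] = MISSING
        probs[:, cols, : m + 1] = post
        if m < max_m:
            probs[:, cols, m + 1:] = np.nan
        G[:, cols] = g_map

    called = G != MISSING
    log.info("dosage calling: %d/%d cells called (%.1f%%)",
             called.sum(), called.size,
             100.0 * called.sum() / max(called.size, 1))
    dm = DosageMatrix(sites=vt.sites.copy(), samples=list(vt.samples),
                      G=G, ploidy=pv)
    dp = DosagePosterior(probs=probs, map_dosage=G.copy(),
                         missing=G == MISSING, ploidy=pv)
    return dm, dp
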