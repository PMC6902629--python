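"""Variant filtering and diploid/tetraploid call-set intersection.

The analysis-ready table keeps biallelic SNPs with a minimum site
quality of 100, masks genotypes below five reads, and requires data for
at least half of the individuals.  Rules are applied in a fixed order —
depth mask, biallelic, QUAL, call rate — so the completeness test sees
depth-masked missingness, and every threshold is inclusive (``>=``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import VariantTable

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-rule accounting of what the filters removed."""

    input_sites: int = 0
    masked_genotypes: int = 0
    dropped_multiallelic: int = 0
    dropped_qual: int = 0
    dropped_call_rate: int = 0
    output_sites: int = 0

    def dropped_total(self) -> int:
        return (self.dropped_multiallelic + self.dropped_qual
                + self.dropped_call_rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": ["input_sites", "masked_genotypes", "multiallelic",
                      "qual", "call_rate", "output_sites"],
             "count": [self.input_sites, self.masked_genotypes,
                       self.dropped_multiallelic, self.dropped_qual,
                       self.dropped_call_rate, self.output_sites]})


def filter_variants(
    vt: VariantTable,
    min_call_rate: float = 0.5,
    min_qual: float = 100.0,
    min_dp: int = 5,
) -> tuple[VariantTable, FilterReport]:
    """Apply depth masking and the site-level retention rules.

    Genotypes with fewer than ``min_dp`` reads are set missing; a site
    is then retained iff it is biallelic, ``QUAL >= min_qual`` (missing
    QUAL fails) and its non-missing fraction is at least
    ``min_call_rate``.  Returns the filtered table and a
    :class:`FilterReport` with per-rule drop counts.
    """
    if min_call_rate < 0 or min_qual < 0 or min_dp < 0:
        raise ValueError("filter thresholds must be non-negative")
    report = FilterReport(input_sites=vt.n_sites)
    if vt.n_sites == 0:
        log.warning("filter_variants received an empty table")
        report.output_sites = 0
        return vt.copy(), report

    out = vt.copy()
    newly_masked = (out.N < min_dp) & ~out.missing
    report.masked_genotypes = int(newly_masked.sum())
    out.missing |= out.N < min_dp

    biallelic = out.is_biallelic()
    report.dropped_multiallelic = int((~biallelic).sum())

    qual = out.sites["qual"].to_numpy(dtype=float)
    qual_ok = ~np.isnan(qual) & (qual >= min_qual)
    report.dropped_qual = int((biallelic & ~qual_ok).sum())

    if out.n_samples == 0:
        call_rate = np.zeros(out.n_sites)
    else:
        call_rate = 1.0 - out.missing.mean(axis=1)
    rate_ok = call_rate >= min_call_rate
    report.dropped_call_rate = int((biallelic & qual_ok & ~rate_ok).sum())

    keep = np.flatnonzero(biallelic & qual_ok & rate_ok)
    report.output_sites = len(keep)
    return out.take_sites(keep), report


def intersect_callsets(
    a: VariantTable, b: VariantTable
) -> tuple[VariantTable, VariantTable]:
    """Restrict two call sets to the (contig, pos, ref, alt) tuples they share.

    Order is preserved from each input.  Sites at the same position but
    with mismatched alleles are excluded (and logged), so the result is
    symmetric in its arguments.
    """
    keys_a = a.allele_keys()
    keys_b = b.allele_keys()
    shared = set(keys_a) & set(keys_b)
    pos_a = {(k[0], k[1]) for k in keys_a}
    pos_b = {(k[0], k[1]) for k in keys_b}
    for k in sorted(set(keys_a) ^ set(keys_b)):
        if (k[0], k[1]) in pos_a and (k[0], k[1]) in pos_b:
            log.info("allele mismatch at %s:%s excluded from intersection",
                     k[0], k[1])
    idx_a = np.array([i for i, k in enumerate(keys_a) if k in shared], dtype=int)
    idx_b = np.array([i for i, k in enumerate(keys_b) if k in shared], dtype=int)
    return a.take_sites(idx_a), b.take_sites(idx_b)
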