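"""Core data containers shared across the pipeline.

The pipeline moves through three in-memory representations:

``VariantTable``
    read evidence — per site and individual, total (``N``) and
    derived-allele (``D``) read counts, plus a per-site sequencing-error
    probability and the site QUAL.
``DosageMatrix``
    derived-allele dosages (0..ploidy) per individual per site, the
    genotype representation shared by all downstream statistics.
``RelatednessMatrix``
    symmetric pairwise relatedness on the scale where a non-inbred
    diploid parent–offspring pair has expectation 0.5.

``GroupMap`` carries the study design: which individuals belong to which
taxon, which taxa are candidate parents (and in which parental clade) and
which are allotetraploids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing dosage in :class:`DosageMatrix.G`
MISSING: int = -1

SITE_COLUMNS = ("contig", "pos", "ref", "alt", "qual")

CANDIDATE_PARENT = "candidate_parent"
ALLOTETRAPLOID = "allotetraploid"


def _as_2d(a: np.ndarray, name: str, n_sites: int, n_samples: int) -> np.ndarray:
    a = np.asarray(a)
    if a.shape != (n_sites, n_samples):
        raise ValueError(
            f"{name} has shape {a.shape}, expected {(n_sites, n_samples)}"
        )
    return a


@dataclass
class VariantTable:
    """Per-site, per-individual read evidence for a cohort.

    Parameters
    ----------
    sites
        DataFrame with columns ``contig, pos, ref, alt, qual`` (1-based
        positions; ``alt`` may hold a comma-separated list for sites not
        yet reduced to biallelic).
    samples
        Ordered individual identifiers (columns of the count matrices).
    N, D
        Integer arrays of shape ``(n_sites, n_samples)`` with total and
        derived read counts; ``0 <= D <= N`` cellwise.
    eps
        Per-site sequencing-error probability, each in ``[0, 0.5)``.
    missing
        Boolean mask of genotypes with no usable data (always true where
        ``N == 0``).
    """

    sites: pd.DataFrame
    samples: list[str]
    N: np.ndarray
    D: np.ndarray
    eps: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        for col in SITE_COLUMNS:
            if col not in self.sites.columns:
                raise ValueError(f"sites is missing required column {col!r}")
        self.samples = list(self.samples)
        ns, ni = len(self.sites), len(self.samples)
        self.N = _as_2d(self.N, "N", ns, ni).astype(np.int32)
        self.D = _as_2d(self.D, "D", ns, ni).astype(np.int32)
        self.missing = _as_2d(self.missing, "missing", ns, ni).astype(bool)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.eps.shape != (ns,):
            raise ValueError(f"eps has shape {self.eps.shape}, expected ({ns},)")
        if np.any(self.D > self.N) or np.any(self.D < 0):
            raise ValueError("require 0 <= D <= N cellwise")
        if np.any((self.eps < 0) | (self.eps >= 0.5)):
            raise ValueError("per-site error must lie in [0, 0.5)")
        # no data implies missing
        self.missing |= self.N == 0
        keys = list(self.site_keys())
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (contig, pos) site keys")

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> list[tuple]:
        """(contig, pos) keys, unique by construction."""
        return list(zip(self.sites["contig"], self.sites["pos"]))

    def allele_keys(self) -> list[tuple]:
        """(contig, pos, ref, alt) tuples used for call-set intersection."""
        return list(
            zip(self.sites["contig"], self.sites["pos"],
                self.sites["ref"], self.sites["alt"])
        )

    def is_biallelic(self) -> np.ndarray:
        alt = self.sites["alt"].astype(str)
        return (~alt.str.contains(",") & (alt != ".") & (alt != "")).to_numpy()

    def take_sites(self, index: np.ndarray) -> "VariantTable":
        index = np.asarray(index)
        return VariantTable(
            sites=self.sites.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            N=self.N[index],
            D=self.D[index],
            eps=self.eps[index],
            missing=self.missing[index],
        )

    def take_samples(self, names: Sequence[str]) -> "VariantTable":
        idx = [self.samples.index(s) for s in names]
        return VariantTable(
            sites=self.sites.copy(),
            samples=[self.samples[i] for i in idx],
            N=self.N[:, idx],
            D=self.D[:, idx],
            eps=self.eps.copy(),
            missing=self.missing[:, idx],
        )

    def copy(self) -> "VariantTable":
        return VariantTable(
            sites=self.sites.copy(),
            samples=list(self.samples),
            N=self.N.copy(),
            D=self.D.copy(),
            eps=self.eps.copy(),
            missing=self.missing.copy(),
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and self.sites.reset_index(drop=True).equals(
                other.sites.reset_index(drop=True))
            and np.array_equal(self.N, other.N)
            and np.array_equal(self.D, other.D)
            and np.allclose(self.eps, other.eps, atol=1e-12)
            and np.array_equal(self.missing, other.missing)
        )


@dataclass
class DosageMatrix:
    """Derived-allele dosages per individual per site.

    ``G[l, i]`` is the number of derived-allele copies carried by
    individual ``i`` at site ``l`` (0..ploidy), or :data:`MISSING`.
    ``ploidy[i]`` is the individual's ploidy (1, 2 or 4 here).
    """

    sites: pd.DataFrame
    samples: list[str]
    G: np.ndarray
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = list(self.samples)
        ns, ni = len(self.sites), len(self.samples)
        self.G = _as_2d(self.G, "G", ns, ni).astype(np.int16)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int16)
        if self.ploidy.shape != (ni,):
            raise ValueError("one ploidy per sample required")
        over = (self.G > self.ploidy[None, :]) & (self.G != MISSING)
        if np.any(over):
            raise ValueError("dosage exceeds ploidy")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def missing(self) -> np.ndarray:
        return self.G == MISSING

    def ploidy_of(self, sample: str) -> int:
        return int(self.ploidy[self.samples.index(sample)])

    def take_samples(self, names: Sequence[str]) -> "DosageMatrix":
        idx = [self.samples.index(s) for s in names]
        return DosageMatrix(
            sites=self.sites.copy(),
            samples=[self.samples[i] for i in idx],
            G=self.G[:, idx],
            ploidy=self.ploidy[idx],
        )

    def take_sites(self, index: np.ndarray) -> "DosageMatrix":
        index = np.asarray(index)
        return DosageMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            G=self.G[index],
            ploidy=self.ploidy.copy(),
        )

    # -- TSV round trip --------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.G, columns=self.samples)
        meta = self.sites[["contig", "pos", "ref", "alt"]].reset_index(drop=True)
        out = pd.concat([meta, df], axis=1)
        with open(path, "w") as fh:
            fh.write("#ploidy\t" + "\t".join("" for _ in range(3)) + "\t"
                     + "\t".join(str(int(p)) for p in self.ploidy) + "\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DosageMatrix":
        with open(path) as fh:
            first = fh.readline().rstrip("\n").split("\t")
            if first[0] != "#ploidy":
                raise ValueError("dosage TSV must start with a #ploidy line")
            ploidy = np.array([int(x) for x in first[4:]], dtype=np.int16)
            body = pd.read_csv(fh, sep="\t")
        samples = list(body.columns[4:])
        sites = body[["contig", "pos", "ref", "alt"]].copy()
        sites["qual"] = np.nan
        return cls(sites=sites, samples=samples,
                   G=body[samples].to_numpy(), ploidy=ploidy)


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise relatedness with estimator metadata."""

    samples: list[str]
    values: np.ndarray  # (n, n) float, NaN where a pair is unusable
    estimator: str = "product-moment"
    n_loci: np.ndarray | None = None  # co-typed locus counts per pair
    sharing: np.ndarray | None = None  # raw allele-sharing fraction (plastid)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        n = len(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over samples")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("relatedness matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.samples.index(a), self.samples.index(b)])

    def submatrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        ri = [self.samples.index(s) for s in rows]
        ci = [self.samples.index(s) for s in cols]
        return self.values[np.ix_(ri, ci)]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.samples, columns=self.samples)
        df.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA",
                  index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path, estimator: str = "product-moment"
                 ) -> "RelatednessMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(samples=list(df.columns), values=df.to_numpy(),
                   estimator=estimator)


@dataclass
class GroupMap:
    """Study design: individuals → taxa; taxa → role / clade / family.

    Roles are ``candidate_parent`` or ``allotetraploid``.  Candidate taxa
    carry a parental-clade label (exactly two clades by default);
    allotetraploid taxa may carry a sibling-family label, normally
    assigned *after* parentage inference (taxa sharing an inferred parent
    pair form one family).
    """

    individual_taxon: dict[str, str]
    taxon_role: dict[str, str]
    taxon_clade: dict[str, str] = field(default_factory=dict)
    taxon_family: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, taxon in self.individual_taxon.items():
            if taxon not in self.taxon_role:
                raise ValueError(f"individual {ind!r} maps to unknown taxon {taxon!r}")
        for taxon, role in self.taxon_role.items():
            if role not in (CANDIDATE_PARENT, ALLOTETRAPLOID):
                raise ValueError(f"unknown role {role!r} for taxon {taxon!r}")
            if role == CANDIDATE_PARENT and taxon not in self.taxon_clade:
                raise ValueError(f"candidate taxon {taxon!r} has no clade label")

    def individuals_of(self, taxon: str) -> list[str]:
        return [i for i, t in self.individual_taxon.items() if t == taxon]

    def taxa_with_role(self, role: str) -> list[str]:
        return [t for t, r in self.taxon_role.items() if r == role]

    @property
    def candidate_taxa(self) -> list[str]:
        return self.taxa_with_role(CANDIDATE_PARENT)

    @property
    def allotetraploid_taxa(self) -> list[str]:
        return self.taxa_with_role(ALLOTETRAPLOID)

    @property
    def clades(self) -> list[str]:
        seen: list[str] = []
        for t in self.candidate_taxa:
            c = self.taxon_clade[t]
            if c not in seen:
                seen.append(c)
        return seen

    def candidates_in_clade(self, clade: str) -> list[str]:
        return [t for t in self.candidate_taxa if self.taxon_clade[t] == clade]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for t in self.allotetraploid_taxa:
            fam = self.taxon_family.get(t)
            if fam is not None:
                fams.setdefault(fam, []).append(t)
        return fams

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for ind in self.individual_taxon:
            taxon = self.individual_taxon[ind]
            rows.append({
                "sample": ind,
                "taxon": taxon,
                "role": self.taxon_role[taxon],
                "clade": self.taxon_clade.get(taxon, ""),
                "family": self.taxon_family.get(taxon, ""),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupMap":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        gm = cls(
            individual_taxon=dict(zip(df["sample"], df["taxon"])),
            taxon_role={r.taxon: r.role for r in df.itertuples()},
            taxon_clade={r.taxon: r.clade for r in df.itertuples() if r.clade},
            taxon_family={r.taxon: r.family for r in df.itertuples()
                          if getattr(r, "family", "")},
        )
        return gm


# ---------------------------------------------------------------------------
# ploidy maps: plain dicts with TSV helpers

def write_ploidy_map(ploidy: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame({"sample": list(ploidy), "ploidy": list(ploidy.values())}
                 ).to_csv(path, sep="\t", index=False)


def load_ploidy_map(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["ploidy"].astype(int)))


def ploidy_vector(ploidy: Mapping[str, int], samples: Sequence[str]) -> np.ndarray:
    """Per-sample ploidy array; error names any unmapped individual."""
    out = np.empty(len(samples), dtype=np.int16)
    for i, s in enumerate(samples):
        if s not in ploidy:
            raise KeyError(f"no ploidy recorded for individual {s!r}")
        out[i] = ploidy[s]
    return out


@dataclass
class FrequencyTable:
    """Per-taxon derived-allele frequencies across loci, all in [0, 1]."""

    taxa: list[str]
    values: np.ndarray  # (n_taxa, n_loci)

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.taxa):
            raise ValueError("values must be (n_taxa, n_loci)")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def __getitem__(self, taxon: str) -> np.ndarray:
        try:
            return self.values[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None
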