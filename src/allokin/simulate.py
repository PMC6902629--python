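"""Forward simulation of a synthetic allopolyploid complex.

The generator builds the study system the inference pipeline assumes:

* two diverged clades of diploid candidate-parent taxa whose
  derived-allele frequencies drift along a species tree under the
  Balding–Nichols model (child frequency ~ Beta with mean equal to the
  parent frequency and variance ``c p (1-p)``);
* within-taxon inbreeding via a per-taxon F_is;
* allotetraploids founded by one unreduced-gamete genome from each of
  two parent taxa in different clades, with strictly disomic
  inheritance (the two subgenomes never exchange alleles);
* post-origin drift of each subgenome for ``age`` generations and
  accumulation of lineage-private derived substitutions at a pool of
  previously monomorphic sites, so older lineages carry more private
  alleles;
* maternally inherited plastid haplotypes (an allotetraploid's plastid
  is a lightly diverged copy of its maternal taxon's); and
* short-read evidence: Poisson total depth and binomial derived-read
  counts under a per-base error rate, written as VCF 4.2.

Post-founding drift is applied by default as the Balding–Nichols
endpoint with ``c = 1 - exp(-age / 2Ne)`` — the diffusion limit of
per-generation Wright–Fisher binomial resampling, which is also
available exactly via ``drift_mode="wf"``.  New mutations are modelled
as lineage substitutions (weak-mutation limit): a mutated site becomes
fixed for the derived allele in one subgenome, so ``mu_sim`` is a
per-site per-generation substitution probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ALLOTETRAPLOID,
    CANDIDATE_PARENT,
    MISSING,
    DosageMatrix,
    FrequencyTable,
    GroupMap,
    VariantTable,
    write_ploidy_map,
)
from .vcfio import write_vcf

# ---------------------------------------------------------------------------
# species tree


@dataclass
class SpeciesTreeSpec:
    """Rooted species tree over candidate taxa with per-branch drift.

    ``parent`` maps every non-root node to its parent; ``drift[node]``
    is the Balding–Nichols coefficient c of the branch above ``node``,
    strictly inside (0, 1).  ``clade`` labels each *taxon* (leaf) with
    one of the two parental clades.
    """

    taxa: list[str]
    clade: dict[str, str]
    parent: dict[str, str]
    drift: dict[str, float]
    root: str = "root"

    def __post_init__(self) -> None:
        for t in self.taxa:
            if t not in self.clade:
                raise ValueError(f"taxon {t!r} has no clade label")
        for node, c in self.drift.items():
            if not (0.0 < c < 1.0):
                raise ValueError(
                    f"drift coefficient on branch above {node!r} is {c}; "
                    "must lie strictly in (0, 1)")
        # connectivity / acyclicity: every node must reach the root
        for node in self.parent:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle in species tree at {cur!r}")
                seen.add(cur)
                if cur not in self.parent:
                    raise ValueError(f"node {cur!r} is disconnected from the root")
                cur = self.parent[cur]

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parent.items() if p == node)

    def clade_of(self, taxon: str) -> str:
        return self.clade[taxon]


def default_species_tree(
    clade_drift: float = 0.2, taxon_drift: float = 0.1
) -> SpeciesTreeSpec:
    """Two clades of three diploid taxa each (A1–A3 vs B1–B3)."""
    taxa = ["A1", "A2", "A3", "B1", "B2", "B3"]
    parent = {"cladeA": "root", "cladeB": "root"}
    drift = {"cladeA": clade_drift, "cladeB": clade_drift}
    clade = {}
    for t in taxa:
        anc = "cladeA" if t.startswith("A") else "cladeB"
        parent[t] = anc
        drift[t] = taxon_drift
        clade[t] = anc
    return SpeciesTreeSpec(taxa=taxa, clade=clade, parent=parent, drift=drift)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AllotetraploidSpec:
    """One simulated allotetraploid lineage of known origin."""

    label: str
    maternal: str
    paternal: str
    age: int
    n_ind: int = 5


@dataclass
class SimulationConfig:
    """Parameters of the synthetic complex.

    Defaults emulate a polymorphism-ascertained RADseq study of a
    two-clade orchid complex: 5,000 variable nuclear loci over six
    candidate taxa and sixteen allotetraploids of five individuals
    each, ~200x sequencing depth at Phred 30, and a plastid panel of
    200 sites.
    """

    n_loci: int = 5000
    n_ind: int = 5
    f_is: dict[str, float] = field(default_factory=dict)
    tets: list[AllotetraploidSpec] = field(default_factory=list)
    mu_sim: float = 1e-5
    invariant_sites: int = 20000
    n_e: int = 50000
    plastid_sites: int = 200
    plastid_branch_divergence: float = 0.05
    plastid_divergence: float = 1e-3
    depth: float = 200.0
    base_q: float = 30.0
    site_qual: float = 200.0
    drift_mode: str = "beta"
    inheritance: str = "disomic"
    allow_same_clade: bool = False

    def validate(self, tree: SpeciesTreeSpec) -> None:
        if self.n_loci < 1 or self.n_ind < 1 or self.plastid_sites < 1:
            raise ValueError("counts must be positive")
        if self.depth <= 0:
            raise ValueError("mean depth must be positive")
        if not (0.0 <= self.mu_sim <= 1e-4):
            raise ValueError("mu_sim must lie in [0, 1e-4]")
        if self.base_q < 2:
            raise ValueError("base quality must be >= 2")
        for t, f in self.f_is.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"F_is for {t!r} must lie in [0, 1]")
        for spec in self.tets:
            if spec.maternal == spec.paternal:
                raise ValueError(f"{spec.label}: identical parents")
            same = (tree.clade_of(spec.maternal) == tree.clade_of(spec.paternal))
            if same and not self.allow_same_clade:
                raise ValueError(
                    f"{spec.label}: parents {spec.maternal}/{spec.paternal} "
                    "are in the same clade (set allow_same_clade to override)")
            if spec.age < 0 or spec.n_ind < 1:
                raise ValueError(f"{spec.label}: age >= 0 and n_ind >= 1 required")


def default_config() -> SimulationConfig:
    """The default synthetic complex: 16 allotetraploids over 6 candidates.

    The A1 x B1 family spans ages 100–20,000 generations, giving a
    four-taxon sibling family for relative-age ranking; maternal
    parents alternate between clades so plastid direction calls are
    exercised both ways.
    """
    tets = [
        AllotetraploidSpec("T01", "A1", "B1", 100),
        AllotetraploidSpec("T02", "A1", "B1", 1000),
        AllotetraploidSpec("T03", "B1", "A1", 5000),
        AllotetraploidSpec("T04", "A1", "B1", 20000),
        AllotetraploidSpec("T05", "B2", "A1", 500),
        AllotetraploidSpec("T06", "A1", "B2", 3000),
        AllotetraploidSpec("T07", "A2", "B1", 800),
        AllotetraploidSpec("T08", "B1", "A2", 8000),
        AllotetraploidSpec("T09", "A2", "B2", 2000),
        AllotetraploidSpec("T10", "B1", "A3", 1500),
        AllotetraploidSpec("T11", "A3", "B1", 6000),
        AllotetraploidSpec("T12", "A3", "B3", 400),
        AllotetraploidSpec("T13", "B3", "A2", 2500),
        AllotetraploidSpec("T14", "A2", "B3", 12000),
        AllotetraploidSpec("T15", "A1", "B3", 700),
        AllotetraploidSpec("T16", "B2", "A3", 5000),
    ]
    f_is = {"A1": 0.1, "A2": 0.3, "A3": 0.05, "B1": 0.5, "B2": 0.2, "B3": 0.0}
    return SimulationConfig(tets=tets, f_is=f_is)


# ---------------------------------------------------------------------------
# frequency and genotype simulation


def _beta_drift(rng: np.random.Generator, p: np.ndarray, c: float) -> np.ndarray:
    """Balding–Nichols draw: mean p, variance c p (1-p)."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    interior = (p > 0.0) & (p < 1.0)
    scale = (1.0 - c) / c
    a = np.maximum(p[interior] * scale, 1e-12)
    b = np.maximum((1.0 - p[interior]) * scale, 1e-12)
    out[interior] = rng.beta(a, b)
    out[~interior] = p[~interior]  # fixed states stay fixed under pure drift
    return np.clip(out, 0.0, 1.0)


def simulate_parent_frequencies(
    tree: SpeciesTreeSpec, n_loci: int, seed: int | np.random.SeedSequence
) -> FrequencyTable:
    """Drift ancestral frequencies down the species tree.

    Ancestral (root) frequencies are Uniform(0.05, 0.95) — variable
    sites, as in a polymorphism-ascertained SNP catalog — and every
    branch applies an independent Balding–Nichols draw with its own c.
    Deterministic given the seed.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    node_p: dict[str, np.ndarray] = {
        tree.root: rng.uniform(0.05, 0.95, size=n_loci)
    }
    stack = [tree.root]
    while stack:
        node = stack.pop(0)
        for child in tree.children(node):
            node_p[child] = _beta_drift(rng, node_p[node], tree.drift[child])
            stack.append(child)
    values = np.vstack([node_p[t] for t in tree.taxa])
    return FrequencyTable(taxa=list(tree.taxa), values=values)


def _locus_sites(n_loci: int) -> pd.DataFrame:
    return pd.DataFrame({
        "contig": [f"locus_{k}" for k in range(n_loci)],
        "pos": 1,
        "ref": "A",
        "alt": "T",
        "qual": np.nan,
    })


def simulate_diploid_genotypes(
    freqs: FrequencyTable,
    taxon: str,
    n_ind: int,
    f_is: float,
    seed: int | np.random.SeedSequence,
) -> DosageMatrix:
    """Diploid dosages under partial inbreeding.

    Per locus and individual: with probability ``f_is`` the two alleles
    are one Bernoulli(p) draw duplicated (identical by descent), else
    two independent draws; dosage is their sum, so the heterozygote
    fraction is 2 p (1-p) (1 - f_is).
    """
    if not (0.0 <= f_is <= 1.0):
        raise ValueError("F_is must lie in [0, 1]")
    p = freqs[taxon]  # KeyError names an unknown taxon
    rng = np.random.default_rng(seed)
    L = p.size
    ibd = rng.random((L, n_ind)) < f_is
    a = (rng.random((L, n_ind)) < p[:, None]).astype(np.int16)
    b = (rng.random((L, n_ind)) < p[:, None]).astype(np.int16)
    G = np.where(ibd, 2 * a, a + b).astype(np.int16)
    return DosageMatrix(
        sites=_locus_sites(L),
        samples=[f"{taxon}_{i}" for i in range(n_ind)],
        G=G,
        ploidy=np.full(n_ind, 2, dtype=np.int16),
    )


def drift_frequency(
    rng: np.random.Generator,
    p0: np.ndarray,
    age: int,
    n_e: int,
    mode: str = "beta",
) -> np.ndarray:
    """Subgenome frequency after ``age`` generations of drift at size Ne.

    ``mode="beta"`` draws the Balding–Nichols endpoint with
    ``c = 1 - exp(-age / 2Ne)``; ``mode="wf"`` iterates per-generation
    binomial resampling of 2Ne gene copies (exact but O(age)).
    """
    if age == 0:
        return np.asarray(p0, dtype=float).copy()
    if mode == "wf":
        f = np.asarray(p0, dtype=float).copy()
        two_ne = 2 * n_e
        for _ in range(age):
            f = rng.binomial(two_ne, f) / two_ne
        return f
    c = 1.0 - np.exp(-age / (2.0 * n_e))
    if c <= 1e-12:
        return np.asarray(p0, dtype=float).copy()
    return _beta_drift(rng, np.asarray(p0, dtype=float), min(c, 1.0 - 1e-12))


def found_allotetraploid(
    freqs: FrequencyTable,
    maternal: str,
    paternal: str,
    n_ind: int,
    age: int,
    mu_sim: float,
    seed: int | np.random.SeedSequence,
    *,
    label: str | None = None,
    tree: SpeciesTreeSpec | None = None,
    allow_same_clade: bool = False,
    n_e: int = 50000,
    invariant_sites: int = 20000,
    drift_mode: str = "beta",
    inheritance: str = "disomic",
) -> tuple[DosageMatrix, dict]:
    """Found an allotetraploid lineage and age it.

    Each individual carries a maternal and a paternal subgenome that
    never recombine; subgenome dosages are Binomial(2, f) draws from
    the subgenome's current frequency.  Founding frequencies are the
    parent taxa's; ``age`` generations of within-lineage drift are then
    applied per subgenome, and new derived alleles fix in one subgenome
    at previously monomorphic sites with per-site probability
    ``mu_sim`` per generation (appended as ``denovo_*`` contigs).

    ``inheritance="tetrasomic"`` instead merges the founding gamete
    pool (autopolyploid-style polysomic segregation): dosages are
    Binomial(4, f) draws from the pooled frequency, and drift acts on
    the single merged pool.

    Returns the dosage matrix (standing loci + de novo sites) and a
    truth row recording parentage, direction and age.
    """
    if inheritance not in ("disomic", "tetrasomic"):
        raise ValueError("inheritance must be 'disomic' or 'tetrasomic'")
    if maternal == paternal:
        raise ValueError("maternal and paternal taxa must differ")
    if tree is not None and not allow_same_clade:
        if tree.clade_of(maternal) == tree.clade_of(paternal):
            raise ValueError(
                f"parents {maternal!r} and {paternal!r} are in the same clade")
    label = label or f"{maternal}x{paternal}"
    rng = np.random.default_rng(seed)
    f_m = freqs[maternal].copy()
    f_p = freqs[paternal].copy()
    if inheritance == "tetrasomic":
        pool = drift_frequency(rng, (f_m + f_p) / 2, age, n_e,
                               mode=drift_mode)
        G = rng.binomial(4, pool[:, None],
                         size=(pool.size, n_ind)).astype(np.int16)
        n_loci_total = pool.size
    else:
        f_m = drift_frequency(rng, f_m, age, n_e, mode=drift_mode)
        f_p = drift_frequency(rng, f_p, age, n_e, mode=drift_mode)
        g_m = rng.binomial(2, f_m[:, None], size=(f_m.size, n_ind))
        g_p = rng.binomial(2, f_p[:, None], size=(f_p.size, n_ind))
        G = (g_m + g_p).astype(np.int16)
        n_loci_total = f_m.size
    sites = _locus_sites(n_loci_total)

    n_denovo = 0
    if mu_sim > 0 and age > 0:
        p_hit = 1.0 - (1.0 - mu_sim) ** age
        n_denovo = int(rng.binomial(invariant_sites, p_hit))
        if n_denovo:
            extra = pd.DataFrame({
                "contig": [f"denovo_{label}_{j}" for j in range(n_denovo)],
                "pos": 1,
                "ref": "A",
                "alt": "T",
                "qual": np.nan,
            })
            # fixed for the derived allele in one randomly chosen subgenome
            sites = pd.concat([sites, extra], ignore_index=True)
            G = np.vstack([G, np.full((n_denovo, n_ind), 2, dtype=np.int16)])

    dm = DosageMatrix(
        sites=sites,
        samples=[f"{label}_{i}" for i in range(n_ind)],
        G=G,
        ploidy=np.full(n_ind, 4, dtype=np.int16),
    )
    truth = {
        "taxon": label,
        "maternal": maternal,
        "paternal": paternal,
        "age": int(age),
        "n_ind": int(n_ind),
        "n_denovo": int(n_denovo),
        "family": "x".join(sorted([maternal, paternal])),
    }
    return dm, truth


# ---------------------------------------------------------------------------
# plastid haplotypes


def simulate_plastid_haplotypes(
    tree: SpeciesTreeSpec,
    n_sites: int,
    branch_divergence: float,
    seed: int | np.random.SeedSequence,
) -> dict[str, np.ndarray]:
    """Haploid 0/1 haplotypes for the candidate taxa.

    The root haplotype is all-reference; each branch flips every site
    independently with probability ``branch_divergence``, so taxa
    separate in proportion to their path length in the tree.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    haps: dict[str, np.ndarray] = {
        tree.root: np.zeros(n_sites, dtype=np.int16)
    }
    stack = [tree.root]
    while stack:
        node = stack.pop(0)
        for child in tree.children(node):
            flips = rng.random(n_sites) < branch_divergence
            haps[child] = np.where(flips, 1 - haps[node], haps[node]).astype(np.int16)
            stack.append(child)
    return {t: haps[t] for t in tree.taxa}


def derive_allotetraploid_plastid(
    haplotypes: Mapping[str, np.ndarray],
    maternal: str,
    divergence: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Maternal plastid copy with Poisson(divergence * n_sites) substitutions."""
    if maternal not in haplotypes:
        raise KeyError(f"unknown maternal taxon {maternal!r}")
    rng = np.random.default_rng(seed)
    hap = np.asarray(haplotypes[maternal]).copy()
    n_mut = int(rng.poisson(divergence * hap.size))
    if n_mut:
        idx = rng.choice(hap.size, size=min(n_mut, hap.size), replace=False)
        hap[idx] = 1 - hap[idx]
    return hap.astype(np.int16)


def plastid_matrix(
    haplotypes: Mapping[str, np.ndarray],
    individuals: Mapping[str, str],
) -> DosageMatrix:
    """Expand per-taxon haplotypes to a haploid per-individual matrix.

    ``individuals`` maps individual id -> taxon; every individual of a
    taxon carries the taxon haplotype (maternal, clonal inheritance).
    """
    samples = list(individuals)
    n_sites = len(next(iter(haplotypes.values())))
    G = np.zeros((n_sites, len(samples)), dtype=np.int16)
    for i, s in enumerate(samples):
        G[:, i] = haplotypes[individuals[s]]
    sites = pd.DataFrame({
        "contig": "plastid",
        "pos": np.arange(1, n_sites + 1),
        "ref": "A",
        "alt": "T",
        "qual": np.nan,
    })
    return DosageMatrix(sites=sites, samples=samples, G=G,
                        ploidy=np.ones(len(samples), dtype=np.int16))


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    dm: DosageMatrix,
    depth: float,
    base_q: float,
    seed: int | np.random.SeedSequence,
    site_qual: float = 200.0,
) -> VariantTable:
    """Sequencing evidence for known dosages.

    Per cell: total reads N ~ Poisson(depth); derived reads
    D ~ Binomial(N, (g/m)(1-eps) + (1-g/m) eps) with
    ``eps = 10^(-base_q/10)``.  Cells with N = 0 (or missing dosage)
    are missing.  Site QUAL is a constant, high enough by default that
    synthetic data pass the quality filter.
    """
    if depth <= 0:
        raise ValueError("mean depth must be positive")
    if base_q < 2:
        raise ValueError("base quality must be >= 2")
    rng = np.random.default_rng(seed)
    eps = 10.0 ** (-base_q / 10.0)
    ns, ni = dm.n_sites, dm.n_samples
    N = rng.poisson(depth, size=(ns, ni))
    g = dm.G.astype(float)
    m = dm.ploidy[None, :].astype(float)
    frac = np.where(dm.G == MISSING, 0.0, g / m)
    p_read = frac * (1 - eps) + (1 - frac) * eps
    D = rng.binomial(N, p_read)
    missing = (N == 0) | (dm.G == MISSING)
    N[dm.G == MISSING] = 0
    D[dm.G == MISSING] = 0
    sites = dm.sites.copy()
    sites["qual"] = float(site_qual)
    return VariantTable(
        sites=sites,
        samples=list(dm.samples),
        N=N,
        D=D,
        eps=np.full(ns, eps),
        missing=missing,
    )


# ---------------------------------------------------------------------------
# pedigree pairs (estimator calibration)


def simulate_pedigree_pairs(
    p: np.ndarray,
    n_pairs: int,
    relationship: str,
    seed: int | np.random.SeedSequence,
) -> DosageMatrix:
    """Diploid pairs of known pedigree relationship, for calibration.

    ``relationship`` is one of ``unrelated``, ``parent_offspring``,
    ``full_sib`` or ``self`` (the same non-inbred individual listed
    twice).  Samples are ordered pair-wise: (pair0_a, pair0_b,
    pair1_a, ...), all drawn at the supplied frequencies with
    independent founder alleles.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    L = p.size
    cols: list[np.ndarray] = []
    names: list[str] = []

    def draw() -> tuple[np.ndarray, np.ndarray]:
        return ((rng.random(L) < p).astype(np.int16),
                (rng.random(L) < p).astype(np.int16))

    for k in range(n_pairs):
        if relationship == "unrelated":
            a1, a2 = draw()
            b1, b2 = draw()
        elif relationship == "self":
            a1, a2 = draw()
            b1, b2 = a1, a2
        elif relationship == "parent_offspring":
            a1, a2 = draw()
            transmit = rng.random(L) < 0.5
            other = (rng.random(L) < p).astype(np.int16)
            b1 = np.where(transmit, a1, a2).astype(np.int16)
            b2 = other
        elif relationship == "full_sib":
            p1a, p1b = draw()
            p2a, p2b = draw()
            pick = lambda x, y: np.where(rng.random(L) < 0.5, x, y).astype(np.int16)
            a1, a2 = pick(p1a, p1b), pick(p2a, p2b)
            b1, b2 = pick(p1a, p1b), pick(p2a, p2b)
        else:
            raise ValueError(f"unknown relationship {relationship!r}")
        cols.extend([a1 + a2, b1 + b2])
        names.extend([f"{relationship}_{k}_a", f"{relationship}_{k}_b"])

    G = np.column_stack(cols).astype(np.int16)
    return DosageMatrix(
        sites=_locus_sites(L),
        samples=names,
        G=G,
        ploidy=np.full(len(names), 2, dtype=np.int16),
    )


# ---------------------------------------------------------------------------
# full complex


@dataclass
class SyntheticComplex:
    """Everything the pipeline needs, with truth labels."""

    tree: SpeciesTreeSpec
    config: SimulationConfig
    seed: int
    freqs: FrequencyTable
    dosages: DosageMatrix          # all individuals, standing + de novo sites
    plastid: DosageMatrix          # haploid, all individuals
    ploidy: dict[str, int]
    groups: GroupMap
    truth: pd.DataFrame
    reads: VariantTable            # nuclear read evidence, all individuals
    plastid_reads: VariantTable


def simulate_complex(
    config: SimulationConfig | None = None,
    seed: int = 0,
    tree: SpeciesTreeSpec | None = None,
) -> SyntheticComplex:
    """Simulate the full synthetic complex deterministically from one seed.

    The seed fans out to stages through ``numpy.random.SeedSequence``
    spawning in a fixed order (frequencies, per-taxon genotypes,
    per-lineage founding, plastid, reads), so every stage is
    independently reproducible and the whole object is bit-identical
    across runs with the same config and seed.
    """
    config = config or default_config()
    tree = tree or default_species_tree()
    config.validate(tree)

    ss = np.random.SeedSequence(seed)
    n_children = 1 + len(tree.taxa) + len(config.tets) * 2 + 1 + 2
    children = ss.spawn(n_children)
    it = iter(children)

    freqs = simulate_parent_frequencies(tree, config.n_loci, next(it))

    taxon_dms: list[DosageMatrix] = []
    for taxon in tree.taxa:
        taxon_dms.append(simulate_diploid_genotypes(
            freqs, taxon, config.n_ind,
            config.f_is.get(taxon, 0.0), next(it)))

    tet_dms: list[DosageMatrix] = []
    truth_rows: list[dict] = []
    for spec in config.tets:
        dm, row = found_allotetraploid(
            freqs, spec.maternal, spec.paternal, spec.n_ind, spec.age,
            config.mu_sim, next(it), label=spec.label, tree=tree,
            allow_same_clade=config.allow_same_clade,
            n_e=config.n_e, invariant_sites=config.invariant_sites,
            drift_mode=config.drift_mode, inheritance=config.inheritance)
        tet_dms.append(dm)
        truth_rows.append(row)
    truth = pd.DataFrame(
        truth_rows, columns=["taxon", "maternal", "paternal", "age",
                             "n_ind", "n_denovo", "family"])

    # assemble the union site list: standing loci then each lineage's de
    # novo sites, zero dosage everywhere outside the owning lineage
    denovo_frames = [dm.sites.iloc[config.n_loci:] for dm in tet_dms]
    sites = pd.concat([_locus_sites(config.n_loci), *denovo_frames],
                      ignore_index=True)
    n_total = len(sites)
    samples: list[str] = []
    ploidy: dict[str, int] = {}
    ind_taxon: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for taxon, dm in zip(tree.taxa, taxon_dms):
        block = np.zeros((n_total, dm.n_samples), dtype=np.int16)
        block[:config.n_loci] = dm.G
        blocks.append(block)
        samples.extend(dm.samples)
        for s in dm.samples:
            ploidy[s] = 2
            ind_taxon[s] = taxon
    offset = config.n_loci
    for spec, dm in zip(config.tets, tet_dms):
        block = np.zeros((n_total, dm.n_samples), dtype=np.int16)
        block[:config.n_loci] = dm.G[:config.n_loci]
        n_dn = dm.n_sites - config.n_loci
        if n_dn:
            block[offset:offset + n_dn] = dm.G[config.n_loci:]
        offset += n_dn
        blocks.append(block)
        samples.extend(dm.samples)
        for s in dm.samples:
            ploidy[s] = 4
            ind_taxon[s] = spec.label
    G = np.hstack(blocks)
    dosages = DosageMatrix(
        sites=sites, samples=samples, G=G,
        ploidy=np.array([ploidy[s] for s in samples], dtype=np.int16))

    # plastid: taxon haplotypes down the tree, tet copies of the maternal
    haps = simulate_plastid_haplotypes(
        tree, config.plastid_sites, config.plastid_branch_divergence, next(it))
    for spec in config.tets:
        haps[spec.label] = derive_allotetraploid_plastid(
            haps, spec.maternal, config.plastid_divergence, next(it))
    plastid = plastid_matrix(haps, ind_taxon)

    taxon_role = {t: CANDIDATE_PARENT for t in tree.taxa}
    taxon_role.update({s.label: ALLOTETRAPLOID for s in config.tets})
    groups = GroupMap(
        individual_taxon=ind_taxon,
        taxon_role=taxon_role,
        taxon_clade={t: tree.clade_of(t) for t in tree.taxa},
        taxon_family={r["taxon"]: r["family"] for r in truth_rows},
    )

    reads = simulate_reads(dosages, config.depth, config.base_q, next(it),
                           site_qual=config.site_qual)
    plastid_reads = simulate_reads(plastid, config.depth, config.base_q,
                                   next(it), site_qual=config.site_qual)

    return SyntheticComplex(
        tree=tree, config=config, seed=seed, freqs=freqs, dosages=dosages,
        plastid=plastid, ploidy=ploidy, groups=groups, truth=truth,
        reads=reads, plastid_reads=plastid_reads)


def write_complex(sc: SyntheticComplex, outdir: str | Path) -> dict[str, Path]:
    """Write the complex to standard formats (VCF 4.2, TSV, JSON echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diploids = [s for s in sc.reads.samples if sc.ploidy[s] == 2]
    tetraploids = [s for s in sc.reads.samples if sc.ploidy[s] == 4]
    paths = {
        "diploid_vcf": outdir / "nuclear_diploid.vcf",
        "tetraploid_vcf": outdir / "nuclear_tetraploid.vcf",
        "plastid_vcf": outdir / "plastid.vcf",
        "ploidy": outdir / "ploidy.tsv",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config_echo.json",
    }
    write_vcf(sc.reads.take_samples(diploids), paths["diploid_vcf"], sc.ploidy)
    write_vcf(sc.reads.take_samples(tetraploids), paths["tetraploid_vcf"],
              sc.ploidy)
    write_vcf(sc.plastid_reads, paths["plastid_vcf"],
              {s: 1 for s in sc.plastid_reads.samples},
              dosages=sc.plastid)
    write_ploidy_map(sc.ploidy, paths["ploidy"])
    sc.groups.to_tsv(paths["groups"])
    sc.truth.to_csv(paths["truth"], sep="\t", index=False)
    echo = asdict(sc.config)
    echo["seed"] = sc.seed
    paths["config"].write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
    return paths
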