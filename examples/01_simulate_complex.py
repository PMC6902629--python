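"""Simulate a synthetic allopolyploid complex with known truth.

Builds a reduced version of the default study system — two clades of
diploid candidate parents plus allotetraploids of known parentage,
direction and age — and prints what the generator produced.
"""

from allokin import AllotetraploidSpec, SimulationConfig, simulate_complex

config = SimulationConfig(
    n_loci=1500,
    n_ind=4,
    tets=[
        AllotetraploidSpec("T_young", "A1", "B1", age=200),
        AllotetraploidSpec("T_old", "A1", "B1", age=10_000),
        AllotetraploidSpec("T_other", "B2", "A2", age=1_000),
    ],
    f_is={"A1": 0.2, "B1": 0.4},
)
sc = simulate_complex(config, seed=42)

print(f"candidate taxa : {sc.tree.taxa}")
print(f"nuclear sites  : {sc.reads.n_sites} "
      f"({config.n_loci} standing + de novo substitutions)")
print(f"individuals    : {sc.reads.n_samples} "
      f"({sum(1 for p in sc.ploidy.values() if p == 2)} diploid, "
      f"{sum(1 for p in sc.ploidy.values() if p == 4)} tetraploid)")
print(f"mean depth     : {sc.reads.N.mean():.1f}x")
print("\ntruth table (the acceptance oracle):")
print(sc.truth.to_string(index=False))
# n_denovo grows with age: these lineage-private substitutions are what
# the private-allele chronology downstream will count.
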