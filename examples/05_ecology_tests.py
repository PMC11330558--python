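"""Downstream ecology tests: latitude, ecospace and predator/prey counts.

Runs the phylogenetic regression of size on palaeolatitude (a test of
Bergmann's rule), tallies potential predators and prey for each eurypterid
in its assemblage, and tests whether large (>= 0.5 m) and small species
occupy different ecospace with a permutational ANOVA.
"""

from eurysize import ecology
from eurysize.simulate import ScenarioConfig, eurypterid_scenario

scenario = eurypterid_scenario(config=ScenarioConfig(seed=1, n_trees=1))
mcc = scenario["trees"].mcc
traits = scenario["traits"].set_index("taxon")

res = ecology.pgls(mcc, traits["log_size"], traits["palaeolatitude_deg"])
print(f"PGLS size ~ palaeolatitude: slope={res['slope']:.4f}  R2={res['r2']:.3f}")
print("  (values near zero mean no latitudinal size gradient)")

records = ecology.ecospace_table(scenario["community"])
print(f"\necospace records for {len(records)} eurypterids; "
      f"{(records.size_group == 'large').sum()} are large (>= 0.5 m)")

anova = ecology.permutational_anova(records, n_perm=999, seed=3)
print(f"PERMANOVA large vs small: pseudo-F={anova['F']:.2f}  p={anova['p_value']:.3f}")

corr = ecology.correlation_report(records, n_perm=199, seed=4)
print("\nsize correlations (Spearman rho, permutation p):")
print(corr.to_string(index=False))
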