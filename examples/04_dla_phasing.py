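"""EM phasing of the DLA class I and II STR blocks.

Simulates a cohort whose founders carry known class I / class II
haplotype pairings, phases each region by EM, names haplotypes against
the bundled catalog, and applies the joint class I-II linkage correction.
"""
from strpopgen import (DLA_CLASS_I, DLA_CLASS_II, SimulationConfig, datasets,
                       em_phase, extended_linkage_correct, name_haplotypes,
                       simulate_cohort)

cohort = simulate_cohort(SimulationConfig(seed=5, n_founders=120,
                                          n_generations=2, pop_size=250,
                                          interblock_recombination=0.01))
gt = cohort.genotypes
lookup = datasets.dla_haplotype_lookup()

cat_i, dip_i = em_phase(gt, DLA_CLASS_I, seed=0)
cat_ii, dip_ii = em_phase(gt, DLA_CLASS_II, seed=0)
ext, dip_i, dip_ii = extended_linkage_correct(dip_i, dip_ii, gt, cat_i, cat_ii)
name_haplotypes(cat_i, lookup)
name_haplotypes(cat_ii, lookup)

print("class I haplotypes (name: frequency):")
for vec, f in sorted(cat_i.frequencies.items(), key=lambda kv: -kv[1]):
    print(f"  {cat_i.names[vec]:>10s}  {f:.3f}")
print(f"class II haplotypes: {len(cat_ii.frequencies)}; "
      f"extended class I-II pairings: {ext.n_pairings}")
hom = sum(d.homozygous for d in dip_i.assignments.values())
print(f"class I homozygous dogs: {hom}/{len(dip_i.assignments)}")
print()
print("Tight linkage lets a handful of founder haplotypes explain every")
print("7-locus genotype; the joint EM uses cross-region linkage to fix")
print("phase calls that are ambiguous within one region.")
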