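"""Diversity statistics from the bundled published allele frequencies.

Loads the printed 33-locus genomic STR frequency table for Italian
Greyhounds (USA and Continental Europe cohorts) and recomputes the
frequency-derived diversity summary: mean alleles per locus (Aa),
effective alleles (Ae = 1/sum p^2) and expected heterozygosity
(He = 1 - sum p^2).
"""
from strpopgen import diversity_from_frequencies
from strpopgen.datasets import genomic_frequency_table

for pop, label in (("usa", "USA (n=213)"), ("eu", "Continental Europe (n=174)")):
    ds = diversity_from_frequencies(genomic_frequency_table(pop))
    t = ds.per_locus
    print(f"{label}: Aa = {t['a'].mean():.3f}  Ae = {t['ae'].mean():.3f}  "
          f"He = {t['he'].mean():.3f}")

print()
print("He ~0.62-0.64 is typical for a closed breed that retains moderate")
print("STR diversity; Ae around 3 of ~6 observed alleles shows frequency")
print("concentration on a few common alleles per locus.")
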