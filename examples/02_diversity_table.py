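"""Diversity statistics across populations of a simulated archipelago.

Simulates two mainland source populations and one island founded by
three related males, then prints the standard diversity table: sample
size N, observed genotypes MLG, rarefied richness eMLG, corrected
Simpson's index lambda, haplotype diversity Hd, and the unique/private
haplotype percentages.
"""

from ystr_founder import SimulationConfig, diversity_table, generate_dataset

config = SimulationConfig(
    source_ne=200,
    burn_in=1200,
    n_source_pops=2,
    n_islands=1,
    n_founders=3,
    n_patrilines=1,
    island_ne=400,
    generations_since_founding=57,
    sample_size=50,
    seed=11,
)
ds = generate_dataset(config).dataset

table = diversity_table(ds)
print(table.round({"eMLG": 2, "lambda": 2, "Hd": 2, "pct_unique": 1, "pct_private": 1})
      .to_string(index=False))
# The island shows the founder signature: fewer genotypes than either
# source at the same rarefaction depth (lower eMLG), lower lambda/Hd, and
# a smaller share of unique haplotypes -- fifty samples trace back to
# three founders carrying one ancestral haplotype 57 generations ago.
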