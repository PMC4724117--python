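"""Generate a synthetic duplicate-gene dataset and write it as TSV tables.

The generator emulates a Biomart-style extraction in which small-scale
duplicate (SSD) pairs share more annotation and expression than
whole-genome duplicate (WGD) pairs.
"""

from dupfates import generate_dataset, paper_like_config, write_dataset

config = paper_like_config(n_pairs_ssd=300, n_pairs_wgd=300, seed=1)
dataset = generate_dataset(config)
paths = write_dataset(dataset, "scratch/example_dataset")

print(f"genes:            {len(dataset.genes)}")
print(f"paralog pairs:    {len(dataset.pairs)}")
print(f"ortholog records: {len(dataset.ortholog_rates)}")
print(f"tissues:          {len(dataset.tissue_names)}")
for name, path in paths.items():
    print(f"  wrote {path}")
# Each SSD/WGD pair carries dN, dS and percent identity; genes carry GO term
# sets, a 27-tissue expression profile, essentiality/disease flags, Pfam
# domain counts and a phylostratum age rank.
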