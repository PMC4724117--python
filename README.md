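# dupfates

Comparative divergence analysis of **small-scale duplicated (SSD)** versus
**whole-genome duplicated (WGD, "ohnolog")** gene pairs, for molecular
evolution researchers studying the long-term fates of gene duplicates.

Vertebrate genomes retain thousands of paralogs from the two rounds of
whole-genome duplication in early vertebrate evolution alongside paralogs from
ongoing small-scale duplications. The two classes differ in age, and therefore
in sequence divergence, so naive comparisons confound origin with divergence.
This package implements the divergence-matched comparison: paralog pairs are
stratified into nonsynonymous-divergence bins (dN 0.0–0.1, 0.1–0.2, 0.2–0.3,
0.3–0.4, >0.4) and SSD vs WGD pairs are compared *within* each stratum.

## What it computes

Per paralog pair (i, j):

- **Shared-annotation (Dice) similarity** over GO term sets,
  `S(i,j) = 2·|GO(i) ∩ GO(j)| / (|GO(i)| + |GO(j)|)`, applied to the
  biological-process and molecular-function domains (functional similarity)
  and the cellular-component domain (subcellular colocalization);
- **Expression-profile similarity**: Pearson r of the two genes' expression
  levels across ≥27 named tissues.

Per gene, on the SSD-only / WGD-only sets (genes with paralogs from both
classes are excluded):

- **Evolutionary rate**: dN and dN/dS against outgroup orthologs (mouse,
  chimpanzee), discarding saturated records (dS ≥ 3);
- **Multifunctionality**: unique GO-BP term count and Pfam domain count;
- **Importance**: proportions of essential and disease-associated genes,
  compared with the pooled two-sample Z-test
  `z = (p₁ − p₂) / √(p̄(1−p̄)(1/n₁ + 1/n₂))`.

Distributional comparisons use the two-tailed Mann–Whitney U test (exact for
small untied samples, normal approximation with tie/continuity corrections
otherwise). Because no database extraction ships with the package, a
**synthetic-data generator** produces datasets with configurable per-origin
effect sizes (annotation overlap, expression correlation, dN distributions,
essentiality/disease rates); its defaults reproduce the group means reported
for the human SSD/WGD comparison.

## Worked example

```python
from dupfates import (paper_like_config, generate_dataset, score_all_pairs,
                      binned_metric_comparison)

dataset = generate_dataset(paper_like_config(n_pairs_ssd=800, n_pairs_wgd=800, seed=2))
scores, excluded = score_all_pairs(dataset, "BP_similarity")
for row in binned_metric_comparison(scores):
    print(f"{row.bin_label:>8}  SSD {row.mean_ssd:.3f} (n={row.n_ssd:4d})"
          f"  WGD {row.mean_wgd:.3f} (n={row.n_wgd:4d})  p={row.p_two_tailed:.2e}")
```

prints

```
 overall  SSD 0.712 (n= 762)  WGD 0.421 (n= 814)  p=3.95e-174
 0.0-0.1  SSD 0.717 (n= 318)  WGD 0.423 (n=  84)  p=2.30e-32
 0.1-0.2  SSD 0.721 (n= 206)  WGD 0.412 (n= 158)  p=1.93e-44
 0.2-0.3  SSD 0.682 (n= 119)  WGD 0.433 (n= 144)  p=1.06e-22
 0.3-0.4  SSD 0.718 (n=  49)  WGD 0.422 (n= 149)  p=1.25e-17
    >0.4  SSD 0.709 (n=  70)  WGD 0.417 (n= 279)  p=5.01e-27
```

SSD pairs keep a mean GO-BP Dice similarity near 0.71 in every dN stratum
while WGD pairs sit near 0.41: the functional-similarity gap between the two
duplicate classes is not explained by sequence divergence. The p column is
the two-tailed Mann–Whitney test within the stratum. The `examples/`
directory has one short script per capability (simulation, binned divergence,
rates/importance, full report); the command-line interface mirrors them
(`dupfates simulate`, `dupfates run`, `dupfates report`).

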