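# Methods

## The comparison and its assumptions

The package contrasts two classes of human-like paralog pairs: ohnologs
retained from the two early-vertebrate rounds of whole-genome duplication
(WGD), and small-scale duplicates (SSD). WGD pairs are older, hence more
diverged in sequence; every pairwise comparison is therefore stratified by
the pair's nonsynonymous divergence dN into the five half-open bins
[0, 0.1), [0.1, 0.2), [0.2, 0.3), [0.3, 0.4), [0.4, ∞). Half-open bins are
the only convention under which the five labels partition the dN axis; the
boundary value 0.1 belongs to the second bin.

Class labels come from a compiled WGD reference list, which overrides the
sequence-identity rule: a pair on the list is WGD regardless of identity,
any other candidate pair with percent identity ≥ 50 (inclusive) is SSD, and
the rest are excluded with a logged reason. Gene-level analyses use only
genes whose paralogs all belong to one class; genes with both SSD and WGD
paralogs are excluded, and the exclusion is counted.

Pairs are stored and counted once as unordered pairs. A `mirror_pairs`
option counts each pair in both orientations (doubling every N); it changes
test sample sizes but not group means, and exists because published
per-group Ns for pairwise metrics are frequently even, suggesting
orientation-doubled counting. The default is unordered-once.

## Divergence scores

* **Dice similarity** between GO term sets, `2|A∩B|/(|A|+|B|)`, computed per
  GO domain (BP, MF as functional similarity; CC as colocalization). Term
  sets are used exactly as annotated — no propagation through the ontology
  graph — because the score is defined on flat exported term sets. Pairs in
  which either gene has an empty set for the domain are excluded from that
  metric, not scored zero: zero-filling would conflate "unannotated" with
  "functionally unrelated" and is inconsistent with per-metric Ns differing
  across metrics.
* **Expression correlation**: Pearson r across the common tissue panel
  (default 27 named tissues), computed in centered form; the centered form
  is algebraically identical to the raw-sums formula
  `(NΣxy − ΣxΣy)/√([NΣx²−(Σx)²][NΣy²−(Σy)²])` and the equivalence is
  asserted in tests to 1e-12. Constant profiles (zero variance) are
  excluded; profiles given as tissue-labelled Series are aligned on their
  common tissues and require at least 3.

## Statistical tests

Group location differences use the two-tailed Mann–Whitney U test with
midrank tie handling, delegated to scipy: the exact null distribution when
the pooled sample is ≤ 12 without ties, otherwise the normal approximation
with tie correction and continuity correction. Group means are reported for
display alongside the rank test. The proportion comparisons use the pooled
two-sample Z-test; it accepts proportions directly (published proportions
are typically printed rounded, and feeding them back reproduces published Z
values) as well as integer counts. No multiple-testing correction is applied
to the per-bin p-values; raw p-values are reported per stratum, and a
display floor (`<1e-6`) is a rendering convention only — the numeric values
are kept in the tables.

## Evolutionary rate and importance

Per-gene dN and dS against each outgroup are consumed as inputs (no codon
model is fitted here). Records with dS ≥ 3 are discarded as mutationally
saturated. A record with dS = 0 keeps its dN but contributes no dN/dS —
dropping the whole gene would discard valid dN evidence. Comparisons are
stratified by outgroup; rates are never averaged across outgroups.
Multifunctionality counts unique GO-BP terms (set semantics, so duplicated
annotation rows are harmless) and Pfam domains. Importance proportions
ignore genes whose flag is unknown; a group with no flag-bearing genes is a
tabulation error rather than a silent zero.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the biology underneath it. Per origin group it draws:

* **Annotation overlap**: per-gene term-set sizes are 1 + Poisson(m − 1)
  with per-domain mean m (defaults: BP 5 for SSD and 10 for WGD, matching
  the reported multifunctionality means; MF 4 and CC 6 for both origins,
  unreported and chosen as typical annotation depths). The pair's sizes are
  jointly redrawn until the Dice target t is feasible
  (t(nₐ+n_b)/2 ≤ min(nₐ,n_b)), then the shared count is
  Binomial(min(nₐ,n_b), t(nₐ+n_b)/(2·min)). Conditional on accepted sizes
  the expected Dice equals t exactly, so group means are recovered without
  bias; a target of 1 forces equal sizes and identical sets. Default Dice
  targets: BP 0.710/0.415, MF 0.840/0.659, CC 0.782/0.541 (SSD/WGD).
* **Expression**: per tissue, correlated bivariate normals shifted to mean 5
  (sd 1) and clamped at 0 — clamping is a ≈5σ event and negligible. The
  latent correlation is inflated by the small-sample factor
  ρ(1 + (1−ρ²)/(2(N−1))) to cancel the downward bias of the sample Pearson r
  at N = 27 tissues; Monte-Carlo checks show the residual bias of the mean
  recovered r is below 0.001. Targets: r = 0.403 (SSD), 0.193 (WGD).
* **Pair divergence**: dN ~ Gamma(shape, scale) with mean 0.18 (shape 1.2)
  for SSD and 0.35 (shape 2.0) for WGD — dispersions are free parameters
  chosen so all five dN bins are populated for both groups at a few hundred
  pairs per group, with WGD shifted toward higher dN as expected for the
  older class. dS = dN × (1 + Gamma), so dS ≥ dN always.
* **Gene-level rates**: per outgroup, dN ~ Gamma with per-origin means
  (mouse 0.089/0.062, chimp 0.012/0.006), and dN/dS drawn directly with
  means mouse 0.135/0.101, chimp 0.480/0.257; dS is derived as dN ÷ (dN/dS),
  which naturally produces a small saturated tail that exercises the dS ≥ 3
  filter (and biases post-filter recovered means slightly below the
  configured values — the comparisons are directional, not mean-matching).
* **Importance**: Bernoulli flags at per-origin rates (essential
  4.601%/11.344%; disease 27.89%/61.46%); Pfam counts 1 + Poisson
  (means 1.61/2.02); phylostratum ranks geometric (p = 0.35, capped at 20),
  so most genes are old and a young/old SSD split at rank ≈ 10 yields a
  small young fraction. The young/old threshold itself has no asserted
  default; it is a required parameter of the robustness split.
* **Mixed-history genes**: a fraction (default 5%) of SSD genes receive an
  additional WGD pair, producing the `both` partition class the gene-level
  analyses must exclude.

Everything is a pure function of the configuration (including its seed).
What the generator does **not** emulate: the GO ontology graph and term
correlations, tissue-specific expression programs, gene families larger
than 2–3 members, identifier mismatches between sources, and any dependence
of annotation overlap on dN within a group. Passing tests therefore show
that the pipeline recovers configured effects and directions under the
assumed structure — not that the specific published means would be
reproduced from live database extractions.

## Problem sizes and numerical conventions

The shipped default configuration uses 5,000 pairs per origin, which puts
hundreds of pairs in every dN bin and keeps full-pipeline runs in seconds;
recovery assertions in the test suite use 2,000 pairs per group, and the
null-calibration check uses 20 seeds × 800 pairs per group, sizes at which
the binomial 99% band around the nominal 5% false-positive rate is a
meaningful constraint. Ties in the Mann–Whitney test fall back to the
corrected normal approximation regardless of sample size. The closest-pair
robustness subset keeps, per gene and origin class, the minimum-dN pair
(ties broken by higher identity, then lexicographic partner id); "closest"
means minimum dN — identity is only a tie-break, since dN is the divergence
axis used throughout. Report writing sorts all tables deterministically so
identical runs are byte-identical.

## Known limitations

* The pipeline consumes pre-reconciled gene identifiers; no cross-database
  id mapping is attempted.
* dN/dS means are computed as the mean of per-gene ratios (not a ratio of
  means), which is sensitive to small-dS genes; the saturation filter bounds
  but does not remove this.
* The generator's group effects are exchangeable across bins by
  construction; real annotation similarity decays with dN within a group,
  which the defaults deliberately do not model (between-group contrasts per
  bin are the analysis surface, not within-group trends).
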