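# nucorg

Analysis toolkit for studying how chromatin features relate to nuclear
organization in fission yeast (*Schizosaccharomyces pombe*) — and in any
organism with comparable data. It covers the three quantitative assays such
studies rest on:

1. **Feature-class enrichment with a circular-permutation null.**
   Tiling-array or coverage signals (ChIP log2 enrichment, DamID
   fusion-over-control ratios, ...) are compared between probes overlapping a
   feature class (tRNA genes, LTR retrotransposon relics, subtelomeric
   domains, 5S rRNA genes, ...) and the rest of the genome. Because such
   signals are strongly autocorrelated along the chromosome, significance is
   assessed by rotating the class-membership labels circularly along each
   chromosome's probe index: the spatial structure of both the signal and the
   annotation is preserved while their alignment is broken. For a signal
   *x₁…x_N* and membership mask *m*, the statistic is
   *T = mean(x[m]) − mean(x[¬m])* and the one-sided sampled p-value is
   *(1 + #{T\* ≥ T}) / (n_perm + 1)*; an exhaustive per-offset enumeration is
   available as an exact reference.
2. **Paired nucleosome-occupancy comparison.** Mean per-base MNase coverage
   per feature in two genotypes, compared with a two-sided Wilcoxon
   signed-rank test (exact tie-aware null distribution for small classes,
   continuity- and tie-corrected normal approximation otherwise), plus
   median fold-change summaries.
3. **Equal-volume nuclear-zone assay.** A fluorescent locus' distance to the
   nuclear envelope, normalized by the nuclear radius, is scored into three
   concentric shells of equal volume (cutoffs *1−(2/3)^⅓ ≈ 0.126* and
   *1−(1/3)^⅓ ≈ 0.307*); strains are compared with a two-sided Pearson
   chi-square test on the strain × zone table.

A synthetic-data generator produces annotated toy genomes, autocorrelated
probe tracks with injected class effects, paired negative-binomial occupancy
counts and nuclear spot measurements, so the whole pipeline is testable
without any external download. Standard text formats are used throughout:
GFF3, BED, bedGraph, TSV.

## Worked example

```python
import numpy as np
from nucorg import (SimulationConfig, SignalModel, make_genome_and_features,
                    simulate_probe_signal, simulate_spots,
                    ClassEnrichment, ZoneAssay)

cfg = SimulationConfig(seed=42,
                       signal=SignalModel(effects={"tRNA": 1.0,
                                                   "subtelomere": 0.6}))
layout, features = make_genome_and_features(cfg)
_, _, ratio = simulate_probe_signal(layout, features, cfg)
print(ClassEnrichment(ratio, features).fit(n_permutations=999, seed=1).summary())
```

```
Class enrichment (circular permutation, n=999, alternative=two_sided, seed=1)
=================================================================================
feature_class  n_probes  median_member  median_rest  mean_diff  p_value  p_adj_bh
      5S_rRNA        30         0.1512       0.1063   -0.08164     0.63      0.63
          LTR       254       -0.03858       0.1089    -0.1297    0.078     0.104
  subtelomere      2004         0.5887     0.006264     0.6015    0.001     0.002
         tRNA        95          1.125       0.1022     0.9838    0.001     0.002
```

The two classes that were simulated with an additive log2 effect (tRNA at
+1.0, subtelomeres at +0.6) come out with mean differences close to the
injected values and the smallest attainable p-value at 999 permutations
(0.001); the unperturbed classes do not reach significance. Similarly for the
zone assay, comparing a peripherally anchored strain against a released one:

```python
spots = (simulate_spots(cfg, "wildtype", 150, np.random.default_rng(2))
         + simulate_spots(cfg, "released", 150, np.random.default_rng(3)))
print(ZoneAssay(spots).fit().summary())
```

```
Zone occupancy (% of cells, 3 equal-volume zones, zone1 = peripheral)
=====================================================================
  strain  n_cells  zone1  zone2  zone3
released      150  45.33  26.67     28
wildtype      150  74.67  15.33     10

Pairwise chi-square comparisons
=====================================
strain_a strain_b  chi2  df   p_value
released wildtype 28.13   2 7.783e-07
```

About 75% of wild-type spots sit in the outermost zone, the released strain
shifts toward the interior, and the chi-square test calls the difference.

## Command line

```bash
nucorg simulate --seed 13 --out fixtures/
nucorg features --gff fixtures/features.gff3 --layout fixtures/genome.tsv \
    --subtelomeres fixtures/subtelomeres.bed --out features.tsv
nucorg enrich --track fixtures/log2_ratio.bedgraph --layout fixtures/genome.tsv \
    --features fixtures/features.tsv --classes tRNA,LTR --n 1000 --seed 7
nucorg occupancy --table fixtures/occupancy.tsv
nucorg zones --spots fixtures/spots.tsv --compare wildtype,released
```

Each stage writes a TSV table plus a JSON report embedding the seed, a
configuration hash and input checksums; identical inputs and seed reproduce
byte-identical reports.

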