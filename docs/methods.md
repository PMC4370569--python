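# Methods

This note documents the statistical models behind nucorg, the choices made
where conventions differ, and what the synthetic-data generator does and
does not emulate.

## Coordinate conventions and annotation handling

Internal coordinates are 0-based half-open on every code path; GFF3 records
(1-based closed) are converted at the I/O boundary, BED and bedGraph are
native. Overlap between a probe and a feature means at least one shared
base; strand is ignored, since tiling probes are effectively unstranded.
A probe abutting a feature end-to-start (half-open touch) does not overlap.

Pombase-style annotations carry several element types in attribute fields
rather than the type column. The reclassifier applies, in order,
substring rules that turn `LTRTF2`-matching records into class `LTR`,
protein-coding genes named `Tf2` into class `Tf2`, `origin_of_replication`
records into `origin`, and records whose `external_name` contains `intron`
into `intron`. First matching rule wins; application is idempotent; the rule
set is user-configurable. The four *S. pombe* subtelomeric domains of
chromosomes I and II ship as package defaults (chromosome I: 1–98,950 and
5,496,300–5,579,133; chromosome II: 1–96,400 and 4,437,300–4,539,804,
read as 1-based closed and converted — the published endpoints do not state
their convention, so the inclusive reading is an explicit, documented
choice).

Probe uniqueness (one genomic match) is modeled as a boolean flag per probe,
consumed by `filter_unique` before any statistic; the full track is retained
for visualization/export. Synthetic tracks mark all probes unique.

## Circular permutation test

Tiling signals have strong positive spatial autocorrelation, so an i.i.d.
label-shuffling null grossly understates the variance of the mean-difference
statistic between a feature class and the rest of the genome. The circular
permutation null draws, per permutation, one independent uniform offset per
chromosome and rotates the membership labels by that offset over the
chromosome's probe index. Values stay fixed; per-chromosome membership
counts are conserved; within-chromosome autocorrelation of both signal and
annotation geometry is preserved.

Choices, since the construction is not fully determined by convention:

- **Rotation unit** is the probe index (not base pairs), independent per
  chromosome. A joint single-offset mode over the concatenated genome is
  available (`joint=True`).
- **Sampled p-value** uses +1 smoothing, `p = (1 + k) / (n_perm + 1)`, so
  p is never zero and never below `1/(n_perm + 1)`. Default
  `n_permutations = 1000`, default alternative `two_sided` on |T|;
  one-sided alternatives are available for directional hypotheses.
- **Exhaustive mode** enumerates the full cartesian product of
  per-chromosome offsets (bounded, default 10⁶ combinations), counts the
  identity, and returns `p = k / total`; it is the exact reference the
  sampled test is validated against.
- **Ties** between null and observed statistics count as at least as
  extreme, with an absolute slack of 1e-9 (scaled by |T|) because null
  statistics are the same addends summed in a different order.

The null is exactly invariant only for circularly stationary signals; a
linear (non-circular) autoregressive signal breaks exchangeability at the
origin wrap-around. With correlation lengths of a few probes on chromosomes
of hundreds to thousands of probes this seam effect is negligible, which the
type-I calibration verifies empirically.

## Paired occupancy comparison

Occupancy per feature is the mean per-base coverage over the feature
interval. Length normalization is the default so that classes with
heterogeneous feature lengths are comparable; a raw overlapping-read-count
mode exists (`mode="reads"`). The genotype comparison is the Wilcoxon
signed-rank test on per-feature differences B − A, two-sided: zero
differences are dropped (Wilcoxon's original treatment), ties in
|difference| are mid-ranked, and

- for ≤ 25 remaining pairs the exact null distribution of W⁺ is built by
  dynamic programming over doubled ranks (equivalent to full sign-pattern
  enumeration, which the tests verify up to n = 10), two-sided
  p = min(1, 2·min(P(W ≤ w), P(W ≥ w)));
- above 25 pairs a normal approximation with tie correction
  (−Σ(t³−t)/48 on the variance) and a 0.5 continuity correction is used;
  it agrees with the exact computation to within 0.01 at n = 30.

An unpaired two-sided Mann–Whitney U option is provided for comparison but
is not the default: for per-feature paired designs the signed-rank test is
the appropriate rank procedure. Fold-change summaries report the per-class
median of B/A (configurable pseudocount for zero counts) and the fraction
of features with a strict decrease.

## Nuclear zone assay

The nucleus is modeled as a sphere; with d = spot-to-envelope distance
divided by the nuclear radius, the n equal-volume shells have cutoffs
d_k = 1 − ((n−k)/n)^{1/3}. Zone 1 is peripheral; a spot exactly on a
boundary is assigned to the more peripheral zone (the published procedure is
silent on ties). Strain pairs are compared with a Pearson chi-square on the
2 × n zone table, df = n − 1, no continuity correction (undefined beyond
2×2). Expected counts must be positive; the error message suggests pooling
zones otherwise. Decapping and distance measurement happen upstream in image
analysis; this package consumes measured distances.

## Synthetic data generator

The generator defines the study conditions used by the tests and the
acceptance script:

- **Genome/annotation**: 3 toy chromosomes (300/240/150 kb) named with
  roman numerals; subtelomere-style end-domains (20 kb per end by default),
  LTR-style features placed just inside the domain borders, plus randomly
  placed non-overlapping tRNA/LTR/5S classes.
- **Probe signal**: one probe per 60 bp. The log2 ratio is a stationary
  lag-1 autoregressive series per chromosome with marginal sd σ = 0.5 log2
  units and autocorrelation ρ = 0.7 — the minimal model of tiling-probe
  spatial correlation, the phenomenon the circular permutation null exists
  to respect — plus an additive per-class effect Δ on member probes.
  Condition and control tracks are emitted on the linear scale such that
  log2(condition/control) returns the simulated ratio exactly.
- **Occupancy**: independent negative-binomial counts per feature,
  mean 100, dispersion 10 (variance μ + μ²/10; Poisson in the
  dispersion → ∞ limit), condition B mean multiplied by the fold f.
- **Spots**: zone drawn from per-strain presets — wild-type-like
  (0.75, 0.15, 0.10), uniform (no anchoring), released (0.45, 0.25, 0.30) —
  then the radial position drawn volume-uniformly within the zone shell
  (inverse CDF of the r² density), so "uniform" is exactly uniform in the
  ball and generator labels agree with `assign_zone` for every spot.
  Nuclear radii are uniform on 0.8–1.2 μm.

What the generator does **not** emulate: probe-specific affinity biases and
cross-hybridization, GATC-fragment resolution of DamID, MNase sequence
preference, nucleosome positioning structure within features, optical
sectioning or measurement error in the microscopy, and any real sequence
content. Passing tests therefore demonstrate the correctness and calibration
of the statistical machinery under the stated stochastic models, not
robustness to these instrument-specific artifacts.

## Problem sizes and numerical choices

Calibration and recovery simulations run at deliberately compact sizes
chosen to exercise the asymptotics while staying cheap: 200 replicates with
199 permutations on ~2,000-probe tracks for permutation-test calibration,
40–100 features for the rank test, 150 cells per strain for the zone assay,
and 50–100 random instances for the enumeration and interval oracles.
Quartiles use linear interpolation (numpy default, type 7); whiskers are the
most extreme data points within 1.5 IQR of the box. The log2-ratio
pseudocount defaults to 0 (tracks are assumed normalized and positive) and
is configurable. Benjamini–Hochberg adjusted p-values are reported alongside
raw permutation p-values when several classes are tested in one run; raw
values are primary.

## Known limitations

- The circular null assumes the probe grid is (approximately) evenly
  informative along the chromosome; large masked gaps reduce the effective
  number of distinct rotations.
- The exhaustive test is exponential in the number of chromosomes times
  per-chromosome probe counts and is intended as a small-instance oracle.
- The zone model assumes spherical nuclei with a single measured radius;
  oblate nuclei are out of scope.
- The exact signed-rank path doubles ranks to an integer lattice; midranks
  are always half-integers so this is lossless.
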