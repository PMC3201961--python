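# tetracomb

Tetrad genotyping and meiotic recombination analysis for hybrid yeast
crosses.

In budding yeast, a single meiosis yields four spores that stay together as
a tetrad. Crossing two sequenced strains and genotyping tens of thousands
of polymorphic markers in all four spores reveals every detectable
recombination product of that meiosis: crossovers (COs, reciprocal
exchanges seen as a reciprocal genotype switch on two chromatids) and gene
conversions (GCs, non-reciprocal tracts of 3:1, 1:3 or 4:0 segregation),
including non-crossovers (NCOs). `tetracomb` covers the computational
pipeline from read pileups to genome-wide statistics of crossover control:

* **genotyping** — markers are called per spore from read pileups against
  *both* parental reference genomes. The decision statistic per genome
  pool is the cumulative quality score of each candidate allele
  (sum of supporting base qualities minus the sum of all others),
  thresholded and then reconciled across the two pools; indels use
  border/reference-base qualities and a 2x cross-pool dominance rule.
* **event classification** — from the four-spore segregation profile,
  COs and GC tracts are detected, classified into 9 CO and 11 GC
  categories (connected, detached-but-near, independent, double,
  merged-close events...), positioned by marker midpoints, and measured
  (estimated/minimum/maximum tract lengths).
* **recombination statistics** — CO interference via a maximum-likelihood
  gamma fit to inter-CO distances (shape γ, scale β; γ = 1 means no
  interference), chromatid interference via the 2/3/4-strand composition
  of adjacent CO pairs against the 1:2:1 expectation (χ², df 2), CO
  homeostasis via per-tetrad CO/NCO correlation, and centromere/telomere
  distance profiles.
* **PMS** — post-meiotic segregation detection by comparing mother and
  daughter tetrads position by position.
* **simulation** — a ground-truth generator (gamma-renewal CO placement,
  1:2:1 chromatid choice, lognormal conversion tracts, realistic marker
  spacing, a positional-error read simulator) that makes every stage
  testable without external data.

The segregation ("seg") file format of upstream microarray and sequencing
pipelines is read and written directly, so classification can be applied
to existing profiles regardless of how they were genotyped.

## Worked example

Simulate three wild-type-like tetrads (~67,000 markers, γ = 1.96,
β = 61.7 kb, 65% of COs with a connected conversion tract), classify
them, and fit interference:

```python
from tetracomb import (simulate_tetrad_batch, classify_tetrad, summarize,
                       inter_event_distances, fit_gamma)

tetrads, truths = simulate_tetrad_batch(3, seed=11)
reports = [classify_tetrad(t, tetrad_id=f"sim{i}") for i, t in enumerate(tetrads)]

stats = summarize(reports)
print("markers per tetrad:", tetrads[0].n_markers)
print("COs per tetrad:    ", stats.per_tetrad_co)
print("NCOs per tetrad:   ", stats.per_tetrad_nco)
print("CO types:          ", dict(sorted(stats.co_type_counts.items())))
t1 = stats.gc_type_length_stats[1]
print(f"GC type 1 tracts:   mean {t1['mean']:.0f} bp, median {t1['median']:.0f} bp")

d_kb = [d / 1000 for d in inter_event_distances(reports)["co_co"]]
fit = fit_gamma(d_kb)
print(f"interference:       gamma = {fit.shape:.2f}, beta = {fit.scale:.1f} kb (n = {fit.n_distances})")
```

prints

```
markers per tetrad: 67775
COs per tetrad:     [103, 101, 91]
NCOs per tetrad:    [41, 29, 25]
CO types:           {0: 109, 1: 181, 3: 2, 4: 1, 5: 1}
GC type 1 tracts:   mean 2561 bp, median 2250 bp
interference:       gamma = 2.20, beta = 50.8 kb (n = 246)
```

Read it as: each tetrad carries ~100 COs and ~30–40 NCOs across the 16
chromosomes; most COs are Type 0 (no detectable conversion) or Type 1
(with a connected conversion tract averaging ~2.5 kb); and the ~250 pooled
inter-CO distances already recover the simulated interference strength to
within sampling error (the fitted γ of 2.2 sits within the uncertainty of
the true 1.96 at n = 246 — a few tetrads suffice to distinguish
interference from its absence, not to pin γ precisely).

The same pipeline runs from the shell:

```
tetracomb simulate --n-tetrads 2 --seed 3 --out sims/
tetracomb crossover --seg sims/sim000.seg.txt --out events/
tetracomb stats --events sims/sim000.seg.txt --events sims/sim001.seg.txt --out stats/
tetracomb pms --mother mother.seg.txt --daughter daughter.seg.txt --out pms.tsv
tetracomb threshold-exp --coverage 25 --out accuracy.tsv
```

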