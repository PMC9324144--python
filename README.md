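# paleoresil

Did a regional community pass through an environmental perturbation cycle
unchanged, shift and reassemble, or drift into ever-new configurations?
`paleoresil` answers this for fossil assemblage data spanning a
glacial–interglacial cycle — the motivating system is nearshore mollusk
assemblages of the Adriatic shelf sampled in three time slices (last
interglacial LIG, last late glacial LG, current interglacial CIG) — and
classifies the long-term response as **persistent**, **resilient**, or
**stochastic**.

It is aimed at quantitative paleoecologists and community ecologists working
with samples × species specimen-count matrices, and provides, as a tested
library plus a small CLI:

* data ingestion and validation for count matrices (wide or long/occurrence
  CSV), sample metadata, biogeographic trait tables, and bathymetric census
  records, with valve-to-individual resolution (⌈valves/2⌉) and the standard
  selection protocol (habitat exclusion, minimum sample size n ≥ 25 or 60,
  single-occurrence species removal, fourth-root transform of relative
  abundances);
* Bray–Curtis distances, BC(x,y) = 1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ), non-metric
  multidimensional scaling (Kruskal stress-1, best of seeded restarts),
  PERMANOVA, and mid-rank Spearman correlation (exact p for n ≤ 9);
* two bespoke randomization null models of a homogeneous system: a
  size-preserving specimen-permutation test of the mean between-interval BC
  dissimilarity, and a multinomial resampling envelope for pooled per-species
  abundances, both with the add-one p-value rule p = (b+1)/(B+1);
* rarefied richness (analytic hypergeometric E[Sₙ]), dominance,
  biogeographic affinity profiles, top-k abundance-rank overlap, and
  abundance-weighted bathymetric estimation (per-species preferred depth →
  per-sample weighted mean);
* an explicit decision rule mapping the three pairwise test outcomes to the
  persistent / resilient / stochastic labels;
* a Dirichlet–multinomial synthetic-data generator that reproduces the
  study system's structure (three interval groups, extreme interglacial
  dominance, interglacial convergence, glacial divergence) so the entire
  pipeline runs and is validated without any data download.

## Worked example

Generate a synthetic resilient-scenario dataset, run the full analysis, and
summarize it:

```sh
paleoresil synth --scenario resilient --seed 42 --out data
paleoresil run --config config.yaml    # paths to the four CSVs + seed: 7
paleoresil report --run out
```

which prints:

```
# Community response analysis report

- samples retained: 98
- species retained: 60
- NMDS stress (k=2): 0.0568
- PERMANOVA pseudo-F: 83.416 (p = 0.001)

## Scenario call: **resilient** (alpha = 0.05, confidence: high)

Pairwise mean Bray-Curtis permutation tests:
- interglacial vs interglacial: p = 0.9051
- glacial vs interglacial (1): p = 0.000999
- glacial vs interglacial (2): p = 0.000999

Pooled-abundance Spearman correlations:
- rho_interglacial: rho = 0.980 (p = 1.878e-42)
- rho_glacial_1: rho = -0.201 (p = 0.1243)
- rho_glacial_2: rho = -0.167 (p = 0.2009)
```

Reading: the two interglacial sample groups are statistically
indistinguishable from one homogeneous system (the observed mean
between-interglacial dissimilarity falls well inside the permutation null,
p = .91, and their pooled species abundances correlate strongly), while both
glacial–interglacial comparisons depart from the null at the smallest
reportable p (1/1001) — the signature of a community that shifted to an
altered glacial state and then reassembled, hence the *resilient* call.
PERMANOVA corroborates the distinct group locations, and the low NMDS stress
says the 2-D ordination represents the Bray–Curtis structure faithfully.

The same analysis is available in-memory:

```python
from paleoresil import (RunConfig, run_analysis, default_spec, generate_dataset)

cm, meta, traits, census = generate_dataset(default_spec("resilient", seed=42))
res = run_analysis(cm, meta, traits, census=census, config=RunConfig(seed=7))
print(res["scenario"].label)          # "resilient"
print(res["sample_metrics"].head())   # per-sample richness/dominance/depth...
```

Run artifacts (ordination coordinates, distance and null-model outputs,
per-sample metric tables, rank tables, provenance and a manifest whose hash
certifies end-to-end determinism) are written as plain CSV/JSON to the
configured output directory.

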