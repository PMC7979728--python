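# escapekit

Tools for quantifying **escape from drug-induced quiescence** in
BRAF-inhibitor-treated melanoma. When BRAF^V600E^ melanoma cells are
exposed to MAPK-pathway inhibitors such as dabrafenib, most enter a
CDK2-low quiescent state — but a subpopulation ("escapees") later
re-enters the cell cycle and divides in drug. `escapekit` implements the
bespoke computations needed to find and characterize these cells, for
researchers analyzing live-cell CDK2-sensor movies, droplet scRNA-seq of
treated populations, and survival cohorts:

- **`escapekit.traces`** — rule-based segmentation of single-cell CDK2
  activity traces (seed regions above an activity threshold, restriction
  points by a slope rule, mitosis points at H2B intensity maxima) and
  escapee / non-escapee classification, with hierarchical-clustering
  heatmap ordering.
- **`escapekit.posterior`** — a naive-Bayes posterior probability that a
  cell is proliferative, from binary detection of a 51-gene cell-cycle
  panel: P(P|X) ∝ p₀ ∏ᵢ pᵢ^xᵢ(1−pᵢ)^(1−xᵢ), against a quiescent model
  with shared detection rate ε = 0.01, computed in log space; cells with
  posterior exactly 1 (beyond double precision) are escapees, below
  e^−40 non-escapees.
- **`escapekit.scqc`** — the matched preprocessing pipeline:
  library-size matching by exact down-sampling, invalid-gene removal,
  5-MAD outlier-cell removal, LogNormalize, Wilcoxon rank-sum
  differential expression (logfc.threshold 0.25, min.pct 0.01,
  Bonferroni), signature intersection and Fisher gene-set overlap.
- **`escapekit.survival`** — per-gene prognosis (Cox
  `survival ~ age + gender + stage + expression`, quartile Kaplan–Meier,
  log-rank) and the trinomial signature-enrichment tail probability
  Σᵢ₌ₖⁿ C(n,i)·f₋^i·(1−f₋−f₊)^(n−i).
- **`escapekit.synth`** — generators for all of the above with known
  ground truth (planted escape times, cell states, DE genes, QC
  violations, hazard effects), so every stage is testable end to end.

## Worked example

```python
from escapekit import synth, traces, posterior
from escapekit.survival import enrichment_probability

# 500 simulated drug-treated cells, 15-min frames, drug at 18 h
ts, truth = synth.simulate_traces(synth.TraceSimConfig(n_cells=500, rng_seed=1))
ann, calls = traces.classify_all(ts, traces.TraceConfig(smoothing_window=3))
labels = [c.label for c in calls]
print(labels.count("escapee"), labels.count("non-escapee"), labels.count("excluded"))
# 225 192 83      (54.0% escape among complete traces)

# proliferation posterior on a simulated treated population (prior 0.18)
dm, states = synth.simulate_detection_matrix(
    synth.DetectionSimConfig(n_cells=2000, p0_true=0.18, rng_seed=1))
model = posterior.estimate_detection_probs(dm, p0=0.18)
res = posterior.assign_subgroups(posterior.proliferation_posterior(dm.x, model))
print(res.label.value_counts().to_dict())
# {'non-escapee': 1645, 'escapee': 349, 'intermediate': 6}

# enrichment of negatively prognostic genes in a 38-gene signature
print(round(enrichment_probability(38, 5, frac_neg=0.056, frac_pos=0.075), 6))
# 0.004008
```

The first block recovers the planted escapee fraction from the trace
rules alone; the second shows the posterior separating proliferative
from quiescent cells (subgroup-5 cells are 100% truly proliferative in
this run); the third evaluates the probability that a random 38-gene
signature would contain at least 5 genes negatively and none positively
correlated with survival, given genome-wide fractions of 5.6% and 7.5%.

A `escapekit` console command wraps each stage
(`simulate`, `traces`, `posterior`, `scqc`, `deg`, `prognosis`, `run`);
every stochastic stage takes an explicit `--seed`, and `escapekit run`
writes a manifest with SHA-256 hashes of its outputs so identical
configs reproduce byte-identical results.

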