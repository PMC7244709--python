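# macrogen

Mapping intraspecific genetic diversity of terrestrial mammal assemblages
and weighing its macroecological drivers.

Georeferenced mitochondrial sequences make it possible to ask where, on an
equal-area grid covering the globe, species harbour the most within-species
genetic variation — and whether that pattern tracks evolutionary history
(phylogenetic diversity, species richness), Late Quaternary climate
stability, or human land use.  `macrogen` implements that analysis chain as
a reusable library for researchers in macrogenetics and macroecology,
together with a synthetic-data module that generates every input with known
ground truth, so the whole stack is testable without touching external
databases.

## The quantities

Per species, nucleotide diversity is the average proportion of differing
sites over all valid pairwise comparisons of its aligned sequences,

$$\hat\Pi = \binom{n}{2}^{-1} \sum_{i<j} \frac{k_{ij}}{m_{ij}},$$

where $m_{ij}$ counts positions at which both sequences carry an
unambiguous base (gaps and N are skipped), $k_{ij}$ the differing subset,
and a pair counts only when the sequences overlap in at least half of the
longer sequence's unambiguous length.  Assemblage genetic diversity of a
grid cell (385.9 km Behrmann equal-area cells) or region with $S$ sampled
species is

$$\mathrm{GD} = \frac{1}{S}\sum_{p=1}^{S} \hat\Pi_p .$$

Candidate drivers per cell: species richness and Faith's phylogenetic
diversity (sum of branch lengths, in My, of the minimal subtree connecting
the cell's species; averaged over a posterior sample of trees), centennial
temperature/precipitation trend and inter-annual variability during
centuries of rapid global temperature change, the timing of historical
land-use exceeding 20%, and the modern human-footprint index.  Inference
combines hierarchical partitioning (independent contributions with a
1000-fold randomisation test, applied iteratively), AICc multimodel
inference with Akaike weights and summed weights per variable, Dutilleul's
modified t-test of spatial association, and Moran's I residual diagnostics;
the most parsimonious model is projected back onto all cells as a
prediction surface.

## Worked example

```python
from macrogen import pipeline

cfg, opts = pipeline.recovery_config(seed=1)   # synthetic world, known truth
result = pipeline.run_pipeline(cfg, opts)

print("retained drivers:", result.retained)
print("best model:", result.best_model.variables,
      "R2 = %.3f" % result.best_model.r2)
print("Moran's I of residuals: %.3f (p = %.3f)"
      % (result.moran["I"], result.moran["p"]))
```

```
retained drivers: ['sr', 'pd', 'prec_var']
best model: ('pd', 'prec_var') R2 = 0.547
Moran's I of residuals: 0.077 (p = 0.095)
```

The synthetic world gave true effects to phylogenetic diversity and
precipitation variability only.  The pipeline retains exactly those two
drivers plus species richness — an expected alias, since simulated SR and
PD are correlated at r ≈ 0.85, just as in real mammal assemblages — and
AICc parsimony then selects the true pair, which explains about half of
the variance, as designed.  The near-zero Moran's I says the best model
leaves no spatial structure in its residuals.

The same stages are scriptable from a shell:

```bash
macrogen all --config config.yaml --seed 1 --out run/
```

which writes the world (FASTA + coordinates CSV, GeoJSON ranges, Newick
trees, climate/ALCC/footprint CSVs), the per-cell GD table, the
hierarchical-partitioning report, the model-selection table with Moran
diagnostics, the SAW table, the prediction surface and a run manifest.
Individual stages (`simulate`, `filter`, `gd`, `diversity`, `climate`,
`footprint`, `stats`, `predict`) operate on the same directory.

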