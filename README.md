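# plankton-assembly

Community-assembly analysis for plankton ASV (amplicon sequence variant)
tables. The package compares eDNA metabarcoding communities — e.g.
phytoplankton versus microzooplankton across two estuarine regions — and
asks *what assembles them*: passive dispersal and drift (stochastic
processes) or environmental selection (deterministic processes). It
provides, as both a Python library and a CLI:

- **Normalization** — singleton removal (ASVs with a table-wide total of 1)
  and seeded rarefaction (multivariate hypergeometric subsampling) to a
  common read depth.
- **Diversity** — Chao1, Shannon, Pielou evenness, Faith's PD; Bray-Curtis
  dissimilarity; PCoA; one-way PERMANOVA (Adonis); Welch *t* and Wilcoxon
  rank-sum group tests.
- **Spatial and environmental structure** — haversine geographic and
  z-scored Euclidean environmental distances; distance-decay regression of
  community similarity; PCNM/dbMEM spatial eigenfunctions; variation
  partitioning (Hellinger-transformed RDA, adjusted R²) into pure
  environmental [a], shared [b], pure spatial [c] and unexplained [d]
  fractions.
- **Sloan neutral community model (NCM)** — the occurrence frequency of a
  taxon with source relative abundance *p* in local communities of *N*
  reads at immigration rate *m* follows the Beta(*Nmp*, *Nm*(1−*p*))
  abundance law; the package fits *m* by least squares on the zero-class
  occupancy curve, reports the fit R², and partitions ASVs into
  above / neutral / below a 95% Wilson band around the prediction, with
  richness and sequence-abundance summaries per phylum-level lineage.
- **Niche breadth and dispersal** — Levins' niche breadth
  *B* = 1/Σᵢ qᵢ² per taxon, its per-sample community mean (Bcom), and a
  dispersal proxy: the average pairwise shared proportion of sequence
  numbers between samples.
- **Synthetic data** — generators for neutral (Dirichlet-multinomial,
  marginals exactly matching the NCM) and niche-structured (Gaussian
  response curves along a spatial transect) communities, metadata and
  random phylogenies, so the full analysis is testable end to end.

## Worked example

Simulate a two-region bundle (neutrally assembled phytoplankton,
niche-structured microzooplankton along an environmental gradient) and run
every analysis stage:

```bash
plankton-assembly demo-config --bundle-dir demo --out demo/config.yaml --seed 7
plankton-assembly run-all --config demo/config.yaml
cat demo/results/ncm_params.tsv
```

```
group	region	m	r_squared	N	n_samples	n_asvs
microzooplankton	LH	0.1181838498	0.7592985995	3000	12	116
microzooplankton	YLJ	0.08937808259	0.8331165572	3000	12	115
phytoplankton	LH	0.6225547962	0.9202103411	3000	12	120
phytoplankton	YLJ	0.5156704765	0.9101294539	3000	12	120
```

The neutrally assembled phytoplankton fit the NCM closely (R² ≈ 0.91–0.92)
with high immigration estimates (m ≈ 0.52–0.62), while the niche-structured
microzooplankton show depressed fit quality and an order-of-magnitude lower
m — the dispersal-versus-selection contrast the pipeline is built to
detect. The accompanying `niche_tests.tsv` shows the same story from traits:
phytoplankton have significantly wider community niche breadth and higher
dispersal scores than microzooplankton (Welch *t*, p < 0.05 in LH for both
metrics). Other result families written by `run-all`: per-sample alpha
diversity with between-region tests, Bray-Curtis matrices, PCoA coordinates,
PERMANOVA (`adonis.tsv`), distance-decay fits per predictor
(`distance_decay.tsv`), VPA fractions (`vpa.tsv`), NCM per-ASV tables and
above/neutral/below partition summaries, Levins' B and Bcom/dispersal
tables. Re-running the same config reproduces byte-identical tables.

The same stages are available piecewise (`simulate`, `diversity`, `decay`,
`vpa`, `ncm`, `niche`) and as library functions:

```python
from plankton_assembly import (
    NeutralSimConfig, simulate_neutral_table, occurrence_stats, fit_ncm,
)

table = simulate_neutral_table(NeutralSimConfig(m=0.3, seed=1))
fit = fit_ncm(occurrence_stats(table), N=5000)
print(f"m = {fit.m:.3f}, R2 = {fit.r_squared:.3f}")   # m = 0.317, R2 = 0.959
```

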