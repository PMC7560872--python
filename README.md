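# topostates

Topological identification of metastable community states and state
transitions in microbiome time series.

Community compositions are treated as points in a metric phase space
(square-root Jensen-Shannon distance, base-2, so distances lie in
[0, 1]; Aitchison distance optional). The shape of the sampled density
is summarized as a **Mapper graph**: samples are binned by overlapping
intervals of the ranked first two principal coordinates, each bin is
clustered by single linkage with a first-empty-histogram-bin cutoff, and
vertices (local clusters) are joined whenever they share a sample. Data
density per vertex is estimated from k-nearest-neighbor distances
(`D_inv(V) = sum_i kNN(i, k) / n^2`, `D = 1/D_inv`); local maxima of `D`
seed **metastable states**, and every other vertex joins the state whose
maxima it reaches by a uniquely shortest density-ascending path (ties
are labeled unassigned — transition regions). State persistence is
quantified by a temporal correlation function `corr_x(tau)` with `1/p`
weighting for samples associated with several states, and robustness of
the graph structure is assessed by a rarefaction test (re-running Mapper
on random subsamples with unchanged hyperparameters).

No external data are required: a simulation module provides an
antagonistic two-species toy ecosystem and a Markov-switching Dirichlet
community with ground-truth state labels.

## Command line

```sh
# generate a synthetic 3-state fixture
topostates simulate --kind markov --n-states 3 --n-subjects 3 \
    --n-timepoints 100 --seed 1 --outdir demo

# full pipeline: distances, Mapper graph, densities, states
topostates run --abundance demo/abundance.tsv --metadata demo/metadata.tsv \
    --outdir demo/out --n-intervals 10 10 --overlap-pct 70 --plot

# temporal correlation for one (subject, state) pair
topostates correlate --sample-states demo/out/sample_states.tsv \
    --metadata demo/metadata.tsv --subject S0 --state 0 \
    --out-prefix demo/out/corr_S0_0

# rarefaction robustness (90/50/10%, 10 replicates)
topostates rarefy --abundance demo/abundance.tsv --metadata demo/metadata.tsv \
    --feature subject --out demo/out/rarefaction.tsv \
    --n-intervals 10 10 --overlap-pct 70

# hyperparameter heuristic (largest vertex <= ~10% of samples)
topostates check-params --abundance demo/abundance.tsv \
    --metadata demo/metadata.tsv --n-intervals 10 10 --overlap-pct 70
```

Inputs are plain TSV/CSV: an abundance table (samples x taxa, counts or
relative abundances; `--orientation taxa_as_rows` for transposed files)
and a metadata table with `sample_id`, `subject`, `time` columns.
Artifacts are TSV (distance matrix, vertex states, per-sample state
labels), GraphML (Mapper graph) and a JSON run manifest. Mapper
hyperparameters can also come from a `key = value` config file
(`n_intervals_1`, `n_intervals_2`, `overlap_pct`, `n_hist_bins`).

## Library

```python
import topostates as ts

table, truth = ts.simulate_markov_community(ts.MarkovCommunityConfig(seed=1))
result = ts.run_pipeline(table, config=ts.MapperConfig(n_intervals=(10, 10),
                                                       overlap_pct=70))
result.partition.n_states          # recovered metastable states
result.sample_labels               # per-sample state label sets
series = ts.membership_series(
    {table.samples[i]: result.sample_labels[i] for i in range(table.n_samples)},
    table.meta, subject="S0")
corr = ts.temporal_correlation(series, x=0)
ts.monotonicity_index(corr)        # < 0: transient occupancy; >= 0: recurrence
```

## Layout

- `src/topostates/data.py` — tables, compositions, JS/Aitchison distances
- `src/topostates/mapper.py` — PCoA-rank filters, cover, local clustering, nerve
- `src/topostates/density.py` — kNN density, maxima, basin/state assignment
- `src/topostates/dynamics.py` — temporal correlation, smoothing, monotonicity
- `src/topostates/rarefaction.py` — subsampling robustness summaries
- `src/topostates/simulate.py` — synthetic generators with ground truth
- `src/topostates/pipeline.py`, `cli.py`, `plotting.py` — orchestration, CLI, plots
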