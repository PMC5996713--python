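# effconn

Supervised effective-connectivity detection between multivariate neural
timeseries, with two built-in generative models and a Granger-causality
baseline.

The package simulates three interacting cortical circuits of leaky
integrate-and-fire neurons whose directed inter-circuit projections follow
a known causal configuration (one of the 25 labeled DAGs on three nodes),
and emits per-circuit LFP-like signals (the summed absolute AMPA and GABA
currents on pyramidal cells). A second generator produces mixed
multivariate autoregressions with the same ground-truth structure. Each
3-channel timeseries is encoded into a 627-dimensional causality feature
vector (regression goodness-of-fit scores under all cause-set scenarios,
conditional Granger indices, and engineered powers/products), on which a
25-class logistic regression learns to predict the causal configuration.
Class posteriors marginalize into six directed-edge scores, evaluated as a
pooled per-edge ROC and compared against the conditional Geweke (GCA)
baseline.

## Layout

| module | contents |
|---|---|
| `effconn.graphs` | DAG counting/enumeration, canonical 25-class catalog |
| `effconn.lif` | LIF circuit simulator, desk preset, NN dataset generation |
| `effconn.mar` | stationary MAR signal/noise mixture generator |
| `effconn.geweke` | conditional Geweke index, chi-square p-values, edge scores |
| `effconn.features` | 627-dimensional causality feature encoding |
| `effconn.classify` | classifier, edge-score marginalization, pooled ROC/AUC, CV and transfer evaluation |
| `effconn.diagnostics` | trial-averaged cross-correlograms, p-value uniformity summaries |
| `effconn.dataset` | Example/Dataset containers, HDF5 I/O |
| `effconn.config`, `effconn.cli` | run configuration and the `effconn` command |

## CLI

```sh
# generate a desk-scale LIF dataset (500-neuron circuits)
effconn generate --generator NN --scale desk --n-per-config 20 \
    --duration-ms 3000 --seed 1 --out scratch/nn.h5

# append 627-dim feature vectors (lag p defaults to 3 for NN, 10 for MAR)
effconn featurize scratch/nn.h5

# cross-validated supervised evaluation + GCA baseline
effconn evaluate scratch/nn.h5 --folds 5 --report scratch/report.json

# cross-correlogram peak lag and Geweke p-value summary
effconn diagnose scratch/nn.h5 --pair 0 1
```

`--scale paper` selects the full-scale defaults (5,000 neurons/circuit,
1,000 examples per configuration, 6,000 timepoints); expect hours of
compute. The desk preset (`effconn.lif.desk_preset`) is tuned so that the
latency and detection properties of the full model survive the 10x circuit
reduction; see its docstring.

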