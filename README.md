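# molsample

Resampling strategies for imbalanced binary molecular fingerprint datasets.

Classifiers trained on strongly imbalanced chemical data (e.g. toxicity
endpoints where actives are rare) tend to be biased toward the majority
class: specificity looks fine while sensitivity collapses. `molsample`
implements nine sampling conditions behind one uniform contract to close
that sensitivity–specificity gap, together with the fingerprint plumbing,
a Random-Forest cross-validation harness, and a synthetic data generator
so everything is testable offline.

## Sampling conditions

| name | kind | description |
|---|---|---|
| `none` | baseline | original dataset, untouched |
| `randus` | under | uniformly random majority removal |
| `augrandus` | under | iterative removal of majority rows most similar to the MCF fingerprint |
| `randos` | over | uniformly random minority duplication |
| `augrandos` | over | iterative duplication of minority rows least similar to the MCF fingerprint |
| `kmedoids1` | under | Tanimoto k-medoids via 100 random restarts; best total-similarity medoid set kept |
| `kmedoids2` | under | Tanimoto k-medoids via 30 random swaps per medoid; best-ever configuration kept |
| `smotetc` | over | binary SMOTE, Tanimoto neighbourhoods, per-bit 2-of-3 majority vote |
| `smotevdm` | over | binary SMOTE, Value-Difference-Metric neighbourhoods |

The MCF (most-common-feature) fingerprint is a reference bit vector whose
set bits are the highest-frequency features strictly exceeding the
reference class's average per-bit feature frequency; it steers the
augmented samplers and is rebuilt after every removal/duplication batch.
Every sampler is seeded, exactly balances the classes, and returns a full
audit trail (removed/duplicated indices, synthetic parents, per-iteration
MCF bits) that the test-suite replays.

## CLI

```sh
# compute MACCS fingerprints from a compound table (csv/tsv, .smi + sidecar labels, or SDF)
molsample fingerprint --input compounds.csv --descriptor maccs --output data.fps

# or generate a synthetic imbalanced dataset (no chemistry needed)
molsample simulate --bits 166 --n-majority 200 --n-minority 20 --seed 1 --output data.fps

# apply one sampling condition, keeping the audit trail
molsample sample --input data.fps --method smotetc --k 5 --seed 2 \
    --output balanced.fps --audit audit.json

# compare conditions under 10-fold CV (and optionally an external test set)
molsample evaluate --train data.fps --methods none,randus,smotetc,kmedoids2 \
    --folds 10 --trees 1000 --seed 3 --report report.json

# pairwise similarity matrix of a small dataset
molsample similarity-debug --input small.fps --metric tanimoto
```

Dataset files are plain text (`#molsample-dataset v1` header, then
`id<TAB>label<TAB>bitstring` rows). A JSON/YAML config file of default
flag values can be passed as `molsample --config conf.json <subcommand>`;
explicit flags win. Reports are deterministic JSON: identical
configuration and seed reproduce byte-identical output.

Evaluation applies the sampler **inside** the CV loop, to the training
part of each fold only; the held-out fold is never resampled. The leaky
before-split variant exists behind `--leaky` for reproduction studies and
warns loudly.

## Layout

```
src/molsample/
  fingerprints_io.py   compound tables, MACCS/Morgan fingerprints, dataset format
  similarity.py        Tanimoto + VDM kernels, deterministic k-NN
  samplers.py          MCF construction and the nine sampling conditions
  evaluation.py        RF harness, CV/external validation, metrics, reports
  synthetic_data.py    seeded imbalanced fingerprint generator
  cli.py               command-line entry point
tests/                 unit, property and acceptance tests
scripts/acceptance.py  acceptance report runner
```
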