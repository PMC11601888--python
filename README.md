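# funlnc

Prioritize functional long noncoding RNAs (lncRNAs) from multi-omic
regulatory evidence. `funlnc` assembles a heterogeneous regulatory network
around each lncRNA — promoter-proximal regulators (TF ChIP peaks, TF motif
hits, histone marks, methylation sites, SNPs), distal elements
(typical/super-enhancers and accessible chromatin linked by distance or by
3D chromatin contacts) and downstream partners (target mRNAs, miRNAs, bound
proteins) — derives a 57-column feature matrix from it, trains a random
forest to separate functional from nonfunctional lncRNAs, and flags
high-confidence calls with an empirical permutation score
(−log10 exceedance probability, cutoff > 2).

## Inputs

Everything is plain text, 0-based half-open coordinates:

| file | format |
|---|---|
| lncRNA genes | BED6/BED12 (chrom, TSS from the 5' end, strand, id) |
| regulator elements | BED3/5/6 per kind (name = regulator identity, col 5 = signal) |
| 3D contacts | BEDPE (col 8 = contact frequency) |
| downstream pairs | TSV `lncrna_id  partner_id  partner_kind` |
| labels | TSV `lncrna_id  label` (1 = functional) |
| sequences (optional) | FASTA, for similarity-grouped splitting |

## CLI

```bash
funlnc simulate --out bundle/ --seed 1            # synthetic fixture bundle
funlnc build-network --lncrnas bundle/lncrnas.bed \
    --tf-chip bundle/tf_chip.bed --histone bundle/histone.bed ... \
    --interactions bundle/interactions.bedpe --pairs bundle/pairs.tsv \
    --out net/
funlnc featurize --edges net/network_edges.tsv --out fm.tsv
funlnc train --matrix fm.tsv --labels bundle/labels.tsv --out model/
funlnc predict --model model/ --matrix fm.tsv --out preds.tsv
funlnc permscore --model model/ --matrix fm.tsv --B 1000 --mode safe \
    --seed 1 --out scored.tsv
funlnc ablate --matrix fm.tsv --labels bundle/labels.tsv --out ablation.tsv
funlnc noise --matrix fm.tsv --labels bundle/labels.tsv --out noise.tsv
funlnc run --config run.json --out results/                # all stages
```

`funlnc run` consumes a JSON `RunConfig` (paths per input kind, promoter
window, enhancer assignment distance, split mode, forest/permutation
settings, seed) and emits the network edge list + summary, feature matrix,
saved model, evaluation report, prediction + score table and a manifest.

## The feature matrix

57 features in three categories: 8 promoter-proximal (C1: SNP counts, TF
ChIP / core-TF / motif counts, methylation count + normalized signal,
activating histone-mark type count), 46 distal (C2: super-enhancer 12,
typical enhancer 23, chromatin accessibility 10 — each under the
distance-based and the 3D-interaction assignment manner — plus total
promoter contact frequency), and 3 downstream partner counts (C3). Absent
regulators featurize to 0, never NaN; normalized columns are cohort-relative
and lie in [0, 1]. See `funlnc.features.default_schema()`.

## Python API sketch

```python
from funlnc.synthetic import SimConfig, simulate_dataset
from funlnc.pipeline import network_from_bundle
from funlnc.features import build_feature_matrix
from funlnc.classifier import LabeledSet, split_random, fit_model, predict_and_label, evaluate
from funlnc.permscore import random_probabilities, score_records, call_hc

bundle = simulate_dataset(SimConfig(seed=1))
matrix = build_feature_matrix(network_from_bundle(bundle))
labeled = LabeledSet(
    tuple(i for i, z in bundle.labels.items() if z),
    tuple(i for i, z in bundle.labels.items() if not z),
)
train, test = split_random(labeled, 0.8, seed=1)
model = fit_model(matrix, train, seed=1)
records = predict_and_label(model, matrix)
r = random_probabilities(model, matrix, B=1000, seed=1)
scored = call_hc(score_records(records, r))
```

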