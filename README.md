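# cobind

Discovery of combinable transcription-factor co-binding modules from
multi-factor binding data.

Pooled per-factor binding calls are expanded ±50 bp around their summits
and merged into non-overlapping *co-binding regions* (≥3 sites). Treating
regions as documents and TF sites as words, a hierarchical Dirichlet
process (HDP) topic model — a collapsed Gibbs sampler with the number of
modules inferred from the data — summarizes the corpus into a module-TF
matrix and a per-site assignment table. Downstream layers derive factor
participation and per-module "main drivers" (z > 1 calls), region-level
module usage (≥3 sites and within-region z > 1), multi-module usage
census, module groups (average-linkage clustering at correlation
distance 0.5), and PCA. Companion analyses cover fixed-k baselines
(k-means / NMF) with a TF-correlation fidelity metric, direct-vs-indirect
binding (dX/iX factor splitting, diversification scores, random-forest
prediction), protein-interaction rediscovery with a permutation test,
annotation overlap fractions, and cross-cell-type module usage. A
synthetic generator with planted ground truth makes every stage testable
offline.

## Tests

```bash
python -m pytest tests/          # unit + property tests and the
                                 # acceptance criteria (~5 min total)
```

`tests/test_acceptance.py` holds the seven property-based acceptance
criteria (region-merge oracle, planted-module recovery, fidelity
ordering vs k-means, multi-module detection, direct/indirect
separability sweep, permutation-test calibration, mechanical
invariants).

## CLI

The `cobind` console script chains the pipeline stages:

```bash
cobind simulate --seed 3 --out sim/                      # synthetic calls + truth
cobind build-regions --calls-dir sim/calls --out reg     # regions + region-TF matrix
cobind fit --matrix reg.region_tf_matrix.tsv \
           --eta 0.1 --max-iter 2000 --seeds 1,2,3 --out fit
cobind analyze --module-matrix fit.module_tf_matrix.tsv \
               --assignments fit.assignments.tsv --out analysis
cobind compare --matrix reg.region_tf_matrix.tsv \
               --module-matrix fit.module_tf_matrix.tsv --k 49 --out cmp
cobind split-di --calls-dir calls/ --spec seq_specific.txt --out split/
cobind predict-di --matrix split.region_tf_matrix.tsv --factor TF26 \
                  --spec seq_specific.txt --out rf.tsv
cobind eval ppi --module-matrix fit.module_tf_matrix.tsv --ppi pairs.tsv --out ppi.tsv
cobind eval spacing --anchor A.calls.tsv --partner B.calls.tsv --out spacing.tsv
cobind run --synthetic --seed 0 --out out/               # full pipeline + manifest
```

Inputs are plain text: per-factor TSV point calls
(`chrom<TAB>summit[<TAB>motif 0/1[<TAB>strength]]`), BED blacklists and
annotation tracks, 2-column PPI TSVs. Outputs are TSV/BED plus a JSON
manifest recording parameters and seeds.

## Package layout

| module | contents |
| --- | --- |
| `cobind.regions` | binding-call IO, blacklist filter, region construction, region-TF matrix |
| `cobind.topic_model` | corpus building, HDP collapsed Gibbs sampler, module-TF matrix + assignments |
| `cobind.module_analysis` | z-scores, participation/driver calls, usage rules, census, module groups, PCA |
| `cobind.baselines` | k-means / NMF at fixed k, fidelity metric, module matching |
| `cobind.direct_indirect` | dX/iX splitting, d-i correlations, diversification, RF prediction |
| `cobind.evaluation` | PPI rediscovery + permutation test, annotation overlap, cross-cell-type, spacing |
| `cobind.synthetic` | planted-module generator with ground truth, recovery scoring |
| `cobind.cli` / `config` / `pipeline` / `io` | CLI, run configuration, end-to-end driver, TSV/BED writers |
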