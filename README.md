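# coherence-screen

A pipeline for discovering genes whose expression is "coherent" with an
anchor gene (default `METTL3`) in case/control expression data. Stages:

1. **Dual differential-expression screen** — case-vs-control DEGs and
   anchor-median-split DEGs within cases (`|log2FC| > 0.3`, `p < 0.05`),
   intersected into an anchor-related gene set.
2. **Ant-colony seriation** — genes are ordered into a linear "gene
   sequence" minimizing total squared-Euclidean distance between consecutive
   expression profiles (case samples, z-scored by default). The
   optimization is repeated 10 times with independent seeds; genes landing
   within a positional window (default 5) of the anchor in ≥ 5 runs are the
   coherent candidates.
3. **Clinical ranking** — candidates are fit against MMSE and NFT scores by
   OLS; the best MMSE fit is the final candidate.
4. **Two-gene diagnostic** — an SVM on (anchor, candidate) expression, with
   stratified 10-fold CV AUC, a 60/40 hold-out AUC, and an empirical anchor
   threshold (the largest expression value below which every sample is a
   case).

A synthetic data module generates cohorts with planted coherent genes,
known anchor correlations, and clinical scores linearly coupled to a
designated gene, so every stage is testable offline with ground truth.

## CLI

```sh
# generate a synthetic 74-control / 87-case dataset with ground truth
coherence-screen simulate --outdir data --seed 1

# run the full pipeline (synthetic by default, or from a YAML config)
coherence-screen run --outdir results --seed 1
coherence-screen run --config config.yaml --outdir results \
    --window 5 --runs 10 --min-count 5 --iterations 200

# pretty-print the machine-readable run report
coherence-screen report --outdir results
```

A pipeline config YAML holds either a `synthetic:` block or
`expression_path`/`phenotype_path` pointing at tab-delimited inputs
(expression: first column gene id, header row sample ids; phenotype
columns: `sample_id, group, severity, mmse, nft`). All ACO, DEG, and
diagnostic knobs are exposed both in the YAML and as CLI flags
(`--ants --alpha --beta --rho --iterations --objective --no-standardize
--samples --kernel --c --folds --train-fraction`).

Each run writes per-stage TSVs (`degs_*.tsv`, `sequences.tsv`,
`frequency.tsv`, `fits.tsv`, `cv_auc.tsv`) plus `report.json`; the TSVs are
sufficient to re-run any later stage in isolation.

## Package layout

```
src/coherence_screen/
  synthetic_data.py   # planted-ground-truth cohort generator
  dataio.py           # TSV readers/writers with validation
  diffexpr.py         # dual DEG screen (Welch / moderated t)
  aco_seriation.py    # ant system, oracle, neighbor-frequency screen
  clinical_assoc.py   # OLS fits and candidate ranking
  diagnostic.py       # SVM, CV AUC, anchor threshold
  pipeline.py         # orchestration + run report
  cli.py              # coherence-screen simulate|run|report
```
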