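# crsig

Cross-tissue transcriptional signature detection and conservation
testing for caloric-restriction-style intervention studies.

## The problem

Interventions such as caloric restriction (CR) act in parallel across
tissues, but single-gene analyses miss the shared program: different
genes can drive the same pathway in different tissues, and platforms
disagree on transcript coverage. `crsig` works at the gene-set level
instead. Given several independent two-group expression studies
("tissues") and a GO-style gene-set collection, it:

1. collapses probe-level matrices to one row per gene (largest mean
   intensity wins; unannotated and multi-annotated probes dropped);
2. computes per-gene log2 fold changes and Welch t-tests per study;
3. scores every gene set in every study with the PAGE statistic
   **Z = (Sm − μ)·√m/δ**, where Sm is the set's mean fold change, μ and δ
   the mean and sample SD of all fold changes, and m the number of set
   members measured in that study (size filter 10–1000, ontology levels
   3–5 by default);
4. extracts the cross-study consensus signature: per-term one-sample
   t-tests on Z, Benjamini–Hochberg correction, and the dual filter
   *adjusted p < 0.00285 AND |median Z| ≥ 2.58*;
5. quantifies conservation of the signature between two study groups by
   Spearman correlation of median-Z vectors, with four resampling
   schemes — permutation, pair bootstrap, and two Gaussian-model schemes
   whose null accounts for the correlation that shared member genes
   induce between gene-set Z-scores (predicted null correlation
   `overlap/√(size₁·size₂)`, injected via Cholesky factorisation).

A synthetic-data module generates multi-study compendia with overlapping
gene sets and a known embedded signature, so the whole pipeline is
testable end to end without any downloads. See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
import pandas as pd
from crsig import (SimulationConfig, simulate_collection, simulate_studies,
                   differential_stats, page_matrix, consensus_signature,
                   median_z, overlap_correlation, model_permutation, page_zscore)

# the PAGE statistic on a toy study: six genes with fold changes 1..6,
# a two-gene set holding the top two genes
fc = pd.Series([1., 2, 3, 4, 5, 6], index=list("abcdef"))
print(round(page_zscore(fc, ["e", "f"]), 5))        # 1.51186

# an eight-study compendium with 10% signal terms embedded
cfg = SimulationConfig(n_genes=20000, n_terms=1000, n_studies=8,
                       effect_size=0.5, noise_sd=0.25,
                       signal_term_fraction=0.1, seed=7)
coll = simulate_collection(cfg)
studies, truth = simulate_studies(coll, cfg)
zmat = page_matrix([differential_stats(s) for s in studies], coll)
sig = consensus_signature(zmat)                      # p_adj<0.00285, |median Z|>=2.58
print(int(sig["passed"].sum()), len(truth.signal_terms()))   # 100 100
```

The signature table reports, per term, the median Z across studies, the
one-sample t statistic and raw/BH-adjusted p, the pass flag, and the
direction (`up`/`down`). In this run all 100 embedded terms are
recovered with no false positives.

Concordance between two groups of studies:

```python
terms = list(sig.index[sig["passed"]])
a = median_z(zmat, ["S01", "S02", "S03", "S04"]).loc[terms]
b = median_z(zmat, ["S05", "S06", "S07", "S08"]).loc[terms]
corr = overlap_correlation(coll, terms)
res = model_permutation(a, b, corr, n_sim=999, seed=1)
print(round(res.r, 3), res.p)                        # 0.981 0.001
```

`p = 0.001` is the floor of the add-one Monte Carlo estimator at 999
resamples — the observed correlation exceeded every simulated null draw.

## Command line

Every stage is also a subcommand of the `crsig` tool:

```bash
crsig simulate --config sim.yaml --outdir data/
crsig diff --study data/S01.tsv --out diff/S01.tsv
crsig page --gmt data/collection.gmt --meta data/terms.tsv \
      --diff diff/S01.tsv --diff diff/S02.tsv --out zmatrix.tsv
crsig signature --zmat zmatrix.tsv --out signature.tsv
crsig concordance --vec-a median_a.tsv --vec-b median_b.tsv \
      --gmt data/collection.gmt --scheme modelperm --n 999 --seed 1 --out conc.json
crsig run --config pipeline.yaml --outdir run/   # everything, with a manifest
```

Matrices are TSV with `NA` missing markers; gene sets are GMT plus a
term-metadata TSV (term_id, name, depth); runs write a manifest with
parameters, seed, and SHA-256 checksums, and identical config + seed
reproduce it byte for byte.

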