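# clipdiff

Quantitative comparison of two CLIP-seq experiments.

CLIP-seq (crosslinking immunoprecipitation followed by sequencing) maps the
binding sites of an RNA-binding protein genome-wide. Many questions are
*comparative*: how does binding change between wild-type and knockout, between
cell types, or between treatment conditions? Peak-calling each sample
separately and intersecting the peaks answers this badly — it ignores depth
and signal-to-noise differences between libraries and gives no per-site
quantitative call. `clipdiff` addresses the two-sample comparison directly,
for HITS-CLIP, PAR-CLIP and iCLIP libraries.

## Method

Aligned tags are collapsed for PCR duplicates strand-specifically, CLIP
clusters are called as maximal regions of non-zero combined coverage, and
each cluster is divided into small bins (default 5 bp). The i-th bin of the
j-th cluster carries tag-intensity counts $(x_{i,1}^j, x_{i,2}^j)$, the sum
of per-base coverage per condition. Two stages follow:

1. **MA normalization.** For each bin, with pseudocount $c>0$:

   $$M = \ln(x_1+c) - \ln(x_2+c), \qquad A = \ln(x_1+c) + \ln(x_2+c)$$

   A line $M = a + bA$ is fitted by OLS over bins whose raw counts both
   exceed a cutoff (confident signal in both conditions), and the fitted
   value is subtracted from every bin's $M$. The residual ("adjusted M")
   removes depth and intensity-dependent bias.

2. **Three-state HMM.** Adjusted M values are modelled by a three-component
   normal mixture with means $(+\mu, 0, -\mu)$ and shared $\sigma$: state 0
   = stronger binding in condition 1, state 1 = common binding, state 2 =
   stronger in condition 2. $\sigma$ is estimated robustly as
   $\mathrm{MAD} \times 1.4826$; $(p,\mu)$ (with $p$ the weight of each
   outer component) by a grid-search MLE under the second-moment constraint
   $\hat\mu_2 = 2p\mu^2 + \sigma^2$. Emission densities are then fixed, a
   shared 3×3 transition matrix is trained by Baum–Welch over all cluster
   sequences, and per-bin states are decoded by Viterbi. A warning is issued
   when the estimated common-binding fraction $1-2\hat p$ falls below 50%,
   where the model's central assumption becomes doubtful.

Protocol specifics: HITS-CLIP deletions and PAR-CLIP T→C (or G→A)
substitutions are profiled per tag from the CIGAR/MD fields; iCLIP reads are
deduplicated pre-mapping by their 5′ random barcode
(`clipdiff remove-barcodes`), and after mapping the crosslink nucleotide
(one base upstream of each cDNA) is expanded ±w bases into per-base cDNA
count tracks.

## Worked example

Simulate a two-condition HITS-CLIP dataset with planted common and 4-fold
differential regions, then compare:

```bash
clipdiff simulate --out-dir sim --seed 1 --n-regions 30
clipdiff run --sam1 sim/cond1.sam --sam2 sim/cond2.sam \
    --mutation-type deletion --out-prefix out/run
```

The run prints the estimation summary:

```
Differential CLIP-seq comparison
================================================
bins: 2371   clusters: 30

MA normalization  M = a + b*A
  a (intercept)     -0.792857
  b (slope)          0.107773
  bins in fit       2262

Emission mixture on adjusted M
  sigma (MAD)        0.779147
  p (outer weight)   0.078000
  mu (|outer mean|)  1.390971
  common fraction    0.8440
  log-likelihood    -3238.1969  (n=2371)

HMM transitions (8 iterations, converged=True)
  0.9857  0.0143  0.0000
  0.0016  0.9981  0.0003
  0.0000  0.0125  0.9875

Decoded bin states
  0 cond1_stronger   423
  1 common           1612
  2 cond2_stronger   336
```

Reading it: the regression line absorbs the libraries' depth and
intensity-dependent bias before any state is called; the fitted mixture
attributes ~84% of bins to common binding (no warning — the assumption that
most binding is unchanged holds), with outer components at ±1.39, close to
ln 4 for the planted 4-fold regions; the strongly diagonal transition
matrix reflects the
spatial persistence of binding states along clusters. Outputs under
`out/`: `run.regions.bed` (merged same-state regions, one BED6 line each),
`run.bins.txt` (per-bin counts, M/A values and decoded state) and eight
bedGraph tracks — {total, mutant} × {condition 1, 2} × {+, −} — ready for
the UCSC genome browser.

The `ClipDifferentialModel` / `ClipDifferentialResults` API exposes the
same pipeline programmatically:

```python
from clipdiff import ClipDifferentialModel, PipelineConfig

model = ClipDifferentialModel.from_sam("cond1.sam", "cond2.sam",
                                       PipelineConfig(mutation_type="deletion"))
results = model.fit()
print(results.summary())
strong = results.filter_regions(state=0, min_mean_intensity=30, which_condition=1)
```

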