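# Methods

This note records the statistical model behind `clipdiff`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the known limitations of the estimators. It
states no empirical result that the test suite or `scripts/acceptance.py`
do not themselves compute.

## Model

### Data reduction

All processing is strand-specific. Tags from each condition are PCR-duplicate
collapsed on the key (chrom, start, end, strand) — both ends, not just the 5′
position, so tags of different lengths are never merged. The mutation list of
a collapsed group is the union of its distinct (kind, pos, ref, alt) entries,
counted once, so amplification cannot inflate mutation evidence. Reads are
used exactly as aligned: never shifted or extended; soft-clipped bases are
outside the tag span. In paired-end mode a properly-paired fragment
contributes one tag spanning the outer fragment coordinates, attributed to
read1 (whose strand and mutations it carries — the mate is not buffered);
orphan mates count as single-end.

CLIP clusters are maximal strand-specific runs of bases with non-zero
*combined* (condition 1 + condition 2) coverage; tags retain their condition
identity inside them. Clusters with fewer than `min_cluster_tags` combined
tags (default 10; the threshold is on the combined count because clusters
are defined jointly) are dropped as noise. Each cluster is partitioned
left-to-right into `bin_size` windows (default 5 bp; only the last bin may
be shorter, and it is kept without length normalization). The bin's
tag-intensity count is the *base-wise coverage sum* over the bin — a bin
fully covered by a single tag spanning all five of its bases scores 5.

iCLIP differs twice. Pre-mapping, PCR duplicates are reads identical over
their full sequence — random barcode *and* insert; barcode equality alone
would collapse independent cDNAs that happened to draw the same barcode.
The first occurrence is kept and barcodes (random + optional fixed
experimental barcode) are trimmed with qualities in register. Post-mapping,
the crosslink nucleotide — the reference base immediately upstream of the
cDNA 5′ end; by strand symmetry, position `start − 1` for a `+` tag and
position `end` (half-open) for a `−` tag — is expanded ±w bases (default
w = 2, a 5-nt window matching the default bin scale) into per-base cDNA
count tracks, and mutant counts are identically zero.

### Normalization

Per bin, with pseudocount c (default 1, guarding the logarithm):

    M = ln(x1 + c) − ln(x2 + c)
    A = ln(x1 + c) + ln(x2 + c)

An ordinary least-squares line M = a + bA is fitted over bins with
x1 > cutoff **and** x2 > cutoff (strict, default 5 ≈ one tag-depth unit per
base at the default bin size), and M_adj = M − (a + bA) is computed for
*every* bin in every cluster, including bins outside the fit. Plain OLS is
used deliberately — no robust or weighted variant. Natural logarithms
throughout. Exact consequences used as test oracles: refitting on
(A, M_adj) returns a ≈ b ≈ 0; swapping condition labels negates M and
M_adj and preserves A exactly.

### Emission mixture

Adjusted M under the three binding states follows

    f(m) = p φ(m; +μ, σ) + (1 − 2p) φ(m; 0, σ) + p φ(m; −μ, σ)

with the zero-mean middle component representing common binding (the
normalization centres common bins at zero), equal outer weights and a
shared σ to keep extreme M values from being assigned unreasonably. The
+μ component pairs with state 0 (stronger in condition 1) because M is
positive when condition 1 is higher.

Estimation is a deliberate hybrid, not EM:

* σ̂ = median(|M − median(M)|) × 1.4826, computed once over all adjusted M
  and never updated. The constant makes MAD consistent for a normal; the
  outer components are treated as outliers.
* The mixture's second moment satisfies μ₂ = 2pμ² + σ², so the sample
  second moment μ̂₂ pins μ for any candidate p:
  μ(p) = sqrt((μ̂₂ − σ̂²) / 2p). p is searched on the grid 0.001…0.499 in
  steps of 0.001 (μ is *not* gridded independently — the constraint holds
  exactly at every evaluated point), the full mixture log-likelihood is
  evaluated at each feasible point with σ̂ plugged in, and the arg-max pair
  wins. If no grid point is feasible (μ̂₂ ≤ σ̂²) the run aborts with "no
  differential signal detectable" — the honest outcome on null data.

Emission densities e_s(m) = φ(m; mean_s, σ̂) are computed once per bin and
remain fixed through HMM training.

A warning is issued when the estimated common fraction 1 − 2p̂ is strictly
below 50%: the method assumes most sites bind similarly in both conditions,
and below that point results need independent corroboration. Analysis
continues regardless.

### HMM

One observation sequence per cluster; all sequences share a single 3×3
transition matrix and the fixed emissions. Training is Baum–Welch
restricted to the transition matrix: per iteration, scaled forward–backward
over every sequence, expected transition counts pooled across sequences,
rows renormalized. The initial distribution is uniform (1/3, 1/3, 1/3) and
never re-estimated. Initial Π has diagonal 0.9 / off-diagonal 0.05 —
spatial persistence without bias toward any state. Stopping: max |ΔΠ| <
1e−4 or 100 iterations. A transition row whose state collects no expected
mass is reset to uniform with a warning. Decoding is per-cluster Viterbi in
log space; every arg-max tie breaks toward the lowest state index, making
runs deterministic. Correctness anchors: on sequences of length ≤ 6 both
the Viterbi path probability and the expected transition counts are checked
against exhaustive 3^L enumeration; training log-likelihood is
non-decreasing (EM monotonicity).

### Reporting

Adjacent same-state bins are merged into regions within (never across)
clusters. Outputs: BED6 regions (name `cluster<j>_state<s>`, score
min(1000, round(200·|mean M_adj|)) since BED needs a bounded score and
UCSC caps at 1000), a per-bin TSV with every intermediate quantity
(cluster, bin, coordinates, x1, x2, m1, m2, M_raw, A, M_adj, state), and
exactly eight bedGraphs: {total, mutant} × {condition} × {strand}, zero
intervals omitted, equal-value runs merged. Mutant tracks count per-base
mutation events, not coverage of mutated tags. All coordinates are 0-based
half-open.

## Synthetic data

`simulate_bin_sequences` draws directly from the generative model (Markov
states from Π with uniform initial, normal emissions) and returns the true
paths; its defaults — 500 clusters × 50 bins, Π diagonal (0.80, 0.95,
0.80), mixture (p = 0.15, μ = 1.5, σ = 0.8) — are the reference conditions
used by the parameter-recovery tests.

`simulate_sam_pair` writes a toy two-contig (2 × 100 kb) genome's worth of
alignments: 60 planted regions of 400 bp separated by 300 bp gaps (larger
than any read, so each region is its own cluster), of which a
`common_fraction_target` = 0.7 share is common and the rest splits between
stronger-in-1 and stronger-in-2 at `intensity_ratio` = 4. Read counts are
Poisson around 100 expected tags per region per condition (≈ 9× base
coverage, a realistic CLIP cluster depth), starts uniform within the
region, lengths uniform in 36 ± 5 nt — adapter-trimmed CLIP tags vary in
length, and this variation is what keeps coordinate-based duplicate
collapsing from saturating the planted intensity ratios. `depth_ratio`
scales condition 2 globally to emulate sequencing-depth imbalance.
Characteristic mutations are planted at each region's central crosslink
site with per-tag probability 0.2: CIGAR-encoded 1-bp deletions
(HITS-CLIP) or MD-encoded T→C substitutions (PAR-CLIP; A→G in reference
orientation on `−` regions, with the crosslink base forced to the
photoactivatable nucleotide). A 10% share of reads is emitted twice to
exercise duplicate collapsing. iCLIP scenarios additionally write FASTQ
with 5-nt random barcodes and planted exact-duplicate reads.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: transcriptome-structured read placement (clusters sit
on a uniform background, not on exons), sequencing errors beyond the
planted characteristic mutations, non-uniform crosslinking efficiency,
overlapping or nested binding sites, multi-mapping ambiguity, and
transcript-abundance differences between conditions (a fold change in
expression is indistinguishable from a fold change in binding here, as in
the method itself).

## Numerical choices and degenerate inputs

Likelihoods are computed in log space; forward–backward uses per-position
scaling; zero-probability forward mass raises rather than propagating NaNs.
Fatal conditions with explanatory messages: substitution profiling without
MD tags, fewer than two qualifying regression bins (advises lowering the
cutoff), all adjusted M identical (σ̂ = 0), empty feasible grid, empty
input. Record-level problems (malformed CIGAR, inconsistent MD) skip the
record with a logged warning. Chromosomes are processed in lexicographic
order and ties broken deterministically throughout, so fixed inputs give
byte-identical outputs.

## Known limitations

* **The MAD scale estimate is biased upward whenever differential mass is
  appreciable.** MAD × 1.4826 is consistent for the middle component only
  as its weight → 1. At p = 0.15 per outer component (30% differential
  mass, μ/σ ≈ 1.9) the estimator converges to the *mixture's* population
  MAD, ≈ 36% above the true component σ (the unit suite checks this
  against the analytic quantile). Downstream, the inflated σ̂ shrinks p̂
  and the decoded differential calls are correspondingly conservative —
  state recovery remains high because decoding depends on the likelihood
  *ordering*, not the absolute scale. With differential mass above 50%
  the sample second moment can fall below σ̂² entirely, aborting with "no
  differential signal"; this is the same regime the common-fraction
  warning exists for.
* On null data (no differential binding) the moment constraint leaves no
  excess second moment: the fit either aborts (the usual case) or returns
  a negligible μ̂ — there is no spurious-separation mode, but also no
  graceful "p = 0" estimate.
* The mixture likelihood treats bins as independent during estimation
  while the HMM then models their dependence; the inconsistency is part of
  the method's design and is reproduced, not resolved.
* Bins are compared without transcript-abundance covariates; differential
  expression masquerades as differential binding.
* Terminal short bins are not length-normalized; at the default 5-bp bin
  the effect on the fit is negligible, but very large bin sizes would
  distort their M values.
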