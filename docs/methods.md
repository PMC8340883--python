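# Methods

`fibromir` re-implements, at desk scale, the integrated miRNA–mRNA analysis
used to study spontaneous reversal of liver fibrosis in the mouse
thioacetamide (TAA) model: three groups (control, fibrotic, recovery; n = 3
each), small-RNA and mRNA count profiles, and a cascade of filters that ends
in a small set of hub genes and key miRNAs. This note documents the models,
the defaults and why they were chosen, and what the synthetic benchmark does
and does not show.

## Differential expression

Counts are modelled as negative binomial with variance μ + φμ². The stage is
a deliberately compact NB Wald pipeline:

* **Size factors** — median-of-ratios: for features with nonzero counts in
  every sample, factor_j = median_i(count_ij / geometric-mean_i). No
  rescaling is applied afterwards.
* **Dispersion** — per-feature method of moments on normalized counts with
  the residual variance pooled within groups, φ̂ = max(0, (s² − μ̄)/μ̄²), then
  shrunk halfway toward a trend fitted by least squares of φ̂ on 1/μ̄. The
  50/50 shrinkage stabilises the very noisy per-feature moments at n = 3 per
  group while preserving genuine heterogeneity; features with zero mean get
  φ = 0.
* **Wald test** — log2 fold change is the shrinkage-free log2 ratio of
  normalized group means with a +0.5 pseudocount (keeps fold changes finite
  when a group is all zeros; the emulated study reports linear fold changes
  up to ~10⁵, which implies near-zero denominators, so behaviour under zeros
  must be defined). The standard error comes from the delta method applied
  to each group mean, Var(mean) = (q·Σ1/s_j + φq²·n)/n², and the two-sided
  p-value from the normal distribution. Degenerate features (zero SE) are
  p = 1 when the fold change is zero.
* **Multiplicity** — Benjamini–Hochberg step-up per contrast (fibrotic vs
  control; recovery vs fibrotic), implemented directly from the definition
  and cross-checked against `statsmodels` in the tests.
* **Fold-change convention** — signed linear: 2^lfc when up, −2^(−lfc) when
  down, so |signed FC| ≥ 1 and a halving prints as −2.

Calibration measured by the test suite at the study's design (n = 3 vs 3):
null p-values are uniform (KS ≤ 0.05 over 2,000 features), the fraction of
null features passing FDR < 0.05 is ≪ 1% over ten seeds, and > 70% of planted
four-fold features at φ = 0.05 pass the default gate (FDR < 0.05,
|FC| ≥ 2). Numerical agreement with DESeq2 is not claimed and not a goal:
no LFC shrinkage, no outlier filtering, no independent filtering.

## Reversal filtering and pair mining

A feature is *reversed* when it passes the DE gate in **both** contrasts with
opposite signs — the Venn-intersection reading of the study's design. A
relaxed `sign_only` mode (significant in fibrosis, opposite-signed in
recovery) is available behind a flag. Direction labels downstream follow the
recovery-vs-fibrotic orientation ("up" = up during reversal), matching the
convention of the study's top-DEM tables.

Candidate pairs are predicted-target edges (miRWalk-style table with
per-program evidence for TargetScan / miRDB / miRTarBase; `min_programs`
defaults to 1, i.e. the union, because the consensus level is genuinely
ambiguous in this kind of export) restricted to reversal miRNAs × reversal
genes. Each candidate is scored by the Pearson correlation across **all
nine samples** of log2(TPM/FPKM + 1); the sample scope and transform are
configuration options, since which samples fed the published correlations is
not stated. Pairs with |PCC| ≥ 0.8 and p < 0.05 are retained (at n = 9 the
first gate implies the second: t = 0.8·√(7/0.36) ≈ 3.53 > t₀.₉₇₅(7) ≈ 2.36).
Negative pairs are split by the miRNA's recovery direction into
upMiR–downGene and downMiR–upGene; positive pairs are reported but excluded
from network stages, since miRNA-mediated repression implies anti-correlation.

Correlation p-values use t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom,
with p = 0 exactly at r = ±1.

## Enrichment

Over-representation is the hypergeometric upper tail
p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n) (via `scipy`'s stable survival
function), with BH correction across the tested sets of one collection and
significance at FDR < 0.05. The universe defaults to the collection's
universe and can be restricted to the measured genes; overlaps of k ≥ 1 are
reported, k ≥ 3 required for the significance flag (common ORA practice; the
emulated workflow used a web service whose background is unspecified, so the
choice is exposed rather than hard-coded). No GO-graph or pathway-topology
awareness is attempted.

## Networks and hubs

The regulatory network is the bipartite graph of retained negative pairs;
nodes carry the recovery-contrast signed fold change, edges carry PCC and
p-value, and exports are Cytoscape-loadable (SIF and GraphML, round-trip
tested). Hub genes are the intersection of designated ECM gene sets
(collagen-like ∩ elastin-like) among the reversal genes; in the emulated
study this recovers the lysyl oxidase family. The PPI subnetwork is the
first-degree neighborhood of the hubs at combined score ≥ 400 (STRING's
conventional medium confidence; the study states no cutoff), restricted by
default to the down-in-recovery reversal genes; edges among included
neighbors are kept (a hub-spoke-only mode exists), and node degree is
computed within the displayed subnetwork. Key miRNAs are the triple-Venn
intersection of the miRNAs whose negative pairs hit each of three designated
target categories (ECM components, HSC activation, LOX regulation).

## Synthetic data

The generator plants everything the pipeline is supposed to find:

* **Counts** — gamma-Poisson (NB) with constant dispersion φ (default 0.02,
  a low inbred-strain value; variance = μ + φμ²; φ = 0 degenerates to
  Poisson, tested against the variance≈mean limit). Baseline means are
  log-uniform over 10^1.5–10^3 (default), i.e. moderately-to-highly expressed
  features — the regime where correlation mining at n = 9 is informative.
* **Reversal features** — group means (μ, μ·f^d, μ) with planted fold change
  f = 4 and direction d = ±1; the fibrotic shift is fully restored in
  recovery. Background features have equal group means. Defaults: 200
  miRNAs / 1,000 genes with 15% reversal — a deliberate scale-down of the
  study's cascade that keeps every acceptance run in seconds.
* **Coupling** — each planted pair shares a per-sample log-normal latent
  factor, multiplied into the miRNA mean and divided out of the gene mean
  (mean-one correction exp(−s²/2), so group means are unbiased). The scale s
  is set by a one-dimensional search whose objective is the mean planted-pair
  |PCC| measured on log2(TPM + 1) of a full fixed-seed calibration draw —
  i.e. exactly the quantity the pipeline later computes. Measuring on TPM
  matters: with a desk-scale panel, large latent factors destabilise the
  library totals that TPM divides by, so the objective rises and then falls;
  the search walks the rising branch and, when the requested coupling is
  unreachable, settles on the smallest scale within the Monte-Carlo noise
  band of the best achievable value. With the default four-fold reversal
  pattern the planted pairs already correlate at ≈ 0.95 with no latent at
  all, so the default target of 0.9 resolves to s = 0; the latent engages
  when dispersion is high or the pattern weak (verified by a dedicated test
  at φ = 0.15).
* **Anchor block** — four key miRNAs (down in fibrosis) target four hub
  genes plus two dedicated "ECM" and two "HSC" category genes each; each key
  miRNA additionally targets a second hub gene without latent coupling,
  mirroring the shared-target structure of real regulatory networks. Anchor
  features sit at the top of the mean range so that exact hub/key recovery
  is a property of the method rather than of sampling luck.
* **Target map** — every planted pair appears with full three-program
  evidence; background edges are added uniformly (default density 0.002 —
  sparse enough that group-pattern-driven correlations among non-paired
  reversal features do not swamp the planted pairs) with at least one random
  program each.
* **Gene sets** — collagen-like and elastin-like both contain exactly the
  hub genes plus disjoint fillers drawn from the down-in-recovery reversal
  genes (collagen/elastin genes are themselves DEGs in the emulated study);
  the three DEM-target categories carry the anchor-block assignments padded
  with background genes; remaining sets are uniform draws.
* **PPI** — hubs are wired to each other and to the ECM/HSC partners at
  scores ≥ 700, over a random background.
* **Determinism** — the seed is mandatory and identical parameters give
  bit-identical outputs, including after serialization.

What the benchmark does **not** emulate: read-level artifacts, batch
effects, library-size confounding beyond scalar size factors, per-feature
dispersion trends, miRNAs with many weak targets, or annotation noise in the
target map. Passing the end-to-end recovery tests therefore shows the
pipeline's logic and thresholds behave as specified under the stated
statistical structure — not that the thresholds are optimal for real data.

## Worked-example fixtures

The published cascade counts of the emulated study (206 → 102 DEMs,
4,118 → 2,845 DEGs, 2,492 overlap genes, 3,769 negative pairs in classes
2,168 = 23 × 1,056 and 1,601 = 53 × 434, four LOX-family hubs, four key
miRNAs) are not reproducible from first principles without the deposited
reads and the external databases. `fibromir.examples` instead encodes the
printed compositions as *inputs* — schematic DE tables, target maps and pair
tables on the passing side of every threshold — and the test suite and
`scripts/acceptance.py` recompute the counts by running the pipeline's own
bookkeeping operations on them. These fixtures are synthetic encodings, not
the study's data.

## Problem sizes and runtime

Defaults were sized so the full test suite runs in well under a minute and
the acceptance script in seconds on one CPU: 200 × 9 and 1,000 × 9 count
matrices for the end-to-end fixture; 2,000-feature single-platform
simulations for null/power calibration; exhaustive hypergeometric grids up
to N = 25. All randomness flows from explicit integer seeds.

## Known limitations

* The Wald test is anti-conservative for very low counts at n = 3; the
  default base-mean range avoids that regime, and real low-count data would
  need exact or quasi-likelihood tests.
* TPM for miRNA counts uses no length term (mature miRNAs are near-constant
  length); FPKM requires a user-supplied length table and falls back to TPM
  when absent.
* The correlation stage assumes a shared sample set between platforms and
  does not model partial correlation, lagged effects, or seed-match
  mechanics.
* Hub/key mining is purely set-theoretic; no centrality beyond degree.
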