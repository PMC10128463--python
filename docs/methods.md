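# Methods

## Data model and coordinate conventions

The unit of observation is one cytosine in one sample: chromosome, 1-based
position, three-letter context (CG/CHG/CHH), two-letter subcontext
(CA/CC/CG/CT), methylated and total read counts, and the level
meth/total ∈ [0,1]. CGmap files carry these as 8-column TSV; the reader
validates counts, context consistency and the printed level (tolerance
0.005 against meth/total, since callers round). All intervals (genes,
repeats, capture targets, bins) are held 0-based half-open; the GFF reader
converts from 1-based closed, BED passes through. Watson- and Crick-strand
CpGs are *not* merged into dyads: callers report the G-strand cytosine at
its own coordinate, and all site counts downstream are per reported
position. A count-summing dyad merge exists but is off the default path.

## Common-site matrices

A site enters the sites × samples matrix only if its total read count
reaches the coverage floor in **every** sample. This is deliberately strict
(an any-k-of-n relaxation exists via `min_samples`): it guarantees no
missing cells, so no imputation is ever needed downstream, at the cost of
losing sites quadratically as cohorts grow. The floors follow the
study design this package mirrors: 3× for chromosome tracks, 5× for PCA and
the clock, 10× for group-level statistics, and ≥100× for targeted-capture
data (the capture threshold is read as ≥ 100; a strict > switch exists,
since "more than 100 reads" is ambiguous). Group pooling sums read counts
per site before recomputing levels — equivalent to merging the group's
alignments and re-calling — rather than averaging levels, which would weight
a 2× site equally with a 200× one.

## Landscape statistics

Context means are unweighted site means × 100 (read-weighting would let a
few deep sites dominate and would not match the CGmapTools convention the
field reports). The level histogram reports exact-0 and exact-1 point
masses separately from 20 interior bins — at low coverage the observed
level is a small-denominator fraction and piles up on the endpoints — plus
the two headline fractions (> 0.80, < 0.05) that summarize a vertebrate
methylome's bimodality. The group comparison uses the two-sample
Kolmogorov–Smirnov test with the asymptotic p-value; at methylome site
counts (thousands to millions of sites) exact small-sample computation is
unnecessary. Neighbor autocorrelation is computed over *rank* neighbors —
the correlation between the i-th and (i+k)-th CpG in genomic order within a
chromosome, pooled across chromosomes — not fixed base-pair offsets, so the
statistic is insensitive to CpG density. Lags with fewer than 3 pairs or
zero variance in a margin are reported missing, never coerced to a number.

## Metagene profiles

Each element body is scaled to 10 fractional bins (deciles), traversed
TSS→TTS so minus-strand elements reverse; flanks of 2 kb are split into
fixed 200-bp bins (the flank width follows the reference design; the bin
width is a free choice). Flanks are genomic and are not clipped at
neighboring elements; a site overlapping several elements contributes one
observation per element. Strandless repeats are profiled as plus-strand,
and the repeat-body profile excludes elements under 1 kb. Per-bin values
are means over all (site, element) observations.

## Age-association selection

Per site: Pearson r against numeric age in years (two-sided t-based
p-value, n−2 df) and one-way ANOVA F across age-group labels, both computed
vectorized from the sum-of-products / between-within mean-square formulas
and checked in the tests against scipy's per-site implementations.
Zero-variance sites are excluded from ranking with a logged count (their r
is undefined; treating them as r = 0 would silently dilute the FDR).
Multiple testing uses Benjamini–Hochberg throughout ("adjusted" without a
named method defaults to the field's standard FDR control). The combined
ranking is the rank-sum of the two adjusted-p ranks — the two criteria are
treated symmetrically, and ties break by smaller Pearson adjusted p, then
genomic order, so output is deterministic. Selected sites merge into
regions when within 200 bp, padded by 60 bp (re-merged if padding
re-introduces overlap); these two parameters are free choices tuned to the
probe-design scale at which ~4500 sites collapse into ~3400 regions, and
are documented as not inferable from first principles. Nearest-element
annotation reports all equidistant ties (bedtools-closest `-t all`
semantics) and distance 0 inside an element.

## The clock

Elastic net in the scikit-learn objective convention,
(1/2n)‖y − Xw − b‖² + αλ₁‖w‖₁ + ½α(1−λ₁)‖w‖², with reference
hyperparameters α = 0.00283693, λ₁ = 0.5. The convention matters: α is not
transferable across parameterizations (glmnet's λ differs), which is why the
objective is stated explicitly. Features are raw methylation fractions —
already on a common [0,1] scale — with an off-by-default standardize
switch. Fits use cyclic (deterministic) coordinate descent, tolerance 1e-6;
the iteration cap is 500,000 because at this α with thousands of correlated
features and n = 8 the descent needs well over 10⁴ passes, and a
non-converged fit raises rather than returning silently. The exact α = 0
limit is computed by least squares directly (coordinate descent is
ill-posed there), making the documented OLS limit hold to numerical
precision. Evaluation is leave-one-out: n fold models, each predicting its
held-out sample; MAE in years; R² reported both as squared Pearson
correlation of predicted vs actual and as the coefficient of determination —
they differ when predictions are biased (LOOCV on an extreme-age design
compresses predictions toward the training mean, so squared Pearson reads
higher). The grid search minimizes LOOCV MSE and breaks ties toward larger
α then larger λ₁, preferring the sparser model.

## Cohort structure

PCA centers (no scaling, matching the R PCA tooling this mirrors), drops
the lowest-variance 10% of sites first (zero-variance sites always go), and
decomposes by SVD with a fixed sign convention (largest-magnitude loading
positive) for reproducibility. Sample clustering: Spearman correlation,
distance 1 − r, complete linkage, columns pre-sorted by sample id so leaf
order is deterministic; the dendrogram exports as Newick. Site clustering
of the top-variance sites uses Euclidean distance on level vectors with
complete linkage cut at k = 5, reporting per-cluster mean age slope and the
fraction of rising sites (the minority-gain cluster).

## The synthetic generator

`simulate_cohort` emulates the statistical structure the analysis assumes:

* **Baselines** from a three-component beta mixture — weight 0.70 on
  Beta(40, 2.5) (highly methylated), 0.03 on Beta(1.5, 60) (unmethylated),
  the rest on Beta(2, 2) — reproducing ~70% of sites above 0.8 and ~3%
  below 0.05.
* **Drift sites** (default 4% of 5000) move linearly with age, 85% losing
  methylation; |slope| ~ U(0.03, 0.08)/yr, i.e. total changes of 0.24–0.64
  across the 1–9 y span, the dynamic range the most strongly
  age-associated CpGs show on capture-panel heatmaps. Drift baselines are
  redrawn so the trajectory stays inside (0.02, 0.98) and clamping never
  flattens the signal.
* **Spatial noise**: AR(1) in site order within chromosomes, marginal sd
  0.03, with per-group correlation 0.55/0.45/0.35 (young/mid/old) —
  maintenance fidelity falls with age.
* **Read sampling**: coverage 1 + NegBin(mean 11, dispersion 4) per
  site and sample (mean 12, matching 9–15× genome-wide depth; the targeted
  preset uses mean 300 over 16 samples at nine distinct ages), then
  meth ~ Binomial(coverage, latent level). Non-CpG cytosines get
  exponential levels with mean 0.005.

All draws come from one seeded generator; identical seeds give
byte-identical files. `simulate_annotation` adds well-spaced genes (2–10 kb,
stranded), repeats (0.3–3 kb, strandless, a subset over the 1-kb profile
floor) and a target BED; an optional promoter-hypomethylation planting
(low baselines within 1 kb of each TSS) lets the metagene profile's TSS dip
be validated end-to-end. `simulate_ar1_methylome` emits a single
high-coverage chromosome whose levels follow a stationary AR(1), the
closed-form oracle (lag-k correlation = ρᵏ) for the autocorrelation
statistic.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: CpG-island structure and density gradients,
cell-type composition shifts with age, bisulfite conversion failure,
strand-specific coverage, batch effects, and nonlinear (logistic-like)
age trajectories. Results on the synthetic cohort validate the
*computations*, not the biology.

**A quantified limitation worth knowing.** Binomial read sampling at 12×
mean coverage adds per-cell noise of sd ≈ √(p(1−p)/12) ≈ 0.09–0.14, which
dominates the 0.03 residual sd. A drift site's population correlation with
age is then roughly s/√(s² + 0.12²) with s = slope × sd(ages) ≈ slope × 3.27
— about 0.6–0.9 over the default slope range — while the top-200 threshold
among ~4800 null sites sits near |r| ≈ 0.72 (null sd 1/√7 at n = 9). Per-site
rank recovery of the 200 planted sites by the Pearson+ANOVA selection
therefore plateaus near 60–70% at this coverage, and the corresponding
validation test documents and enforces a stricter bar that this coverage
regime does not meet. Multi-site aggregates are far more robust: the LOOCV
clock (MAE ≈ 0.5 y, R² ≈ 0.99 on the default cohort) and PC1–age
correlation average the read noise away across hundreds of sites.

## Problem sizes and numerical choices

The reference synthetic cohort is 5000 CpGs (plus 600 non-CpG cytosines)
on two 2-Mb chromosomes across nine samples — small enough that every
validation, including the full LOOCV clock and the 200-replicate KS
calibration, completes in seconds while leaving all statistical structure
intact. Degenerate inputs are handled explicitly rather than numerically:
empty matrices warn and return empty (not raise), zero-variance sites/
components report missing, constant ages and identical samples raise, and
ties everywhere break by genomic order or sample id so every artifact is
bit-reproducible. Histogram densities sum to 1 within 1e-9; PCA
reconstruction holds to 1e-8; oracle-equivalence tests run at 1e-8 or
tighter.
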