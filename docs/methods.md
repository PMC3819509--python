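# Methods

## Model

Each fatty-acid trait is analyzed separately under the linear mixed
model

    y = X b + Z u + e,        e ~ N(0, σ²_e I)

with `X` the fixed-effect design (intercept/"population mean",
contemporary-group indicators with one level dropped, and four centered
covariates: subcutaneous fat thickness, longissimus muscle area, hot
carcass weight, chemically extracted fat), `Z` the animal x SNP dosage
matrix (copies of the B allele), and a spike-and-slab prior on marker
effects: `u_j = 0` with probability π, otherwise `u_j ~ N(0, σ²_uj)`.
Under **BayesC** all included markers share one slab variance σ²_u;
under **BayesB** each locus has its own σ²_uj. Slab and residual
variances carry scaled-inverse-χ² priors with degrees of freedom
ν_u = 4 and ν_e = 10 (common whole-genome-regression defaults; the
analysis protocol does not state them) and scale parameters s²_u, s²_e.
Fixed effects have a flat prior.

Animals with a missing phenotype, contemporary group or covariate are
excluded before analysis and the count is logged.

## Sampler

Single-site Gibbs, JIT-compiled (numba), single-threaded and exactly
reproducible given a seed; markers are updated in map order.

Per iteration:

1. each fixed effect from its normal full conditional;
2. for each marker `j`, the inclusion indicator is sampled with the
   effect integrated out given the current slab variance — with
   `c_j = z'_j z_j` (centered dosages), `rhs = z'_j r₀` and
   `v = c_j σ²_uj + σ²_e`, the log Bayes factor for inclusion is
   `½[log(σ²_e/v) + rhs² σ²_uj/(σ²_e v)]` — then, if included, the
   effect from `N(rhs/(c_j + σ²_e/σ²_uj), σ²_e/(c_j + σ²_e/σ²_uj))`;
3. BayesB locus variances from their scaled-inverse-χ² full conditional
   (`(ν_u s²_u + u_j²)/χ²_{ν_u+1}`) when included, refreshed from the
   prior when excluded; the BayesC common variance from
   `(ν_u s²_u + Σu_j²)/χ²_{ν_u+k}`;
4. the residual variance from `(ν_e s²_e + e'e)/χ²_{ν_e+n}`.

This partially-collapsed Gibbs scheme has the same stationary
distribution as the older Metropolis–Hastings construction that proposes
locus variances from the prior; the MH acceptance ratio with a prior
proposal reduces exactly to the collapsed inclusion probability used
here, so the Gibbs form is preferred for simplicity and mixing.

Dosage columns are centered inside the sampler (the intercept absorbs
the shift; all variance summaries are translation invariant); stored
effects apply unchanged to raw dosages, which is how DGVs are reported.

**Iteration budget.** The reference protocol runs 41,040 iterations,
discards the first "1,000 samples" and keeps every 40th draw of the
40,000 post-burn-in iterations, for 1,000 stored samples. Read as 1,000
*iterations* of burn-in the arithmetic gives 40,040/40 = 1,001 stored
samples; we therefore set the default burn-in to 1,040 iterations so
that exactly 1,000 samples are stored, and enforce
`(n_iter − n_burn) % thin == 0` in the configuration. Tests and the
acceptance script use shorter chains (2,000–20,000 iterations at desk
problem sizes chosen so the Monte-Carlo checks are sharp at n ≤ 1,000
animals and m ≤ 2,000 markers).

**Genetic variance and h².** Per stored sample σ²_g is the
across-animal variance (n−1 denominator) of `Zu` — the genome-wide
application of the window-variance definition below, which keeps window
fractions coherent — not the expected-heterozygosity form `Σ2pq·σ²_u`.
Heritability is the ratio of posterior means,
`mean(σ²_g)/(mean(σ²_g)+mean(σ²_e))`, not the mean of per-sample ratios.

**Prior elicitation.** A preliminary BayesC chain with π = 0.95 and
prior genetic and residual variances each set to half the phenotypic
variance supplies posterior-mean σ²_g, σ²_e. These become BayesB scales
via

    s²_u = σ²_g (ν_u − 2)/ν_u / [(1 − π) Σ_j 2 p_j (1 − p_j)]
    s²_e = σ²_e (ν_e − 2)/ν_e

— the standard spread of genetic variance over the expected nonzero
dosage variance; the exact construction used by the original GenSel
software is unpublished, so this convention is labeled as such. A floor
of 1e-8 guards degenerate (zero-variance) posteriors, with a warning.
The elicitation run also provides the h² estimate used in accuracy
denominators.

## Window association

Windows are `floor(position_bp / 1e6)` per chromosome, labeled
`chrom_MbIndex` (the published candidate-gene coordinates force this
0-based floor labeling: FASN at 51,384,922 bp on BTA19 is window 19_51,
SCD at 21,132,751 bp on BTA26 is 26_21). Unmapped SNPs form one extra
window; X is treated like any autosome. Per stored sample the window
fraction is `var_animals(wDGV)/var_animals(DGV)`; fractions are averaged
over samples (per-sample ratios, matching PPI's per-sample definition;
whether the source averaged ratios or variances first is not stated).
Samples with zero total genetic variance are skipped and counted. The
total-variance denominator includes all markers, unmapped window
included. PPI is the fraction of stored samples with ≥1 nonzero member
effect; the significance rule is strict (PPI > 0.90, so 0.90 exactly is
excluded).

## Validation

The VanRaden method-1 GRM is `G = MM'/(2Σp(1−p))` with `M` the dosage
matrix centered at twice the observed allele frequency; monomorphic SNPs
are excluded from numerator and denominator. Animals are clustered on
the squared genomic distance `d_ij = g_ii + g_jj − 2g_ij` (the distance
induced by G as an inner product; the source's "difference matrix" is
not defined there), either as rows of that matrix (default) or via
classical MDS of it. K-means uses k-means++ initialization with 25
restarts, keeping the best within-cluster sum of squares; the installed
scientific stack implements Lloyd's algorithm rather than
Hartigan–Wong — both minimize the same objective and the fold-partition
properties are unaffected. K = 6 clusters are merged (two smallest) into
5 folds.

Cross-validation trains the BayesB sampler on four folds and predicts
DGVs for the fifth. Held-out phenotypes are adjusted by the
*training-estimated* fixed effects before the regression (b) and
correlation (r) with DGV — raw phenotypes would let contemporary-group
structure masquerade as genomic signal. b and r are pooled across folds
by size-weighted mean (Fisher-z pooling would be monotone-equivalent at
these magnitudes); the prior and the h² in
`accuracy = pooled r / √h²` come from a single full-data elicitation,
for comparability across folds. Under a null trait the accuracy ratio
divides a near-zero correlation by a small √h², so single-replicate
values are noisy even when unbiased; K-means folds also make within-fold
DGVs correlated, inflating the correlation's sampling variance relative
to the independent-observation formula.

## Within-window trait-pair correlations

Traits are fitted in independent chains (as in the source analysis); a
pseudo-joint posterior pairs stored samples by index, ignoring
cross-chain dependence (flagged assumption). For window w the
correlation is `mean_s cov_animals(wDGV_A, wDGV_B) /
sqrt(mean_s var_A · mean_s var_B)`, clamped to [−1, 1] against rounding.
An alternative (correlating posterior-mean window DGVs across animals)
can be assembled from `window_dgv_samples` directly.

## Trait derivation

Ratio and index traits (PUFA/SFA, (14:0+16:0)/All, n3/n6, AI) are
reported x100 on the fat-percent basis — the only scale consistent with
the published summary table (which prints PUFA/SFA 12.6 where the ratio
of printed means is 0.126) — and NA on the beef basis. The AI numerator
is `4·C14:0 + C16:0` (the published equation; the cited
Ulbricht–Southgate form also includes 12:0, but the printed means
corroborate the two-term numerator) over ΣMUFA + ΣPUFA.

Composite memberships are explicit data, not name parsing. Defaults
follow the published summary table where its prose contradicts it:
MCFA = all acids with 10–15 carbons and LCFA = ≥16 carbons (the prose's
MCFA = 12:0+13:0 is available via `mcfa="text"`); n3 = the full omega-3
series 18:3n3 + 20:3n3 + 20:5 + 22:5 + 22:6 (prose two-term version via
`n3="text"`). The published n6 mean is not exactly reproduced by any
obvious subset; the default includes both CLA isomers with the six n6
acids (sum 5.132 vs printed 5.134), with `no_cla` and `text` options —
none asserted in tests. "All" in (14:0+16:0)/All is the sum of the 38
named acids. Trans isomers count as unsaturated by bond count. Summary
statistics use the sample SD (n−1) and CV x100 = 100·SD/mean (NA at
zero mean).

## Synthetic data

The generator reproduces the *statistical* design, not bovine genome
biology: allele frequencies Uniform(0.05, 0.5), Hardy–Weinberg
Binomial(2, p) dosages, optional first-order haplotype-copying LD
(adjacent-SNP correlation ρ) instead of coalescent simulation —
sufficient to exercise window logic at desk scale; evenly spaced
positions giving a fixed SNP count per 1-Mb window (default 20/Mb, the
50K-panel density); QTL effects drawn normal within designated windows
and rescaled so each window contributes its specified fraction of a unit
genetic variance; residuals rescaled so realized in-sample h² equals the
target exactly. Contemporary-group effects are N(0, 0.5²) over 10 groups
and the four covariates are standard normal with coefficients 0.1 (the
source gives no magnitudes; these make fixed effects visible but not
dominant at unit genetic variance). Multi-trait pleiotropy draws per-QTL
effects from a multivariate normal with a user correlation matrix.
Fatty-acid profiles are independent log-normals per acid at the
published beef-basis magnitudes, closed to 100 for the fat-percent
basis; closure induces the mild negative correlation of real
compositions, but independence before closure means simulated
fat-percent SDs exceed the published ones — passing tests show the
pipeline's bookkeeping and recovery behaviour, not that the generator
matches real covariance structure, real LD decay, or the study's
134-sire family structure (not simulated). All randomness flows from one
seed through named `SeedSequence` substreams (genotypes, effects,
per-trait residuals, profiles).

## Numerical choices and edge cases

- Inclusion logits beyond ±35 short-circuit to avoid overflow; π = 0 and
  π = 1 bypass the Bernoulli draw entirely.
- Monomorphic (zero-variance) marker columns carry no likelihood
  information; their indicator is drawn from the prior and their effect
  contributes nothing.
- Missing dosages are mean-imputed per SNP (2p̂), preserving allele
  frequency; the source does not state its handling. No call-rate or
  MAF filters are applied by default, matching the unstated protocol.
- Window variances use the n−1 variance across animals; window DGVs are
  centered per sample (variance is translation invariant; stated for
  clarity).
- An all-zero stored sample makes window fractions undefined for that
  sample — skipped with a reported count; an all-zero chain reports NA
  fractions and PPI 0.
- K-means requires ≥K distinct embedded animals, else it reports failure
  rather than returning degenerate folds.
- Chain files are compressed npz with seed/thin metadata; all tabular
  I/O is TSV, round-trippable to written precision.

## Known limitations

- Single-trait chains only; the pleiotropy probe pairs independent
  chains by sample index rather than fitting a multi-trait model.
- The LD model is first-order Markov copying, not population-genetic; LD
  decay, allele-frequency spectra and family structure of real panels
  are not emulated.
- No convergence diagnostics beyond deterministic seeding and the
  oracle tests; chains of the default length are sized for the desk
  scale the generator targets.
- The X chromosome receives no dosage compensation (treated as an
  autosome, as in the source analysis).
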