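# Methods

This note records the models implemented in `dropdms`, the defaults and the
reasoning behind them, and what the synthetic screen does and does not
capture.

## Screen simulation

**Library.** `simulate_epcr_library` draws, per variant, a
Poisson(`mean_nt_mutations`) number of single-base substitutions at
distinct uniform positions, with the alternative base uniform over the
three non-reference bases. The default rate of 4.5 substitutions per gene
matches a manganese-doped error-prone PCR protocol and yields mostly 2–4
amino-acid substitutions per variant on a gene of a few hundred codons.
The mutation spectrum is deliberately uniform — Taq's transition bias is
omitted because only the mean rate is well constrained; the spectrum does
not affect any downstream contract. Indels are not simulated: the analysis
targets substitution maps, and the calling stage is gapless.

**Latent activity.** Each variant is active with probability
σ(β₀ + Σⱼ βⱼ), the sum running over its substitutions; a premature stop
codon forces the probability to zero. The intercept β₀ is solved by
Brent's method so the library-mean activity probability equals the target
active fraction π (default 0.25, the plate-assay functional fraction of
typical error-prone libraries of an active enzyme). The activity label is
then a single Bernoulli draw per variant — activity is a property of the
sequence, so every cell carrying the variant behaves identically. This has
a practical consequence discussed under *Recovery limits* below.

**Droplets.** Cell counts per droplet are Poisson(λ). "10% occupancy" is
interpreted as P(at least one cell) = 0.10, i.e. λ = −ln 0.9 ≈ 0.105; this
is how droplet occupancy is usually reported and it reproduces the
80–100 cells/s arithmetic at 800–1000 Hz droplet rates. Droplet
fluorescence is Σ(rate × incubation × lognormal expression noise) over
resident cells plus Gaussian autofluorescence. Droplets above the gate
contribute **all** resident cells to the sorted pool, so a passenger
inactive cell co-encapsulated with an active one is carried over — one of
the two false-positive mechanisms.

**Sorter operating point.** Defaults (arbitrary fluorescence units, AFU):
active rate 100 AFU/min, inactive rate 10 AFU/min, incubation 3 min,
expression CV 0.3, autofluorescence SD 30 AFU, gate 70 AFU. These were set
analytically, once, so that a 25%-active library sorts to roughly 70%
active: an inactive-only droplet signals ≈ N(30, 31) AFU and passes the
70-AFU gate with probability ≈ 0.10, giving an expected sorted purity of
0.25 / (0.25 + 0.75·0.10) ≈ 0.77 before co-encapsulation carryover
(≈ λ/2 ≈ 5% of occupied droplets hold a second cell) pulls it down a few
points. This lands inside the 60–90% post-sort functional band that
droplet screens of this design report, with autofluorescence and
carryover — not an ad-hoc error knob — supplying the impurity.

**Reads.** Full-length gene copies sampled with replacement from a pool,
with i.i.d. per-base substitution errors and a constant Phred quality of
round(−10 log₁₀ e). Fragmentation is not simulated; it would add no tested
behavior given gapless calling.

## Mutation calling

Reads are filtered on **mean** Phred quality ≥ 30 (the mildest reading of
a "quality < 30" discard rule; the threshold is configurable). Calling is
codon-wise against the reference ORF: synonymous codon changes yield
nothing, stop gains are reported with alt `*`, and positions are shifted
by `numbering_offset` into canonical residue numbering (so a
pro-domain-deleted construct still reports, e.g., the maturation aspartate
as D175). Substitutions observed fewer than 10 times — counting the pooled
input+sorted total within a replicate, the least destructive choice since
the per-pool alternative was not specified — are dropped before fitting.
Stop-gain reads are retained: they are informative negatives.

## Positive-unlabeled fitness model

The screen labels pools, not variants: sorted reads are (mostly) from
active variants; input reads are an unlabeled mixture with known active
fraction π. Under case-control sampling the conditional probability that a
read with indicator vector x sits in the sorted pool is
q(x) = n_P σ(x) / (n_P σ(x) + n_U π) with σ(x) = logistic(β₀ + xᵀβ), and
the fit minimizes the negative log-likelihood of pool membership with an
exact analytic gradient. This is the standard case-control PU likelihood
with known prevalence; π is supplied (default 0.25), never estimated.

Numerics: L-BFGS-B from β = 0; slopes carry an L2 penalty of 10⁻⁴ (the
intercept is unpenalized) for stability on rare substitutions; relative
objective tolerance 10⁻⁸; at most 500 iterations; the converged flag
mirrors the optimizer's decrease test. Separable substitutions — present
in only one pool — would diverge, so slopes are box-bounded at ±10 and
bound-hitting coefficients are flagged and warned about. Membership
probabilities are clamped at 10⁻¹² from 0/1 with a logged warning.
Standard errors come from the analytic Hessian of the penalized objective
(computed when the feature count is ≤ 2000). Observations are reads, not
deduplicated variants: without barcodes, read counts are the only
abundance signal.

**Replicates.** Coefficient tables are compared by Pearson correlation on
shared substitutions. With three or more replicates, outliers are excluded
greedily: while the worst replicate's mean correlation with the remaining
ones is below the threshold (default 0.5), it is dropped and the means
recomputed. The recomputation matters — a single noise replicate drags
every good replicate's plain mean correlation down with it, and a flat
rule would then discard the good ones too. With two replicates nothing is
excluded, since fault cannot be assigned. Survivors are combined by
count-weighted mean.

**Recovery limits.** Two effects bound desk-scale truth recovery in the
full simulated pipeline and would equally bound a real screen. First,
activity is realized once per variant, so the effective sample size per
substitution is the number of distinct variants carrying it, not the read
depth; reads of the same variant are correlated through its label.
Second, sorter impurity (≈30% inactive reads in the sorted pool at
defaults) attenuates slopes toward zero. The estimator itself, checked on
read-level observations drawn directly from the PU sampling model
(5000 variants, 100 substitutions, 10⁵ reads per pool), recovers the true
coefficients at Spearman ρ ≥ 0.9.

## Profiles

Site tolerance is the mean |β| over all retained substitutions at a
position; sites with no retained substitutions are omitted rather than
zero-filled, because "no data" and "perfectly intolerant" must not be
conflated. Percentile ranks are rank/n × 100 with average ranks at ties
(a constant profile therefore ranks at 100·(n+1)/(2n), e.g. 62.5 for
n = 4). Paralog positions are mapped by global pairwise alignment
(BLOSUM62, gap open −11, extend −1, fixed in config for reproducibility).
Divergence is the site-wise difference of mean |β| on aligned positions,
smoothed with a centered moving average (default window 9, truncated at
the edges); the window is a declared default, chosen to span roughly a
secondary-structure element. MSA-based tolerance uses normalized Shannon
column entropy (gaps excluded, columns > 50% gap omitted) — a declared
choice of conservation metric. Per-site divergence significance uses a
permutation test that shuffles substitution-level |β| between the two
enzymes within a site, with Benjamini–Hochberg correction; this too is a
declared procedure, selected because it makes no distributional
assumption at the typical 5–15 substitutions per site.

## Kinetics

The Hill equation v = V·Sⁿ/(Kⁿ+Sⁿ) is fitted by bounded nonlinear least
squares from multiple starts — K initialized at quantiles of the positive
substrate concentrations, n at 1 and 2 — keeping the best optimum, because
the (K, n) surface is multimodal when n is weakly identified. n can be
fixed (n = 1 recovers Michaelis–Menten exactly). Active-site titration
fits a line to the declining regime of residual activity versus
irreversible-inhibitor concentration and reports the x-intercept as the
active enzyme concentration; non-monotone titrations (beyond 5% of the
dynamic range) are rejected. k_cat = V/[E] and efficiency k_cat/K are
derived only when an enzyme concentration is supplied, and are meaningful
only if velocities are in concentration/time units — unit conversion is
the caller's responsibility.

## Proportion statistics

Binomial proportion intervals default to the Wilson score interval, which
keeps near-nominal coverage at the small clone counts (n ≈ 20–50) of
plate-based validation; Wald and Clopper–Pearson are selectable through
the statsmodels backend. A clone is "functional" iff its activity strictly
exceeds half the wild-type activity.

## Problem sizes

The test suite and the acceptance script run the simulation at desk scale,
chosen so each statistical check has adequate power: 10⁴–2×10⁴ variants
for library-rate checks, 10⁵ droplets per sort (occupancy and purity
bands are 3-SE tests at this size), 10⁵ reads per pool for estimator
recovery, 10⁴ simulations for CI coverage, and 50 seeds for kinetic noise
medians. The pipeline's demo configs are smaller still (hundreds of
variants) and exercise plumbing, not statistical claims.

## Known limitations

No indels, chimeras, or fragment reads; uniform mutation spectrum; no
epistasis terms in the fitness model (single-substitution effects only);
π is taken as known, and misspecifying it shifts β₀ and attenuates
slopes; gapless calling cannot use partial reads; the co-encapsulation
false-positive mechanism is one plausible model of sorter impurity, not a
measured one.
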