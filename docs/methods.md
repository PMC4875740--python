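# Methods

## The model under test

The dental inhibitory cascade (DIC) proposes that the relative sizes of
the three lower molars are set by a single developmental parameter, the
balance of activators and inhibitors *a/i* acting cumulatively along the
tooth row.  With M1 normalised to one,

    M1 = 1,   M2 = a/i,   M3 = 2(a/i) − 1,

so every attainable phenotype lies on the line *M3/M1 = 2(M2/M1) − 1* in
molar-proportion morphospace, M2 is always one third of the summed molar
area, and the third molar is predicted absent once *M2/M1* falls below
one half.  `dic_core` implements exactly these identities; a ratio below
0.5 raises rather than silently clamping, because a negative predicted
M3 is the agenesis regime and callers must treat it as such.  Regions of
morphospace are labelled by the ordering of the three areas with a tie
tolerance of 1e-9 on the ratio comparisons; exactly equal molars satisfy
the line equation and are counted as cascade-consistent.  Membership of
the line itself is controlled by a perpendicular-distance tolerance
`line_tol` whose default is 0 (only the two monotonic regions and exact
ties count); no published tolerance exists for "on the line", so the
parameter is exposed rather than guessed.

## Morphometric preparation

Crown area is mesio-distal length times the mean of trigonid and talonid
bucco-lingual breadths.  Because that rectangle overestimates occlusal
area, a shape coefficient *x* = (oa − ea)/(ra − ea) is calibrated on
specimens with traced outline areas (oa), where ea = πra/4 is the
inscribed ellipse, and applied as ca = ra·x + ea·(1 − x); the
construction reconstructs oa exactly on the calibration set.
Coefficients are averaged per molar position across calibration species
(a per-species option exists); values outside [0, 1] are legal and left
unclamped.  Exclusion rules run in a fixed order — wear, indeterminate
sex, zoo provenance, incomplete dentitions, then species with fewer than
four specimens or a single sex — and a per-rule count is logged; order
affects only the attribution of counts, not the retained set.  Species
means are sex-pooled two-stage means (mean within sex, then the
unweighted mean of the two sex means) so unbalanced sex sampling does
not bias the species value.  The coefficient of variation uses the
small-sample correction (1 + 1/(4n))·s/x̄ with the n−1 standard
deviation.  Species centroids are ratios of mean areas (a
mean-of-specimen-ratios alternative is a one-line change in the ratio
frame construction); the within-species term of the proportion
regression is the specimen ratio minus that ratio-of-means, since a
ratio of deviations is undefined whenever a specimen sits at its species
mean M1.

## Phylogenetic covariance and signal

The phylogenetic random effect assumes Brownian covariance: Σ[i,j] is
the shared root-to-MRCA path length of species i and j divided by tree
height, giving unit diagonal.  Unit-height scaling (rather than, say,
unit mean diagonal) makes the phylogenetic variance σ²ₚ directly
comparable with the species-level σ²ₛ and residual σ²ₑ components, so
phylogenetic signal is

    λ = σ²ₚ / (σ²ₚ + σ²ₛ + σ²ₑ),

with σ²ₑ estimated for Gaussian responses and fixed at π²/3 for
Bernoulli ones.  λ is computed per posterior draw and summarised by its
posterior mean and HDI (not as a ratio of posterior means).  Clade
subsets re-prune the tree to the subset MRCA and rescale Σ to the
subtree height.  Trees must be ultrametric to a relative tolerance of
1e-6; a single fixed tree is used throughout, so phylogenetic
uncertainty is not propagated.

## The mixed-model engine

`PGLMM` fits y = Xβ + Zp p + Zs s + e with identity link (Gaussian) or
a latent-logistic link (Bernoulli, residual variance fixed at π²/3,
success probability logistic(l) with the residual included in l).
Priors: Gaussian fixed effects N(0, 1e8); Bernoulli fixed effects
Cauchy(0, γ) with γ = π²/3 + v, where v — the total random-plus-residual
variance — is evaluated at the current draw's variance components each
iteration (a config option fixes it instead); random-effect variances
use a parameter-expanded prior with scale 1, one degree of freedom, and
a working parameter of mean 0 and variance 1e3, i.e. u = αξ with
ξ ~ N(0, σ²_ξ K), σ²_ξ ~ IG(1/2, 1/2), α ~ N(0, 1e3), which induces a
heavy-tailed half-t-like prior on the effect standard deviation.  The
residual variance takes an IG(0.001, 0.001) prior.

Sampling is blocked Gibbs: all location effects (β and every ξ) are
drawn jointly from their Gaussian full conditional via one Cholesky
factorisation per iteration; α and the variance components have scalar
normal and inverse-gamma conditionals; Bernoulli latent values take an
elementwise random-walk Metropolis step (proposal sd 2.2).  Because the
joint location update removes the β–u random-walk coupling and the
expansion parameter decouples variances from effects, the chain mixes
well enough that the desk-scale schedule (110,000 iterations, 10,000
burn-in, thinning 10) retains 10,000 draws with lag-1 autocorrelation
typically below 0.1 — the same retained-draw count as the study-scale
schedules (1.1e7/1e6/1000 Gaussian, 1.5e7/3e6/1200 Bernoulli), which
remain available by configuration.  Seeds are mandatory; identical
seeds give identical draws.

Two caveats documented deliberately.  First, the marginal event
probability of the Bernoulli family is E[logistic(β₀ + e)], not
logistic(β₀); consumers wanting probabilities on the data scale should
apply the logistic-normal scaling (divide the linear predictor by
√(1 + 0.346·σ²ₑ)).  Second, the Heidelberger–Welch stationarity test
estimates its long-run variance from an AIC-selected autoregressive fit
to the second half of the chain; smooth high-amplitude mean drifts
inflate that estimate and can mask non-stationarity (a known property of
this diagnostic family, shared by the standard R implementation, which
the lag-autocorrelation check partially compensates).  Our
Cramér–von Mises p-value clamps the four-term series CDF to 1 beyond
statistic 2 (where the true CDF is 0.999987), avoiding a truncation
artefact that otherwise reports moderate p-values for enormous
statistics.

ROPE decisions report the posterior mass inside a closed interval
together with the 95 % HDI (shortest interval over sorted draws; a
unimodal-posterior construction).  Default ROPEs follow the cascade
point predictions: slope [1.90, 2.10], intercept [−1.10, −0.90], M2
share [0.323, 0.343], proportion mediated [0.9, 1].

## Mediation

The proportion of the M1→M3 association mediated by M2 is computed from
two fits sharing a retained-draw count: per draw t,
ab⁽ᵗ⁾ = β₂B⁽ᵗ⁾·β′₁B⁽ᵗ⁾, |c′|⁽ᵗ⁾ = |β₁B⁽ᵗ⁾| and
pr_m⁽ᵗ⁾ = ab/(ab + |c′|); point estimates are the means of ab and |c′|
with pr̂_m their ratio.  Note the estimand's mechanical floor: |c′| is a
folded mean, bounded below by ~0.8× the posterior sd of the direct
slope, so pr_m can only approach 1 when the direct slope is precisely
estimated.  That requires the mediator to carry variance of its own:
with M1 and M2 species means correlated at r, sd(β₁B) scales like
1/√(n(1−r²)).

## Synthetic data

The generator produces the structure the analyses assume, with every
recoverable parameter known.  Defaults mirror the study shape: 100
species on a pure-birth tree of unit height, ~29 specimens per species,
log(a/i) Brownian with root-to-tip sd 0.25 around log 1 (λ_true blends Σ
with the identity and defaults to 1), M1 size lognormal around 30 mm²,
specimen-level multiplicative lognormal noise at 5 % CV, 5 % sexual
dimorphism in area, wear/indeterminate-sex/zoo labels injected at rates
of 4 %, 1 % and 0.2 % to exercise the filters, agenesis by the model
threshold, and frugivory odds multiplied by 9.5 when M2 is the largest
molar.  Areas are decomposed into length and unequal trigonid/talonid
breadths with a per-species aspect ratio so the morphometric pipeline
round-trips exactly.  A controlled violation multiplies M2 within one
clade (the internal node closest to a target fraction of species).

The strict-mediation generator draws species M1 with sd 2.5 and sets
M2 = 1.1·M1 + N(0, 1) and M3 = 1.2·M2 + N(0, 0.3) with zero direct
path.  The mediator noise is deliberately comparable to the M1 spread
(r ≈ 0.93): as explained above, a nearly collinear design caps
attainable pr_m below 1 for purely mechanical reasons even when the
truth is 1.  The human-sample generator mirrors a 66-individual,
6-population layout with group means 0.92 (agenesis) and 0.95
(retained), population sd 0.01 and individual sd 0.03.

What the generator does not emulate: measurement error in the linear
variables separate from biological CV, taxon-specific sampling
imbalance, missing-at-random patterns other than agenesis, allometric
scaling of molar shape, or diet categories beyond a frugivore/other
contrast.  Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the stated generative model, not
robustness to real-data pathologies.

## Problem sizes and numerics

Recovery checks run at 100 species × 10 specimens with the desk-scale
schedule (five replicates for the line-recovery summary, one for
mediation); unit tests use 25–40 species with ~1,000-iteration chains.
Degenerate inputs are errors, not warnings: non-ultrametric trees,
duplicated taxa, unmatched species names, single-sex species,
zero-variance CVs, ROPEs with lo ≥ hi, schedules whose retained count is
not integral.  The phylogenetic covariance receives a 1e-10 jitter
before inversion; morphospace ties use the 1e-9 tolerance above.
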