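# Methods

## The expression variance and evolution (EVE) model

Gene expression is modelled as a quantitative trait evolving on a rooted
species tree under a stationary Ornstein–Uhlenbeck (OU) process with
optimum θ, drift variance σ² and selection strength α (both per unit
branch length). The stationary (evolutionary) variance is
v = σ²/(2α). Individual measurements within a species scatter around the
species mean with variance β·v, so β is the ratio of within-species
("population") expression variance to evolutionary variance.

The vector of expression values over all individuals is multivariate
normal with mean θ and covariance

- v·(1+β) on the diagonal,
- v between two individuals of the same species,
- v·exp(−α·d) between individuals of species at patristic distance d.

Stationarity at the root means every tip has the same marginal variance
v, so non-ultrametric trees are handled by the same covariance with no
extra assumptions. The same-species covariance is exactly v (species
mean shared, individual noise independent).

### Divergence/diversity test

The null hypothesis for a gene is that its β equals a β shared by all
tested genes; the alternative frees β for that gene. The shared β is the
joint maximum-likelihood estimate over all screened genes (the tested
gene included), with gene-specific (θ, σ², α). Each arm of the
likelihood-ratio test re-optimises (θ, σ², α); the statistic
LRT = 2·(ℓ_free − ℓ_shared) is referred to a χ² distribution with one
degree of freedom. Genes with p below the cutoff (default 0.05) are
called *divergence* when their gene-specific β falls below the shared
estimate (between-lineage variance dominates: a lineage-specific
expression shift) and *diversity* when above (inflated within-species
variability). Raw p-values drive the calls; Benjamini–Hochberg q-values
are reported alongside but not used for calling.

### Likelihood computation and optimisation

θ and v are profiled analytically: writing the covariance as
v·C(α, β) with C = R(α) + β·I and R(α) the between-individual OU
correlation matrix, the profiled estimates are the GLS mean
θ̂ = (1ᵀC⁻¹y)/(1ᵀC⁻¹1) and v̂ = (y−θ̂1)ᵀC⁻¹(y−θ̂1)/n. Numerical
optimisation therefore runs only over log α and (in the free arm)
log β, with box constraints log α ∈ [−8, 8], log β ∈ [−8, 8]. This
two-dimensional profiled parameterisation is exactly equivalent to the
full four-parameter maximisation (verified against direct Nelder–Mead
maximisation and dense 2-D grids to 1e-8) and makes the fit exactly
equivariant under adding a constant to a gene's values.

Single-gene likelihood evaluations use a Cholesky factorisation of C.
Batch paths (the shared-β outer search, per-gene starting values)
exploit the fact that C = R(α) + βI shares eigenvectors with R(α): per
grid-α eigendecompositions of R are precomputed once and every β
evaluation is a vectorised operation over all genes. The shared-β fit
is an outer bounded scalar search over log β (tolerance 1e-6) with an
inner per-gene profile over an α grid (97 points, parabolic
refinement). The final per-gene arms are refined with exact bounded
scalar (null arm) and L-BFGS-B (free arm) optimisation; the free arm
starts at the null-arm optimum, which enforces LRT ≥ 0 by construction.
A negative LRT beyond −1e-6 raises (optimiser-bug sentinel).

Genes with total variance below 1e-10, or with fewer than two finite
values in any species, are excluded from testing and flagged
(`degenerate`): the within-species variance component is unidentifiable
for them.

### Finite-sample behaviour at three species

With three species and three replicates there are nine observations per
gene against five free parameters in the alternative arm. Two
consequences, both measured on synthetic data by the acceptance
machinery and worth stating plainly:

1. **The χ²(1) reference is conservative.** The per-gene information
   about β is small and the α profile is nearly flat once α exceeds the
   scale of the shortest branch, so the LRT's null distribution sits
   stochastically below χ²(1): the measured false-positive rate at
   p < 0.05 is ≈ 0.02–0.03 rather than 0.05, and a Kolmogorov–Smirnov
   test against χ²(1) rejects. The χ²(1) reference is retained because
   it is the method's stated convention (and no boundary/Bartlett
   correction is applied); calls are therefore conservative, not
   anti-conservative. Calibration improves with more species.
2. **β̂ is biased upward.** With three species the between-species
   variance is estimated from three species means with α free, so the
   ML v̂ is systematically small and β̂ = (within)/(v̂) is inflated —
   by roughly two- to three-fold in our simulations, for both the
   shared and the gene-specific estimates. The *ratio* of β̂ to the
   shared β̂, which is what the test uses, is much better behaved:
   planted lineage shifts of 10 stationary SDs are called divergent in
   ≳ 97% of cases, and planted diversity genes separate cleanly.

## EVE-R

EVE-R targets genes with a divergent ambient baseline that also respond
to the stimulus. Step 1 runs the divergence test on control samples
only and retains genes called divergent with p < p_div. Step 2 applies
per species a two-sided Welch t-test of control vs treatment (unequal
variances, Satterthwaite degrees of freedom; chosen over the pooled
test for robustness at n = 3); a gene is thermally induced if p <
p_change in at least one species (configurable to "all"). Final
candidates are the intersection, so EVE-R candidates are always a
subset of the ambient divergence candidates.

## EVEReSt

EVEReSt tests the *response* rather than the baseline: per species,
paired treatment-minus-control differences (one per complete replicate
pair, pairing by replicate label reflecting the paired colony-fragment
design; sorted-order pairing is available for unlabelled data and is
recorded loudly in provenance) become the individuals of the divergence
test. Baseline differences cancel exactly in the differences, so the
variant is invariant to gene-wise baseline shifts; the OU likelihood is
symmetric under global negation, so the subtraction direction only
flips θ̂ and both conventions are supported (default
treatment−control), with the choice recorded in output provenance.
Under the response null the paired differences carry no phylogenetic
variance at all, so the shared β̂ runs to its upper bound and the test
reduces to asking whether a gene's between-species response variance
exceeds its paired noise — with the same conservative χ²(1) caveat as
above, amplified by the halved effective information of differencing
(response noise variance is 2βv). Detection of a one-species response
of 3 stationary SDs at 3 pairs/species is therefore partial (≈ 25% in
our simulations; an oracle one-way ANOVA at the same effect and sample
size would reach only ≈ 60%); responses of 6+ stationary SDs are
detected in most cases.

## Quantitative Metabolic Fingerprint (QMF)

Transcripts first pass an expression filter: TPM ≥ 10 in ≥ 2 samples,
control and treatment samples counted together. For each holobiont
member (host, symbiont, bacteria), pathway and condition, a
transcript's condition value is its mean TPM over that condition's
replicates, and the fingerprint entry is a statistic of those values
over the member's transcripts annotated to the pathway, divided by a
denominator. Defaults: statistic = sum, denominator =
`member_kegg_total` (the member's total over all its pathway
assignments in that condition), under which fingerprint rows sum to
exactly 1 per (member, condition). A transcript annotated to k
pathways counts in each of the k numerators and k times in the
denominator — no fractional splitting. The alternative
`median`/`library_total` modes implement the other published wording of
the statistic and are recorded in output provenance. Fold changes
compare heat to ambient per (member, pathway); a pathway silent at
ambient but expressed under heat yields an explicit infinite flag, not
a number.

Capability shares count distinct kept transcripts per (member,
pathway) as proportions of all kept pathway-annotated transcripts; a
multi-pathway transcript counts in each pathway but once in its
member's marginal share.

## Metabolic redundancy

Each EC number's carrier set is the set of members with at least one
annotated transcript carrying it (optionally restricted to expressed
transcripts via the same TPM filter). Carrier-set size alone determines
the category: 3 → multipartite, 2 → bipartite (the member pair is
recorded), 1 → unique; ECs with an empty carrier set under a restricted
rule go to an "unexpressed" bucket rather than a category. Per-category
expression sums the per-condition mean TPM of transcripts whose ECs
fall in the category; a transcript whose ECs span categories
contributes to each and is flagged.

## Photophysiology

De675 = log10(1/R675) (decadic absorbance estimated from reflectance at
the 675 nm chlorophyll-a peak; the decadic reading is forced by the
ln(10) factor in the companion formula) and
a*_sym = (De675/density)·ln(10), in m² per symbiont cell, with density
in cells·m⁻². The composition identity a*_sym = ln(1/R675)/density
holds to machine precision and is tested. a*_sym is strictly
increasing in De675 and strictly decreasing in density, which is the
mechanism linking bleaching-driven cell loss to rising per-cell light
dose.

## Synthetic data generator

The generator emulates the study design the analyses assume: three
species on the tree ((A:1,B:1):1,C:2) (sister pair at patristic
distance 2, outgroup at 4), two conditions × three replicates per
species, with the same replicate label across conditions denoting a
paired colony fragment. Expression is simulated directly on the
continuous analysis scale (the OU model's scale), not as read counts.
Per gene, (θ, σ², α) are drawn uniformly from θ ∈ [3, 8],
σ² ∈ [0.5, 2], α ∈ [0.25, 1] — giving cross-species correlations
between the sister species of roughly 0.14–0.6, i.e. a phylogenetic
signal that is present but far from saturated — and β is the single
shared value 1.0 (within-species variance equal to evolutionary
variance). Gene classes:

- **null** — the shared-β model unmodified;
- **divergence** — a lineage optimum shift (default 3 stationary SDs)
  added post hoc to all individuals of one randomly chosen species,
  both conditions; this leaves the marginal covariance identical to the
  null while making the ground truth explicit;
- **diversity** — β multiplied by a factor (default 8);
- **responsive** — a treatment-only shift (default 3 stationary SDs)
  added to one randomly chosen species' treatment samples.

Species means are drawn from the OU stationary distribution (no fixed
root state), matching the covariance used for inference. All
generators are pure functions of (config, seed).

What the generator does **not** emulate: count noise and
library-size/normalisation artefacts, colony-level random effects
(pairing therefore carries no extra precision), expression-dependent
variance, annotation errors, and correlated genes. Passing tests
demonstrate correctness of the inference machinery under the model's
own assumptions, not robustness to real-data violations of them.

The annotation generator assigns each transcript one member, one KO and
1–2 pathways; ECs are planted per an explicit overlap design (EC →
carrier member set) so the true redundancy partition is known. TPM
columns are normalised to one million per sample. The physiology
generator draws per-fragment records around per-species control means
with additive treatment shifts (multiplicative for density) and clips
to the physical domains with a warning.

## Problem sizes and numerical choices

Calibration and power summaries use 2,000-gene simulations (the scale
at which binomial error on a 5% rate is ≈ ±0.5%), 200 planted genes
for power estimates and 200 genes for recovery; the orchestration and
determinism checks use 30-gene runs. Optimisation tolerances: 1e-6 on
log β (outer), 1e-7 on log α (inner scalar), L-BFGS-B ftol 1e-12; LRT
clamped to 0 above −1e-6. Missing values are serialised as "NA"; all
tables are tab-separated UTF-8 with '.' decimals; every writer's output
is accepted by its reader, and provenance headers (version, seed,
config hash — no timestamps) make identical runs byte-identical.

## Known limitations

- χ²(1) calibration of the divergence LRT is conservative at few
  species (see above); p-values near the cutoff should be read
  accordingly, and absolute β̂ values at three species are inflated —
  interpret β̂ relative to the shared estimate, not on its own scale.
- The shared β is estimated including the tested gene (the cited
  model's practice); leave-one-out estimation is not implemented.
- No branch-specific optimum-shift test: divergence is detected through
  the variance-ratio contrast only.
- The two-stage variants (EVE-R, EVEReSt) do not model control and
  treatment jointly in one likelihood; that is by construction.
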