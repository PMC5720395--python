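# Methods

## Poisson dN/dS framework

Substitutions are classified on the coding strand of each gene by
substitution class *i* — the base change plus *w* flanking bases on each
side (w = 0, 1, 2 giving 12, 192, 3,072 classes) — and by functional impact:
synonymous (s), missense (m), nonsense (n), essential splice (e). "Truncating"
refers to n and e together. Counts aggregated over a cohort follow

    n[i,s] ~ Poisson(t r_i L[i,s]),   n[i,c] ~ Poisson(t r_i L[i,c] ω_c),

with one rate class pinned to 1 for identifiability (we pin the class with
the largest synonymous site count, reported in the output, and absorb scale
into t). The composition matrix L is built by exhaustively enumerating all
3 · CDS-length coding changes plus 3 changes at each essential-splice site;
contexts at exon boundaries use the genomic (intronic) neighbors. Indexing
rates on the coding strand makes the 192-class model strand-asymmetric,
capturing transcription-coupled repair.

Maximum-likelihood estimation alternates two exact coordinate updates —
`u_i = Σ_c n[i,c] / Σ_c ω_c L[i,c]` and
`ω_c = Σ_i n[i,c] / Σ_i u_i L[i,c]` with `u_i = t r_i` — to convergence
(|Δ logL| < 1e-10, cap 10,000 sweeps). Each conditional update maximizes the
Poisson log-likelihood exactly, so the iteration is monotone; a statsmodels
Poisson GLM reproduces the same estimates in the test suite. Three ω
structures are exposed: free (ω_m, ω_n, ω_e), tied truncating (ω_n = ω_e),
and single (one ω for all non-synonymous classes). 95% CIs come from the
profile likelihood with the χ²(1) cutoff; the profile is re-maximized over
all nuisance rates at each candidate ω. Model adequacy is compared by
AIC = 2k − 2 logL computed cell-wise on the same data layout for all models,
including the collapsed single-rate (Nei–Gojobori-style) model.

Impact rules: amino-acid identity from the standard genetic code; changes
creating a stop are nonsense; stop→stop is synonymous; stop-loss (stop→amino
acid, last codon only) is grouped with nonsense as termination-disrupting.
Essential-splice sites default to intronic donor positions +1, +2, +5 and
acceptor positions −1, −2 (configurable); single-exon genes have none.
Overlapping genes resolve deterministically to the longest CDS, ties by
lexicographic id.

## Gene-level tests (dNdSunif / dNdSloc / dNdScv)

Per gene the neutral class expectations are E_c,j = Σ_i u_i L[i,c,j]. On the
expected-synonymous-count scale s_j = t_j E_s,j, with ρ_c,j = E_c,j / E_s,j,
the joint likelihood is

    L(s_j) = Poisson(n_s,j | s_j) · Gamma(s_j | α, β_j) · Π_c Poisson(n_c,j | s_j ρ_c,j ω_c),

where the Gamma prior comes from a negative-binomial regression of
synonymous counts on covariates with offset log E_s,j (α = θ, β_j = θ/μ_j;
statsmodels NB2, θ = 1/alpha_NB2; Poisson fallback with a warning if the NB
fit degenerates, collinear covariates dropped). Every hypothesis admits a
closed-form profile over s_j because each free ω group contributes a term
independent of s_j at its conditional MLE:

    s_j* = (n_s,j + Σ_fixed n_c,j + α − 1) / (1 + β_j + Σ_fixed ρ_c,j ω_c).

Under the free alternative s_j* = (n_s,j + α − 1)/(1 + β_j) — the shrunk
expected synonymous count E'_s,j — and ω̂_c = n_c,j / (s_j* ρ_c,j), observed
over shrunk-expected. dNdSloc is α = 1, β = 0; dNdSunif fixes s_j = E_s,j.
LRTs re-profile s_j under both hypotheses (tied-truncating 2 df — the
default screen test — free 3 df, missense 1 df); the one-sided negative test
halves the 1-df p-value when ω̂_m < 1 and reports 1 − p/2 otherwise.
Gene-level ω CIs are profile-likelihood with s_j re-profiled at every
candidate value. All-zero genes under dNdSloc report p = 1 with ω undefined.

Indel recurrence uses a negative-binomial regression of per-gene indel
counts on covariates with offset log CDS length, fitted on passenger genes
only (a user-supplied known-cancer-gene list is excluded); the default
statistic is the number of unique indel start sites, which is robust to
hotspots and recurrent artifacts. The upper-tail NB p-value is combined
with the substitution p-value by Fisher's method (χ², 4 df, p-values clamped
at the smallest positive float). Multiple testing uses Benjamini–Hochberg
within a dataset, across a dataset×gene matrix, or restricted to an a-priori
gene list. Adjacent same-sample substitutions (distance 1) are collapsed
into MNV events and routed to the indel channel by default.

## Excess-based quantities

For ω > 1 the excess formula f = (ω − 1)/ω gives the fraction of observed
mutations of a class that are drivers, and d = f · n their number; for
ω < 1 the lost fraction is 1 − ω. The channel-level excess test fits an NB
background for a channel (synonymous, missense, nonsense, splice, indel) on
passenger genes — offset: expected channel rate under the context model for
substitutions, log CDS length for indels — applies it to a target gene set,
reports per-gene upper-tail NB p/q-values and converts the set-level excess
into driver fractions/counts with gene-bootstrap percentile CIs (default
1,000 replicates, seeded).

## Mixture model of selection across genes

Conditioning on a gene's total count, the synonymous/non-synonymous split is
binomial with success probability
ρ_x,j(ω) = Σ_i r_i L[i,x,j] ω / (Σ_i r_i L[i,s,j] + Σ_i r_i L[i,x,j] ω) —
independent of the gene's absolute rate. The distribution of ω across genes
is modeled as a free probability mass over the 27-point grid
(0, 0.1, …, 2, 3, 4, 5, 10, 15, 20), fitted by EM from a uniform start
(|Δ logL| < 1e-8 or 5,000 iterations; the iteration runs in row-normalized
linear space for speed and its log-likelihood is non-decreasing). Bootstrap
CIs resample genes with replacement, warm-starting each replicate at the
full-data optimum. Posterior gene memberships follow the empirical-Bayes
formula. Selection budgets per tumor are

    δ_neg = (1/N) Σ_j Σ_{ω_k<1} P(ω_k|·) (1−ω_k) ((n_x,j/ω_k) + n_s,j) ρ_x,j(1),

and symmetrically δ_pos over ω_k > 1, with ρ evaluated at neutrality; they
assume genes are purely positively or purely negatively selected. Known
small-sample limitation: with few mutations per gene the grid spreads mass
over 0.9/1.0/1.1 (these are statistically indistinguishable), which biases
δ upward on neutral data; with informative counts (≳100 per gene in the test
suite) the mass concentrates at 1 and the budgets vanish.

Power for negative selection is simulated as
m_j ~ Gamma(θ, θ/m), n_s ~ Pois(m_j ρ_s), n_m ~ Pois(m_j ρ_m ω_m),
n_t ~ Pois(m_j ρ_t ω_t), with the two-sided 1-df missense test under
dNdSloc or dNdScv; defaults ρ = (0.287, 0.649, 0.064), θ = 6.03 (typical
exome-cohort values), 5,000 replicates, seeded.

## Signature decomposition

A sample's 96-channel pyrimidine-centric spectrum (channel order: C>A, C>G,
C>T, T>A, T>C, T>G × upstream × downstream base, both alphabetical) is
decomposed over a user-supplied signature matrix by EM: responsibilities
p_i ∝ c_i m_i,j per channel, exposures re-estimated as count-weighted
responsibility sums, stopping at Σ|Δc| < 1e-5; uniform initialization by
default with a random-restart option for degeneracy checks. Hypermutators
(> 1,000 coding substitutions by default) are labelled by their dominant
process when one signature group exceeds 50% exposure; the two APOBEC
signatures are merged before the dominance check. No signature set is
bundled; synthetic matrices serve the tests.

## Simulators and synthetic data

Neutral catalogs draw (site, alt) pairs with probability proportional to the
spectrum rate of each site's substitution class; within a sample, duplicate
positions are re-drawn. Spectrum presets ("pancancer_like" CpG-heavy,
"uv_like", "tobacco_like", "flat") are stylized: they reproduce the
qualitative context biases (direction, not magnitude, of the published
bias figures) and are deliberately more divergent than real mutational
signatures. Consequences of that choice are reported where they matter: on
heterogeneous-cohort simulations mixing divergent spectra with unequal
selection, the single-ω cohort estimate is a count-weighted mean over
substitution classes and can sit a few percent away from the naive
burden-weighted mean of per-patient ω (exactly recovered when selection is
homogeneous); the tests assert both consistency with the estimator's
analytic population value and ~7% agreement with the weighted-mean truth.

The local randomizer reassigns each substitution to a uniformly chosen
position with an identical (2w+1)-mer within a window, preserving per-sample
burden and per-context counts exactly; mutations without an eligible target
stay in place and are counted. Germline contamination adds variants whose
impact composition follows the germline selection profile (missense 0.38,
truncating 0.08 relative to synonymous); SNP over-filtering removes records
at a generated blacklist over-sampling synonymous-capable sites.

Synthetic genomes are non-overlapping validated genes (lognormal CDS
lengths, optional GT..AG introns, both strands); covariates pair
Gamma-distributed latent rate multipliers (shape 6.03, mean 1) with one
covariate column correlated with log-rate at a requested level plus noise
columns. Cohorts plant selection multiplicatively on site rates — the exact
ω parameterization of the Poisson model — and scale the per-sample burden by
the planted-weight inflation so ω > 1 adds mutations rather than
redistributing a fixed burden. Every fixture is regenerable byte-identically
from (seed, parameters) and ships a truth sheet sufficient to recompute
expectations analytically. Default test scale (chosen so the suite runs in
minutes on one CPU): 100–800 genes, up to 200 samples, 30–120 coding
mutations per sample.

## Numerical and calibration notes

- p-values of the gene-level LRTs rely on the χ² approximation; with ~40
  mutations per gene its approximation error is real but small — detectable
  by a Kolmogorov–Smirnov test at n ≈ 2,000 genes even when data are drawn
  exactly from the null model. The suite therefore asserts exact-uniformity
  via KS for dNdSloc (calibrated by construction through binomial
  conditioning) and tail-calibration plus zero significant genes for dNdScv,
  which is the operationally relevant specificity property.
- θ estimates above 1e6 are treated as Poisson; expected synonymous counts
  are floored at 1e-12 when used as rates; EM and fit tolerances are stated
  above and fixed.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); CLI manifests echo the seed and options of
  every run.
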