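# Methods

## Problem setting

A sample of multigenerational pedigrees drawn from an admixed population
can hide family-level ancestry structure: one kindred descending from a
founder (or a whole founding subgroup) with a different ancestral mix than
the rest. `pedstruct` quantifies this with principal components of
genome-wide SNP dosages and a leave-one-family-out standardized centroid
distance, and ships a generative model of exactly such samples so every
claim the toolkit makes can be checked against planted ground truth.

## Pedigree model and kinship

Pedigrees are forests keyed by (family id, individual id); parents are
both-present-or-both-absent, and generation numbers are assigned
topologically (generation 0 = no parents in the pedigree: the founders and
the marry-ins). Kinship uses the classical recursion

- φ(i,i) = (1 + φ(father_i, mother_i)) / 2,
- φ(i,j) = (φ(father_i, j) + φ(mother_i, j)) / 2, recursing on the
  individual of the later generation,

with founders of distinct lineages unrelated. The maximal pairwise
unrelated genotyped subset (kinship ≤ threshold, default 0) is found
exactly per family by branch-and-bound over the relatedness graph with a
deterministic preference order (lower generation, fewer missing genotypes,
lexicographic id), so results are reproducible; a greedy fallback exists
for families beyond 150 genotyped members but is never reached at realistic
sizes. On pedigrees without inbreeding loops the threshold-0 answer is
precisely the genotyped founders and marry-ins — asserted against brute
force in the tests.

## Genotype QC

The cleaning chain runs in a fixed order: duplicate/MZ-twin removal →
call-rate filtering → LD pruning → Hardy–Weinberg sweep.

- **MZ twins** are detected by genotype concordance over the non-missing
  overlap within a family (default threshold 0.999), clustered by
  transitive closure, and one member of each cluster is kept at random
  under the run seed. Concordance is a reproducible surrogate for
  provider-identified twin lists.
- **Call rate**: SNPs below 0.98 are removed first, then samples below
  0.95 on the surviving panel. SNP-first ordering is deliberate — a sample
  should not be lost because of markers that were about to be discarded.
- **LD pruning** removes dosage correlation: within a sliding window
  (default 50 SNPs, step 5, per chromosome in position order) any pair
  with r² > 0.5 loses its later-position member. r² is computed over
  pairwise-complete observations; pairs with fewer than 10 complete
  observations are left unexamined and logged. The threshold is the
  analysis-defining value; window and step are conventional pruning
  defaults and configurable.
- **HWE** uses the exact conditional test: given n genotyped individuals
  and the alt-allele count, P(n_het) ∝ multinomial weight × 2^n_het, and
  the p-value sums all heterozygote counts no more probable than the
  observed one. Monomorphic SNPs return p = 1. By default the test runs on
  the maximal unrelated subset only, because relatives violate the
  independent-sampling assumption; a flag restores all-sample behavior.
  The Q-Q summary reports observed vs expected −log₁₀ p and a
  median-χ² inflation factor. Note that exact-test p-values are
  conservative (super-uniform) by discreteness, so the null inflation
  factor sits well *below* 1 at moderate sample sizes (≈0.4 at n = 100);
  the diagnostic signal is inflation above 1, not deviation from it.

## Principal components, three ways

All derivations share the normalization: with weighted alt-allele
frequency q_j (estimated over non-missing entries), each column is centered
at 2q_j — making the weighted column mean exactly zero — and scaled by
√(p̂_j(1−p̂_j)), where p̂_j adds plus-one smoothing at the effective sample
size n_eff = 1/Σw_i² (p̂ = (2·n_eff·q + 1)/(2·n_eff + 2)). Missing entries
become 0 after centering (mean imputation); columns monomorphic among
observed entries are dropped.

1. **all**: uniform weights 1/n.
2. **weighted**: w_i = 1/(n_f F). The weights enter frequency estimation,
   centering, and the operator C = W^{1/2} X Xᵀ W^{1/2} — the reading under
   which "families contribute equally" holds for the fitted operator
   itself. A `covariance-only` mode weights only the operator.
3. **unrelated**: uniform-weight PCA on the unrelated subset; everyone
   else is projected onto the fitted loadings using the subset's frequency
   estimates, and flagged as projected so fit and projection are never
   mixed silently in downstream statistics.

Scores use s = Xv with unit-norm loadings v, so Σᵢ wᵢ s_ik s_il =
λ_k δ_kl (orthogonal under the weight metric, weighted mean zero). Signs
are fixed by making each component's largest-magnitude loading positive.
Variance fractions are λ_k over the operator trace. The scree report
suggests k as the largest k with λ_k > 1.2 × mean(λ_{k+1..m}) — a labeled
elbow heuristic, not a significance test (no Tracy–Widom machinery); the
retained count is a user parameter everywhere downstream.

### Why the unrelated derivation is the robust detector

With a post-pruning panel of several thousand SNPs and ~1,000 relatives,
the standardized genotype covariance contains family kinship blocks whose
leading eigenvalues (≈ 2·φ̄·n_f for a family of n_f members with mean
kinship φ̄) are comparable to the ancestry eigenvalues (≈ 4F·n·var(a) for
admixture proportions a). Under the all-sample derivation the top
components therefore mix ancestry with single-family axes, and any family
that owns such an axis looks many SDs away from the rest regardless of its
ancestry. Fitting on the pairwise-unrelated subset removes kinship blocks
entirely, leaving ancestry (plus noise) as the only systematic structure;
relatives inherit clean coordinates by projection. The all-sample and
weighted derivations remain available and informative — in particular
weighting rescues small families from being swamped — but outlier
*flagging* is most trustworthy on the unrelated axes.

## Leave-one-family-out distance

For each family, the centroid of its member scores (projected members
included) over the first k PCs is compared against the mean and per-PC
population SD (divide by n) of all remaining individuals; the distance is
the per-axis standardized Euclidean norm (a diagonal Mahalanobis — full
covariance available via flag; the statistic is deliberately covariant
with the PC axes, not rotation invariant). PC scores are *not* refit after
removing a family: only the centroid and SD are recomputed. Families are
ranked descending, and the flagging threshold defaults to 2 SD — a tool
default chosen to sit between the outlier and background ranges the
statistic produces, not a universal constant.

Generational trajectories group one family's members by generation and
report mean distance to the global centroid, with marry-ins flagged and
excluded from descendant-only means (marry-ins come from the general
population and sit near the centroid; including them would mask the
founder lineage's convergence). Note the founding couple's own children
carry undiluted founder ancestry, so the dilution-by-half pattern starts
at the first generation with marry-in parents: descendant means are
expected flat from generation 0 to 1, then halving.

## The simulator

`SimConfig` defaults define the emulated study: 20 families of 22–86
genotyped members across 4 generations, K = 3 ancestral populations at
F = 0.1 each (Balding–Nichols: population frequency ~
Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p ~ U(0.05, 0.95)), and
founder admixture ~ Dirichlet(4.4, 3.2, 0.4) — roughly a 55/40/5 mix with
realistic between-individual spread, as reported for Mexican American
samples. Families grow from a founder couple; each couple has Poisson
offspring (rate solved per family to hit a target size, resampled into the
configured range) and each non-terminal-generation child marries a new
generation-0 spouse with probability 0.75. Explicit per-family size
targets (honored to ±10%) let experiments pin size structure, e.g. making
the planted outlier the smallest family.

Genotypes descend by gene dropping: a generation-0 individual with
admixture a draws each allele Bernoulli(Σ_k a_k p_kj); children receive
one uniformly chosen allele from each parent, independently per SNP.
Uniform missingness and MZ-twin duplication are optional. All randomness
flows from one seed; identical configuration reproduces bit-identical
output.

Outlier families come in two scopes. `gen0` shifts every generation-0
member's admixture by a' = (1−δ)a + δe_k — an endogamous family whose
marry-ins come from the same distinct subgroup, the strongest family-level
stratification and the detection test bed. `founders` shifts only the
founding couple, with marry-ins at the base Dirichlet — a single outlier
ancestral couple whose families regress toward the sample mean by half per
generation, the trajectory test bed.

### What the simulator does not emulate

SNPs are independent (no linkage or haplotype structure) — adequate for a
post-LD-pruning panel, and the reason the pruning step is exercised on
separately planted correlated columns rather than simulator output. There
is no genotyping-error model beyond uniform missingness, no sex
chromosomes, no mutation, and the ancestral allele-frequency spectrum is
uniform rather than realistic. Passing tests therefore demonstrate the
statistical machinery under clean Mendelian inheritance with known
admixture, not robustness to assay artifacts or LD confounding.

## Validation scale and numerical conventions

The replicated validation studies (tests and `scripts/acceptance.py`) use
the default study size — 20 families, ~1,000 genotyped members, 5,000
SNPs — with 50 replicates in the test suite and 25 in the acceptance
script; planted effects are δ = 0.4 (detection, trajectory) and δ = 0.25
(size masking, planted as the smallest family), both toward the minor
ancestry, mirroring the observation that outlier kindreds are typically
enriched for a minority ancestral component. Detection uses the
scree-suggested k per dataset (typically 1 under the null, 2 with a
planted family, which creates its own axis).

Conventions worth knowing when comparing against other tools: dosages
count the alt allele with −1 as the missing sentinel; positions are
1-based; in PLINK .bim output allele 1 is the counted (alt) allele; .ped
input infers the counted allele as the lexicographically larger of the two
observed (the format carries no designation), so text round trips are
exact only for SNPs with both alleles observed; eigenvalues are reported
for the unnormalized operator (variance fractions are scale-free);
degenerate (numerically null) components are dropped rather than reported
as zeros; all tie-breaks (unrelated-set selection, twin-cluster retention,
rank ties) are deterministic under the run seed.
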