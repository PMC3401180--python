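# Methods

## Biological model

All inference assumes haplodiploid monogyny with polyandry: each colony
is headed by a single diploid queen mated to several haploid drones;
every sampled worker carries one maternal allele (Mendelian, probability
½ per queen allele) and one paternal allele (the whole genome of a
haploid drone). Loci are treated as unlinked and autosomal-codominant;
alleles are microsatellite fragment sizes in base pairs. Colonies are
analysed independently; there is no model of worker reproduction,
multiple queens, or mutation.

## Queen and paternal inference

Per locus, the candidate set for the queen genotype Q = (q₁, q₂) is every
pair (homozygotes included) of alleles observed among the colony's
workers such that every worker shares at least one allele with Q. Each
candidate is scored by the profile likelihood

  L(Q) = max_f ∏ᵥ P(worker w | Q, f),

with f the paternal allele frequency vector and P summing ½·f(paternal)
over the worker's compatible maternal/paternal splits. With a
heterozygous queen, the only workers with more than one split are those
whose genotype is exactly {q₁, q₂}; merging those with the
q₁/q₂-homozygote-derived counts into a single multinomial cell reduces
the maximization over f to an ordinary multinomial maximum, so L(Q) has
a closed form (the inner split of the merged cell is proportional to the
unambiguous q₁/q₂ counts). The test suite checks this closed form
against an independent EM maximization of the same mixture likelihood on
every worker multiset with ≤ 6 workers over ≤ 4 alleles (8 007
instances).

Likelihood ties are broken deterministically: (1) fewer distinct
paternal alleles (parsimony), (2) queen homozygote over heterozygote,
(3) smallest allele pair. Ties are compared with an absolute
log-likelihood tolerance of 1e-9. If no candidate covers all workers
(possible genotyping error), the candidate covering the most workers is
used, the uncovered workers are dropped, and the result is flagged with
the dropped indices.

Identifiability limit: some configurations are genuinely ambiguous or
even favour the wrong queen — e.g. if every worker carries allele x,
Q = (x, x) with two paternal alleles can out-score the true heterozygous
queen. At the default study scale (20 workers, 6–11 alleles per locus)
exact per-locus recovery in simulations is ≈ 98%; the acceptance suite
asserts ≥ 95%. A full multi-colony, multi-locus pedigree likelihood
(which couples loci through drone identities) would resolve some of
these cases but is outside this package's scope.

### Effective mating number and intracolonial relatedness

From the inferred paternal counts, m_e = 1/Σqᵢ² with qᵢ the paternity
proportions (uncorrected; the unbiased-Σq² variant is available via
`corrected=True` and is infinite when all fathers are distinct). Because
inference is per-locus, counts refer to paternal *alleles*: drones
sharing an allele are indistinguishable at that locus, so per-locus m_e
estimates the effective number of paternal alleles — a lower bound on
the effective number of matings that approaches it as allele number
grows. Simulation truths are therefore recorded (and compared) at the
same paternal-allele level. Colony m_e is the arithmetic mean over loci
± SE (sd/√L). Worker relatedness follows Crozier's haplodiploid
pedigree argument: super-sisters (same drone) share r = 0.75, maternal
half-sisters r = 0.25, so r = 0.25 + 0.5/m_e; it is 0.75 at m_e = 1 and
decreases strictly towards 0.25.

## Diversity statistics

For allele frequencies pᵢ at one locus: Na (distinct alleles),
Ne = 1/Σpᵢ², Ho (heterozygous fraction of individuals),
He = 1 − Σpᵢ² and Botstein's PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ². He is
deliberately uncorrected — no 2N/(2N−1) factor — because that is the
convention of the spreadsheet tools whose tables these statistics
mirror; the packaged reference table reproduces only under the
uncorrected form. Statistics default to queen genotypes (one independent
diploid per colony); worker genotypes are non-independent within
colonies. The summary table appends an arithmetic mean ± SE (sd/√L) row
and the total allele count.

Note on PIC: the printed PIC column of the reference table is not
reproduced by the Botstein formula on the packaged genotypes (e.g. first
locus: computed 0.753 vs printed 0.627); the computation behind the
printed column is unidentified, so PIC values are reported but never
asserted.

## Queller–Goodnight relatedness

For focal individual x against y at one locus,

  num_x = Σ_{a∈x} (share_y(a) − p_a),  den_x = Σ_{a∈x} (share_x(a) − p_a),

summing over x's two allele slots, with share_g(a) the fraction of g's
slots equal to a and p the reference allele frequencies. Loci are pooled
by summing numerators and denominators (ratio of sums — stable for
near-fixed loci), giving the directional estimate r_x(y); the reported
R is the average of r_x(y) and r_y(x). This directional-average
convention (that of GenAlEx-style tools) reproduces the packaged
reference matrix; the single symmetric ratio (both directions pooled
before dividing) is available via `symmetric="pooled"`. Reference
frequencies are computed once from the whole queen sample, focal pair
included; a pair-excluded variant is available.

An exact identity follows from self-referential frequencies: summed over
all partners y, the numerator of a focal x equals minus its denominator,
so the mean R over all N(N−1)/2 pairs is exactly −1/(N−1) — with N = 20,
−0.0526. The slightly negative "background" mean relatedness is thus
structural, not biological. Corollary: resampling loci cannot move the
mean, so the default locus bootstrap of the mean yields a degenerate CI
under the directional-average estimator (it is informative for the
pooled variant and for any statistic other than the global mean);
colony resampling is a sensible alternative unit when a non-degenerate
interval is needed. Negative R values are reported as-is.

Known fixture discrepancy: the packaged genotypes of nests 19 and 20 are
identical at 9 of 15 loci and share exactly one allele at the remaining
6, giving R ≈ 0.76 under every estimator variant, while the reference
matrix prints 0.950 (which implies identity at 10 loci). The two
published sources are mutually inconsistent for this pair; the package
reports the value computed from the genotypes.

## Differentiation

Fst defaults to the heterozygosity-based Nei form Gst = (Ht − Hs)/Ht per
locus — Hs the unweighted mean within-population 1 − Σp², Ht from the
unweighted mean allele frequencies — averaged over loci; monomorphic
loci are skipped. Weir–Cockerham θ (variance-component a/(a+b+c), summed
over alleles and loci) is available via `method="wc"`. Significance is
by permuting individuals among populations (999 by default, seeded),
P = (1 + hits)/(1 + permutations).

Paternal pools enter these diploid analyses by diploidization: each
paternal allele becomes a homozygous pseudo-individual replicated with
the smallest integer weights preserving the paternity proportions
(deterministic and frequency-exact, unlike random pairing of haploids).

The three-level AMOVA encodes each allele copy as a one-hot vector
(squared distance between copies 0/2, i.e. the allele-mismatch metric
for codominant data), sums SS over loci, and partitions: among colonies
/ among workers within colonies / within workers, with df (a−1, N−a, N).
Variance components come from the standard unbalanced nested
expected-mean-square equations (coefficient n₀ = (N − Σmᵢ²/N)/(a−1) in
individuals); negative components are truncated to zero for the
percentage decomposition, with raw values retained. Φ statistics:
Φ_CT = σ_a/σ_tot, Φ_IS = σ_b/(σ_b+σ_w), Φ_IT = (σ_a+σ_b)/σ_tot.
P-values: the among-colony level permutes workers among colonies; the
within-colony level re-pairs allele copies among workers of the same
colony. Complete genotypes are required (missing data raise); colonies
with a single worker are excluded with a warning.

## Exact HWE and LD tests

The HWE test conditions on allele counts; Levene's distribution assigns
each genotype table probability n!·∏nᵢ!·2^H / ((2n)!·∏aᵢⱼ!). The exact
P is the mass of tables no more probable than the observed one. The
Markov chain operates on the ordered 2×n allele arrangement: a uniformly
random transposition of two allele copies is symmetric and irreducible,
and the uniform distribution over ordered arrangements induces exactly
Levene's distribution over tables, so every proposal is accepted and no
Metropolis ratio is needed. The running statistic (−Σ log aᵢⱼ! + H log 2)
updates in O(1) per transposition. Defaults: 100 000 steps, 1 000
dememorization; the MC standard error is the sd of 20 batch means /√20.
P-value comparisons use a 1e-9 tolerance against the observed statistic
to make probability ties robust to float drift. Full enumeration of all
compatible tables (recursion over the upper-triangular cells) provides
the exact value for small tables and the oracle for the chain; the suite
checks agreement within 3 MC-SE on every table with ≤ 6 individuals over
≤ 3 alleles.

The genotypic LD test keeps both loci's genotype margins fixed and
shuffles the locus-2 column by random transpositions (uniform over
pairings); extremeness is measured by the log-likelihood-ratio statistic
G of the genotype-by-genotype contingency table (expected counts depend
only on the fixed margins, so G also updates incrementally). Degenerate
(single-category) margins return P = 1. Raw P-values are reported; a
Bonferroni option exists but is off by default.

## Spatial dispersion

Nest coordinates are planar metres (projected grid; no geodesy — all
distances involved are tens of km at most). Quadrat counts use an
axis-aligned grid anchored at the bounding-box lower-left (counts are
translation-invariant; an explicit origin and an anchor-offset
sensitivity helper exist), default cell 1 000 m — the estimated forage
radius of a nest. The Poisson fit uses λ = sample mean; the negative
binomial (mean m, clumping k, variance m + m²/k) uses moments
k = m²/(s²−m) refined by bounded 1-D ML, and is inapplicable when
s² ≤ m. Goodness of fit is a χ² over count classes with expected
frequencies pooled from the upper tail (then any sparse interior class
into its right neighbour) until every class expects ≥ 1 — the textbook
threshold of 5 would leave no classes with only tens of points; df =
classes − 1 − fitted parameters, and P is reported only when df ≥ 1.
Classification: random if Poisson is not rejected at 0.05 (or NB is
rejected at 0.01 while Poisson fits better); aggregated if NB is
accepted while Poisson is rejected; uniform if Poisson is rejected and
the index-of-dispersion test ((n−1)s²/m ~ χ²ₙ₋₁) is significantly low;
indeterminate otherwise. With 20 points the qualitative label is the
meaningful output; exact GOF P-values at this sample size depend on the
(unknowable) original quadrat construction.

## Synthetic data

The generator draws, per locus, an allele count uniformly in 6–11 and
frequencies from a symmetric Dirichlet (concentration 1); queens under
HWE; drones iid from the same frequencies (panmictic drone
congregation, consistent with the random-mating conclusion the HWE tests
support); paternity shares Dirichlet over 10 drones (concentration 100
≈ even shares, so ≈ 10 effective matings); 20 workers per colony, each
one random queen allele plus the assigned drone's allele. Genotyping
error replaces an allele with a uniform random allele of the locus
(simplest substitution model — no stutter or allelic dropout).
Relatedness scenarios plant mother–daughter (expected R ≈ 0.5) or
duplicated-queen (R ≈ 1) pairs. Coordinates come from CSR over a
17 × 22 km window (the reference sampling extent) or a Thomas cluster
process conditioned to exactly n points. Everything derives from one
seed.

What the generator does not emulate: null alleles, size-calling
artefacts, population substructure among colonies, linked loci, and
drone pools correlated between colonies. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to those field artefacts.

## Validation scale and numerical choices

The test suite validates at these problem sizes (chosen to exercise the
study's own scale while keeping the default run short): queen-inference
oracle on all 8 007 small instances; 200 simulated colonies for
queen/m_e recovery; all ≤ 6-individual/≤ 3-allele HWE tables (one
representative per allele-relabelling class, chains of 100 000 steps)
plus 500 null datasets at N = 50 with 20 000-step chains; 200 panmictic
datasets × 99 permutations for AMOVA P uniformity; 200 CSR and 50
Thomas patterns for dispersion classification; and 100 end-to-end
duplicated-queen recovery runs. Fixed tolerances: frequency sums to
1e-12; likelihood tie tolerance 1e-9; MC agreement within 3 MC-SE.

Curation: one cell of the packaged queen-genotype table is repaired (a
separator shifted one character, "2102/14" → 210/214); the loader
exposes raw and curated views and the JSON log records the change.
Further cells of the published summary tables disagree with direct
recomputation from the genotype table itself (several Ne/Ho entries and
the 19–20 relatedness above); the package always reports the recomputed
values.
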