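# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `pikepop`.

## Data model

Genotypes are unordered diploid allele pairs at codominant loci; allele
labels are fragment sizes (integers, assumed already binned to a repeat
grid upstream). Half-calls (one allele scored) are normalised to missing on
construction, following the GENEPOP convention that a missing genotype has
both alleles absent. GENEPOP files (2- and 3-digit) and a CSV dialect
(`id, population, <locus>:1, <locus>:2`) round-trip bit-exactly; population
labels follow the GENEPOP convention of naming each block after its last
individual id, with an explicit override that wins when given.

## Marker validation

**Hardy–Weinberg exact tests.** The test is conditional on the observed
allele counts. The Markov chain performs random transpositions of gene
copies between individuals; every pairing of the 2n copies is equally
likely at stationarity, which is exactly the Levene conditional
distribution of genotype tables. The one-sided ordering statistic is the
heterozygote count (`deficit` accumulates P(het ≤ observed), `excess` the
upper tail). This is the package's own convention for the one-sided
ordering; it coincides with the classical orderings for two alleles and is
verified against complete enumeration for every table with ≤ 6 diploids
and ≤ 3 alleles. Defaults mirror common practice: 10,000 dememorisation
steps, 100 batches of 10,000 iterations, standard error from batch means.
Monomorphic (population, locus) combinations raise an explicit
undefined-test error and are excluded from battery denominators rather
than silently contributing p = 1.

**Linkage disequilibrium.** A Monte-Carlo permutation test of independence
on the two-locus genotype contingency table (statistic: log-likelihood-
ratio G; no gametic phase assumed). p-values use the add-one rule
(k+1)/(N+1), so the resolution floor is 1/(reps+1).

**Excess of significance.** With X ~ Binomial(n, α), `binomial_excess`
returns P(X ≥ k) and the critical count — the largest k₀ with
P(X ≥ k₀+1) > α. The complementary convention (smallest k with
P(X ≥ k) ≤ α) is exposed separately (`min_significant_count`) because the
two differ by at least one and published reports do not always say which
was used.

**FDR.** Benjamini–Yekutieli step-up (valid under arbitrary dependence),
applied within groups — by population for Hardy–Weinberg batteries, by
locus pair for LD batteries — delegated to
`statsmodels.stats.multitest`.

**Allelic dropout.** A per-locus EM model: each of an individual's two
allele copies drops independently with locus rate d. A heterozygote with
one dropped copy is scored as a homozygote of the surviving allele; two
dropped copies give a missing call. True genotype frequencies are free
per-population parameters (no Hardy–Weinberg assumption), so the rate is
identified jointly by the missing-data fraction (≈ d²) and the
homozygosity excess (≈ 2d(1−d) transfer from heterozygotes). This is a
deliberately transparent re-derivation of the dropout-correction idea; the
interface isolates it so a different error model can replace it.
Correction imputes the most probable true genotype given the observed call
and the fitted frequencies; a called heterozygote is never altered, an
observed homozygote can only become a heterozygote carrying the same
allele, and missing calls become the most probable genotype. Parameter
recovery on simulated dropout (d = 0.2, N = 200) is within ±0.05. A
caveat: missing data from other causes (PCR failure) is attributed to
dropout, biasing rates upward at high-missingness loci. Loci to *remove*
(monomorphic, or > 12% missing in any one population) are judged on the
raw panel, before imputation masks the missing-data pattern, and then
dropped from the corrected table.

## Diversity and differentiation

Expected heterozygosity is Nei's unbiased (2n/(2n−1))(1 − Σp²) — the
"unbiased vs plain gene diversity" choice is flagged here because sources
often leave it unstated. Allelic richness rarefies to g gene copies with
the exact combinatorial formula; the default g is the smallest
per-(population, locus) gene-copy count in the dataset, which makes A_R
comparable across sample sizes of 20–58. F_IS is 1 − ΣH_O/ΣH_E over loci
(ratio of sums), with a 95% percentile bootstrap over loci.

θ follows Weir & Cockerham (1984): the a, b, c variance components per
allele per locus, summed over loci and alleles before taking the ratio,
which is robust to unequal sample sizes; negative estimates are reported
as computed. Jost's D uses Nei–Chesser unbiased H_S and H_T per locus with
the K/(K−1) factor; loci combine by harmonic mean, with an arithmetic
fallback (flagged by the per-locus vector) when any per-locus value is
non-positive and the harmonic mean is undefined. Both estimators are
checked to 1e-12 against independent plain-loop implementations on random
tables. All CIs are percentile bootstrap (2.5/97.5) over loci, 10,000
replicates by default.

Exact G tests of differentiation permute population labels against
genotypes per locus; the global test is Fisher's combination
χ² = −2 Σ ln p with df = 2 × (loci with defined tests).

## LD effective population size

Burrows' composite Δ̂ = (S/(S−1))(Σxy/2S − 2p̂q̂) is computed for every
allele pair of every locus pair from dosage vectors, and
r² = Δ̂²/(p(1−p)q(1−q)). Comparisons are averaged with information weights
p(1−p)q(1−q): with flat weights the many low-information rare-allele
comparisons dominate the mean while carrying little drift LD, which
inflated N̂e by ~12% in Wright–Fisher recovery runs; the weighted mean is
median-unbiased there (median 50.7 at true N = 50). The sampling
expectation E[r²|S] uses the random-mating formulas (1/S + 3.19/S² for
S ≥ 30; 0.0018 + 0.907/S + 4.44/S² below), with S the weighted harmonic
mean sample size, and N̂e comes from the quadratic inversion of
r²′ = r² − E[r²|S]; non-positive r²′ gives ∞ (no detectable drift signal).

Screening removes singleton alleles — alleles present as a single copy,
necessarily in one heterozygote — per the explicit study rule, not a MAF
cut-off; re-screening is a no-op. Confidence intervals: delete-one
jackknife (over individuals by default) feeds a chi-square interval with
effective degrees of freedom n′ = 2r̂⁴/Var_jack. The individual jackknife
was chosen over the locus jackknife after the latter under-covered
(≈ 88% vs ≈ 96% empirical coverage of the nominal 95% on the recovery
design); the locus variant remains available (`jackknife="loci"`). With
`subsample_s`, the estimate is repeated on 100 random subsamples (count
configurable, seed logged) and the harmonic mean across runs reported.

## Hybrid simulation

A genotypic class is its gene-origin vector z = (z11, z12, z22). Cohorts
are built by multinomial gamete sampling: each offspring draws one allele
per locus from each of two pools, loci independent (unlinked markers, free
recombination). The crossing tree is F1 = P1×P2, F2 = F1×F1, first
backcross = P1×F1, second backcross = P1×(first backcross), mirrored
toward pool 2; each stage's pool is the empirical allele frequencies of
the simulated cohort, re-estimated at cohort size. The default hatchery
roster is 100 each of P1, F1, F2, P1_bx, P1_bx1 (500 simulated, 50 sampled
into the mixture without replacement); the roster is configurable, and the
four-class variant (no F1, 400-strong pool) is exercised in tests. At
fixed-difference loci the simulated class z-vectors converge to the
Mendelian expectations within binomial error at n = 10,000.

## Island simulator and outlier scan

The forward simulator evolves unlinked loci in demes × populations with
non-overlapping generations: each offspring picks a source population
(stay / sister population with probability m_within / other-deme
population with probability m_between), draws two uniform parents, and
each transmitted allele mutates with probability μ (KAM over k states by
default — the simplest model consistent with "ideal" microsatellites — or
SMM). The default scenario configuration (2 demes × 2 populations,
N = 100, m_within = 0.02, m_between = 2×10⁻⁴, 11 loci, k = 12,
μ = 2×10⁻⁴, 400 generations) was chosen by the built-in calibration grid
(`calibrate_island`) to land mean within-population H_E in [0.38, 0.58]
and between-deme θ in [0.3, 0.5], the bands the pipeline targets; run
length, mutation scheme and rates are declared assumptions. Equilibrium θ
agrees with the finite-island expectation 1/(1 + 4Nm·d/(d−1)) within 30%.

The outlier scan is FDIST-style: neutral loci are simulated from the
equilibrium island-model allele-frequency law — deme frequencies
~ Dirichlet(θ_m · ancestral) with θ_m = (1−F̄)/F̄ set from the observed
multi-locus mean F_ST — then sampled at the observed sample sizes and
pushed through the same Weir–Cockerham estimator. Each observed locus'
upper-tail p is its rank within the simulated loci of the same
heterozygosity bin (50 bins, widened until ≥ 200 null draws). On
forward-simulated all-neutral input the raw α = 0.05 flag rate is ~3%
(band [0.01, 0.10]). Only this one scan is implemented; the convention
that a locus is a selection candidate only when two independent methods
agree therefore cannot fire on a single method's flag alone.

## Assignment engines

**Bayesian MCMC (genotype-frequency classes).** Gibbs sampling over latent
per-individual class labels, per-locus pair-of-origin indicators, and the
two species' allele frequencies with Jeffreys Dirichlet(1/2) priors. The
class likelihood at a locus is z11·P(g|pool1) + z12·P(one copy from each
pool) + z22·P(g|pool2). Posterior q is the class-label frequency after
burn-in (library defaults 500,000 + 100,000; reduced lengths are used in
tests and the acceptance script, where agreement with exact enumeration on
fixed-frequency toys is within Monte-Carlo error by 20–30k sweeps).
Replicates run independently and are reported separately — replicate
disagreement is a finding. Label switching between the two pools is
resolved afterwards by anchoring pool 1 to the first reference population
(mirroring all class columns if needed, flag recorded); a within-run
switch diagnostic (`mixing_warning`) is reported, not silently fixed.
Reference individuals are analysed without fixed class priors by default;
`fix_references=True` clamps them to P1/P2 for sensitivity runs.

**EM with hybridity coefficients.** Each class is a coefficient α (share
of gene copies from pool 1): parents 1 and 0, F1 1/2, backcrosses 3/4 and
7/8 mirrored. Every gene copy is independently from pool 1 with
probability α, so F2 is indistinguishable from F1 (both α = 1/2) and is
absent from the default roster. The E-step computes class memberships;
the M-step re-estimates pool frequencies from per-copy origin posteriors
weighted by memberships (0.01 pseudocounts for stability). This is a
proper EM (latent class + copy origins), so the log-likelihood is
monotone — asserted on every fit in the tests. Initialisation is the
geometric rule: split by the first principal-component axis of the allele
dosage matrix; if a parental pool empties, the fit restarts from a random
split (seeded, logged in the result). Note a structural ceiling: with a
full backcross roster on ~10 informative loci, a pure parental
individual's q cannot exceed ≈ 0.93 because the second backcross
(α = 7/8) is likelihood-close — confident-parental checks use the minimal
parents+F1 roster.

Missing genotypes contribute likelihood 1 at their locus (marginalised) in
both engines. Both q matrices row-normalise to 1 within 1e-9.

**DAPC.** Allele dosages (missing imputed at the overall mean), centred
and scaled, PCA, then LDA on the retained PCs; the PC count is picked by
stratified cross-validated held-out reassignment over a nine-point grid
(ties to fewer PCs). A negligible (1e-7·scale) deterministic jitter on the
PC scores keeps the within-group scatter non-singular when groups are
perfectly separated. `find_clusters` runs k-means on PC scores with the
dimension-free BIC n·ln(WSS/n) + k·ln(n) and the diffNgroup rule: split
the successive BIC decreases into sharp/flat by 1-D 2-means and keep the k
after the last sharp decrease; a curve whose best drop is within one
penalty unit (ln n) of flat declares no structure (k = 1). On strongly
hierarchical data the rule may stop at the top-level split (the two
species) rather than the finest one — inherent to this family of rules.

## Power evaluation

`classify` assigns the argmax class iff its q strictly exceeds the
threshold (0.5 / 0.75 / 0.9), else UNASSIGNED; raising the threshold never
converts UNASSIGNED to assigned. Detection counts a true hybrid assigned
to *any* hybrid class as a success (the exact class is disregarded); false
negatives are hybrids assigned to a parental class; for true hybrids
detection + false-negative + unassigned = 1 identically. Replicate
agreement is summarised as pairwise modal-class agreement.

## The synthetic study generator

`synthetic_study` emulates the four-population design the pipeline
targets: FLU N=58, TRA N=20, CAR N=28 (southern pike) and DRA N=22
(northern pike), 16 raw loci of which 11 are analysable. Population
frequencies follow a hierarchical F-model (species pools
~ Dirichlet(2.5·ancestral); populations ~ Dirichlet(4·species pool)),
calibrated once so the realised data sit in the study's bands: global
θ ≈ 0.31 ± 0.03, between-species θ ≈ 0.43, within-species ≈ 0.19, mean
H_E ≈ 0.49, N_A ≈ 3–4 per population. Genotypes are drawn with
per-population inbreeding coefficients (TRA −0.22 and slight negatives in
the other southern samples — the heterozygote excess typical of small
supportive-bred populations; DRA +0.04). One locus is monomorphic; four
carry > 12% implanted missing data in one population each; dropout is
overlaid on the same observation model the estimator assumes (three
removed-panel loci at 0.25–0.39, one retained locus at 0.15, the rest
below 0.05).

What the generator does *not* emulate: the exact allele-frequency
configurations of real pike loci (only their summary bands), linkage,
null-allele size structure, and drift LD — genotypes are drawn
independently per individual, so the study tables carry no N_e signal and
the LD-Ne method is validated on the Wright–Fisher simulator instead.
Consequently, passing study-scale tests shows the pipeline reproduces the
*design* (filter outcome, diversity and differentiation bands, zero false
positives, threshold-dependence of detection), not the exact printed
values of any particular empirical dataset; hybrid-detection rates on the
synthetic study come out more favourable than on real data, because
per-locus diagnosticity is not constrained by the bands the generator
matches. Measured F_IS is also attenuated (TRA ≈ −0.09 after correction
versus −0.22 implanted) since dropout overlays add homozygosity that
imputation only partially undoes.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py` (chosen as
desk-scale designs): exact-test chains of 5k–20k steps against full
enumeration; 500 random tables for the 1e-12 estimator checks; 50
Wright–Fisher replicates (N = 50, S = 50, 20 loci) for N_e recovery; 10,000
offspring for Mendelian checks; mixtures of 50 with 20k–30k MCMC sweeps
for power runs; 500 neutral loci and 20k null draws for the outlier-scan
calibration. Library defaults keep the larger published settings (10k×100
exact-test batches, 10k bootstraps, 500k MCMC sweeps).
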