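# Methods

`wisentpanel` implements the analysis chain around a reduced 96-marker
biallelic SNP panel for non-invasive genetic monitoring of European bison
(*Bison bonasus*): replicate-based consensus genotyping with error
decomposition, individual identification, pairwise parentage, marker-subset
selection, breeding-line assignment, cross-species detection, and molecular
plus pedigree-based genetic diversity. This note documents the models, the
parameters that matter, the synthetic-data generator used for validation,
and the numerical and design choices that were genuinely open.

## The panel and its subsets

The default panel holds 95 autosomal biallelic markers plus one Y-associated
marker (`AmelY1`-style) for sexing. Overlapping functional subsets mirror the
panel's design: 90 polymorphic autosomal loci for individualisation, a nested
subset of 63 unlinked loci in Hardy–Weinberg equilibrium for parentage and
diversity, 18 loci for breeding-line discrimination, and 5 loci monomorphic
in the focal species but polymorphic in related bovids for cross-species
detection. Marker identities in the shipped default panel are synthetic
placeholders (`BB0001`…); real panels are supplied as marker-metadata tables.

## Consensus genotyping

Non-invasive samples are genotyped in replicates (default minimum 3;
invasive samples 1). Per autosomal marker, with replicate tallies
(n_AA, n_AB, n_BB) over called replicates, rules apply in a fixed precedence
order — most specific, heterozygote-forcing rules first:

1. all replicates missing → NoCall;
2. n_AB ≥ 1 with both opposite homozygotes seen at least twice → AB;
3. all three genotype classes present → AB;
4. n_AB > 0 and n_AB ≥ max(n_AA, n_BB) → AB (homo/het ties go heterozygous);
5. unique plurality class → that genotype;
6. the two homozygotes tied, no heterozygote → NoCall.

The precedence order is a design decision: the individual rules do not by
themselves determine an order, and this one applies the het-forcing rules
before simple plurality, which reproduces every worked phrasing of the rule
set. The test suite checks all replicate tallies up to r = 6 against an
independent sentence-by-sentence restatement.

**Error decomposition.** Each replicate call is scored against its sample's
consensus: an allelic dropout (ADO) is a homozygous replicate at a
heterozygous consensus; a false allele (FA) is a replicate carrying an
allele absent from the consensus. With biallelic markers the two are
mutually exclusive (asserted in tests). Rates are reported on two scales:
*marginal* (events / all comparisons) and *per-opportunity* (ADO events /
heterozygous-consensus comparisons, FA events / homozygous-consensus
comparisons). The per-opportunity scale is the one on which the per-call
event probabilities of the error model are defined, and the one the
acceptance script prints. Loci with a genotyping-error rate above 5%
(configurable `ge_exclude`) are flagged for exclusion.

**Sex calling** is a majority vote over Y-bearing replicate calls:
y-fraction > 0.5 → male, < 0.5 → female, exactly 0.5 → undetermined. This
reproduces the observed failure taxonomy of replicated Y-cluster false
alleles: 4 spurious Y calls in 6 replicates produce a male false positive,
3 in 6 an undeterminable sample.

## Identity and parentage

Per-locus probability of identity for unrelated individuals and for full
siblings:

    PID_l    = Σ_i p_i⁴ + Σ_{i<j} (2 p_i p_j)²
    PIDsib_l = 0.25 + 0.5 Σ p_i² + 0.5 (Σ p_i²)² − 0.25 Σ p_i⁴

Cumulative curves multiply per-locus values over loci sorted by descending
expected heterozygosity; accumulation is in log10 space so the curves stay
meaningful far past the double-precision underflow point. The reported locus
counts are where each curve first drops below a threshold (default 1e-4, the
conventional sufficiency threshold for natural populations).

Same-individual matching counts loci, called in both samples, whose
unordered genotypes differ; samples within `max_mismatch` (default 3) are
linked and connected components form match groups. The default sits far
below typical between-individual minima (≥ 11 in the synthetic runs).

**Parentage** is pairwise (every individual against every other, excluding
only self): the exclusion count is the number of loci with opposing
homozygotes, and the likelihood score per candidate is

    LOD = Σ_l log10[ ((1−ε) T(g_o | g_c) + ε P_HW(g_o)) / P_HW(g_o) ]

where T is the single-parent Mendelian transition probability with the
untyped second parent drawn from Hardy–Weinberg frequencies, P_HW the
unconditional HWE genotype probability, and ε the per-locus genotyping error
(default 1e-4, appropriate for consensus genotypes built from triplicates).
A candidate is assigned iff exclusions ≤ 1 (one mis-scored locus must not
veto a true parent at ε = 1e-4 over 63 loci) and LOD > 0; equal-LOD passing
candidates in the same sex pool are flagged ambiguous; pair orientation
(which member is the parent) is left undetermined, as it is not identifiable
from a pairwise genotype comparison. Full-likelihood sibship reconstruction
is deliberately out of scope; the family-network module reconciles assigned
links with a studbook pedigree into the categories verified / not-verified /
not-testable / novel.

With ε = 0 the score reduces exactly to pure exclusion (LOD = −∞ iff an
opposing-homozygote locus exists), asserted on enumerated genotype tables;
the transition matrix is validated against brute-force enumeration over
transmitted alleles.

## Marker selection

Per-locus statistics: genotype counts, allele frequencies, observed and
expected heterozygosity, a chi-square HWE test (1 df; an exact conditional
test with mid-p correction is available), composite pairwise LD as the
squared Pearson correlation of allele-dosage vectors over shared-complete
individuals (no phasing; default minimum 20 shared individuals), and
per-locus FST between breeding lines as Nei's (H_T − H_S)/H_T with
unweighted group means (Weir–Cockerham θ available as an option; the two
differ by construction and the threshold convention belongs to the Nei
form). Frequencies are estimated on a first-degree-relative-free set:
offspring with both parents genotyped are removed. Note that in a fully
genotyped multi-generation pedigree this filter collapses the set towards
founders — it is intended for monitoring samples where one or two
generations are genotyped.

The diversity subset keeps polymorphic autosomal loci passing HWE at
α = 0.05 with Bonferroni correction across tested loci (the exact cutoff
used to arrive at a diversity panel is not uniquely determined by outcome
counts; both α and the correction are configurable), then greedily prunes
LD: while any pair exceeds R² = 0.8, the member of the worst pair with the
higher mean R² is dropped. The line subset keeps loci with FST ≥ 0.075.
Private alleles are alleles with nonzero count in exactly one line.
Selection is idempotent: re-running on a selected subset changes nothing.

## Breeding-line assignment

Two independent routes feed a dual-threshold rule:

1. **Classification EM** under a HWE-within-cluster likelihood: the E-step
   assigns each individual to the cluster maximising Π_l P(g_l | cluster
   frequencies), the M-step re-estimates cluster allele frequencies from the
   assignments; membership Q is the row-normalised per-cluster likelihood at
   convergence. Multi-start (20 by default) with a deterministic seed
   schedule: a farthest-point centroid start on mean-imputed dosages plus
   random restarts; the best classification likelihood wins, and the
   classification log-likelihood is non-decreasing across iterations
   (asserted every run). Cluster frequencies are clipped to [1e-6, 1−1e-6]
   so an individual carrying an allele unseen in its cluster keeps a finite
   likelihood.
2. **Supervised leave-one-out assignment**: per reference line, allele
   counts exclude the focal individual; with a symmetric Dirichlet(1) prior
   the posterior-predictive probability of the focal genotype
   (Dirichlet-multinomial, two draws) is multiplied over called loci and Q
   is the row-normalised marginal likelihood across lines. This replaces a
   full admixture MCMC: the practical use case — two predefined lines with
   reference individuals — is supervised, and the leave-one-out construction
   avoids self-assignment bias.

**Model choice.** The most likely K minimises BIC = −2 log L + K·L·log n
with K·L free frequency parameters, where log L is the *equal-weight
mixture* log-likelihood at the fitted cluster frequencies. The
classification (max-assignment) sum is not a proper model likelihood: its
improvement from an extra spurious cluster grows with n, which makes BIC
overfit K systematically; with the mixture likelihood, K = 2 is recovered in
100/100 seeded two-line runs at per-locus FST 0.1 with 18 loci (n = 120).
On full pedigree data, within-line family clans are themselves genuine
structure, so K is best estimated on the relative-filtered reference set.

**Dual rule.** An individual is assigned to a line only when both methods
give that line at least 60% membership; otherwise it is unassigned with a
reason flag (below-threshold or method conflict). Anonymous EM clusters are
aligned to line labels by the bijection maximising summed anchor
memberships, making the decision invariant to cluster permutation. F1
crosses of the two lines land between the clusters and are unassigned at a
clearly elevated rate relative to purebreds (asserted as a rate difference
over 100 simulated F1s, rather than an absolute rate, which depends on the
realised line differentiation).

## Cross-species detection

Individuals are gated on panel call rate (default ≥ 80% over the autosomal
loci in use). Pairwise genetic distance is the codominant squared distance —
per locus 0/1/4 between same / one-step / opposite genotypes, equivalently
the squared allele-dosage difference — summed over shared called loci and
rescaled by (total loci / shared loci), which is unbiased under
missing-at-random and invents no genotypes. PCoA double-centres −½ D² and
eigendecomposes; negative eigenvalues are reported, never silently dropped,
and coordinates use the positive axes. On Euclidean-embeddable inputs the
coordinates reproduce the input distances to 1e-8 (property-tested).
Absolute eigenvalue magnitudes depend on the distance scaling convention and
are not comparable across tools; axis percentages and cluster separation
are.

## Molecular and pedigree diversity

Per locus per group: H_O, Nei's unbiased expected heterozygosity
ĥ = (2n/(2n−1))(1 − Σp²); H_S is the unweighted group mean of ĥ, H_T uses
unweighted mean allele frequencies (the Nei & Chesser small-sample
correction is available but off by default, matching the plain-definition
convention of the spreadsheet-tool outputs the workflow emulates).
F-statistics come in two averaging modes: arithmetic means of per-locus
values, and values recomputed from locus-averaged H's — under the second
mode (1 − F_IT) = (1 − F_IS)(1 − F_ST) holds to machine precision. Loci
monomorphic across all groups are excluded from F-statistics with a note.
Allelic richness is rarefied to the smallest per-locus group gene-copy
count: AR = Σ_alleles [1 − C(2N − N_i, g)/C(2N, g)]. Standard errors are
delete-one-locus jackknives.

**Pedigree engine.** Coancestry by the tabular method in topological order:
f(i,j) = ½[f(sire_i, j) + f(dam_i, j)], f(i,i) = ½(1 + f(sire_i, dam_i));
an unknown parent behaves as a unique non-inbred phantom founder. Gene
diversity of a living set two ways: GD_kinship = 1 − mean coancestry over
all ordered pairs *including self-pairs* — the convention under which the
kinship and gene-drop estimators agree in expectation (tools differ here;
the choice is deliberate and documented) — and GD_genedrop by Monte-Carlo
transmission of uniquely labelled founder alleles (default 1000 iterations,
autosomal Mendelian sampling), averaging 1 − Σq². Founder contributions are
expected shares of the living gene pool by recursive averaging of parental
contributions. Pedigree F-statistics use mean inbreeding F̄ and mean
pairwise coancestry: F_IS = (F̄ − f_w)/(1 − f_w) with f_w the
unweighted-group mean of within-group coancestry (self-pairs *excluded*
here), F_ST = (f_w − f_all)/(1 − f_all), and F_IT from the multiplicative
identity. Group-size weighting conventions vary across pedigree software;
unweighted group means are used and stated in the output metadata. Groups
with fewer than two living members are excluded from the within-group mean.

## The synthetic-data generator

The generator defines the study conditions; its defaults are not tuning
knobs. It emulates the managed European bison population: 12 founders, a
lowland line founded by a nested subset of 7, a lowland–Caucasian line
founded by all 12, and one-directional gene flow from the lowland line into
the other. Founders (generation 0, line label `U`) are the shared pre-split
stock; from generation 1 each line breeds within itself — random mating with
polygamy, Poisson offspring per pair — except that a lineB offspring takes a
lineA sire with the migration probability. Founder genotypes are
Hardy–Weinberg draws at Beta(2, 2) frequencies per marker (cross-species
markers fixed monomorphic in the focal species); descendants are produced by
Mendelian gene dropping of unlinked loci. Sexes are 1:1; the sex marker is
XY in males, X in females. Everything is bit-reproducible under a fixed
seed, and Mendelian consistency is property-tested on every run.

Default demographic parameters — 6 generations, 3.2 offspring per pair,
migration 0.10 — were chosen once so that the simulated population resembles
the real one in the quantities the workflow measures: a final population of
a few hundred with a pedigree of ~700–1200, between-line per-locus FST in
the few-percent range with a tail above the 0.075 selection threshold, and
living-pool gene diversity around 0.8.

The observation model corrupts each replicate call independently: missing
with p_miss (defaults 0.076 non-invasive / 0.02 invasive, solved so expected
call rates are 92.4% and 98%); a heterozygote loses a random allele with
p_ado = 0.016 (false homozygote); a homozygote gains the marker's other
allele with p_fa = 0.003 (false heterozygote — with a biallelic panel the
injected allele can only be the other allele). The sex marker uses the same
mechanisms: spurious Y in females is an FA event, a dropped Y in males an
ADO event. Per-event independence is the minimal model consistent with
marginal rate reporting; correlated-error profiles (e.g. sample-quality
effects) can subclass `ErrorProfile`. Every injected event is retained in an
event log so estimators are scored against exact truth, not just rates.

Non-target species (ESUs) for cross-species tests get per-marker allele
frequencies offset from the focal baseline by a configured magnitude with
random signs, a per-ESU baseline call rate emulating phylogenetic dropout,
and polymorphism at the cross-species markers when flagged.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage and recombination (loci are unlinked by
construction, so LD pruning exercises machinery, not realistic haplotype
structure), locus-specific or sample-quality-correlated error rates,
null alleles, the irregular mating structure of the real studbook,
overlapping generations, and real cross-species ascertainment bias.

## Validation-scale choices

The test suite and acceptance script run at desk scale, chosen as the sizes
at which the statistical assertions have adequate power: error-model
recovery uses 200 individuals × 3 replicates × 63 heterozygote-enriched loci
(binomial 99% CIs); parentage uses an error-free 3-generation pedigree of
200+ individuals over 63 loci drawn near frequency 0.5 — emulating the
informativeness ascertainment of a real parentage panel, and the regime in
which every per-locus true-parent LOD contribution is non-negative, so the
all-pairs recovery assertion is meaningful — on a 40-founder base (under the
full 12-founder bottleneck, pervasive inbreeding shrinks true-pair LODs and
occasional negatives are expected, which is a property of the population,
not the estimator); K-selection runs 100 seeded two-line datasets at
per-locus FST 0.1 with 18 loci and n = 120 over K = 1–4; the pedigree engine
is cross-checked on 50 random pedigrees with 1200 gene-drop iterations
against the closed-form kinship value, at a 4σ joint Monte-Carlo band.

## Known limitations

- Pairwise parentage is not sibship reconstruction: in bottlenecked
  populations many non-PO relatives pass the exclusion + LOD screen, so the
  assigned-pair list is a candidate set to reconcile against a pedigree, not
  a pedigree estimate. False positives concentrate on close relatives of
  missing true parents (property-tested).
- The LOD threshold is not calibrated to any posterior probability of
  parentage; it is a likelihood-ratio screen.
- Counts of selected markers (diversity subset size, line subset size) are
  threshold-sensitive and population-dependent; they are reported, not
  guaranteed.
- The exact-test mid-p option for HWE is provided for small samples but the
  chi-square form is the default, matching the workflow convention.
- VCF/PED exports are interoperability sugar; internal computation never
  routes through them.
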