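# Methods

`cgpatch` models how an extreme sweepstake reproduction event, combined with
collective larval dispersal, produces chaotic genetic patchiness (CGP):
fine-scale, temporally unstable genetic differentiation below the spatial
scale of effective larval dispersal in a broadcast spawner. The package has
three computational pillars — a forward pedigree-and-genotype simulator, a
genomic kinship/diversity toolkit, and a multiple-merger coalescent
spectrum-fitting module — plus a synthetic-data generator that stands in for
the study system's RAD-seq SNP panel.

## Forward simulator

**Reproductive model.** Limpets spawn in "stacks" of up to 20 individuals with
a 1:1 sex ratio. Each generation the population is randomly partitioned into
stacks of size `St` (St/2 females, St/2 males, drawn without replacement;
leftovers form one smaller balanced stack; an unpairable remainder stays
unstacked). Under **sweepstake** reproduction one focal stack is chosen
uniformly among complete stacks, `F` of its females are designated breeders,
and exactly `K` offspring are produced — each with its mother drawn uniformly
from the F breeders and its father drawn uniformly (with replacement) from the
stack's males, sex Bernoulli(1/2), genotype by Mendelian transmission with
free recombination. Under **relaxed** reproduction all complete stacks breed:
the mother of each offspring is uniform over all stacked females and the
father uniform over her stack's males. Offspring are produced one at a time
with parent resampling per offspring; there is no clutch structure, selection,
age structure, or overlapping generations.

Defaults `F = 1`, `K = 1000`, `St = 10` are the configuration that the
single-population sweep identifies as optimal: they reproduce an
all-close-kin sample of 10 with certainty, because with one mother every
offspring pair shares her (`P(shared father) = 1/5` with five stack males,
hence a ~1:4 full:half-sibling mix).

**Metapopulation.** Five demes on a linear chain; the sink sits at position 3
(two neighbours), the source at position 5. The source reproduces by
sweepstake; the other demes are relaxed. A proportion `CD` of the source's
offspring disperses collectively to the sink. Order of operations within a
generation: reproduction in every deme, then stepping-stone migration (each
deme exchanges a fraction `m`, default 0.1, of offspring with each adjacent
deme, simultaneously and size-preservingly), then the collective cohort
arrives at the sink en bloc, displacing uniformly chosen sink-born offspring.
The source breeds `K + round(CD*K)` offspring from the same focal-stack
breeders so that it remains at carrying capacity after dispersal; every deme
ends every generation at exactly `K`. Dispersing last is what "collective"
means operationally — the cohort is not diluted by diffuse migration in its
arrival generation, and its kin reach demes adjacent to the sink only through
the next generation's migration, which is also the observed decay pattern.

**Kinship by pedigree.** One-generation memory: full siblings share both
parents, half siblings exactly one, all other pairs are "unrelated" (founders
are mutually unrelated; deeper identity such as cousins maps to unrelated,
matching the three categories the analyses report). A replicate is
"successful" when a random sample of 10 offspring contains only full- and
half-siblings.

**Experiments.** `run_single_pop_experiment` (one deme, one generation, 100
replicates by default), `run_cd_experiment` (CD grid; per replicate the
success indicator, sink sample kinship composition, and the diversity ratio
pi_sink/pi_source of the full offspring demes), and `run_decay_experiment`
(one event generation at `CD >= 0.95`, then three relaxed generations with
CD = 0 and migration active). The pi comparison is reported as a continuous
ratio rather than a thresholded success because the empirical comparison
target is not a printed number. In the decay experiment the informative
baseline is the source's **pre-event** diversity: the event-generation source
cohort is itself the sweepstake family (equally depressed pi, and — sitting at
the chain end with a single neighbour — slower to recover than the sink), so
comparing the sink against the contemporary source cohort would measure which
of two affected demes recovers faster, not whether the sink is still below the
unaffected level.

**Founder genotypes.** Per replicate, founders are Hardy-Weinberg draws from a
fresh founder pool of `L = 1000` unlinked loci with frequencies
uniform(0.05, 0.95) — common SNPs give stable, well-conditioned pi ratios at
small L, and only relative diversity across demes is interpreted. L = 1000 is
a deliberate reduction (the kinship dynamics are genotype-free; pi ratios
stabilize well below the empirical panel size) that keeps 100-replicate
experiments in the minutes range on one core.

**Mutation.** Transmission accepts an optional symmetric per-allele flip
probability. It is off (0) everywhere except in
`sample_recurrent_sweepstake_cohort`, which runs a single population under
one sweepstake event per generation for a burn-in (default 30 generations;
the model-fit analysis uses 20) from a monomorphic start with mutation rate
1e-3 per transmission at 20,000–30,000 loci. This matters for the coalescent
analyses: without mutation a cohort's site-frequency spectrum only reflects
reshuffled standing founder variation (which a sweepstake event *flattens*,
since founder variants carried by the few parents are amplified to
intermediate frequencies); the link between genealogy and spectrum,
`E[X_i] = theta * E[B_i]`, exists only for mutations arising on the
genealogy's branches. Recurrent sweepstake generations with mutation produce
the singleton-rich multiple-merger spectrum that the coalescent comparison is
designed to detect.

## Synthetic data generator

`make_study_like_dataset` emulates the structure of the empirical panel at
reduced scale: 14 cohorts of 10 diploid individuals, `L = 5000` biallelic
SNPs (about a 20-fold reduction of the real panel — large enough that kinship
classification error is negligible, small enough that everything runs in
seconds), exactly one cohort tagged as a sweepstake cohort (one mother, five
candidate fathers, each offspring's father uniform among them — all pairs
full- or half-siblings, diversity depressed), all other cohorts unrelated HWE
founders from the common pool. Founder frequencies default to the standing
neutral spectrum (density proportional to 1/p, truncated at 1e-3), under
which an unrelated cohort's folded SFS matches the Kingman expectation — the
appropriate null for the spectrum analyses. Optional uniform per-genotype
missingness (default 0) is the only error model; there is no sequence-level
simulation. Loci are unlinked, so LD within family cohorts arises purely from
co-ancestry, which is the signal of interest. Monomorphic loci are excluded
at pool creation. All randomness descends from one master seed via named
substreams (`seeding.py`), so identical seeds give bit-identical datasets.

What the generator does *not* emulate: linkage, genotyping error, allele
dropout, cohort-specific missingness patterns, and real site-frequency
spectra shaped by demography. Passing tests therefore demonstrate estimator
correctness and the internal consistency of the simulation chain, not
robustness to the technical noise of a real RAD-seq dataset.

VCF round-tripping writes VCFv4.2 with unphased diploid GT on one synthetic
contig plus a `sample_id`/`cohort` TSV sidecar; reading goes through cyvcf2
and rejects multiallelic records by name.

## Kinship estimation

`ibd_moments` is the PLINK-style method-of-moments estimator: with pooled
allele frequencies (per-cohort frequencies are badly biased inside a family
cohort), the expected counts of IBS classes 0/1/2 are linear in (Z0, Z1, Z2)
with closed-form HWE coefficients; the triangular system is solved exactly and
the estimate clamped to the simplex and renormalized (degenerate all-zero
cases lean on Z1). `PI_HAT = Z2 + Z1/2`. Loci with pooled MAF < 0.01 are
excluded (near-monomorphic loci carry no IBS information and destabilize the
moment system); pairs with fewer than 100 jointly called informative loci are
flagged unreliable and left unclassified. The classic small-sample bias
correction is omitted — the uncorrected estimator is consistent at large L,
and correctness is established by parameter recovery on pedigreed synthetic
pairs.

`robust_kinship` is the allele-frequency-free within-pair estimator
`phi = (N_AaAa - 2 N_AAaa) / (N_Aa_i + N_Aa_j)` over jointly called loci
(undefined, and flagged, when neither individual has a heterozygous call).

Classification uses half-open powers-of-two phi intervals — duplicate above
2^(-3/2), then first/second/third/fourth degree down to unrelated below
2^(-11/2) — with Z0 < 0.1 splitting the first degree into parent-offspring
(Z0 = 0 exactly, barring genotype error) versus full siblings. Second degree
is reported as half-sib. The boundary convention (exact boundary values fall
to the more distant degree) is a documented choice; pedigree categories sit
far from the boundaries so it never matters on clean data. The three-class
cohort summary maps third degree and beyond to "unrelated" and excludes
duplicates with a warning.

## Population statistics

Nucleotide diversity is the mean over the pooled segregating SNP panel of the
unbiased per-site heterozygosity `n/(n-1) * 2p(1-p)` with missing genotypes
reducing n locally — a per-SNP (not per-bp) quantity, comparable across
cohorts on a fixed panel. LD is composite (genotype-dosage) r^2, avoiding
phasing, with seeded uniform pair subsampling above `max_pairs`; its
1/(n-1) finite-sample bias floor is checked by simulation. Pairwise F_st is
Weir-Cockerham theta combined as a ratio of summed per-locus variance
components (negative multilocus estimates reported as computed); significance
is one-sided — the proportion of 10,000 locus-bootstrap replicates with
F_st <= 0 — with Bonferroni correction over cohort pairs. The folded SFS
counts minor-allele classes 1..floor(n/2) over sites fully genotyped within
the cohort, including the j = n/2 class for even n (`Y_{n/2} = X_{n/2}`; the
conventional folding formula covers j < n/2 only, so the top class is a
stated convention).

## Coalescent spectra

Sweepstakes reproduction in a diploid population yields, in the large-N
limit, a simultaneous multiple-merger Xi-Beta(2-alpha, alpha) coalescent with
`1 < alpha < 2`: a reproduction event involves a single pair of diploid
parents, so participating ancestral lineages fall into up to four parental
groups that merge simultaneously; alpha → 2 recovers Kingman. The event
semantics implemented (and enumerated exactly by the oracle): with b active
lineages, a candidate event with k participants occurs at rate
`4 C(b,k) lambda_{b,k}`, `lambda_{b,k} = B(k-alpha, b-k+alpha)/B(2-alpha, alpha)`;
participants drop independently and uniformly into 4 groups; groups of 2+
merge; candidates in which no group reaches 2 are no-ops that still consume
their exponential holding time (correct by memorylessness of the superposed
clocks). The global factor 4 is a pure timescale choice that pins the
effective pair-coalescence rate at b = 2 to 1 (a k = 2 candidate lands both
lineages in the same group with probability 1/4); every quantity the package
compares is a normalized spectrum and is invariant to it.

Expected normalized folded spectra `E[B_i]/E[B]` are estimated by Monte-Carlo
genealogy simulation (default 20,000 trees per (n, alpha); per-class SEs by
the delta method on the ratio of means, well under 0.002 for n <= 40 at the
default replicates). An independent exact oracle for n <= 5 enumerates the
configuration space and solves the first-step occupation-time equations,
pinning down the event semantics; the Monte-Carlo generator is verified
against it to 3 SE. The deterministic recursion that computes these spectra
exactly for general n is not reproduced here; Monte-Carlo with reported,
propagated SEs delivers the precision the l2 comparison needs.

Model comparison: `l2 = sum_j (x_j - y_j)^2` (no square root) between the
empirical normalized folded spectrum and each model's expectation; the alpha
grid defaults to 1.05..1.95 in steps of 0.05 (only the open interval is
specified by the model); ties within 1e-12 go to Kingman by parsimony. A fit
is "decisively" Xi-Beta only when the improvement over Kingman exceeds a
propagated Monte-Carlo tolerance on l2
(`sum_j 2|x_j - y_hat_j| * 3 se_j + (3 se_j)^2`), so spectra that merely
wander within MC noise of Kingman are not over-interpreted. Theta is never
estimated: it cancels in every normalized quantity.

## Numerical and degenerate-input conventions

Dosage matrices are int8 with -1 for missing; estimators drop missing data
pairwise per locus. Monomorphic cohorts have pi = 0 by the formula; cohorts
of one, empty alpha grids, odd stack sizes, out-of-range CD/m, and
multiallelic VCF records raise typed errors naming the offending value. Zero-
variance locus pairs are skipped in LD. All experiment drivers accept a
single integer seed and derive per-stage substreams by hashing stage names
into `numpy.random.SeedSequence`, so adding a stage never shifts another
stage's stream and every result in the tests and analysis scripts is
bit-reproducible.

## Problem sizes

Default experiment sizes — 100 replicates for the single-population and CD
experiments, 50 for decay, L = 1000 simulation loci, L = 5000 panel SNPs,
20,000 Monte-Carlo trees (tests use 4,000–8,000 with correspondingly wider
stated SEs; the oracle comparison uses 100,000) — were chosen so the full
study reproduction runs on a single core in minutes while keeping every
Monte-Carlo comparison inside its stated error budget.

## Known limitations

No linkage or recombination map; no spatially explicit larval transport or
oceanographic forcing; no selection; pedigree kinship has one-generation
memory, so inbreeding accumulated by recurrent sweepstakes is invisible to
the truth labels (though not to the genotypes); the moments IBD estimator
assumes HWE reference frequencies and is not structure-adjusted; the
Xi-Beta fit is a grid search on l2, not a likelihood method, and no other
multiple-merger families are implemented.
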