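# Methods

`steppekin` analyses the joint relationship between geographical exogamy
(how far apart spouses are born) and genetic inbreeding in SNP-array
cohorts of the kind collected in multi-population anthropological-genetic
field studies. Because survey and genotype data of this kind are usually
access-restricted, the package ships a pedigree-based simulator that
reproduces the study design with exact ground truth, and every estimator is
validated against that truth.

## Data model and conventions

Genotypes are alt-allele dosages (0/1/2, missing) at biallelic autosomal
SNPs with both physical (bp, 1-based inclusive) and genetic (cM) positions.
All reported intervals are closed `[start_bp, end_bp]`. Text PED/MAP is the
only genotype format (auditability over compactness); the genetic map is a
whitespace table `chrom pos_bp rate_cM_per_Mb pos_cM`, linearly interpolated
and clamped at chromosome ends. No genome build is assumed: the map is a
required input. Downstream per-SNP computations skip missing calls rather
than imputing.

## Spousal-distance exogamy

Couple distances are great-circle (haversine, R = 6371.0088 km) between
recorded birthplaces, for the surveyed couples themselves ("current"
generation) and for each respondent's parents ("parental" couples). The
endogamy/exogamy limit is not fixed a priori: per population we estimate a
Gaussian kernel density of log10 distance (bandwidth 0.2 on the log10
scale, i.e. the kernel SD — R's `bw` semantics) and take the antimode, the
lowest local minimum strictly between the two highest modes; the limit is
the cross-population mean of the antimodes. Unimodal populations are
excluded with a warning. Zero distances (same-village couples) cannot enter
a log-scale density, so they are floored at 0.1 km *for density estimation
only*; rates and counts always use true distances. A couple exactly at the
limit counts as endogamous. Parental distances are binned into the four
classes `<=4`, `(4,20]`, `(20,40]`, `>40` km, closed on the left class.

## IBD hidden Markov model

The inbreeding coefficient f is the probability that a marker is
autozygous. Hidden states {nonIBD, IBD} form a Markov chain along each
chromosome with stationary P(IBD) = f and transitions over d cM

    P(IBD -> IBD)    = exp(-a d) + (1 - exp(-a d)) f
    P(nonIBD -> IBD) = (1 - exp(-a d)) f,

with a (per cM) the IBD segment-turnover rate: shorter inbreeding loops
produce longer segments and hence smaller a. Emissions are Hardy-Weinberg
genotype probabilities in the nonIBD state and {hom-ref: p, hom-alt: 1-p}
in the IBD state, both contaminated by a genotyping-error rate eps (the
observed genotype equals the true one with probability 1 - eps, else one of
the other two uniformly). Missing calls emit 1 in both states; chains
restart at stationarity per chromosome. eps defaults to 0.001 and is fixed,
not estimated (identifiability at desk scale).

(f, a) are estimated by bounded L-BFGS-B maximum likelihood over
f in [1e-6, 0.5], a in [1e-3, 1] per cM, from a 3x3 grid of starts, with
the forward recursion JIT-compiled. **F-Median / A-Median** are the medians
of per-submap estimates over random sparse submaps: per chromosome a random
start inside the leading 0.5 cM window, then greedy left-to-right
acceptance of markers strictly more than 0.5 cM apart (approximate linkage
equilibrium, as in multi-subset inbreeding pipelines; the field default is
100 submaps). Allele frequencies for emissions default to leave-one-out
within-population estimates, clipped away from 0/1.

### Inbred/outbred likelihood-ratio test

H0: f = 0 lies on the boundary, so the LRT p-value uses the
0.5 chi2_0 + 0.5 chi2_1 mixture. By default the statistic uses the
maximised *full-panel* likelihood: the chain models linkage through genetic
distance, so when emissions are near linkage equilibrium the panel-wide
likelihood is valid and keeps the information the submaps split up. On
simulated 5,000-SNP genomes this raises power on second-cousin offspring
from ~65% to ~87% at a 3.5% empirical type-I error (nominal 5%). For
heavily LD-structured, unpruned arrays the conservative alternative
(`statistic="consensus"`: the single submap whose f-hat is the per-submap
median) is available and documented in the output.

### Mating-type classification

Parental mating types AV (avuncular, F = 1/8, 5 loop meioses), 2x1C
(double first cousins, 1/8, 6), 1C (first cousins, 1/16, 6), 2C (second
cousins, 1/64, 8) and OUT (less related) are assigned in two steps: the LRT
decides OUT; otherwise a 2D Gaussian kernel density of each simulated
reference cloud — gene-dropped offspring of that type pushed through the
same submap estimator — is evaluated at the individual's
(F-Median, log10 A-Median) and combined with a uniform prior over the four
inbred types. The log10 transform of a reflects its positivity and right
skew. AV and 2x1C share F = 1/8 and differ only through segment length, so
they confuse with each other most; errors concentrate in adjacent types on
the ladder OUT - 2C - 1C - {2x1C, AV}.

## Runs of homozygosity

Calling is the standard sliding-window scan: windows of `window_snp`
consecutive SNPs pass with at most `window_het` heterozygous and
`window_missing` missing calls; a SNP is inside a ROH when the passing
fraction of windows covering it exceeds `hit_threshold`; maximal runs are
kept if they satisfy `min_snp`, `min_kb`, a SNP-density floor and a maximum
inter-SNP gap. The defaults (50 SNPs / 500 kb / 1 het) suit dense
genome-wide arrays; all parameters are exposed because sensible values
scale with SNP spacing, and the desk-scale harnesses use settings matched
to their panel density (25-SNP windows at 1 SNP / ~120 kb).

Classification is dual: fixed literature thresholds (intermediate
[500, 1500] kb, long > 1500 kb) and population-specific classes from a
three-component Gaussian mixture of log10 length fit by EM (tolerance 1e-6
on the log-likelihood, best of 10 seeded restarts; a component collapsing
below weight 0.01 triggers a flagged 2-component refit). Class boundaries
are the intersections of adjacent mean-ranked weighted component densities,
found by bisection between the means; a segment exactly at a boundary joins
the upper class. The EM is implemented in-package (40 lines, 1D) so the
monotone log-likelihood trace is available; tests cross-check the recovered
means against scikit-learn's `GaussianMixture`.

**Excess homozygosity** per individual is (O_hom - E_hom)/N over its
non-missing sites, with E_hom the within-population panmictic expectation
using the small-sample correction n/(n-1) on 2p(1-p) (n = allele count at
the site). Negative values mean fewer homozygotes than random mating
predicts.

## Diversity statistics

Allele-sharing dissimilarity between two individuals is 1 minus the mean
shared-allele fraction, `2 - |g1 - g2|` shared alleles per
pairwise-complete site. Kinship uses the single method-of-moments
estimator `phi = mean (g_i - 2p)(g_j - 2p) / (4 p (1-p))` with
within-population frequencies (parent-offspring ~ 0.25); relatives closer
than first cousins (phi > 1/16 + 0.02) are removed greedily — always the
individual with most over-threshold partners, ties broken by sample id —
until no pair remains. Haplotypic heterozygosity is the unbiased estimator
`H = n/(n-1) (1 - sum p_h^2)` over distinct block haplotypes in maximal
runs of consecutive SNPs whose local map rate is below 0.5 cM/Mb (>= 5
SNPs), averaged per autosome and then across autosomes. It requires phase
and is therefore defined on simulator-provided haplotypes; real-data
phasing is out of scope, which is sufficient because the statistic itself —
not a phasing method — is what needs validation.

## Statistics layer

Mann-Whitney U is exact for small samples (the exact null distribution
when tie-free; exhaustive group-label enumeration when ties make that
invalid and the number of splits is tractable) and tie-corrected normal
otherwise; Spearman uses exact permutation for n <= 8; the 2x2 test is
Yates-corrected chi-squared. Raw p-values are reported (with an optional
Benjamini-Hochberg column that never gates conclusions); one-tailed
directions are always configured explicitly, never inferred from the data.
Confounder analysis is OLS plus type-I ANOVA via statsmodels, categorical
covariates one-hot with a reference level.

The distance-binned report joins, per individual, the parental-couple
distance with three inbreeding measures (F-Median, class-C ROH count,
class-C ROH total kb), bins them into the four distance classes, and
contrasts each exogamous class against `<=4` km with MWU, plus Spearman of
log10 distance vs each measure among exogamous individuals. This is the
design that exposes a bell-shaped distance-inbreeding relationship when
kinship endogamy operates at intermediate distances.

## Synthetic cohorts and what they do (not) emulate

Founder haplotypes are drawn site-wise from per-SNP frequencies (uniform
0.05-0.95, array-like common-SNP ascertainment), with an optional
first-order LD knob that is a free parameter, not a claim of realism.
Pedigrees are gene-dropped with Poisson recombination on the cM scale
(no interference, sex-averaged map); founder-haplotype labels make
autozygous segments exact, so ROH callers and the HMM can be scored against
truth rather than against another estimator. No mutation and no genotyping
error are introduced at generation time; an optional post-hoc flip process
(default rate 0.001) exercises the HMM's error parameter separately.

Geography: couple and parental distances follow an endogamous/exogamous
mixture — exponential mass at sub-km scale plus a lognormal tail (median
~30 km, tail to ~1,500 km), defaults 50/50 — and birthplaces are placed by
exact spherical geodesics in a 40-50N band so haversine recovers the drawn
distances to machine precision. The study-like layout is 16 populations
(12 + 4 across two cultural groups) of ~27 individuals; the mating-type
mixture defaults to mostly outbred with second cousins dominant (~29%),
first cousins ~6% and double-first-cousins marginal. Kinship endogamy is
planted by overriding the mixture inside a parental-distance band
(elevated 1C/2C at 4-40 km).

Not emulated: coalescent founder ancestry, population structure beyond a
symmetric frequency draw, X chromosomes, ascertainment schemes of specific
arrays, real LD. Passing tests therefore demonstrate estimator correctness
and calibration under the stated generative model, not robustness to every
artefact of real array data.

## Problem sizes and numerical choices

Validation harnesses run at desk scale: a 5,000-SNP / 22-chromosome /
3,500-cM panel for HMM calibration (cohorts of 100-200 individuals,
5-16 submaps — submaps of this panel already contain most markers, so the
median over ~10 is a stable surrogate for the field's 100), and a
physically dense 5,000-SNP / 600-cM panel (1 SNP per ~120 kb) wherever ROH
calling needs realistic density. The generator and every harness are fully
seeded; identical seeds give byte-identical outputs. Optimiser
non-convergence on all starts returns the best boundary evaluation; KDE
grids use 512 points over [0.1, 2000] km; mixture boundaries are bisected
to 1e-5 on the log10 scale.

## Known limitations

* Frequencies for HMM emissions are estimated within small populations;
  leave-one-out reduces but does not remove the bias for n ~ 27.
* Single outbred genomes can absorb homozygosity sampling noise into small
  positive f-hat at sparse marker counts; cohort medians are the stable
  summary.
* AV vs 2x1C assignment is intrinsically hard (equal F); only the
  segment-length signal separates them.
* The excess-homozygosity baseline assumes within-population panmixia;
  admixed populations would need stratified baselines.
* Pooled vs per-population mixture fitting of ROH lengths can give
  different class boundaries; both are available and the choice is
  reported in the output.
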