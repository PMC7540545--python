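# Methods

## Sib-pair IBD hidden Markov model

At each marker a full-sib pair shares 0, 1 or 2 alleles identical by
descent.  The paternal-match and maternal-match indicators are
independent two-state Markov chains along the chromosome; between
adjacent markers at recombination fraction θ each indicator persists
with probability ψ = θ² + (1 − θ)².  Aggregating the product chain by
the number of matches gives the 3×3 IBD transition matrix
(T(2→2) = ψ², T(2→1) = 2ψ(1 − ψ), T(2→0) = (1 − ψ)²,
T(1→1) = ψ² + (1 − ψ)², T(1→2) = T(1→0) = ψ(1 − ψ), row 0 mirroring
row 2), which is reversible with stationary law (¼, ½, ¼).

θ is obtained from inter-marker map distance by the Haldane function
θ = (1 − e^(−2d/100))/2, d in cM.  Haldane is chosen over Kosambi for
closed-form consistency between the generator's crossover process and
the HMM: under Haldane, simulated meioses follow exactly the Markov
chain the HMM assumes, so estimator checks are not confounded by map
mis-specification.  When a map lacks a genetic column, 1 cM/Mb is
assumed (configurable).

Emissions are genotype-pair likelihoods under Hardy–Weinberg
equilibrium given the counted-allele frequency: the IBD-0 likelihood is
the product of the two HWE genotype probabilities; IBD-2 requires equal
genotypes; IBD-1 sums over the shared allele.  Missing genotypes
contribute a factor 1 to every state.  Genotyping error is absorbed by
mixing each state's likelihood with the uniform average over the nine
observable genotype pairs, L ← (1 − ε)L + ε/9, default ε = 0.01 — a
deliberately crude contamination model whose only purpose is to stop a
single miscalled marker from forcing an IBD switch.  Posteriors come
from the scaled forward–backward recursion with prior (¼, ½, ¼) at
every chromosome start; chains reset at chromosome boundaries.

Only sib pairs are modelled; no joint Lander–Green over the whole
sibship, no parental genotypes, and autosomal treatment of all markers.
A full multipoint pedigree engine (e.g. Merlin) conditions on slightly
more information; the pair-wise HMM is self-contained, exact for pairs,
and desk-checkable against path enumeration, which the test suite does
to 1e-9 on instances up to 8 markers.

## Cut-off calibration and region construction

IBD2 calls use a strict posterior threshold, P2 > c.  To limit
false-negative regions, c is calibrated as the largest value at which
*every* sib pair selects at least a minimum fraction (default 25%,
matching the expected pair-wise IBD2 genome share) of its markers; when
the configured default c = 0.05 already satisfies the rule it is
adopted, and the largest admissible value is reported alongside.
Calibration is global across pairs (per-family calibration is a flag).
The returned threshold sits one floating-point step below the limiting
order statistic, because the selection rule is a strict inequality.

Strict mode selects markers at which every pair is called IBD2;
one-phenocopy mode, available from three sibs, repeats this within each
all-but-one-sib subset that contains the sequenced proband (subsets
excluding the proband would have no exome to filter; they are not
emitted).  Per-excluded-sib region sets are kept separate rather than
unioned so co-segregation counts remain attributable.

Each maximal run of selected markers becomes one interval that starts
one base pair after the nearest upstream unselected marker and ends one
base pair before the nearest downstream unselected marker.  Runs
touching a chromosome edge are bounded by the outermost marker
positions, not chromosome lengths — the data say nothing beyond the
last marker.  Intervals are held 1-based inclusive and written as
0-based half-open BED with the family (and excluded sib) in the name
column.

Because the calibrated cut-off is permissive, region coverage
systematically exceeds the theoretical (¼)^(k−1) sharing fraction
(25%, 6.25%, 1.5625% for k = 2, 3, 4); the test suite asserts this
inflation rather than exact agreement, since it is a property of the
calibration rule, not an error.

## Variant filtering

"Allele frequency" always means the maximum over the reference
databases in which the variant is observed (EVS, HapMap, 1000G, ExAC,
GoNL columns); absent entries are ignored, never imputed as zero or as
failing.  The cascade: keep variants inside the family's shared
regions (chromosome-name dialect mismatches raise, they are never
silently dropped); drop anything above 10% in any reference database or
above 30% in the internal cohort (platform artifacts); select PTVs
(stop-gained, frameshift, canonical splice — taken from the annotation
table's class column, not re-derived); in each gene with a heterozygous
PTV, report every other heterozygous PTV or missense variant as a
candidate pair, and every homozygous PTV as a single candidate.
Candidates are *prioritized* when every member variant is below 2% in
every database where it appears — the frequency regime plausible for a
causal recessive allele.  The internal 30% filter is applied to the
allele fraction column as given; phase is unknown without parents, so
compound-het pairs are candidate pairs, not phased claims.

The missense recessive scan keeps in-region missense variants below 1%
with PolyPhen > 0.7 and Grantham > 75 (a missing score fails the gate
and is counted in the log), reporting homozygotes and same-gene het
pairs.

The panel scan ignores haplotype sharing.  PTVs in the six high-risk
genes (BRCA1, BRCA2, PALB2, TP53, PTEN, CDH1) pass at ≤0.1%, in the two
moderate-risk genes (ATM, CHEK2) at ≤2% — the looser cut-off exists
because real pathogenic founder alleles such as CHEK2 c.1100delC reach
~1% in some populations.  Missense variants in any panel gene pass
below 2% when CADD > 20 or the gene has level-1/2 (including syndromic
high-risk) evidence.  The default panel has 35 genes; only the eight
named above carry a fixed tier, the rest are a representative,
explicitly user-replaceable membership (`GenePanel.from_tsv`), since no
canonical public list pins down the remainder.

## Polygenic risk score

PRS_j = Σ_i n_ij ln OR_i over the SNP panel (160 by default).  Scores
are normalized by the control mean and sample SD; the odds ratio per SD
is exp of the slope of a Newton-fitted univariate logistic regression
(statsmodels) with Wald CI, complete separation raising instead of
returning a degenerate estimate.  Group comparisons use Welch's
two-sample t-test with Welch–Satterthwaite degrees of freedom.  A group
with mean normalized score m has mean-equivalent odds ratio
(OR/SD)^m; report rounding is two decimals for means and ORs and two
significant figures for p-values.  Missing dosages fail by default or,
on request, impute the panel expectation 2p_i; fractional (imputed)
dosages are accepted as input.

## Synthetic data generators

The generators define the study conditions under which the pipeline is
tested; they are first-class, seeded, and bit-reproducible.

**Sibship genotypes.**  Defaults emulate a genome-wide linkage panel:
6,000 biallelic markers over 22 autosomes, 0.6 cM spacing (1 Mb per cM
physically), counted-allele frequencies uniform on (0.2, 0.5), 2–4
affected sibs, per-genotype error 0.005.  Parents are drawn under HWE
and never emitted (the study design has no parental DNA); sibs receive
Haldane-recombinant haplotypes; truth IBD per pair per marker is the
number of parents transmitting identical haplotype copies, stored in
fields the estimation pipeline never reads.  Genotype errors replace
the true genotype with a uniformly chosen different one — the simplest
model that stresses the HMM's error handling.  No linkage
disequilibrium, mutation, or sex-specific maps are simulated.

**Exome tables.**  Decoys (default 1,500 — of the order of the
in-region variant counts the filter actually confronts, far below a
full exome, keeping repeated-seed tests cheap) are placed uniformly on
the marker scaffold with log-uniform allele frequencies on (1e-4, 0.5),
class frequencies weighted toward missense/synonymous (8% PTV),
HWE-conditional genotypes given that the proband carries the allele,
per-database presence probability 0.8 with log-normal jitter, and
class-appropriate in-silico scores.  Genes are deterministic 100-kb
positional bins, allowing occasional same-gene decoy pairs.  Planted
candidates (homozygous PTV, PTV+missense compound het, homozygous
missense) are positioned in the central half of the *longest* truth
IBD2-shared span — where a genuinely co-segregating recessive allele
would sit, flanked by supporting markers — with genotypes consistent
with the mechanism in every sib; planting fails loudly when no shared
span exists.  Decoy realism is deliberately limited: no LD with the
markers, no gene-length variation, no annotation errors.

**PRS cohorts.**  Panel ORs uniform on (1.05, 1.3) and risk-allele
frequencies on (0.1, 0.9).  Affection is Bernoulli with log-odds =
logit(prevalence 0.1) + centred raw PRS + family-shared N(0, 0.8²) +
individual N(0, 0.8²).  No quantitative ascertainment model exists for
"all siblings affected" families, so these liability parameters are
free knobs chosen once to make full-sibship ascertainment feasible
(~10⁻²–10⁻³ per family) while producing the qualitative enrichment
ordering controls < population cases < ascertained affected sibs; they
are not estimates of breast-cancer epidemiology, and the per-SD effect
they imply is larger than in real cohorts.  Tests therefore assert the
ordering and estimator calibration, never specific cohort means.

## Numerical choices and degenerate inputs

Forward–backward uses per-marker scaling (no log-space needed at these
lengths); posterior triples renormalize to 1 within 1e-9.  Calibration
with min_fraction = 0 reports the threshold just below 1; degenerate
all-zero posteriors raise.  Empty region sets produce header-only BED
files; empty variant tables flow through the cascade as empty results.
Welch's test refuses only when both groups are constant.  Logistic
fitting uses Newton iterations with tolerance 1e-10 and raises on
non-convergence or separation.  All simulation seeds derive from numpy
`SeedSequence` spawning, so per-family streams are independent and
reproducible.

## Problem sizes used in the checked examples

The test suite and acceptance script size their simulations to what the
statistical claim needs: 200 families per sibship size for sharing
fractions (Monte-Carlo SE well under the 1.5-pp check), 3 families ×
3,000 markers for calibration/coverage properties, 100 exome seeds for
the null false-positive rate, and 100 replicates × 700 per arm for
logistic-regression CI calibration.

## Known limitations

* Pair-wise HMM, not joint multipoint over the full sibship: posteriors
  for k ≥ 3 sibs are combined only through the per-pair call
  conjunction.
* No LD model anywhere; real linkage panels violate marker independence
  mildly, real exomes strongly.
* The default gene panel beyond its eight anchor genes, and the default
  PRS panel, are placeholders to be replaced by study-specific tables.
* The phenocopy mode is limited to one excluded sib, and subsets
  without the sequenced proband are intentionally unavailable.
* Manual inspection steps of real pipelines (alignment review, Sanger
  validation) have no automated counterpart here beyond the filters
  themselves.
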