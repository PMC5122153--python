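# Methods

## The threshold liability model

A binary return-to-estrus record is modeled through an unobserved
Gaussian liability

    U_ijkl = μ + PARITY_i + FARM_j + YM_k + b·AGE_ijkl + a_ijkl + e_ijkl
    Y = 0 if U ≤ t,  Y = 1 if U > t

with `a ~ N(0, A σ²_a)` (A the pedigree numerator matrix), a permanent
environmental effect per cow across her repeated records
(`pe ~ N(0, I σ²_pe)`), and `e ~ N(0, 1)`.  The threshold is fixed at
`t = 0` and the residual variance at 1: in a probit model the location and
scale of the liability are not identified, so μ absorbs location and σ²_e
sets the unit.  All variance components are therefore on the liability
scale and dimensionless; derived parameters are
`h² = σ²_a / σ²_p`, `c² = σ²_pe / σ²_p`, `R = (σ²_a + σ²_pe) / σ²_p` with
`σ²_p = σ²_a + σ²_pe + 1`.

### Gibbs sampler

Each cycle updates, in order: (1) one truncated-normal liability per
record at its current linear predictor; (2) the fixed effects jointly from
their Gaussian full conditional (flat prior, corner-point constraint —
first level of each factor dropped — so the design is full rank); (3) the
breeding values jointly; (4) the permanent environmental effects (diagonal
precision); (5) σ²_a and σ²_pe from scaled-inverse-chi-square full
conditionals with prior ν = −2, S = 0, i.e. flat on the variances.
Defaults are a desk-scale single chain of 11,000 cycles, 1,000 burn-in,
thinning 10 (1,000 stored samples); the production-scale protocol of
110,000/10,000/100 is available through `LiabilityModelSpec`.  Posterior
ratios (h², c², R) are computed per stored sample and then averaged, which
differs from taking ratios of posterior means; the per-sample convention is
the one used throughout.

Two numerical choices matter:

* **Truncated-normal draws** use the one-sided tail inverse-CDF
  `z = −Φ⁻¹((1−u)·Φ(−α))` (upper tail) and `z = Φ⁻¹(u·Φ(α))` (lower tail),
  which is accurate for truncation points out to ~30 residual SD; beyond
  that an exponential tail approximation takes over.  Draws always fall
  strictly on the correct side of the threshold.
* **The joint breeding-value update** has full-conditional precision
  `Z'Z + A⁻¹/σ²_a` in which only σ²_a changes across cycles.  A one-time
  generalized eigendecomposition `Z'Z V = A⁻¹ V Λ` (with `V'A⁻¹V = I`)
  turns every cycle's solve-and-draw into two matrix-vector products, so an
  11,000-cycle chain over ~2,000 animals runs in well under a minute.  As a
  by-product `a'A⁻¹a = w'w` in the rotated basis, which feeds the variance
  update for free.

With continuous (observed-liability) responses and fixed variances the
sampler's posterior means reduce to Henderson's mixed-model-equation
solutions; the test suite verifies this on a small toy against a direct
dense solve.

## Relationship matrices

A is built by the tabular method (`a_ii = 1 + ½·a(s,d)`,
`a_ij = ½(a(j,s) + a(j,d))`, unknown parent = unrelated non-inbred
founder; no unknown-parent groups).  G is VanRaden method 1:
`ZZ' / (2Σp_k(1−p_k))` on sample allele frequencies, missing dosages
mean-imputed per marker, monomorphic markers dropped with a count.  The
centered (not standardized) form was chosen as the common default of
GWAS mixed-model software.

## CNVR construction and the association scan

Same-type overlapping calls are unioned per chromosome; a region needs at
least two distinct carrier animals and a carrier frequency strictly above
the floor (default 1%).  Loss and gain regions are kept separate.
Coordinates are 1-based inclusive; region length is reported as
`end − start` by default because that is the difference convention used in
the source coordinates, while the inclusive convention remains available
(the homology arm below is an inclusive count — the two conventions are
exposed side by side rather than silently reconciled).

The per-region test is the exact GEMMA strategy: rotate the model by the
eigenvectors of G, profile the REML log-likelihood over the variance ratio
δ = σ²_g/σ²_e by a coarse grid plus bounded Brent search on log δ, and test
the carrier effect with a Wald χ²₁ statistic.  Carriers are coded 0/1
because no homozygous deletion carriers are expected or simulated; an
additive 0/1/2 coding is a caller choice.  With an identity kinship the
procedure reduces exactly to ordinary least squares, which the tests
exploit as an independent oracle (statsmodels OLS), and null simulations
with a genomic kinship yield uniform p-values.  λ_GC is the median observed
χ²₁ statistic over 0.4549.

## Deletion characterization

`find_homology_arms` anchors the first and last `anchor_min` bases of a
junction-spanning read in the reference, extends both alignments maximally,
and reports the overlap as the homology arm: for an NAHR deletion the
breakpoint cannot be placed more precisely than an interval of arm length.
The left-most placement convention is used whenever a single coordinate is
required, and the deletion length is the difference of the arm-adjacent end
coordinates.  Arm search requires exact identity; a mismatch inside the
repeat truncates the arm to the longest segment consistent with both flank
alignments, which is also what the brute-force enumeration oracle yields.

Transcript consequences operate on exon interval arithmetic: exons fully
inside the deletion are removed, survivors are spliced in genomic order,
retained introns are inserted at their anatomical position, and the frame
is read off the fused CDS length (protein = CDS/3 − 1 stop).  When the gene
carries its chromosome sequence the fused transcript is translated to place
premature stops; a product below 10% of wild-type length, or loss of the
start codon, is a null allele.  Exons only partially overlapped by a
deletion are kept intact with a warning — the analyzed deletion removes
whole exons, and truncated-exon splicing outcomes are not predictable from
intervals alone.  Protein mass is approximated as 0.111 kDa per residue and
labeled approximate.

qPCR copy number is `2 × 2^(−ΔΔCT)` against a two-copy calibrator, ΔCt
computed per replicate (target − reference co-amplified in the same
reaction, so the estimate is invariant to a constant shift of a sample's Ct
values), and the SEM propagated by the delta method.

## Replication statistics

The genotype contrast on breeding values is a Gaussian identity-link linear
model (LS-means are only standard there, and the response is a continuous
EBV); LS-means average predictions over covariate levels with equal
weights, and the carrier contrast gets a two-sided t-test.  Variance
explained uses `2p(1−p)a²` over the total genetic variance, treating the
carrier-coded effect as the allele-substitution effect since no homozygotes
are observed — flagged in the documentation because with dominance the two
differ.  Two-group comparisons default to Welch; multi-group litter-size
comparisons use Tukey–Kramer (studentized range with unequal-n correction),
which for two groups collapses to the pooled t-test.

## The synthetic cohort generator

The generator's defaults are the study conditions: five return windows
(18–29, 30–60, 61–90, 91–140, 141–285 days after first AI) with at-risk
incidences 23.00%, 21.97%, 16.91%, 8.47%, 3.30%; liability variance
components σ²_a = 0.03, σ²_pe = 0.07, σ²_e = 1 (the 61–90 day window's
values, the row that is internally consistent at two decimals); a
deleted-type CNV at risk-allele frequency 0.024 with homozygous carriers
forbidden (redrawn as heterozygotes, with a count); 63-bp homology arms
flanking a 33,934-bp deletion; and a −0.45 ± 0.2 one-copy log-R-ratio
shift, a common array response to hemizygous loss.  The CNV liability
effect defaults to 0.5 liability SD in the 30–60 day window — large enough
for an ~800-animal scan to reach a Bonferroni threshold with realistic
power, consistent with a region that was detectable genome-wide.  All
randomness flows from one seed through numpy's splittable `SeedSequence`,
one child stream per sub-generator, so every output is byte-reproducible.

**Risk-set rule.**  Whether a cow that returned in an earlier window is
excluded from later windows or coded 0 is not derivable from the window
definitions alone; the generator and `prepare_period_outcomes` exclude her,
because the per-window record counts of the motivating dataset decrease
monotonically, which is what sequential exclusion produces.  The rule is a
single documented choice applied identically on both the simulation and the
analysis side.

**Intercept calibration.**  Each window's μ is set so that
`P(U > 0) = target` using the total marginal liability SD, including the
variance contributed by the factor-level effects and the age covariate.
The calibration is exact in expectation over the level-effect draws; with
only a handful of levels per factor (2–12), the realized level effects of
one cohort shift its incidence by a point or two, which is visible — and
intended — as between-cohort variation.  Calibration tests therefore run
with level-effect SDs at zero.

**What the generator does not emulate.**  SNP genotypes are independent HWE
draws: no linkage disequilibrium, no pedigree transmission, no minor-allele
spectrum matching a real array.  CNV carrier status is assigned
independently of the pedigree.  Liabilities are exactly Gaussian and
windows share no residual dependence beyond the animal effects.  Passing
tests on these cohorts therefore demonstrates correctness of the estimators
under the model's own assumptions — not robustness to stratification,
genotyping error, or non-Gaussian liability, none of which are claimed.

## Problem sizes and degenerate inputs

Parameter-recovery runs use 1,500 recorded cows (three records each) in
half/full-sib families from 50 sires and 300 dams — enough family
structure to separate σ²_a from σ²_pe, which an unrelated (identity-A)
cohort cannot do: with A = I only the sum σ²_a + σ²_pe is identified and
the split between them mixes slowly.  The matched null in the acceptance
script uses the same design with σ²_a = σ²_pe = 0 for that reason.
Degenerate inputs are rejected loudly: empty chains, monomorphic
predictors or genotype vectors, non-positive-definite relationship
matrices, pedigree cycles (named), inverted intervals, aliased covariates
(named), and zero-variance groups in t-tests.  Variance draws are floored
at 1e−10 to keep precisions finite; diverging liabilities abort the chain
with diagnostics rather than returning garbage.

## Known limitations

Single-trait, single-chain only; no REML alternative to the Bayesian fit;
no sire models or unknown-parent groups; dense linear algebra throughout
(fine to a few thousand animals, not a national evaluation); the LMM scan
profiles one variance ratio and does not handle multiple random effects;
the arm finder assumes the junction read anchors uniquely and exactly, with
no edit-tolerant mode for sequencing error.
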