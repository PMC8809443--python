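# Methods

`redking` re-implements, as a reusable and testable pipeline, a
comparative molecular-evolution analysis contrasting a lichenized fungal
clade with its non-lichenized sister clade: are lichen mycobionts evolving
more slowly genome-wide (a "Red King" pattern)?  The pipeline takes
per-gene codon-aware alignments and a constrained two-clade topology, fits
maximum-likelihood substitution models per gene, converts fitted trees
into clade-level rates, and compares the paired per-gene rate
distributions.

## Models

**Nucleotide.**  General time-reversible model (GTR/REV) with
discrete-gamma among-site rate variation.  The generator is
`q_ij = s_ij * pi_j` for `i != j`, with six symmetric exchangeabilities
(GT fixed at 1) and base frequencies taken from the observed data,
scaled so branch lengths are expected substitutions per site.  Rate
heterogeneity uses ten equal-probability gamma categories whose rates are
the bin means of the Gamma(alpha, alpha) density (mean exactly 1); alpha
is estimated by ML.

**Amino acid.**  An empirical reversible model whose exchangeabilities are
derived from the BLOSUM62 log-odds matrix: scores are half-bit log-odds
`S_ij = 2 log2(q_ij / p_i p_j)`, so `2^(S_ij/2)` recovers the
target/background odds ratio, which serves as the symmetric
exchangeability; stationary frequencies are observed from each alignment
("+F").  No gamma mixture is applied to amino-acid fits.  Because the
published BLOSUM62 scores are integer-rounded log-odds, this matrix is a
coarser relative of rate matrices estimated directly from alignment
databases; for branch-length estimation on a fixed topology the difference
is immaterial.

**Codon.**  GY94-type 61-state model: single-nucleotide codon moves occur
at rate proportional to the target codon's stationary frequency, times
kappa for transitions and omega for non-synonymous changes.  Stationary
frequencies are F3X4 (position-specific nucleotide frequencies multiplied
per codon, stops removed, renormalized) estimated per gene and held fixed;
kappa is estimated by ML.  Codon branch lengths are expected substitutions
per codon.  The branch-model menu assigns omega per branch class:

* `CODON_M0` — one omega for the whole tree;
* `CODON_B2` — both study clades share one omega, the outgroup has another;
* `CODON_B3` — lichenized / non-lichenized / outgroup each get an omega;
* `CODON_FB` — free-ratio, one omega per branch.

Branch classes are defined by subtree membership relative to the basal
trifurcation; each clade's stem branch belongs to its clade's class.  In
the branch models each class generator is normalized to one expected
substitution per codon, so a branch length means the same thing in every
omega class; the simulator and the estimator share the convention.

**Branch-site.**  Model A mixture over four site classes — 0 (omega0
everywhere), 1 (neutral everywhere), 2a (background omega0, foreground
omega2) and 2b (background neutral, foreground omega2) — with proportions
(p0, p1, and the remainder split p0:p1).  The alternative model bounds
omega2 >= 1; the null fixes omega2 = 1.  Site classes are independent
across codon columns.  Unlike the branch models, the site classes of a
branch share one mixture-averaged rate scale (foreground and background
each have their own): normalizing every class separately would cancel the
elevated substitution rate that a positively selected site class is
supposed to produce, destroying the power of the bsA-vs-bsA1 test.  The
simulator uses the identical convention.  The foreground description in the source analysis
("a fraction of sites with omega > 0") is treated as the conventional
omega > 1 parameterisation — the only reading under which the null/
alternative pair is a test of positive selection.

## Likelihood and optimization

Likelihoods use the pruning algorithm on the unrooted topology with the
virtual root at the basal trifurcation (for reversible models the
placement is irrelevant; the suite checks this).  Site patterns are
compressed; per-pattern max-scaling with log accumulators prevents
underflow; gaps and IUPAC ambiguity codes enter as partial-observation
vectors (ambiguous sites are retained, not cleaned).  Transition matrices
come from the symmetrized eigendecomposition of the reversible generator.
Mixtures (gamma categories, branch-site classes) are pruned in one batched
pass and combined per pattern by logsumexp.

All fits keep the topology fixed and maximize branch lengths and global
parameters jointly with L-BFGS-B on transformed parameters: log for
positives (branch lengths bounded [1e-8, 50], omega [1e-6, 999], kappa
[1e-3, 100], alpha [0.02, 100]), logit for omega0 in (0, 1), a softmax
pair for (p0, p1), and log(omega2 - 1) for the bounded-below foreground
omega.  The default multi-start policy is three starts (a pairwise-
mismatch heuristic for branch lengths, a fixed alternative, and a seeded
random start); calibration experiments use one start for speed.  Nested
fits are warm-started from the restricted optimum, which both speeds
convergence and enforces the nesting inequality; `fit_nested` escalates
restarts if an optimizer artefact ever leaves the general model below the
restricted one (violations beyond 2e-4 in the LRT statistic raise rather
than being silently clamped).

## Clade rates, dN/dS and filters

The clade rate of a fitted tree is the tip-to-root statistic: the mean
over the clade's tips of the summed branch lengths from tip to the
clade's MRCA (defined relative to the basal trifurcation; stems excluded).
Because each path spans the same timespan, sister clades can be compared
without calibrating absolute rates, and equal tip counts keep the
comparison balanced.

Per-branch dN and dS are obtained by partitioning each branch's fitted
generator flow into synonymous and non-synonymous components and dividing
the expected counts by mutational-opportunity site counts computed from
the neutral (omega = 1) version of the same process; omega = dN/dS, with
an infinite sentinel when dS = 0.  Clade dN and dS aggregate per-branch
values tip-to-root exactly like branch lengths; clade omega is the ratio
of aggregated dN to aggregated dS (robust to near-zero branch dS; a
mean-of-branch-ratios mode is available).

Two filters reproduce the study's gene selection: a length filter keeping
genes with >= 300 codons (>= 900 nt; a strict-greater flag is available —
the verbal rule "longer than 900 bp (300 codons)" is internally
inconsistent, and the inclusive boundary is the documented default), and
the strict saturation filter retaining genes whose clade-level dS <= 3 and
omega <= 10 in every compared clade (both boundaries inclusive).

## Statistics

Paired comparisons use the Wilcoxon matched-pairs signed-rank test:
differences paired by gene, zeros dropped (count reported; a Pratt mode
exists), midranks for ties, W = min(W+, W-).  For n <= 25 non-zero pairs
the exact two-sided p is computed by convolution of the signed-rank
generating polynomial (valid under ties); above that, a normal
approximation with tie-corrected variance (sum r_i^2 / 4) and continuity
correction.  Median confidence intervals are distribution-free
order-statistic intervals from the Binomial(n, 1/2) distribution — the
smallest symmetric pair with coverage >= 95%.  Nested models are compared
by likelihood-ratio tests against the chi-square upper tail (degrees of
freedom = parameter-count difference; p < .01 for branch models, p < .05
for branch-site screening, following the study's thresholds; no
multiple-testing correction by default).  Normality is screened with the
D'Agostino–Pearson omnibus test.  The branch-site screen classifies
significant genes by whether the fitted foreground omega2 exceeds a small
neutral boundary (positive selection vs neutral-fraction rejections) and
marks genes significant for exactly one foreground as exclusive;
`background_consistency` reports Jaccard overlap between screens run with
different backgrounds.

## Synthetic data

The generator emulates the study design: a pectinate lichenized clade and
an equal-sized pectinate sister clade joined with an outgroup tip at a
basal trifurcation.  Branch lengths are drawn iid Exponential (default
mean 0.1 substitutions/site, the scale of the constrained study trees).
In the balanced (equal-tip-count) design the lichenized clade mirrors its
sister's draws branch-for-branch before the clade-rate multiplier is
applied.  This mirroring is deliberate: with fully independent draws the
sign of the realized clade-rate difference of a whole replicate is set by
a single random tree draw, so no multiplier short of extreme values could
yield reliable detection; mirroring makes the multiplier the only
systematic difference between clades, so a multiplier of 0.7 means the
lichenized clade is exactly 30% slower in expectation and a multiplier of
1.0 is an exact null.  Gene sets share one topology; per-gene rate spread
is a mean-preserving lognormal rescaling of all branch lengths
(sigma = 0.3, a moderate gene-to-gene spread chosen once — the source
data report no per-gene dispersion).  Gene lengths are uniform within
±25% of the requested mean.  Per-gene RNG streams derive from the root
seed by a fixed splitting rule recorded in the truth table.

What the generator does **not** emulate: indels and alignment error
(alignments are ungapped), assembly/annotation artefacts, among-gene
topology variation, GC-content heterogeneity between clades, and
selection regimes beyond the branch and branch-site models.  Passing
tests therefore demonstrate correctness of the estimators and statistics
under the generating models, not robustness to real-data pathologies.

## Numerical choices and problem sizes

Tolerances: optimizer convergence at L-BFGS-B defaults (relative lnL
reduction ~2e-9); nesting tolerance 1e-4 lnL units; dS = 0 yields an
omega sentinel flagged for the saturation filter; F3X4 and observed
frequencies are floored at 1e-6 and renormalized to keep generators
irreducible.  Degenerate inputs (all-identical sequences, zero-length
branches, all-zero differences) are exercised in the suite.

The validation suite runs at desk scale: parameter recovery on
5000-column alignments on a deterministic 5-tip tree with all branches at
0.2 (identifiable for every branch class, unlike an unlucky random draw);
LRT calibration on 40–60 null genes of 200 codons with two-sided
Monte-Carlo bands of 2 binomial SEs; end-to-end recovery on replicate
12–20-gene sets.  The acceptance script analyses a 40-gene nucleotide set
on the full 5+5+1 design and 10–12-gene codon and branch-site sets on a
3+3+1 design.  These sizes were chosen as the smallest at which the
checked properties are statistically meaningful.

## Known limitations

* No codon-model among-site rate variation outside the branch-site
  mixture; no clock models; no topology search.
* Equivalence with other ML implementations holds only to optimizer
  tolerance; initial-value behaviour of other packages is not reproduced.
* The branch-site LRT at the omega2 = 1 boundary is conservative when
  referred to chi-square(1), as in the original analysis.
* Exact reproduction of published confidence intervals is not promised:
  the original CI method is unstated, and the order-statistic method here
  is an assumption-light default.
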