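# Methods

This note records the models and procedures `hemix` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that were genuinely
open.

## Coverage-based X-linkage classification

**Model.** In a male-heterogametic species with a degenerate or absent Y,
X-derived scaffolds receive male genomic coverage at half the autosomal
rate, while female coverage is unaffected. Per-scaffold log2(M/F
coverage) is therefore a two-component mixture: an autosomal component
centred at some value `A_median` (0 plus any global male/female
sequencing-depth offset) and an X component centred at `A_median − 1`.

**Procedure.** A histogram with bins of `bin_width` (default 0.05 log2
units; no canonical value exists, 0.05 resolves the two modes at a few
hundred scaffolds and is exposed as a parameter) is laid over the finite
ratios; `A_median` is the centre of the fullest bin, and scaffolds
strictly below `A_median − 0.5` — halfway between the modes — are called
X-linked. No explicit library-size normalization is applied: centring the
threshold on the empirical mode absorbs global depth differences, which
is the point of using the mode rather than an absolute cutoff.

Numerical details:

- Bin edges sit on a fixed lattice anchored at 0, so shifting all ratios
  by a constant shifts `A_median` by the same amount (± one bin) and
  leaves every classification unchanged.
- Ties between maximal bins are broken toward the bin centre nearest 0
  (autosomes dominate the genome), with a warning. Ties are common with
  symmetric noise and are harmless: the tying bins are adjacent in
  practice.
- A ratio exactly equal to the threshold is autosomal ("less than" is
  strict). In the stringent variant with margin 0 the same value falls in
  the (degenerate) exclusion band and is excluded; this inconsistency is
  deliberate — each rule is the natural reading of its own definition —
  and affects a measure-zero set.
- Scaffolds with zero coverage in either sex carry no ratio and are
  excluded everywhere downstream; genes on excluded or uncalled scaffolds
  are excluded from every X/A contrast.
- Fewer than 2 finite ratios is an error, not a guess.
- The mode is fitted on scaffold-level ratios by default; an option
  weights each scaffold by its gene count instead (the natural choice
  when the histogram is conceptually over genes). On the synthetic data
  the two differ negligibly because scaffolds are linkage-pure.
- Y-linked scaffolds are not separately modelled: with a degenerate Y
  they surface as excluded (zero female coverage) or as extreme-positive
  ratios, which the threshold rule files under autosomal. This is a known
  limitation, acceptable because every downstream contrast only needs
  X vs not-X.

**Stringent variant.** `stringent_classify` excludes a band of half-width
`margin` around the threshold, removing intermediate-coverage scaffolds
most at risk of misclassification. No canonical margin exists; it is
user-set.

**Marker-based assignment.** When a species has published X-linked and
autosomal markers, scaffolds are assigned by mapping the marker primers:
for each marker, candidate scaffolds are those hit by *both* the forward
and reverse primer, and the candidate with the lowest combined e-value
wins. "Combined" is the sum of the per-end best e-values — the published
procedure says only "lowest e-value" for multi-hit markers, and summing
is the simplest symmetric combination; exact ties make the marker
ambiguous and it is skipped with a warning, as are markers hit by one
primer end only. Scaffolds supported by markers of conflicting classes
are reported and left unassigned.

## Dosage compensation

Only genes with FPKM strictly above 1 in both sexes enter any statistic;
FPKM values are consumed as produced upstream (already length- and
library-normalized) and never renormalized here.

`M/F_X` and `M/F_A` are medians of per-gene male/female ratios, computed
as `2^median(log2 M/F)`. The aggregation is not canonically defined;
medians match what boxplot-style displays of these data show and are
robust to the long tails of expression ratios, and means are exposed as
an option. The compensation statistic is `dc_ratio = (M/F_X)/(M/F_A)`:
≈ 1 under full chromosome-wide compensation, ≈ 0.5 under none, with
0.5–0.8 the empirical range of uncompensated systems.

Location tests (female expression, male expression, log2 M/F; X vs
autosomes) are two-sided Wilcoxon rank-sum tests: exact null enumeration
when both groups have ≤ 20 values and no ties, otherwise the normal
approximation with tie and continuity correction (scipy's
implementation). The exact/asymptotic switch at 20 keeps small-group
p-values exact where enumeration is cheap. Note the normal approximation
is accurate to a few percent for p-values in the decision range but
degrades in relative terms for p ≪ 0.01 — immaterial for significance
calls at α = 0.05. Bonferroni correction defaults to m = the number of
contrasts executed together (3 per species in the standard run) and is
configurable; `p_adj = min(1, m·p)`.

Identical values across both groups give p = 1 with a warning rather
than an error: a degenerate but interpretable input.

## Sex-biased genes

A gene is male-biased iff its DE p-value is strictly below α = 0.05 with
male FPKM > female FPKM, female-biased with the reverse inequality, and
unbiased otherwise (including missing p-values and the
synthetic-data-only case of a significant p with exactly equal FPKM,
which is logged). DE p-values are inputs: the package deliberately ships
no differential-expression test, so that upstream engines' p-values (or
simulated ones) pass through unchanged, and no fallback test on raw FPKM
is offered that would misrepresent the method.

X-vs-autosome proportion comparisons use the 2×2 chi-square with Yates'
continuity correction: `chi2 = Σ max(|O−E|−0.5, 0)²/E`, p from χ²(1).
The truncation at zero (standard) makes perfectly proportional tables
score exactly 0. A zero margin is an error. The proportion tests use the
FPKM-filtered gene set, consistent with every other expression analysis,
and are reported without multiple-testing correction (each is a
single-species, single-class question).

## Orthology and X conservation

Hits below score 50 are discarded (boundary inclusive: "minimum score of
50" read as ≥ 50; both the cutoff and strictness are options). Repeated
hits to one target collapse to the max-scoring one; a query whose top two
targets tie has no best hit and drops out of RBH entirely (the
conservative reading of "best"), with an optional e-value tie-break.
A pair (a, b) is kept iff each is the other's unique best hit. Pairs
between two non-reference species are extrapolated through the reference:
a and b are paired iff both are RBH partners of the same reference gene,
which is 1:1 by construction.

For each species pair, orthologs lacking an X/autosome call in either
species are dropped; the remaining `n` pairs give the 2×2 table of
linkage classes. The expected doubly-X count under independent linkage
is `x1·x2/n`; `ratio = obs/exp` > 1 indicates shared X content, < 1 a
deficit suggesting turnover. Significance:

- Yates chi-square on the 2×2 table (conservative for small expected
  counts), and
- a Monte Carlo permutation test: species 2's linkage labels are
  shuffled across the n pairs, preserving both species' X fractions and
  n, so the null distribution of the doubly-X count is exactly
  hypergeometric (which the tests verify against the closed form).
  Permutation rather than, say, binomial resampling was chosen precisely
  because it conditions on both margins. Empirical tails use the add-one
  correction `(b+1)/(reps+1)` so p is never 0, and the two-sided p
  doubles the smaller tail, capped at 1 — both excesses and deficits are
  of interest. Default 10,000 replicates; the seed is a required
  argument, never implicit.

## The synthetic-data generator

`hemix.simulate` emulates the pipeline's inputs at the summary-table
level with known truth. Defaults are the study conditions used by the
analysis scripts and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| `x_fraction` | 0.10 | hemipteran X chromosomes carry ~8–13% of genes |
| `coverage_depth` | 30 | typical resequencing depth |
| `coverage_noise_sd` | 0.15 log2 | per-scaffold depth dispersion of real mappings |
| `zero_coverage_fraction` | 0.01 | exercises the exclusion path |
| `compensation_level` | 0.9 | within the observed range (0.83–1.02) of compensated species |
| `base_log2_fpkm` | N(3, 1.5) | log-normal FPKM spanning ~4 orders of magnitude; puts ~2% of genes per sex under the FPKM>1 filter |
| `expression_noise_sd` | 0.25 log2 | between-sex biological + estimation noise |
| bias probabilities | X: 4% male / 10% female; A: 8% / 8% | a feminized-X regime of realistic magnitude |
| `bias_effect_log2` | 2.0 | 4-fold shifts, typical of confidently called sex-biased genes |
| `conservation_rho` | 1.0 | same X unless the scenario says otherwise |
| `rbh_noise` | 0.02 | a few percent of orthologs lost to spurious best hits |

Mechanics: scaffold labels are Bernoulli(`x_fraction`); female log2
coverage is Normal(log2 depth, sd) and male adds an independent
Normal(0, sd) plus −1 on the X — so the log2 ratio has sd equal to
`coverage_noise_sd` exactly. Gene linkage conservation operates at the
ortholog-group level: species k copies the reference's label with
probability ρ_k, else redraws at `x_fraction`; scaffolds are then built
per species by grouping same-label genes (sizes 1 + Poisson). Expression
applies the compensation shift `log2(c)` to every X-linked gene's male
value (a chromosome-wide mechanism) with bias effects on top. DE
p-values are *simulated*, not computed — Uniform(0,1) for unbiased
genes, Beta(0.1, 1) for biased ones — because the pipeline consumes
p-values rather than producing them; the Beta/Uniform mixture gives a
controllable confusion structure (≈ 74% of biased genes land below
0.05, and 5% of unbiased ones).

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: read-level artefacts
(mapping bias, multi-mapping, GC effects), assembly errors (chimeric
scaffolds mixing X and autosomal sequence — synthetic scaffolds are
linkage-pure), pseudoautosomal regions (which real coverage
classification files under autosomal), correlated expression noise
between the sexes, paralogy and gene-family structure in the hit tables,
and any real DE engine's p-value behaviour. Results on synthetic data
certify the statistics and the plumbing, not robustness to those
artefacts.

## Problem sizes

The default study runs 4 species × ~5,000 genes (~500 scaffolds each).
Parameter-recovery checks use 100 replicates of 2,000 scaffolds per X
fraction (classification), 20 replicates of 5,000 genes per compensation
level (dosage; bias probabilities set to 0 to isolate the statistic),
200,000 permutation replicates for the null-distribution check and 200
seeds × 999 replicates for p-value calibration, and 20 end-to-end runs
of ~2,000-gene 4-species studies for the conservation pattern. These
sizes put Monte Carlo error comfortably inside each tolerance while the
full suite runs in under a minute.

## Known limitations

- The histogram-mode fit is deliberately simple (no mixture-model/EM
  fitting); at high coverage noise (sd ≳ 0.2 log2) the mode jitters by a
  bin or two, which is why the stringent variant exists.
- Marker-based assignment trusts the marker classes; conflicting markers
  silence a scaffold rather than voting.
- RBH extrapolation through a reference cannot pair genes the reference
  has lost.
- Whole-body expression conflates tissue composition with regulation;
  nothing here decomposes tissues.
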