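# Methods

## Data model

Genotypes are dosages of a designated ALT allele (0/1/2) in a samples ×
markers matrix with a boolean missing mask; no sentinel values live in the
dosage matrix. With this coding every downstream statistic reduces to
arithmetic on `p = Σ dosage / (2 · n_called)`. Map coordinates are genetic
(cM) throughout, so no 0/1-based ambiguity arises. Slash-joined gene names
("eps2/HvHOX2/...") are single catalog entries: one mapped genetic factor.

## Marker QC

Markers are removed when call rate or MAF is *strictly below* the
threshold (defaults 0.95 and 0.05); equality passes. Tools differ on this
boundary, so it is pinned and tested. Call rate is evaluated before MAF
purely for reason attribution — the kept set is identical either way.
MAF is computed over all samples jointly (a panel-level gate, not a
per-group one), and markers with zero calls get their own reason code.

## Diversity indices

Per locus with frequencies {p, q}: `Na` counts observed alleles, `Ne =
1/(p²+q²)`, `I = −(p ln p + q ln q)` with `0·ln 0 := 0`, `h = 1−(p²+q²)`,
`uh = n/(n−1)·h` where n is the number of called *individuals* at the
locus, not chromosomes. The individuals-based correction is the one that
reproduces published group tables from (h, n) pairs at 3 decimals; it is
exact per locus, and exact for group means only when no calls are missing
(the group-mean shortcut `uh ≈ n/(n−1)·mean(h)` drifts with per-locus
missingness, which is why some published rows with missing data deviate in
the third decimal). Group summaries report mean ± SE with SE = sd/√L over
loci (sample sd, ddof = 1); %P uses loci with ≥ 1 call as denominator. A
single-member group has uh undefined (NaN) at every locus. Reports are
rounded to 3 decimals; internal math is full precision.

## Nei genetic distance

Per locus, gene identities `Jx = p²+q²`, `Jy` likewise and `Jxy = p_x p_y +
q_x q_y` are averaged over loci shared by both groups before taking
`D = −ln(mean Jxy / √(mean Jx · mean Jy))`. The unbiased variant
substitutes `(2nJ − 1)/(2n − 1)` per locus with the per-locus call count.
Rounding can push the identity ratio above 1; D is clamped at 0. A
non-positive ratio (possible only for pathological profiles such as
disjoint fixed alleles everywhere) is an error naming the pair. The
pipeline default is the unbiased variant — a package choice; both variants
are exposed.

## Ordination and trees

Individual distances are `1 − IBS`, with IBS the mean over jointly called
loci of `(2 − |g_i − g_j|)/2`. This is the natural phase-free similarity
for dosage data; the choice is recorded because distance-based tree tools
do not all agree on it.

PCoA is the Gower construction: eigendecomposition of `−½ J (D∘D) J`.
Coordinates use positive eigenvalues only; percent variance per axis is
the share of the positive-eigenvalue sum; the total magnitude of negative
eigenvalues (non-Euclidean input) is kept as a diagnostic. Eigenvector
signs are fixed by making the first nonzero loading positive so repeated
runs and label permutations give reproducible outputs. When the input is
Euclidean-embeddable the coordinate distances reproduce D exactly.

Neighbor joining follows the Saitou–Nei Q-criterion with branch lengths
from the standard formulas; Q-ties break at the smallest (row, column)
pair, and negative branch lengths are clamped to 0. On additive matrices
the tree's path-length matrix equals the input to numerical precision
(this is the oracle the tests use). No numeric identity with any specific
GUI tool's tree or ordination is claimed — those tools do not document
their exact conventions.

## Admixture and Evanno ΔK

The clustering model is the standard admixture likelihood `g_il ~
Binomial(2, Σ_k q_ik f_kl)`, fitted by EM rather than MCMC: responsibilities
split each allele copy between ancestral populations, then Q rows and F are
re-estimated from the expected counts. Missing genotypes are skipped in the
likelihood; the constant binomial coefficient is omitted. F is clamped to
[1e−6, 1−1e−6] to keep the likelihood finite. The log-likelihood is
nondecreasing by construction and asserted so in tests. Initialization: Q
rows from Dirichlet(1), F from overall frequencies jittered by ±0.05; 5
random restarts by default keep the best likelihood. EM is deterministic
given a seed, which is what a tested pipeline needs; it shares the
likelihood but not the priors of Bayesian samplers, so cluster memberships
are comparable, posterior spreads are not.

Evanno's ΔK uses replicate fits (single-start EMs with distinct derived
seeds) per K: the per-replicate second difference `|L_r(K+1) − 2L_r(K) +
L_r(K−1)|` is averaged and divided by the *sample* standard deviation of
L_r(K). ΔK is undefined at boundary K and where sd = 0 (flagged, never
selected). Selected K is the argmax of ΔK; a Thorndike-style elbow (first K
whose ΔK exceeds all later ones) is reported alongside, and when no ΔK is
defined the selector falls back to the curvature elbow and flags the result
ambiguous. ΔK is invariant to adding a constant to all log-likelihoods.

## LD decay

r² is the squared Pearson correlation of dosage vectors over jointly
called samples — the composite measure appropriate to unphased array
calls — restricted to same-chromosome pairs within `max_dist_cM` (default
50). Pairs with fewer than 10 shared calls or zero variance are skipped and
counted. The decay curve is the binned mean (default bin width 0.25 cM);
the threshold crossing interpolates linearly between the last bin center
at/above the threshold and the first below, scanning outward from zero and
skipping empty bins; a curve that never falls below returns +inf. The
2.5 cM gene-linkage window is also accepted directly as a configuration
constant so mining does not require an LD run.

## Opposite-allele-dominance mining

A marker is selected iff some allele has `f_focal > T` and
`f_contrast < 1 − T` (strict) or `≥ / ≤` (non-strict); both ALT and REF are
tested, so selection is invariant to allele coding. Defaults follow the
wording conventions of the two rules the scan implements: strict for
"more than 50%" (T = 0.5) and non-strict for "at least 65%" (T = 0.65);
the flag exists because such wordings are often inconsistent, and both
behaviors are tested at the exact boundary. Frequencies are compared
directly — no significance test or sample-size weighting; the procedure is
a pure threshold rule. Gene linkage keeps every (SNP, gene) pair on the
same chromosome within the window; summaries report distinct linked SNPs,
distinct linked genes, and total pairs, so either counting convention can
be read off. Contrasting one group against two others is expressed as two
scans plus an intersection (order-stable on the first table); no three-way
rule is invented.

## Synthetic panels

The generator is Balding–Nichols: ancestral `p ~ U(0.05, 0.95)` per
marker, group frequencies `Beta(p(1−F)/F, (1−p)(1−F)/F)` with one F per
group, genotypes `Binomial(2, QF)`, missingness i.i.d. Bernoulli, uniform
map positions over 7 chromosomes of 150 cM (the barley karyotype) by
default. Defaults (2 groups × 30 samples, 600 markers, F = 0.2) are the
desk-scale shape of an array-genotyped breeding panel. Ancestry rows are
one-hot unless an admixture concentration α > 0 draws them from a
Dirichlet with the nominal group kept dominant.

Planted adaptation loci are moved to within 0.8× the window of chosen
catalog genes and given fixed opposite frequencies (default 0.9/0.1) in
the focal and contrast groups; an equal number of decoys get the same
frequencies but sit beyond 1.2× the window from every gene, probing both
sides of the linkage boundary. Planted loci are fully called so they
always survive the QC gate. While planting, background loci in the
focal/contrast pair are redrawn until `|f_focal − f_contrast| ≤ 0.2`: since
the dominance rule at T ≥ 0.6 requires a frequency gap > 0.2, the scan
then separates planted from background *exactly at the true-frequency
level*, which is what the planted-truth tests assert. Empirical frequencies
from finite samples add binomial noise that can push background loci past
the threshold at any sample size, so genotype-level checks assert full
recovery of planted loci without requiring zero background hits.

The LD generator is a separate Markov copy process over two haplotypes per
sample: marker j copies marker j−1 with probability `exp(−Δd/scale)`, so
dosage correlation decays as `exp(−d/scale)` and r² as `exp(−2d/scale)`;
`decay_scale_for_crossing` inverts that for a target threshold crossing.
The estimated crossing sits slightly above the target because the sample
r² of independent markers has expectation ≈ 1/n, lifting the curve's tail;
at n = 200 the bias is a few hundredths of a cM, inside the tolerance the
tests use (±0.5 cM). What these panels do not emulate: real barley LD maps,
coalescent genealogies, selfing, pedigree structure, or genotyping-error
patterns of array chemistry — so passing tests demonstrate correctness of
the statistics, not realism of any particular barley dataset.

## Pipeline

Stages run in the fixed order qc → diversity → distance → pcoa → nj →
admixture → ld → mining → intersections; each writes TSV/JSON/Newick plus
a manifest with counts and the seed. The global seed fans out as
`stage_seed = (seed · 1000003 + stage_index) mod 2³¹`, so stages rerun in
isolation reproduce the pipeline run. A stage failure aborts with the
stage name after writing the partial manifest.

## Problem sizes and tolerances in the test suite

Parameter-recovery checks use panels of 60 samples × 300–500 markers
(admixture RMSE ≤ 0.1 at F = 0.3; Evanno hit rate over 10 trials with
K* ∈ {2,3}; Nei-D vs F_ST Spearman > 0.9 over 5 levels), mining uses 10
seeds of 400-marker panels with 12 planted + 12 decoy loci, and the LD
crossing uses 200 samples × 400 markers per seed — sizes chosen so the
whole suite runs in well under a minute per module while the statistics
being tested are far from their noise floors. EM convergence: stop at
log-likelihood gain < 1e−5 (1e−4 for replicate tables) or 500 iterations.

## Known limitations

Biallelic loci only; no AMOVA or F-statistics beyond what the recovery
tests need; no haplotype-based D′/r²; EM can hit local optima (mitigated by
restarts, not eliminated); the Evanno statistic is undefined when replicate
fits agree to machine precision (flagged rather than silently selected);
and the simulator's exactness guarantee for mining holds at the
true-frequency level, not for empirical frequencies at small n.
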