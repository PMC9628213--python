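# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot tell you about real 16S studies.

## Data model

The central object is an integer ASV × sample count table with unique IDs
and strictly positive sample totals. Taxonomy is a fixed seven-rank
lineage (kingdom…species); ranks missing from an input lineage receive an
explicit rank-prefixed sentinel (`g__unclassified`), so genus-level
aggregation pools all features unassigned at genus under their parent
lineage — one row per `family;g__unclassified` key, matching the
`Family_unclassified` style common in published tables. Trees are rooted
`skbio.TreeNode` objects; an unrooted Newick input (root with more than
two children) is midpoint-rooted, because UniFrac requires a root and
midpoint rooting is the standard neutral choice when the true root is
unknown.

## Alpha diversity

The estimators follow the mothur conventions, the most common ones in
clinical 16S reports:

- Chao1 uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))` rather
  than the classic `F1²/(2F2)`, which is undefined when doubletons are
  absent.
- ACE uses the rare/abundant split at count 10, sample coverage
  `C = 1 − F1/N_rare`, and the coefficient of variation correction
  `γ² = max(0, (S_rare/C)·Σ i(i−1)Fi / (N_rare(N_rare−1)) − 1)`. When every
  rare individual is a singleton (C = 0) the estimator degenerates and
  Chao1 is returned instead.
- Shannon entropy is in nats; Simpson is reported as the finite-sample
  dominance `D = Σ nᵢ(nᵢ−1)/(N(N−1))` with `1 − D` exposed alongside,
  since both conventions circulate.

No rarefaction is applied before diversity computation by default;
`rarefy` (subsampling without replacement, seeded, shallow samples
dropped) is available when even-depth comparison is wanted. Rarefied
richness is validated against the hypergeometric closed form
`E[S] = Σᵢ (1 − C(N−nᵢ,d)/C(N,d))`.

## Beta diversity and permutation tests

Bray-Curtis and binary Jaccard are computed with scipy's pairwise
distances; UniFrac (unweighted, and the normalised weighted variant) is
delegated to scikit-bio. PCoA is the classical double-centred
eigendecomposition; negative eigenvalues are reported but excluded from
coordinates, and explained proportions are taken over the positive
eigenvalues.

PERMANOVA partitions squared distances into among/within-group sums and
reports the pseudo-F; ANOSIM ranks all pairwise distances (midranks for
ties) and reports `R = (r̄_between − r̄_within)/(M/2)` with
`M = n(n−1)/2`, which is bounded in [−1, 1] and equals 1 under perfect
separation. Both use the `(1+b)/(1+m)` permutation p-value so p is never
zero, and switch to exhaustive enumeration of all distinct label
assignments whenever that count is at most 20,000 — below that bound the
p-value is exact and seed-independent. Both statistics are cross-checked
against scikit-bio's implementations in the test suite.

## Group comparisons and cohort tables

Per-taxon comparisons run on relative abundances by default (published
tables report percentages). The two-group test is Mann-Whitney, exact
when both groups have ≤ 8 observations and no cross-group ties, otherwise
the tie-corrected normal approximation; more than two groups use
Kruskal-Wallis. Raw p-values are reported by default (mirroring common
practice in the field); Benjamini-Hochberg correction is a flag.

Cohort ("Table 1"-style) statistics are reconstructed from printed group
summaries: Welch's unequal-variance t with Welch–Satterthwaite degrees of
freedom (the pooled Student variant is also exposed; on the reference
cohort's BMI row only Welch reproduces the printed p = 0.057), and the
Yates continuity-corrected χ² for 2×2 tables (which reproduces the
printed sex-ratio p = 0.264).

## LDA effect size

The procedure normalises each sample to one million, screens features
with Kruskal-Wallis at α = 0.05 (constant raw features are excluded
outright), and scores survivors over 30 bootstrap subsamples (two-thirds
of each class, drawn with replacement). Each bootstrap fits a
one-component linear discriminant with a ridge-regularised pooled
covariance (ε = 1e-6 × trace), needed because sparse taxa frequently
produce singular within-class covariances; the per-feature effect size
averages the feature's raw class-mean difference with its share
(|w| × axis separation) of the discriminant separation. The final score
is log10 of the bootstrap mean, floored at 0 via `max(effect, 1)`, and
features pass at score ≥ 2.5. With two classes the Kruskal-Wallis screen
coincides with the Wilcoxon rank-sum test; with more classes scoring is
one-against-all and each feature keeps the score of the class it is
enriched in (the class with the larger per-million mean). Subclass-aware
designs are not modelled: with no subclass structure the canonical
within-subclass stage is a no-op.

## Diagnostic marker model

Candidates are ASVs with Mann-Whitney p < 0.05 on relative abundances and
a maximum per-sample relative abundance above 0.1%. Marker selection runs
repeated stratified k-fold cross-validation (default 5 × 5): inside each
training fold a forest ranks the candidates — by out-of-bag mean decrease
in accuracy by default, mean decrease in Gini as an option — and held-out
misclassification is measured along a descending count grid (all
candidates, halving steps, and every count up to 10). Re-ranking inside
each fold avoids selection bias; ties on the error curve resolve to the
smallest count. The final marker list is the top of a full-training-data
ranking at the chosen count.

The forest is a bagging ensemble of CART trees (mtry = ⌊√p⌋, grown to
purity, default 500 trees) built directly on scikit-learn decision trees
so that per-tree votes and out-of-bag masks are accessible: the POD index
needs the per-tree vote split, which packaged forests do not expose. The
POD index is reported both as the literal disease/control vote ratio
(with an ∞ sentinel when no tree votes control) and as the vote fraction
`disease/(disease+control)`; the two are strictly monotone transforms of
each other, so all rank statistics (AUC, Mann-Whitney) use the fraction
and avoid infinities. Training-set POD uses out-of-bag votes because
resubstitution votes from a purity-grown forest are nearly pure and
inflate the training AUC; a resubstitution flag exists. AUC uses the
Mann-Whitney identity with midranks, the 95% CI is DeLong's (validated
against R's pROC), and the group-difference p is a two-sided Mann-Whitney
on the POD values.

## Synthetic data

The generator emulates the shape of a 27 + 27 case-control 16S study:
~976 ASVs, library sizes uniform on 35,925–120,795, a log-normal baseline
composition (log-σ 1.5), and Dirichlet-multinomial counts with
concentration 200 × composition — a moderate overdispersion typical of
stool communities and the standard null model for 16S counts. Five
differential ASVs at fold change 4 are planted by default; they are drawn
from ASVs whose baseline relative abundance is at least 0.1%, since an
effect planted on a vanishingly rare ASV is undetectable at any realistic
depth and the abundance floor matches the candidate filter's own floor.
Taxonomy is a random nested partition (geometric genus sizes, mean ~6
ASVs per genus) and the tree is a random bifurcation with exponential
branch lengths. Covariates are produced by a rank-preserving Gaussian
copula: the realised feature abundances are converted to normal scores
and a covariate is drawn at the Pearson level `2·sin(πρ/6)` needed for a
bivariate normal to hit the requested Spearman ρ.

What the generator does **not** emulate: phylogenetic signal in the
planted effects (differential ASVs are taxonomically random), realistic
taxon co-occurrence networks, zero inflation beyond what the DM model
produces, batch effects, and compositional biases of extraction/PCR.
Passing recovery tests therefore show that the statistics behave
correctly under the stated model, not that any particular real study's
effect sizes are detectable.

## Calibration and recovery suites — problem sizes

The null-calibration and recovery tests run at sizes chosen to exercise
the statistics while keeping the suite quick: PERMANOVA calibration uses
50 replicates of 10 + 10 samples × 80 ASVs at 999 permutations;
Mann-Whitney uniformity uses a denser configuration (120 ASVs, log-σ 0.8,
depths 5,000–10,000) because at the study-scale defaults most ASVs are
rare and their Mann-Whitney null is dominated by zero ties, making
literal p-uniformity a property no implementation could exhibit; the null
and recovery marker models use 100–200 trees with 1–2 CV repeats.
Recovery rates at the full study shape (all five planted ASVs in the
candidate set; ≥ 4/5 planted ASVs among the selected markers in ≥ 80% of
25 seeds; held-out AUC ≥ 0.9 at fold change 6) are asserted in
`tests/test_acceptance.py`.

## Numerical conventions

- Permutation p-values are never 0; exhaustive mode includes the observed
  assignment in the numerator and denominator.
- Statistic comparisons in permutation tests use a 1e-12 slack so ties
  with the observed value count as extreme.
- All randomness flows through `numpy.random.Generator` seeded from
  user-supplied integers; derived seeds come from `SeedSequence.spawn`,
  so identical configs give bit-identical outputs, including the written
  TSVs (hash-checked in the pipeline manifest).
- Degenerate inputs are errors, not silent results: all-zero count
  vectors, zero-total samples, single-class labels, empty candidate sets,
  classes with fewer than three samples in the LDA-effect-size procedure.
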