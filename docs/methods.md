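# Methods

## Problem and model

Public two-condition expression studies (e.g. primary versus metastatic
tumours from different cancer types and laboratories) are individually
under-powered and heterogeneous: platforms measure different gene sets,
sample sizes range from a handful to nearly a hundred, and many genes are
regulated in only one study.  The question this package answers is: which
genes are differentially expressed *consistently*, in the same direction,
across a panel of such studies?

The evidence combined across studies is each study's rank-product false
discovery rate.  For study *i* with *m<sub>i</sub>* cases and
*n<sub>i</sub>* controls, every case–control pair yields a log fold change
per gene; genes are ranked within each of the *H<sub>i</sub> =
m<sub>i</sub>n<sub>i</sub>* comparisons (rank 1 = most extreme in the
tested direction, average ranks on ties, one ranking per direction) and the
rank product is the geometric mean rank

γ̄<sub>gi</sub> = (∏<sub>h</sub> γ<sub>gih</sub>)<sup>1/H<sub>i</sub></sup>.

Label permutations give a pooled null: the p-value of a gene is the
fraction of permutation rank products (over all genes and permutations, with
add-one smoothing so p > 0) at or below its observed value, and
F<sub>gi</sub> = p<sub>gi</sub> · G<sub>i</sub> / rank(γ̄<sub>gi</sub>)
is the per-study FDR, computed separately for up- and down-regulation.
Genes absent from a study's platform receive that study's median FDR.

At a per-study FDR threshold *l*, gene *g*'s significance pattern is
δ<sub>gil</sub> = I(F<sub>gi</sub> < *l*).  Writing d<sub>il</sub> for the
number of genes passing the threshold and M<sub>i</sub> for the number of
genes *not* regulated in the tested direction, the probability that a
non-regulated gene is a false call is r<sub>il</sub> = *l* ·
d<sub>il</sub> / M<sub>i</sub>, and the chance of observing the pattern
under pure false positives is the Bernoulli likelihood
∏<sub>i</sub> r<sub>il</sub><sup>δ</sup>(1−r<sub>il</sub>)<sup>1−δ</sup>.
Its negative logarithm Q<sub>gl</sub> is averaged over thresholds with the
linearly decreasing density p(*l*) = −2*l* + 2 (small thresholds carry the
most information about true positives), giving the per-gene evidence score

EL<sub>g</sub> = ∫₀¹ Q<sub>gl</sub> p(*l*) d*l*,

approximated by a 100-bin rectangular rule at bin midpoints.  Significance
of EL is calibrated by shuffling every study's FDR column over genes *B*
times and estimating, per gene, FDR<sub>g</sub> = [(1/B) Σ<sub>b</sub>
#{g′ : EL<sub>g</sub> ≤ EL<sub>bg′</sub>}] / #{g′ : EL<sub>g</sub> ≤
EL<sub>g′</sub>} (inclusive ties; the denominator counts the gene itself so
it is at least 1).  Both directions are analysed independently; a gene is
called at the user's meta-FDR threshold, the smaller-FDR direction winning
if both pass (larger EL on exact ties).

## Non-regulated gene counts: the Beta mixture

Rank-based permutation p-values are not uniform for unaffected genes —
regulated genes capture the extreme ranks, pushing the null bulk away from
the ends — so M<sub>i</sub> cannot be read off a uniform-null estimator.
Instead the one-sided p-values of each study are modelled as a
three-component Beta mixture: θ₁·Beta(1, b₁) for genes significant in the
tested direction (mass near 0), θ₂·Beta(a₂, b₂) for the bulk, and
θ₃·Beta(a₃, 1) for genes extreme in the opposite direction (mass near 1).
Priors: θ ~ Dirichlet(1, 18, 1); a₂ ~ Gamma(4, 2); b₂ ~ Gamma(1, 1); a₃,
b₁ ~ Gamma(400, 20), with Gamma(α, β) parameterised so the mean is α/β.
The fixed shapes a₁ = b₃ = 1 pin the skewed components to opposite ends
and prevent label switching; a posterior check verifies the component
means are ordered.  Sampling is Gibbs with data augmentation over the
component labels; the free shapes move by random-walk Metropolis on the
log scale using the component sufficient statistics, so each sweep costs
O(G).  Defaults: 2 chains × 4,000 sweeps, 2,000 burn-in, convergence
declared at split-R̂ < 1.1 on θ (non-convergence warns and flags the fit,
it does not abort).  Point estimates are posterior means (configurable to
medians).  Then M<sub>i</sub> = round(G<sub>i</sub>·(θ̂₂+θ̂₃)), floored at
1.

A practical note: on real rank-product p-values the extreme genes
concentrate so tightly near 0 that the bulk component (whose shapes are
only weakly constrained) can absorb them with a₂, b₂ < 1, driving θ̂₁
toward 0 and M<sub>i</sub> toward G<sub>i</sub>.  Because M<sub>i</sub>
enters only as a mild normalisation of r<sub>il</sub> (and the meta-FDR
compares observed and permuted EL computed under the *same* rates), this
has little effect downstream; the mixture is accurate when the components
are separated, which is what the recovery tests check.

## Numerical choices

* p-values are clamped to [10⁻⁶, 1−10⁻⁶] before the mixture fit (Beta
  log-densities diverge at the endpoints).
* Rates r<sub>il</sub> are clamped to [10⁻⁸, 1−10⁻⁸]: the plug-in
  *l*·d/M can reach 0 or exceed 1, which would make Q infinite.
* Grid bins are midpoints l = (j−½)/100, avoiding the degenerate l = 0
  (no calls) and l = 1 (Q ≡ 0) endpoints; the discretised density sums to
  1 exactly.
* EL is computed once per (study, bin) and shared across genes; a per-gene
  brute-force loop is kept as a test oracle (agreement to 10⁻¹⁰).
* Within a study, permuted EL uses the same per-bin rates as the observed
  EL — the counts d<sub>il</sub> are invariant under shuffling the FDR
  column, so the rates are too.
* Fold-change ranking uses exact average-tie ranks on small matrices and,
  for large permutation blocks, a float32 stable-argsort path with ordinal
  ranks and deterministic gene-order tie-breaks (exact ties are measure-zero
  for continuous expression values; equivalence with the exact path is
  tested at small scale via exhaustive enumeration).
* When the number of distinct case/control label assignments is at most
  the requested permutation count, the rank-product null enumerates all of
  them instead of sampling.
* Per-study FDRs are reported uncapped (the estimator can exceed 1), with
  a cap-at-1 option; meta-level FDR<sub>g</sub> is reported capped at 1.

## Comparator methods

*Meta-Profile* thresholds each study's FDR column at a fixed *l* (a
"signature") and scores each gene by the number of signatures containing
it.  Null scores come from the same within-study FDR shuffling as the
meta-permutation, and the gene-level FDR applies the same
ratio-of-counts estimator to the count statistic.  The published sketch of
this method leaves the FDR machinery open; mirroring the CDEP permutation
scheme makes the three methods directly comparable.

*Meta-RankProd* pools all Σ<sub>i</sub>H<sub>i</sub> comparisons into one
rank product (equivalently the H<sub>i</sub>-weighted geometric mean of the
per-study γ̄), imputing a study's median rank for genes it does not
measure.  The null permutes expression values within each single array and
recomputes; significance follows the rank-product recipe.  Because every
comparison has equal weight, sample-rich studies dominate — the size bias
the likelihood aggregation is designed to avoid, and a directional test in
the suite reproduces it on a constructed example.

## Simulator

Each study draws log-scale values y = μ + L<sub>i</sub> + G<sub>gi</sub> +
effect·I(case) + ε with L<sub>i</sub> ~ N(0, lab_sd²) (one scalar per
study), G<sub>gi</sub> ~ N(0, gene_sd²) per (gene, study), ε ~ N(0,
noise_sd²) per cell.  Gene categories are mutually exclusive per gene:

* consistent genes (G_M), fraction q panel-wide, one random sign shared by
  every study measuring the gene;
* study-specific genes (G_C), selected independently within each study at
  marginal rate p (conditional rate p/(1−q) among non-consistent genes),
  with an independent random sign per selecting study;
* the rest are null (G_N).

Effects are drawn per case sample as N(δ, ψ) times the sign, so δ is the
mean |log-fold-change| and ψ its variance.  Platforms are nested prefixes
of the largest study's gene list, which reproduces the qualitative feature
that only a minority of genes is measured by every platform; real platform
overlaps are messier than nesting, and the simulator makes no attempt at
batch/probe artefacts beyond L<sub>i</sub> and G<sub>gi</sub>, so passing
tests speak to the statistical machinery, not to array preprocessing.

Default shape: six studies mirroring published primary-vs-metastatic
panels — case/control splits 12/21, 25/65, 15/7, 3/3, 19/8, 10/22 and
platform sizes 20,271 / 9,000 / 5,526 / 13,069 / 13,069 / 13,069,
rescalable proportionally (the study grids use a 2,000-gene universe).
The background parameters are not published for the real panels and were
fixed once at values typical for RMA-summarised log2 data: μ = 8,
lab_sd = 0.5, gene_sd = 1.0, ψ = 0.25, noise_sd = 0.5.  All are
configurable.  Absolute power levels are sensitive to the effect-to-noise
ratio these imply, so cross-study *orderings* of methods (CDEP above the
signature counter in power; pooled rank product far above CDEP in Type I
error) are the robust quantities; absolute power at the default noise runs
higher than the published simulation, which used noise levels estimated
from the real arrays.

## Simulation-study scale

The power/Type-I grids run the scenario p = q = 0.05 at |δ| ∈ {1, 2} with
call FDR 0.05: 10 replicates on a 2,000-gene universe, 50 rank-product
permutations, B = 50 meta permutations, and shortened mixture chains
(2 × 2,000 sweeps, 1,000 burn-in) — chosen as the package's standard
reduced-scale study.  Null calibration shuffles condition labels on a
500-gene, 4-study panel over 20 seeds.  Mixture recovery uses the
well-separated 5/90/5 Beta mixture at G = 2,000 over 10 seeds with the
full default sampler.

## Known limitations

* The Beta-mixture M̄ estimate degrades (θ̂₁ → 0) when the significant
  p-values concentrate much more sharply than Beta(1, ~20) can express;
  see above for why this is benign here.
* Meta-level FDR<sub>g</sub> is conservative when signal is present (after
  shuffling, genes regulated in single studies populate the null, inflating
  the null EL distribution), but on a completely signal-free panel it is
  only *calibrated*, not conservative: for the top-ranked gene the
  denominator of the ratio-of-counts estimator is 1, so roughly 5% of null
  panels per direction produce a single borderline call at FDR 0.05,
  independently of the number of permutations.
* Shuffling condition labels does not produce a true null when planted
  effects exist: affected genes keep inflated variance in every study, and
  the resulting cross-study-correlated extremeness is outside the
  within-study permutation null.
* Paired designs, covariates and alternatives to the linear threshold
  density are out of scope.
* The reconstructed comparators follow the descriptions used for the
  head-to-head simulation, not the original publications' full pipelines.
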