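# Methods

## Model and score

`omicsbn` learns directed acyclic graphs over mixed continuous/discrete
variables under the conditional linear-Gaussian (CLG) model.  A continuous
node `y` with continuous parents `x_1..x_p` and discrete parents `D` is
modelled, within each configuration `d` of `D`, as

    y | x, D = d  ~  Normal(a_d + Σ_j b_j x_j,  σ_d²),

fitted by maximum likelihood (per-configuration OLS).  A discrete node is
multinomial within each configuration of its (necessarily discrete)
parents; continuous parents of discrete nodes are structurally forbidden,
which is enforced during search rather than stored per edge.  Binary traits
may be *declared* continuous in the metadata — the package honours the
declaration instead of inferring type from cardinality, so a 0/1 disease
indicator can take continuous parents when that is the analysis intent.

The network score is the Bayesian information criterion in its penalized
negative log-likelihood form, `BIC = −2 log L + k ln n` with natural logs,
summed over node-parent families; **lower is better**.  The k/2 convention
would rescale all scores without changing any search decision; this one is
fixed for reproducibility of the numbers in tests.

Numerical choices:

* **Parameter counting.** Parameters are counted only for discrete-parent
  configurations actually observed (per configuration: intercept + slopes +
  variance for a continuous child; `levels − 1` for a discrete child).
  Unobserved cells contribute neither likelihood nor parameters, keeping
  scores finite when discrete parents have many levels.
* **Variance floor.** Residual variances are floored at
  `max(1e-12 × var(child), 1e-300)` so that perfect in-sample fits (exactly
  collinear or noise-free synthetic inputs) score finitely.
* **Invalid families.** If any observed configuration has fewer rows than
  regression parameters, the family's MLE is undefined; it is flagged
  invalid and scores +inf, which removes it from consideration in search.
* **Caching.** Family scores are cached by (node, sorted parent set); the
  cache is an optimisation only and is invalidated on any data change — the
  cached value must always equal a from-scratch computation (tested).

## Structure search

Greedy hill-climbing over DAGs with add/delete/reverse moves, starting from
the empty graph plus any required edges.  Moves must preserve acyclicity,
the role constraints (parent-only nodes admit no incoming edges; no-parent
nodes none at all; forbidden/required edge lists) and CLG typing.  Each
iteration applies the single best score-improving move (steepest descent);
ties within 1e-9 are broken lexicographically by (child, parent, move
kind), and the search stops when no move improves the score by more than
1e-9.  This makes results bit-reproducible for a given seed.

`random_restarts > 0` enables perturbation restarts: the current optimum is
perturbed by a handful of random legal moves and re-climbed, keeping the
best final score.  Restarts were implemented this way after dense random
restart graphs proved ineffective at escaping the shallow score plateaus
that single-edge moves create.  The default is 0 restarts.

## Bootstrap average networks

The data are resampled with replacement by whole individual; the best-fit
network is learned on each replicate and each directed edge tallied.  For
an unordered pair {a, b}, *strength* is the proportion of replicates with
an edge in either orientation, *direction* the proportion of those pointing
a→b.  One master seed spawns an independent seed per replicate
(`numpy.random.SeedSequence`), so the result is identical whether
replicates run sequentially or in parallel, and any single replicate can be
reproduced in isolation.  These proportions are often loosely called
posterior probabilities; they are bootstrap frequencies, not samples from a
Bayesian posterior, and the documentation sticks to strength/direction.

The significance threshold on strengths follows the analytic construction
of Scutari and co-workers: with F̂ the empirical CDF of the strength values,
the level `c*` minimising `∫₀¹ |F̂(x) − c| dx` (a weighted median of the CDF
values, computed exactly from the step function) is found, and the
threshold is the `c*`-quantile of the strengths.  The analytic threshold is
applied **inclusively** (strength ≥ t̂): in the degenerate case where every
strength equals 1 the estimator returns 1 and all edges must pass.
User-supplied numeric thresholds are strict (>), matching the usual display
convention "greater than 0.5".  Direction thresholds above 0.5 drop pairs
whose majority direction falls strictly below the threshold; an exact
direction tie of 0.5 is kept, oriented toward the lexicographically larger
node name, and flagged `direction_resolved = False` so no causal reading is
implied.

## Imputation

Two stages.  (1) Every missing cell is filled by sampling with replacement
from that variable's observed values, and an initial best-fit network is
learned from the filled data.  (2) For each individual with missing data
and each of its missing variables, the variables adjacent to the missing
one in the initial network (ignoring orientation) that are observed for
that individual form the "nearby" set; the donor is the individual with the
smallest mixed-data distance over the nearby set among those with observed
values for the nearby set *and* the missing variable, and the donor's value
is copied.  Consequences: imputed values are always genuinely observed
values of that variable, observed cells are never modified, and each
missing variable of the same individual may have a different donor.

Choices where the procedure is underdetermined:

* **Distance.** Continuous variables are z-scored with observed-data
  mean/SD and contribute squared differences; each unequal discrete value
  contributes `discrete_mismatch_cost²` (default cost 1.0); the distance is
  the square root of the sum.  This Gower-like scale-free form is isolated
  in one function for substitution.
* **Ties** go to the smallest sample index.
* **No eligible donor.** Default fallback drops the nearby variable with
  the most missing cells and retries; if the nearby set empties, the value
  is sampled from the variable's observed values with the run's RNG (the
  same distribution as the initial random fill).  This guarantees
  termination.
* **Single pass.** The procedure makes one pass over individuals; it is not
  iterated to convergence.

The aim is not per-cell accuracy but preserving enough dependence structure
to learn the network from the completed data; the validation experiments
measure exactly that (true-edge detection downstream, not imputation RMSE).

## Genetics pre-processing

The association scan regresses a complete continuous phenotype on each SNP
dosage plus covariates (genetic principal components are accepted as a
covariate matrix; computing PCs is standard and out of scope).  Covariates
are projected out of phenotype and dosages (Frisch–Waugh), and Wald
p-values use the exact residual degrees of freedom.  Missing dosages are
mean-imputed per SNP; monomorphic SNPs report p = 1.  Bonferroni filtering
uses `alpha / (total tests in the scan)` by default — the matrix of
variables × SNPs actually tested — with `alpha = 0.01`, ≥ 20 significant
SNPs for metabolite/protein variables and ≥ 2 under the expression rule
(configurable, including the 0.05 level used for clinical traits).
Clumping is greedy by ascending p-value with defaults r² > 0.1 within
250 kb (both exposed as options; no standard values exist).  Allele scores
are weighted dosage sums with missing dosages contributing the SNP mean.
The inverse normal transform uses averaged ranks and the rankit offset
`(r − 0.5)/n`; the Blom offset 0.375 is available by argument.

## Synthetic data

`simulate_model` draws a ground-truth CLG network over the five variable
classes.  Edges are sampled over a random topological order;
class-assortative preference (default 0.8) favours same-class edges,
mirroring the strong within-class connectivity seen in real multi-omics
networks.  Edge coefficients have magnitudes drawn from `effect_range`
with random signs; residual SDs default to 1.  Allele scores are root
nodes with exactly one child: each is backed by simulated SNPs
(dosages ~ Binomial(2, MAF), MAF ~ U(0.1, 0.5), positive weights), and its
coefficient is scaled by the score's theoretical SD so anchors carry
effects comparable to other parents.  LD for clumping tests is induced by
first-order autoregressive allele copying within blocks.

The `direct_like` preset reproduces the structure of a large multi-centre
type-2-diabetes cohort: at full scale, 3029 individuals (795 cases) and 260
variables in class proportions (65 clinical / 34 metabolite / 27 protein /
33 expression / 101 allele scores), a binary disease indicator declared
continuous, two discrete clinical variables (a sex-like binary with no
parents and a centre-like factor), clinical variables with block
missingness by case/control group plus MCAR top-up such that **no
individual is complete**, and a small group (14 at full scale) missing all
protein measurements.  `scale` shrinks both axes for fast tests while
preserving this structure.

What the generator does *not* emulate: realistic molecular-network
topology beyond class assortativity, non-linear or heteroscedastic
effects, genotyping/measurement error, and missingness that depends on
unobserved values (MNAR).  Passing the validation suite therefore shows
the method recovers CLG ground truth under structured-but-ignorable
missingness; it does not certify behaviour under MNAR or model
misspecification.

## Validation experiment conditions

The acceptance experiments (tests and `scripts/acceptance.py`) fix these
problem sizes, chosen as the smallest instances where the statistical
claims are meaningfully testable:

* *Scoring oracle*: 50 random mixed families, n ∈ [40, 200], against a
  closed-form normal-equations/multinomial implementation (relative
  tolerance 1e-8).
* *Search oracle*: 50 three-node instances (25 possible DAGs each),
  n = 5000, effects 0.5–0.9; the climb must reach the enumerated optimum
  in ≥ 90%.
* *Structure recovery*: 20-node models at the study's class proportions
  (5/3/2/2 substantive + 8 allele scores), max in-degree 3, edge density
  0.15, |β| ∈ [0.5, 1], n = 2000, 100 bootstrap replicates, analytic
  threshold; 10 seeds.
* *Imputation value*: 15-node models (4/2/2/2 + 5 scores), |β| ∈ [0.3,
  0.6] — moderate effects, so that usable sample size genuinely determines
  detection power — n = 1500, ~25% missingness on 5 clinical/metabolite
  variables allocated so that under 5% of rows are complete; anchors are
  parent-only but *not* required, so detections must come from data in
  both arms; 10 seeds, 50 replicates per average network.
* *Anchor orientation*: anchor → X → Y with the anchor explaining ~11% of
  X's variance, n = 2000, 20 runs.
* *Threshold separation*: 100 Beta(1,20) noise strengths vs 100
  Beta(20,1) signal strengths.

## Known limitations

* Greedy hill-climbing can stall in local optima created by near-unfaithful
  parameterisations (path-coefficient cancellation); perturbation restarts
  mitigate but do not eliminate this, as with any local search.
* Edges not oriented by anchors or colliders are equivalence-reversible;
  their bootstrap direction values reflect deterministic tie-breaking more
  than evidence, which is why direction 0.5 is explicitly flagged.
* The scorer requires complete data by construction; imputation quality
  bounds everything downstream.
* No equivalence-class (CPDAG) machinery: strengths/directions are tallied
  over DAGs as found.
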