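# Methods

This note documents the models, algorithms, defaults, and design choices in
`rootgrn`, and what the synthetic benchmarks do and do not demonstrate.

## 1. The regulatory circuit being modelled

The package is organised around a three-regulator circuit from *Arabidopsis*
root-hair development: RSL4, a bHLH activator that drives root-hair
elongation, and the trihelix factors GTL1 and DF1, which repress it.  RSL4
activates *GTL1* transcription while GTL1 represses both *RSL4* and itself,
closing a negative-feedback loop; the two repressors also share a few dozen
downstream target genes with RSL4.  The pipeline stages mirror how such a
circuit is reconstructed in practice: rank candidate TF→gene edges from
perturbation expression data, keep a fixed-size high-confidence subnetwork
validated against direct-binding evidence, orient each edge's sign from a
developmental time course, and then study the feedback pair quantitatively
with a two-variable ODE model.

## 2. Forest-based edge scoring

For each target gene a `RandomForestRegressor` predicts the target's
expression (scaled to unit variance so importances are comparable across
targets) from the candidate regulators' expression, excluding the target
itself when it is a regulator.  Edge weight = mean *unnormalised* impurity
reduction per tree (`tree_.compute_feature_importances(normalize=False)`);
per-tree renormalisation to 1 would hand every target the same importance
mass regardless of how much of its variance is explainable.

Choices that matter:

* **Tree budget.** `n_trees` is the total across all per-target forests
  (default 10,000), split evenly with the remainder going to the earliest
  targets in gene order.  With 39 genes that is 256–257 trees per target.
* **Candidate regulators.** Default `{GTL1, DF1, RSL4}`; scoring all genes
  against all genes is supported but produces edges the downstream stages do
  not use.
* **Features per split.** All regulators when there are ≤ 3 candidates
  (subsampling 1 of 3 features mostly produces uninformative splits), else
  ⌈√K⌉.
* **Leaf size.** `min_samples_leaf = 3`, the replicate count of the default
  design.  Fully grown trees can isolate single replicates and thereby award
  substantial importance on targets that are pure replicate noise; capping
  leaves at the replicate scale removes exactly that overfit while leaving
  genotype-level structure (groups of 3) fully resolvable.  This is a
  deliberate departure from the fully-grown-tree convention in forest-based
  network inference.
* **Determinism.** Samples are sorted by sample id before fitting, so edge
  weights are invariant to the column order of the input matrix; per-target
  forest seeds derive from one `SeedSequence`.

Zero-variance targets get all-zero incoming weights.  Ranking breaks weight
ties lexicographically on (regulator, target) so output is reproducible.

### Thresholding and precision

`threshold_edges` keeps the top ⌊multiplier × n_genes⌋ edges (default
multiplier 1.65; 36 genes → 59 edges), capped at availability.
`precision_against_binding` is the fraction of retained edges present in a
(TF, target) binding set, by default restricted to GTL1's outgoing edges —
the TF for which direct-binding validation is typically available.
`select_threshold` scans a candidate multiplier grid and returns the most
precise multiplier (ties to the smallest) together with the full
(multiplier, edge count, precision) table.

## 3. Sign assignment from a time course

For regulator series A and target series B sampled at T ordered times, each
transition k = 1..T−2 votes
`sgn(A(t_{k+1})−A(t_k)) · sgn(B(t_{k+2})−B(t_{k+1}))` — the target is read
one step *after* the regulator (lag-1, first-order Markov reading).  Deltas
with |Δ| ≤ 1e−12 (raw expression scale) are uninformative and vote 0.  Votes
are pooled across zones into one tally per edge (a per-zone
majority-of-majorities mode is available) and the edge takes the strict
majority sign; ties and all-zero tallies give sign 0, rendered as an
unsigned edge.  No smoothing, detrending, or significance testing is
applied.

## 4. The feedback ODE model

State: R = RSL4 protein, G = GTL1 protein, arbitrary concentration units.
Transcription and translation are lumped (both assumed fast) and degradation
is linear.  The *RSL4* promoter is repressed by a GTL1 oligomer of size
`n1`:

    dR/dt = k1 · 1/(1 + (G/K_RG)^n1) − deg_R · R

The *GTL1* promoter carries an RSL4 site (statistical weight
r = (R/K_GR)^n_R) and a GTL1 site (weight g = (G/K_GG)^n1).  Thermodynamic
enumeration of its four occupancy states (empty / R-bound / G-bound / both)
gives the two promoter logics as the choice of transcribing states:

* `EQN1` (repression dominant — GTL1 bound silences the promoter even when
  RSL4 is bound):  f₁ = r / ((1+r)(1+g));
* `EQN2` (activation dominant — any RSL4-bound state transcribes):
  f₂ = (r + r·g) / ((1+r)(1+g)), which simplifies to r/(1+r).

so `dG/dt = k2·f − deg_G·G`, with f₂ ≥ f₁ pointwise.  Note that under
independent-site binding the activation-dominant logic makes GTL1
self-repression *exactly null* — the g terms cancel — which is why the
self-binding threshold `K_GG` has a zero sensitivity index under `EQN2`.

**Default parameters.** All rates and thresholds 1, exponents
n1 = n_R = 2, variant `EQN2`.  These are deliberately neutral units — the
qualitative conclusions (directions of the genotype scenarios, existence and
stability of the steady state) are parameter-robust, while any quantitative
percentage is specific to this choice.  `k2 = 0` encodes the *gtl1 df1*
double null; k2 ≥ 0, everything else strictly positive, exponents ≥ 1.

### Steady states

The R-nullcline is available in closed form,
R(G) = (k1/deg_R)/(1+(G/K_RG)^n1).  Substituting it into the G equation
leaves φ(G) = k2·f(R(G), G) − deg_G·G, whose roots are exactly the steady
states.  `steady_states` evaluates φ on a mixed log/linear grid of 10⁴
points spanning [0, 10·k2/deg_G] (every root satisfies
G ≤ k2/deg_G because f < 1), polishes each bracketed sign change with
Brent's method (xtol 1e−15), merges duplicates at relative tolerance 1e−8,
re-evaluates the residual independently (must be < 1e−8), and classifies
stability from the numerically differentiated Jacobian's eigenvalue real
parts (threshold 1e−9 for "marginal").

A structural fact worth recording: for *both* implemented logics f is
non-increasing in G along the R-nullcline, so φ is strictly decreasing from
φ(0) = k2·f(R(0), 0) > 0 (for k2 > 0) to −∞, and therefore **each variant
has exactly one steady state in the closed nonnegative quadrant, and it is
stable** (the Jacobian trace is negative and the determinant positive at any
root).  In particular, repression-dominant promoter logic does *not*
eliminate the steady state under this model class — any bounded,
continuous, nonnegative production term with linear degradation admits a
fixed point by the intermediate value theorem.  A claim that the
repression-dominant variant has no nonnegative steady state can only arise
from a different (e.g. singular or unbounded) algebraic form; the package
surfaces computed counts rather than asserting either outcome, and the test
suite records the discrepancy explicitly.  `solve_gstar` and
`steady_state_batch` exploit the monotonicity of φ for fast (vectorised)
bisection; they agree with the general scan to ~1e−10 and back the
calibration and sensitivity code paths.

### Simulation and scenarios

`simulate` integrates with LSODA at rtol 1e−8 / atol 1e−10; states are
clipped at zero only within tolerance and an excursion below −10·atol is an
error.  `genotype_scenarios` returns wild type, overexpression (k2 rescaled
by bracketed monotone root finding until G* = 15× wild type, relative
tolerance 1e−6, failure if unreachable within 10⁶× the wild-type k2), and
the null (k2 = 0, closed form (k1/deg_R, 0)), each with trajectory, steady
state, and steady-state ratios versus wild type.  Because G* is strictly
increasing and R* strictly decreasing in k2, the scenario directions are
parameter-free: overexpression always lowers R*, the null always raises it.

## 5. Sobol sensitivity analysis

First-order indices are estimated with the Saltelli paired-matrix scheme:
two base matrices A, B of `n_mc` draws (scrambled Sobol' quasi-random
sequence by default; plain uniform random behind `scheme="random"`), plus
the d radial matrices A_B^(i), at n_mc·(d+2) model evaluations per repeat;
S_i = mean(f(B)·(f(A_B^i)−f(A))) / Var(f) (Saltelli 2010 estimator).  The
analysis is repeated `n_repeats` times (default 10) with independent seeds;
per-repeat indices are retained and negative estimates at finite n are
reported, not clipped.  n_mc defaults to 1000 base draws per block.

**Varied parameters.** Default: the kinetic parameters
{k1, k2, K_RG, K_GR, K_GG}, each uniform over ±50% of its nominal value.
The degradation rates are held fixed because the steady state depends on
(k1, deg_R) and (k2, deg_G) only through the ratios k1/deg_R and k2/deg_G —
a time-rescaling gauge — so varying all four would duplicate two axes and
split each ratio's variance arbitrarily between numerator and denominator.
The oligomer exponents are structural integers (a count of bound proteins),
not kinetic quantities, and are likewise held fixed.  Output functional:
R* by default; G* and R*+G* are available.  Both choices are configurable.

**What the default analysis shows.** At the all-ones nominal point k1
dominates (S₁ ≈ 0.72 for R*), `K_GG` is exactly null (see §4), and k2,
K_GR, K_RG form a statistical near-tie at S₁ ≈ 0.07: the RSL4→GTL1
activation is far from saturation there (r ≈ 0.7), so the binding threshold
carries as much variance as the production rate.  Rankings below rank 1 are
therefore nominal-point-specific and should not be over-interpreted; with a
nominal set in a more saturated regime k2 moves up.  Draws without an
admissible steady state cannot occur for these logics (§4), so no fallback
path is exercised; the estimator nevertheless validates outputs and reports
non-finite draws with diagnostics.

## 6. The synthetic-data generator

The generator provides ground truth for every pipeline stage; its defaults
are the package's reference study conditions.

* **Network.** 3 regulators (GTL1, DF1 repressors; RSL4 activator) over
  `n_targets` = 36 targets; each regulator→target edge present with
  probability `edge_density` = 0.15 (sparse truths are the standard
  benchmark convention and keep precision-recall evaluation informative);
  effect sizes are signed magnitudes ~ Uniform[0.5, 2]; an
  activator↔repressor feedback pair (RSL4→GTL1 positive, GTL1→RSL4
  negative) is added by default, self-repression only on request.
* **Genotype design.** Wild type, *gtl1*, *df1*, *gtl1 df1*, 15× GTL1
  overexpression, 30× DF1 overexpression; 3 replicates each; baseline
  expression 100 arbitrary units for every gene (downstream methods are
  scale-free).
* **Propagation.** One multiplicative step: a target's genotype mean is
  baseline · Π(relative regulator level)^effect.  A knockout zeroes the
  gene's own row; for propagation the missing protein is represented by a
  residual relative level of 0.1, so targets of a knocked-out repressor
  rise above baseline (de-repression) and targets of a knocked-out
  activator fall.  The residual is an identifiability device, not a
  biological estimate.
* **Noise.** Multiplicative log-normal, CV = `noise_cv` (default 0.2, mean
  1).  Each replicate draws one factor per gene, and a regulator's factor
  is *shared* between its measured row and its targets' responses in that
  replicate — targets are per-sample functions of realized regulator
  levels, which is the dependence structure regression-based inference
  assumes.  With fully independent per-cell noise the problem is partially
  unidentifiable: the feedback loop makes RSL4's genotype means a monotone
  function of GTL1's, and with only six distinct genotypes no method could
  attribute shared targets between them.
* **Time course.** Regulators receive randomized multiplicative kicks
  (log-magnitude 0.2–0.5, random sign) on *even* transitions, one regulator
  per transition in round-robin order (offset per zone); every direct
  target responds with the edge's signed effect exactly one transition
  later, and responses do not propagate further.  A parity argument then
  guarantees the lag-1 rule is an exact oracle: informative votes exist
  only where a kick (even slot) meets its direct response (next, odd slot),
  responses at odd slots never coincide with another gene's kick-response
  pair, and consecutive kicks always belong to different regulators, so no
  edge — including the feedback pair — ever receives a wrong vote.  The
  guarantee does not extend to self-loops (off by default), and the
  generator refuses configurations in which some regulator gets no
  scorable kick (e.g. 3 regulators, 5 timepoints, 1 zone).  Default: 5
  timepoints, 2 zones.
* **Binding set.** Each true edge kept with probability `tpr`, each
  TF→gene non-edge added with probability `fpr`.

**What passing the synthetic benchmarks does not show.**  The generator has
no probe effects, no normalisation artifacts, no cell-sorting distortions,
no unmeasured regulators, and its time course satisfies the lag-1 assumption
*by construction*.  Recovery results (e.g. AUPR ≥ 3× the random baseline on
the default design, exact sign recovery on noise-free courses) therefore
validate the implementation and the identifiability of the design — they
are not estimates of accuracy on real transcriptome data, where the Markov
lag, the noise structure, and network sparsity are all violated to unknown
degrees.

## 7. Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the forest stage at the full
10,000-tree budget on the 39-gene design (5 seeds), the Sobol stage at
n_mc = 1000 × 10 repeats, and property checks at reduced sizes (30 random
parameter sets for steady-state counting, 8 × 5 random initial-state
convergence runs, 15-point k2 grids at 10 parameter sets); these sizes were
chosen to exercise every code path at the default study conditions while
keeping a full run in the low minutes on one core.

## 8. Known limitations

* The promoter logics assume independent binding sites and a single lumped
  protein species per gene; competitive binding, mRNA/protein separation,
  spatial growth of the hair tip, and stochastic expression are out of
  scope.
* Quantitative scenario outputs (e.g. "RSL4 at 2.9% of wild type under 15×
  overexpression") are functions of the neutral unit-parameter default;
  only their directions are parameter-free.
* Sensitivity rankings below the top parameter are nominal-point-specific
  (§5).
* The edge-count threshold rule presumes the intended network size is known
  (1.65 × n_genes); the precision scan mitigates but does not remove that
  assumption.
* TSV readers are strict by design (tab-delimited, UTF-8, `#` comments
  before the header only); malformed files fail with line numbers rather
  than being coerced.
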