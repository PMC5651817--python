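# Methods

`glvnet` infers signed, directed interaction networks among bacterial
taxa from longitudinal relative-abundance data, under the assumption
that the observed community sits at (or relaxes toward) an
asymptotically stable equilibrium of a generalized Lotka–Volterra (gLV)
system. This note records the model, the estimation procedure, the
numerical choices, and what the synthetic studies do and do not
demonstrate.

## Model

Community dynamics follow the gLV system

    y'(t) = diag(y(t)) (r + A y(t)),

with intrinsic growth rates `r` and interaction matrix `A`; `a_ij` is
the per-capita influence of taxon `j` on the growth of taxon `i`. An
equilibrium `ȳ` satisfies `diag(ȳ)(r + Aȳ) = 0`, and is asymptotically
stable iff the spectral abscissa (maximum eigenvalue real part) of the
Jacobian

    J = diag(r + Aȳ) + diag(ȳ) A

is strictly negative. At an interior equilibrium the first term
vanishes, so `J = diag(ȳ)A`. For a strictly positive `ȳ` the growth
rates are eliminated analytically, `r = -Aȳ`: every `(A, r)` pair
satisfying the interior equilibrium condition has this form, so the
equilibrium constraint holds to machine precision by construction and
the search space reduces to `A`.

Abundances are treated as relative (compositions). This matters in
three places:

1. **Only the simplex component of the dynamics is observable.**
   Renormalisation adds the same `-d log(total)/dt` to every taxon's
   per-capita growth rate, so all fitting is done modulo a common
   per-sample offset.
2. **A is identifiable only up to additive row and column shifts.**
   Because compositional deviations sum to zero, `A`, `A + u·1ᵀ` and
   `A + 1·vᵀ` fit relative data equally well. The sparsity penalty is
   the identifying assumption: among equivalent matrices the method
   reports the sparsest.
3. **The forward model lives on the simplex** (see below).

## The inverse problem and its solver

Given `ȳ` (estimated from data) the admissible set is every `A` making
`ȳ` a stable interior equilibrium — a nonconvex feasibility problem
with many solutions. The solver is repeated Monte-Carlo-sampled direct
search:

* **Sampling.** Each restart draws a starting matrix with off-diagonal
  entries uniform on ±`init_scale` (default 0.5) and diagonals uniform
  on `[-init_scale, 0]` (a self-limitation bias; random matrices with
  unconstrained diagonals are almost never stable as n grows). When
  trajectory data are supplied, each restart additionally fits a random
  subset of subjects (default 70%), so the ensemble doubles as a
  stability-selection resample.
* **Refinement.** Compass (coordinate pattern) search over the n²
  entries: poll ±step in row-major order, `+` before `-`, accept the
  first improvement, contract the step by `step_contract` (0.5) after a
  full unsuccessful sweep, stop below `step_tol` (1e-3) or at the
  per-restart evaluation cap `max_iters` (20 000).
* **Stability as a hard constraint.** While a candidate is unstable the
  merit is a large offset plus the squared hinge on the spectral
  abscissa, driving the search into the feasible region; once feasible,
  unstable polls are rejected outright (extreme barrier). A soft
  penalty would leave optima marginally unstable and nothing would ever
  satisfy the strict acceptance rule. A configurable margin (default
  1e-6) guards against sign-unreliable near-zero eigenvalues.
* **Acceptance.** A solution is admissible iff its equilibrium residual
  max-norm is below 1e-8 and its spectral abscissa is below the margin.
  Near-misses are recorded but flagged unaccepted. Ensembles are
  bit-for-bit reproducible for a fixed seed.

### Data-anchored merit

With `ȳ` alone, the admissible set is sign-symmetric: flipping the
off-diagonal signs of any taxon's row and column leaves the spectrum of
`diag(ȳ)A` unchanged, so no consensus over restarts could recover a
generating network from the equilibrium by itself. The longitudinal
trajectories carry that information, so when they are available the
merit adds a one-step prediction error: for every sampling interval the
candidate's composition flow (below) is integrated forward from the
observed left-endpoint composition by one classical RK4 step, and the
predicted log-composition slope is compared with the observed one.
Predicting from the left endpoint only means abrupt in-interval
community shifts enter the target but never the predictor, so process
noise acts as unbiased equation error rather than errors-in-variables.
Residuals are double-centered — a precision-weighted per-sample mean
across taxa absorbs the common compositional offset, a per-taxon
intercept absorbs the constant error left by estimating `ȳ` — and
weighted per taxon by the reciprocal pooled variance of the growth
targets, which keeps noisy rare-taxon rows from dominating.

### Adaptive sparsity

The l1 penalty is entry-adaptive. A leave-one-subject-out jackknife of
a model-consistent linear pilot fit yields a standard error for every
entry of `A`; the pilot's additive column-shift structure (the
unobservable common-growth gauge, absorbed by the pilot as the column
mean of the true matrix) is removed by a plain median polish down each
column — true edges are a minority of any column, and precision
weighting would let a tight strong edge drag the shift estimate; and
entries whose shift-resolved pilot exceeds twice their standard error
get proportionally lighter shrinkage (adaptive lasso). The net effect
is that each entry's soft-threshold sits at `sparsity_weight` (default
1.0) times its own sampling noise, so poorly-excited columns (rare,
slowly-mixing taxa) are strongly shrunk while clearly-supported edges
are kept nearly unshrunk. For communities with fewer than five taxa
the shift cannot be resolved from sparsity at all (every column has at
most two off-diagonal entries, so all shift choices tie in l1); there
a single uniform penalty scale is used and the ensemble median centres
the sign-preserving ambiguity — which is why the bundled three-taxon
scenario pairs a facilitation with an inhibition in every row and
column. This calibration was tuned once on the synthetic presets.

### Consensus networks

The ensemble of admissible matrices is distilled per ordered taxon
pair: an edge `j → i` enters the consensus iff the median of `a_ij`
over accepted solutions has magnitude ≥ `strength_floor` (0.05) and the
fraction of solutions agreeing with the median's sign is ≥
`sign_support` (0.8). Because restarts resample subjects, the support
fraction approximates a stability-selection frequency and filters
edges driven by a few subjects. Self-limitation terms (the diagonal)
are reported separately, not as self-loops.

## Equilibrium estimation

`ȳ` is the arithmetic mean of the floored relative abundances over a
chosen week-of-age window — the full series for untreated groups,
post-treatment weeks (≥ 9 weeks of age) for treated ones. A detection
floor (default 1e-4) replaces zeros before renormalisation so `ȳ` is
strictly interior, which both the growth-rate elimination and the
interior Jacobian require. Whether a per-window mean, per-time-point or
terminal estimate is preferable is an open modelling choice; the
window-mean is the package default and is exposed everywhere.

## Synthetic data generator

The generator emulates a two-cohort longitudinal mouse study: seven gut
phyla (Actinobacteria, Bacteroidetes, Cyanobacteria, Firmicutes,
Proteobacteria, Tenericutes, Verrucomicrobia), weekly fecal samples
from 3 to 15 weeks of age, 12 mice per group, an untreated control
group and a vancomycin-treated group with different ground-truth
networks.

* **Latent dynamics on the simplex.** Compositions evolve under the gLV
  field projected onto the simplex: `p' = diag(p)(r + Ap) − p·φ(p)`
  with `φ = Σ_i p_i (r + Ap)_i`. The projection subtracts the common
  total-abundance mode — which is unobservable in relative data — and
  leaves the interaction matrix and interior equilibrium unchanged. A
  free-total latent state would inject an unobservable confounder
  `-(S−1)·r` into every growth target.
* **Initial conditions.** Each subject starts at the equilibrium
  perturbed by i.i.d. lognormal factors (σ = 1.2, the scale of the
  weaning-to-adult composition transition) and renormalised. This
  transient is the main excitation that identifies interaction signs.
* **Process noise.** After each weekly observation the latent
  composition receives a logistic-normal kick (lognormal σ = 0.1,
  renormalised) that persists in the subsequent dynamics — true process
  noise, not readout noise.
* **Read sampling.** Each observation is a multinomial draw of 10 000
  reads from the latent composition; columns sum exactly to the depth.
* **Presets.** Edge magnitudes sit at 0.6 with self-limitation between
  −0.8 and −1.4, chosen once so both presets are comfortably stable
  (diagonally dominant Jacobians). The control network contains a
  Proteobacteria hub (edges to Actinobacteria, Bacteroidetes,
  Verrucomicrobia) plus a positive Bacteroidetes → Verrucomicrobia
  edge; the vancomycin network keeps the latter, removes the hub, and
  gains a positive Firmicutes → Verrucomicrobia edge. Equilibria mimic
  a Firmicutes/Bacteroidetes-dominated gut with Bacteroidetes depleted
  and Verrucomicrobia expanded under vancomycin. All preset values are
  illustrative fixtures, not estimates of a real community.

### What the synthetic studies show — and what they do not

Passing recovery tests on these data demonstrates that the whole chain
(aggregation, flooring, equilibrium estimation, constrained search,
consensus, comparison) is self-consistent and that the method can
recover strong interactions under multiplicative process noise,
multinomial counting noise and compositional closure at realistic
study sizes. It does **not** demonstrate that real gut communities
follow gLV dynamics, that weekly sampling suffices for real systems,
or that the compositional identifiability gap (the row/column-shift
ambiguity resolved here by sparsity) is harmless for real data. Signal
strength matters: with 12 subjects and 13 weekly samples, edges from
taxa near 1% abundance are at the edge of detectability, and
per-dataset noise can push individual weak edges in or out of the
consensus.

## Numerical choices

* Integration: LSODA with rtol 1e-7 / atol 1e-9; negative excursions
  below 1e-10 are clipped (the positive orthant is invariant
  analytically); any |y| above 1e6 aborts with a divergence error —
  divergent candidates are expected while sampling.
* The merit's single RK4 step per weekly interval has truncation error
  far below the process-noise floor for per-capita rates up to ~1/week.
* Eigenvalues via LAPACK (`numpy.linalg.eigvals`); strictness of the
  stability test is enforced through the margin, never by comparing to
  exactly zero.
* Tie-breaks in compass polling: row-major coordinate order, `+step`
  before `-step`; first improvement accepted.
* Degenerate inputs: all-zero samples become uniform after flooring;
  boundary equilibria are supported in the stability report (the
  `diag(r + Aȳ)` term is kept) but the default path forces interior
  equilibria via the floor.

## Known limitations

* Relative-abundance gLV is an approximation; absolute dynamics with a
  varying total are not identifiable from compositions alone.
* The consensus procedure (median + support + floor) is a documented
  design choice; other distillations of the admissible ensemble are
  defensible.
* Time-varying treatments (antibiotic kill terms), higher-order
  interactions, and stochastic gLV simulation beyond weekly kicks are
  out of scope.
* The problem sizes used in the bundled studies (12 subjects, 13 weekly
  samples, 200 restarts) were chosen as the package's default study
  scale; recovery rates degrade quickly below them.
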