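# Methods

## Model structure

The cascade is assembled as an explicit list of 29 elementary reactions over
20 species.  Relative units throughout: [MAPKKK]\_total = 1 sets the
concentration scale, and the MAPKKK-activation catalytic constant — fixed at
1 and excluded from the free parameters — sets the time scale.  The 28 free
rate constants are: input turnover `ka_in`, `ki_in`; the feedback magnitude
`kf`; MAPKKK inactivation `k-1`; and eight binding/dissociation/catalysis
triplets `kbN/kdN/kN` (phosphorylation: N = 2, 3 on MAPKK and 4, 5 on MAPK)
and `kb-N/kd-N/k-N` (dephosphorylation, in the order pp→p then p→0).

Modeling assumptions, and why:

- **Distributive dual (de)phosphorylation.** Each site requires its own
  enzyme–substrate collision.  This is the two-collision mechanism that
  underlies zero-order ultrasensitivity in the cascade and competitive
  inhibition between the unphosphorylated and mono-phosphorylated substrate
  forms at a shared enzyme.
- **Explicit complexes, irreversible catalysis.** Binding is reversible,
  catalysis releases enzyme and product in one step; there are no product
  complexes.  Complexes sequester both partners, which is what makes
  enzyme/substrate competition dynamically consequential.
- **Stimulus acts on the input node only.** The stimulus strength S
  multiplies the input-activation rate (`ka_in·S·[Input_inactive]`), with
  [Input]\_total = 1 fixed.  A consequence worth noting: the cascade's drive
  saturates as S grows (the active-input fraction approaches 1), so
  stimulation cannot be pushed arbitrarily hard — this matters for which
  bistable parameter sets can ever switch on (see Limitations).
- **One feedback magnitude, one feedback at a time.** `kf` adds
  `kf·[pp-MAPK]·[Input_inactive]` to activation (positive topology) or
  `kf·[pp-MAPK]·[Input_active]` to inactivation (negative topology); the
  no-feedback topology constrains `kf = 0`.  With `kf = 0` all three
  wirings are dynamically identical, which makes the paired topology
  comparison in the screen exact.  Feedback acts at the input level (not
  directly on MAPKKK); this choice keeps the cascade proper identical
  across topologies.

Each of the six moieties (input, MAPKKK, MAPKK, MAPK, M2KP, MKP) is
conserved exactly by construction; `stoichiometry @ conservation.T = 0` is
asserted in the test suite and the integrator preserves the totals to
round-off because the right-hand side is evaluated as N·v(x).

The right-hand side and Jacobian are JIT-compiled (numba) with pure-numpy
fallbacks; a separately coded loop over the reaction list
(`rhs_brute_force`) serves as the cross-check oracle in the tests.

## Steady states and the two-branch protocol

`find_steady_state` integrates with LSODA over a fixed checkpoint grid
(log-spaced head for fast transients, dense linear tail to resolve
oscillations) up to `t_cap = 2000` time units.  A checkpoint counts as
converged when the state-change rate falls below `ss_tol / ss_window`
(defaults 1e-9 per 10 time units, scaled by the state magnitude).  Every
candidate is then **confirmed** in two steps before being accepted:

1. a damped root polish of the rhs with six rows replaced by the
   moiety-conservation constraints (residual ≤ 1e-10), rejected if it moves
   the state by more than 1% of its magnitude; and
2. a linear-stability check: no Jacobian eigenvalue with real part clearly
   positive (the six conservation zero modes aside).

The confirmation is not optional bookkeeping.  Trajectories in this model
can crawl along "ghost" plateaus (saddle-node remnants) and slow manifolds
where the drift rate dips below any threshold: without step 1 a drifting
state is reported as steady, and without step 2 the polish can converge
onto a saddle.  Both failure modes were observed and both fake hysteresis.
Unconfirmed candidates simply resume the scan; genuinely slow monotone
transients are extended on a geometric grid to `t_cap_slow = 50000`.  A
trajectory that fails to converge but shows ≥ 3 persistent peaks is
reported as a named non-stationary (oscillating) outcome, distinct from
solver failure.

Dose–response sweeps solve every stimulus on the grid (default {0} ∪ 40
log-spaced points on [1e-3, 10]; 16 points inside screens) **independently
from the quiescent state** for the up branch — no path continuation, since
continuation would erase exactly the history dependence being measured —
and from SCV\_max, the up-branch state of maximal output, for the down
branch.  Non-stationary points are masked, not fatal.

## Indicators

- **Output** counts free pp-MAPK only.  Kinase sequestered on the
  phosphatase is catalytically unavailable, so it does not contribute to
  signaling; the choice is localized in `indicators.output` and testable
  against the total-form convention.
- **Gradient** uses the 10%–90% secant of the up branch, anchored at the
  *measured* saturated maximum.  `S(x)` comes from consistent log-stimulus
  interpolation, optionally refined by bisection on fresh steady-state
  solves; the bisection terminates on both an absolute (1e-4·S\_max) and a
  relative (2%) bracket criterion, because on a log-spaced grid an absolute
  criterion alone leaves crossings near S = 0 unresolved.  When both
  anchors collapse onto one switching stimulus (a discontinuous response),
  the secant is capped at the resolution floor and flagged `saturated`
  rather than reported as a spurious finite slope.
- **Bistability** is the down/up output ratio at the check point
  `S_cp = S(0.1·O_ss_max)`.  Both branches are interpolated *on the same
  grid with the same rule*, so for coincident branches the two
  interpolations cancel exactly and mono-stable systems report exactly 1.0
  no matter how steep the response.  (Evaluating the up value by its
  defining identity `O_up(S_cp) = 0.1·O_ss_max` while solving the down
  value fresh is not safe: for branches steeper than the grid the
  interpolated S_cp can land past the switching threshold, and the
  mismatch manufactures an index near 10 on mono-stable models.  This was
  verified directly with a multi-start root finder and is the reason for
  the consistent-interpolation estimator.)  The index is clipped to its
  theoretical range [1, 10]; the raw ratio is kept alongside.
- **Temporal classes** are detected on the saturating-stimulus time
  course.  Oscillation: ≥ 3 maxima after the first quarter of the horizon,
  peak-to-trough amplitude > 0.05, and last/first peak amplitude ratio
  > 0.5 (sustained, not a decaying ring).  Transient: peak in the first
  half of the horizon with final output below half the peak.  These
  thresholds are conventions of this package, exposed in `Thresholds`.

Classification thresholds (responsive 0.1, ultrasensitive 1.0, bistable
1.5, absolutely bistable 9.5, anchors 0.1/0.9) are config keys with these
defaults; all comparisons are strict.

## Sampling law and screen scale

Rate vectors are drawn i.i.d. log-uniformly on [0.1, 10] per rate — one
decade either side of the unit MAPKKK-activation rate — so forward/backward
and binding/dissociation log-ratios are symmetric about zero and populate
half-decade bins evenly.  The range and law are config keys.  Each sampled
vector is evaluated under all three topologies with shared non-feedback
rates (the `kf` draw is pinned to zero for the no-feedback arm), giving
paired topology comparisons.  Draws are seeded and prefix-stable: the first
n vectors of a larger draw equal the n-vector draw, so subset screens share
their parent's rate vectors.

Screens in the test suite use 100 rate vectors (responsiveness census), 25
(full dose–response indicators), and 50 (weak-stimulus comparison at
S\_max = 1); the acceptance script uses 200 and 50.  These sizes were chosen
as the smallest at which the pooled fractions stabilize to a few percent —
the pipeline itself scales to the full 2000-vector design unchanged, and
per-model records make long runs resumable.  Screens run the
classification-grade solver (rtol 1e-7, ss\_tol 1e-8); an 864-model
comparison against tighter settings produced bit-identical classifications.

## What the generator emulates — and what it does not

The randomized screen emulates *parameter ignorance around a fixed, correct
topology*: every model shares the same 20-species cascade, exact
conservation, and noise-free "measurements" of its own dynamics.  It does
not emulate real-data features — cell-to-cell variability, stochastic
kinetics at low copy number, unmodeled reactions (scaffolds, upstream
receptor dynamics), or measurement noise.  Passing screens therefore
support claims about the *model family's* dynamic repertoire, not about any
specific biological system's parameters.

The dependence on the sampling law is real and documented rather than
hidden:

- Under this law the pooled responsive fraction measures ≈ 40–45%
  (seed-dependent; 44.96% of 21,600 models at acceptance seed 1,
  39.7% of 10,800 at the test-suite seed), around the reported census
  level of ~46%.
- Responsive bistable models are dominated by positive-feedback toggles.
  Feedback-free (competitive-binding) bistability does exist in the law's
  support — confirmed by an independent multi-start root search that finds
  coexisting stable steady states — but it rarely co-occurs with
  responsiveness, because the input saturates and the up sweep cannot push
  the cascade over the switching threshold.  Consequently the small-k3/k5
  enrichment among bistable models is *not* reproduced at this law
  (one-sided rank tests come out flat), and the corresponding property
  test fails honestly rather than being weakened.  The bistable fixture is
  a genuine feedback-free case (small k3, tight phosphatase binding,
  5-fold MAPK excess) located by that root search.
- Temporal dynamics are rare and require negative feedback, and they
  become more frequent when the stimulus is weakened from 10 to 1 — both
  checked as properties on the screens.

## Fixture catalog

Six frozen parameter sets under `data/fixtures/` (regenerated by
`scripts/find_fixtures.py`): quiescent (`ka_in = 0`), linear-responder
(weak binding — first-order cycles, graded and mono-stable), ultrasensitive
(tight binding — zero-order cycles), bistable (see above), oscillator
(slow input turnover, strong negative feedback `kf = 30`, zero-order
cascade; sustained oscillation at stimulus 1.0), and transient (located by
seeded screening at stimulus 1.0).  Every label is re-verified at default
and 10× tighter solver tolerances before the file is written; each file
carries its provenance.  These files are this package's own synthetic
constructions, not parameters of any published system-specific model.

## Degenerate inputs and tie-breaks

All-zero states have zero derivatives; species at zero concentration are
never driven negative (mass action), and reported trajectories clip
round-off at −1e-12.  `S(x)` on non-monotone branches returns the smallest
crossing.  Ratios with zero denominators (e.g. r\_SU with no responsive
models) are null, never 0.  Integration failures are logged, excluded from
denominators, and a failure rate above 5% aborts the screen with a
diagnostic; observed rates are below 1.5%.

## Known limitations

- Statements that depend on the unknown original sampling distribution
  (the exact responsive percentage, bistable share, k3/k5 enrichment) are
  law-conditional; see above.
- No bifurcation continuation or eigenvalue tracking along branches: the
  protocol measures hysteresis operationally, exactly as defined, and can
  miss bistable regions whose low branch exceeds 10% of the maximum before
  the jump (by construction, such hysteresis does not "cover a significant
  range" of the response).
- Oscillation detection is time-domain peak counting on a finite horizon;
  very slow oscillations (period ≳ 500 time units) can be classified as
  slow transients.
- SBML support is a minimal Level-3 writer/reader for mass-action models —
  sufficient for interchange and the reaction database, not a general SBML
  toolkit.
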