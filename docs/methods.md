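# Methods

## Models

All systems are the nondimensional forms obtained under equal degradation
rates, with time measured in units of the common degradation rate. The
package works exclusively in these scaled coordinates; the dimensional
kinetics and the scaling itself are regarded as documentation, since every
dynamical statement (Hopf values, frequencies, periods) is invariant under
the change of variables.

**Single cell** (`SingleCell`, dim 3): mRNA → protein → repressor with
transcription `α f(x₃)` and unit linear degradation in each stage. The
optional rate factor `σ` multiplies the whole vector field; it rescales time
only, so the spectrum and every extracted frequency scale exactly by σ. It
is how "a faster cell" is modelled in the nonidentical pair.

**Repressions** (`HillRepression`, `SequestrationRepression`): both strictly
decreasing with `f(0) = 1`. The Hill form models cooperative promoter
binding (parameters n, k_H); the sequestration form is the unsequestered
fraction of a total activator pool A when the repressor binds it with
dissociation constant k_d. First, second and third derivatives are coded in
closed form (the sequestration derivatives collapse to
`f₂″ = 2k_d/S³`, `f₂‴ = 6k_d w/S⁵` with `w = A−x−k_d`, `S = √(w²+4Ak_d)`),
because the normal-form reduction needs exact quadratic/cubic tensors.

**Coupled identical cells** (`CoupledIdentical`, dim 4N, default N = 2):
each cell gains a released-signal variable `x₄` relaxing to `f(x₃)` at rate
`s` (fast intercellular signalling, default s = 20 in the worked examples)
and every cell's transcription sees the population mean of the signals with
strength `c`. `SynchronousReduced` (dim 4) is the restriction to the
invariant synchronous diagonal; its characteristic polynomial is exactly the
bifurcating factor Δ₊, which is what reduces the N-cell analysis to a
quartic.

**Coupled nonidentical cells** (`CoupledNonidentical`, dim 8): cell 2's
internal clock is multiplied by σ (default 1.05, i.e. a 5% faster cell);
signal kinetics and the mean-field term are shared. The equilibrium is no
longer homogeneous; it is solved as a 2-D system in (x̄₃, ȳ₃), seeded from
the decoupled equilibrium and polished by a damped Newton step (the
sequestration nonlinearity has a sharp knee near x ≈ A that can stall
quasi-Newton solvers).

**Segmentation clock pair** (`SegmentationClockPair`, dim 8): a her-gene
circuit per cell — mRNA, cytoplasmic and nuclear protein with
Michaelis–Menten degradations, plus a coupling signal produced under Hill
repression by nuclear protein and sensed by the partner cell with strength
ν_c. Its Jacobian is derived directly from the stated equations. No
published parameter set ships with the package; the solver runs on
user-supplied parameters (a synthetic oscillatory set used by the test suite
lives in `tests/conftest.py` and is labelled as such).

## Hopf location

`char_coefficients` uses the Faddeev–LeVerrier recursion so the coefficients
are polynomial in the Jacobian entries; the eigenvalue-product route is kept
as a test oracle only. Hurwitz determinants are dense determinants (m ≤ 8,
no symbolic path needed). The degenerate Routh–Hurwitz classification uses a
relative zero tolerance of 1e−9 on `D_{m−1}`.

The **general locator** scans `D_{m−1}(α)` on a bracket (default 40 points),
refines every sign change by Brent's method, and accepts a root only if the
side conditions (`b_m > 0`, `D_i > 0` for i ≤ m−2) hold and the spectrum
shows exactly one conjugate pair with |Re λ| ≤ 1e−7 and everything else
strictly stable. Other roots of `D_{m−1}` — e.g. the second zero where a
pair crosses while another pair is already unstable — are reported as
degenerate candidates, never returned silently. The crossing derivative is a
central difference with step `1e−6·max(1, |α*|)`, re-solving the equilibrium
at each evaluation, because γ(x̄(α)) makes the dependence implicit. Note the
raw magnitude of `D₇` is enormous (∼1e17 for the 8-D gene circuits); only
its sign and zero matter, and a Brent root refined to `xtol 1e−12` in α
leaves a residual `|D₇|` of order 1e8–1e9, which is why the locator
certifies the root by the bracketing, not by a smallness test on D₇.

For identical cells the closed form is used instead: the "+" branch of the
quadratic for α* (only `s > 1` is supported; the other branch belongs to
`s ≤ 1`, which the package rejects), solved self-consistently with
`(α*+c) f(x̄) = x̄` by a scan-and-bracket root finder in x̄. The
sequestration model can produce two self-consistent roots; the smaller
equilibrium is returned since it carries the smaller (biologically relevant)
HB value, and roots violating the positivity bound
`γ < 8(s+1)³/(c s (s+3)²)` are discarded as infeasible. As `c → 0` the
asynchronous pair of the 8×8 spectrum also approaches the imaginary axis
(the decoupled system has a double imaginary pair), so the spectrum
cross-check compares the pair nearest `iω_c*` rather than demanding global
uniqueness in that limit.

**HB curve continuation** is natural-parameter: each solved α* seeds the
bracket at the next coupling value; one bisection of the coupling step is
attempted before a grid point is flagged as lost.

## Eigenvalue paths

`trace_segment` interpolates parameter records linearly (the published
comparisons all use straight segments), solves the equilibrium warm-started
step to step, and matches eigenvalue branches by greedy nearest-neighbour
with an optimal-assignment fallback when the greedy pairing collides.
Default 200 steps. At the degenerate start point (identical cells at c = 0)
branch identity is undefined; labels become meaningful from the first
interior step, and the branch that is purely imaginary at the far endpoint
is the bifurcating one. `classify_transition` distinguishes the route where
the equilibrium passes through a two-dimensional instability mid-segment
(observed for Hill repression in the worked examples) from the route that
stays stable until the endpoint (sequestration).

## Limit cycles

Integration is DOP853 at rtol 1e−12 / atol 1e−14 with dense output (the 8-D
coupled runs in the test suite use 1e−10/1e−12, which changes extracted
frequencies by < 1e−8). The period is measured on a Poincaré section:
upward crossings of the repressor component `x₃` (cell 1) through the mean
of the trailing 50-time-unit window, with event times refined on the dense
interpolant. The transient policy: integrate windows of 50 time units; after
each window probe ≈ 6 periods of crossings; accept when (a) successive
period estimates agree to rel 1e−9 *and* (b) the oscillation span of the
window has stopped changing (rel 5e−4). Condition (b) exists because a
slowly decaying spiral around a stable focus also has convergent return
times — without it a stable equilibrium could masquerade as a cycle. The
overall time cap is 5000 units; within ∼1e−3 of a Hopf value the Floquet
contraction rate is O(α−α*) and the cap is reached first, which the package
reports as a no-cycle error rather than returning an unconverged period.
Tests that probe the immediate post-onset regime therefore start from the
normal-form approximation of the orbit (x̄ + 2ε Re q, ε² = δ/p₂) instead of
a blind perturbation.

Amplitude is half peak-to-trough per component over one final cycle (the
precise convention is not fixed by the source analyses; figure-level
comparisons are qualitative). Phase differences for 8-D models are peak-time
offsets of cell-2 components against cell-1 components, folded to
[−T/2, T/2), with parabolic refinement of the sampled peaks.

`find_matching_coupling` locates the coupling strength where the collective
frequency equals a target (typically the average frequency of the decoupled
cells) by a coarse scan plus Brent refinement over cycle extractions,
warm-starting each extraction from the previous cycle.

## Normal form

`hopf_coefficients` implements the classical center-manifold projection:
right/left eigenvectors with `p·q = 1` and the pivot convention that the
largest-magnitude component of q equals exactly 1 (all sign conclusions and
the period expansion are invariant under this scale choice; individual g
values are not, and are reported under this convention). The quadratic
center-manifold corrections w₂₀, w₁₁ are solved on the full space with the
critical components projected out, so the resonant planar terms enter only
through the explicit `(i/2ω)(g₂₀g₁₁ − 2|g₁₁|² − |g₀₂|²/3)` combination —
solving without the projection double-counts those terms and inflates the
period coefficient (caught during development by comparing the predicted
`dT/dα = T₀T₂/p₂` against brute-force simulated periods; they now agree to
a few percent at offsets of 1e−2). Derivative tensors are analytic for the
gene-circuit models (only f is nonlinear, one direction per cell) and
directional finite differences of the analytic Jacobian for the
segmentation clock. `λ′(α*)` is a central difference over re-solved
equilibria. `|Re C₁| < 1e−10` is classified as degenerate rather than
forced into a sign.

For both gene-circuit repressions at their single-cell Hopf points the
computed pattern is `p₂ > 0, ζ₂ < 0, T₂ > 0`: supercritical, stable cycle,
period growing with α — consistent with the simulated sweeps (frequency
decreases and amplitude grows with α in both models).

## Reference values and known discrepancies

All closed-form anchor values (x̄, γ, α₀, α*, ω_c*, ω*, the printed 8×8
spectra) are reproduced to the printed precision and asserted at abs 1e−4
to 1e−6 in the tests. The simulated-period anchors are the exception: fully
converged runs (rtol 1e−12, transient iterated to rel 1e−9, cross-checked
with an independent lsoda integration) give 3.6372839017 where 3.6367989020
is quoted, 3.9303548 vs 3.9302912, and frequency 1.6643116 vs 1.664346.
The two quoted companion periods agree with each other to 1.3e−7 while the
converged ones differ by 3.2e−4 at the same printed drive value, so the
quoted 10-digit figures cannot be asymptotic periods at those exact
parameters; the acceptance test records this comparison and fails at the
quoted precision by design, and the test-suite reference values are the
converged ones.

## Problem sizes and runtime

Everything is desk-scale: dense linear algebra on m ≤ 8, scalar/2-D root
finding, and 3-D/8-D ODE integration over at most a few thousand time
units. The full test suite runs in about two minutes on one CPU; the
acceptance script in a few seconds.

## Limitations

Only simple Hopf bifurcations are treated (no folds, double-Hopf, or
symmetry-breaking branches); continuation is natural-parameter, so a fold in
the HB curve would end the branch. Cycle stability is inferred from the
normal-form signs plus empirical convergence, not from Floquet multipliers.
The identical-cell closed forms assume `s > 1`. Delay-differential
segmentation-clock variants, Michaelian-degradation feedback loops and
unequal degradation rates are out of scope.
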