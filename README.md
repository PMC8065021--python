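# oscillab

Hopf-bifurcation analysis of genetic negative-feedback oscillators and the
collective rhythms of coupled cells.

Many biological clocks — the mammalian circadian pacemaker, the zebrafish
segmentation clock — are populations of cellular oscillators that agree on a
common rhythm through intercellular signalling. Two questions recur: *at
which parameter values does a cell (or a coupled population) start to
oscillate?* and *how does the collective frequency of the coupled population
compare with the average of the individual frequencies?* `oscillab` answers
both for the minimal genetic negative-feedback loop

```
x1' = α f(x3) − x1        (mRNA)
x2' = x1 − x2             (protein)
x3' = x2 − x3             (repressor)
```

with either **Hill-type repression** `f₁(x) = 1/(1 + (x/k_H)^n)` or
**protein-sequestration repression** `f₂(x) = (A − x − k_d + √((A − x − k_d)² + 4A k_d))/(2A)`,
for mean-field–coupled populations of such cells (identical or with a rate
mismatch σ), and for a two-cell segmentation-clock circuit with
Michaelis–Menten degradation.

## Method

Stability of the equilibrium `x̄` is read off the characteristic polynomial
`λ^m + b₁λ^{m−1} + ⋯ + b_m` of the Jacobian through the Hurwitz determinants
`D_i`. A **simple Hopf bifurcation** — one purely imaginary pair, all other
eigenvalues stable — occurs exactly when

```
b_m > 0,   D_i > 0 (i = 1,…,m−2),   D_{m−1} = 0,   d D_{m−1}/dα ≠ 0,
```

so Hopf values are located as bracketed zeros of `D_{m−1}(α)` with the
equilibrium re-solved at every trial α. Key closed forms implemented and
tested:

* single cell: `α₀ = 8/γ` with `γ = −f′(x̄)`; the frequency at onset is
  `√3` for *any* decreasing repression function;
* two (or N) identical coupled cells (signal timescale `s`, strength `c`):
  the characteristic polynomial factors as `Δ₊·Δ₋`, the synchronous factor
  bifurcates at
  `α* = [−(s−1)(s²+4s+7) + (s+3)√((s²+3)²−4scγ)]/(2γ)` with collective
  frequency `ω_c* = √([√((s²+3)²−4scγ) − (s²−3)]/2)` — here the repression
  mechanism *does* matter, through γ;
* nonidentical cells: numeric `D₇ = 0` locator on the 8×8 system.

Around a located Hopf point the package computes the
Hassard–Kazarinoff–Wan normal form (`g₂₀, g₁₁, g₀₂, g₂₁, C₁, p₂, ζ₂, T₂`)
to classify criticality, cycle stability and the period trend, traces
matched eigenvalue branches along segments in the `(c, α)` plane, and
extracts limit-cycle periods/amplitudes/phase offsets from tightly-toleranced
simulations (Poincaré sections with interpolated event times).

## Worked example

Where does the Hill-type cell (n = 11, k_H = 0.136) start to oscillate, and
what happens when two of them are coupled (s = 20, c = 0.05)?

```sh
$ oscillab hb-single --fixture ex3.1
{
  "alpha0": 0.545173539781,
  "x_bar": 0.148683692668,
  "gamma": 14.6742264916,
  "omega_star": 1.73205080757,
  "crossing_derivative": -4.89140883442
}
$ oscillab hb-coupled --model ht --n 11 --kH 0.136 --s 20 --c 0.05
{
  "alpha_star": 0.474162697928,
  "omega_star": 1.72122892723,
  "x_bar": 0.148031985997,
  "gamma": 15.0591083808,
  "crossing_derivative": -47521.8864522
}
```

Reading: the isolated cell bifurcates at `α₀ ≈ 0.5452` with frequency
`√3 ≈ 1.7321`; the coupled pair bifurcates earlier (`α* ≈ 0.4742` — coupling
promotes oscillation) and at a *lower* collective frequency `ω_c* ≈ 1.7212`,
because `ω_c*` decreases with the repression slope γ and the coupling
strength. The nonzero crossing derivative certifies that the eigenvalue
pair crosses the imaginary axis transversally.

The same analysis from Python:

```python
from oscillab import HillRepression, coupled_identical_hb

hp = coupled_identical_hb(HillRepression(n=11, k_H=0.136), c=0.05, s=20.0)
print(hp.parameters["alpha"], hp.omega_star)   # 0.474162... 1.721228...
```

Other subcommands: `hb-curve` (Hopf curve in the `(c, α)` plane),
`eigenpath` (eigenvalue branches between the decoupled and coupled Hopf
points), `simulate`, `sweep` (frequency/amplitude vs a parameter),
`match-coupling` (coupling strength at which the collective frequency meets
the average of the individual frequencies), `normalform`, `list-fixtures`.

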