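# Methods

## Model and variants

Two structurally identical networks of `n` FitzHugh–Nagumo neurons are
integrated side by side. Per neuron the membrane potential carries the
cubic nonlinearity `x(x-1)(1-rx)` (roots at 0, 1, 1/r), the linear
recovery variable evolves as `b x - c w`, and every membrane receives the
same sinusoidal stimulation `(A/ω) cos(ωt)`, a small ionic disturbance
`a sin(0.2 t)`, and diffusive gap-junction input `Σ_j g_ij x_j1`. The
gap-junction matrix has non-negative off-diagonals and zero row sums, so
the coupling vanishes identically on the synchronization manifold (all
membranes equal) — a conservation property the simulator and several tests
rely on.

Four variants arise from two switches:

* **Delays.** In the delayed variants the drive's coupling term is read at
  `t - τ1` and the slave's at `t - τ2`. Synchronization is then *lag*
  synchronization, judged on the lagged half-errors
  `e^τ = (x(t-τ1) - y(t-τ2))/2`.
* **Noise.** In the noisy variants a Gaussian white noise of intensity `D`
  is added to the membrane equations; drive and slave receive the *same*
  realization (common noise), so the noise cancels exactly in the
  drive–slave difference.

The reference benchmark uses five neurons with `r = (10, 10.2, 10.4, 10.6,
10.8)`, `b = (1, 1.001, …, 1.004)`, `c = (0.001, …, 0.005)`, disturbance
amplitudes `(0.001, …, 0.005)` at rate 0.2, `A = 0.1`, `f = 0.129`, a fixed
5×5 gap-junction matrix printed to five significant figures (validation
tolerance 5e-7 for that reason; exactly constructed matrices validate at
1e-12), and identical drive/slave initial conditions. Under this forcing
the network is chaotic: two copies started `1e-3` apart desynchronize to
order-one errors, which is the uncontrolled baseline the controller is
measured against.

Parameters the benchmark leaves open are fixed once as package defaults:
gap-junction delays `τ1 = 0.4, τ2 = 0.2` (a modest lag difference of the
order of the integration timescale), noise intensity `D = 0.01` (increments
of standard deviation `√(2·0.01·0.005) = 0.01` per step, comparable to but
not dominating the deterministic drift), slave-IC perturbation `ε = 1e-3`,
and horizons `t_end = 300` (non-delayed) / `250` (delayed). The
perturbation exists because the benchmark's drive and slave initial
conditions are *identical*: without it the uncontrolled non-delayed error
is identically zero (drive and slave are the same trajectory bit for bit),
which the degenerate-case test documents.

## Integration

Fixed-step schemes on a uniform grid, `dt = 0.005` by default:

* deterministic variants: classical four-stage Runge–Kutta (fourth order;
  the order test measures a halving ratio ≈ 16 on the benchmark dynamics);
* noisy variants: Euler–Maruyama with additive increments `√(2 D dt) z`,
  the same `z` added to both membrane blocks. With `D = 0` this is explicit
  Euler, and a `D = 0` noisy run is bitwise identical to a non-noisy run
  integrated with the same scheme.

Delayed terms use a history buffer on the step grid with constant
pre-history equal to the initial condition (the simplest reproducible
choice) and linear interpolation between grid points; lookups are exact at
grid points. Delays must be zero or at least one step, so the
mid-interval Runge–Kutta stages never need future history. One seeded
generator drives all randomness of a run; a run is reproducible from
`(config, schedule, t_end, dt, seed, method)`.

A divergence guard aborts with a diagnostic when any state exceeds 1e6.

## Control convention

Both networks nominally carry control inputs with `u = u_x - u_y`
determined by the design. The drive is left unactuated (`u_x = 0`) and the
designed `u` is applied **additively to the slave membrane equation**
(`u_y = u` in the slave's `+u_y` slot), so `u` enters the half-error
dynamics as `-u/2`. This placement was fixed by experiment: with the
trigonometric law the `+u` slave placement synchronizes the non-delayed
benchmark in ~12 time units, while the opposite sign feeds the error back
positively and diverges. The reduced error system

    e_x' = -(r/2) c_d + ((1+r)/2) s_d - e_x - e_y + G e_x + u,
    e_y' = b e_x - c e_y,

with `c_d = x³ - y³`, `s_d = x² - y²` (and a single shared `r`) is kept as
an independent validation path: replaying it along a stored run with the
matched control `-u_applied/2` reproduces the directly simulated errors to
~1.7e-7 in max norm over 50 time units — which pins the factor-of-two
bookkeeping between the half-errors and the applied input.

The gains `g_i1, g_i2` of the trigonometric law are read from columns 1
and 2 of the coupling matrix (row `i`); the columns are configurable
because that subscript convention is genuinely ambiguous.

## What the laws do and do not achieve

These are the package's measured findings on the benchmark, all recomputed
by `scripts/acceptance.py`:

* **Non-delayed variants, controlled:** every error component falls below
  `1e-3` within ~12 time units of activation and stays there. The
  trigonometric law's effective membrane-error gain is ≈ `2(b+c)` ≈ 2,
  enough to dominate the chaotic transversal instability.
* **Delayed variants, controlled:** the lagged linear law does **not**
  synchronize. Its membrane-error gain is `g_i1(b_i - c_i)` = O(1e-3) —
  three orders of magnitude too weak for the chaotic transversal dynamics —
  and with `τ1 ≠ τ2` the stimulation terms `I(t-τ1) - I(t-τ2)` leave a
  persistent forcing of amplitude ≈ `A(τ1-τ2)/2 = 0.01` on the lag error
  that no error feedback can null. Errors remain O(0.1–1). The law is
  implemented exactly as designed; the corresponding acceptance
  parametrizations fail, which is the faithful outcome.
* **Noisy variants, uncontrolled:** common membrane noise at the default
  `D = 0.01` synchronizes the networks *by itself* (noise-induced
  synchronization — the common kicks make the transversal Lyapunov
  exponent negative; observed for `D ≥ 0.001` across seeds). The
  "desynchronized baseline" therefore exists only in the non-noisy and in
  the delayed (lag-error) scenarios.
* **Lyapunov descent:** along the converging non-delayed runs the error
  energy `V` decays by >10 orders of magnitude, but **not monotonically**:
  the convergence is a damped rotation in the `(e_x, e_y)` plane, and the
  finite-difference `V̇` shows transient positive excursions (~8% of the
  descent window). Pointwise `V̇ < 0` would require the cross terms of the
  closed-loop quadratic form to cancel to within `≈ 2√(αc) ≈ 0.06` (the
  recovery damping `c` is only 1e-3), which no sign/scale convention of the
  implemented laws achieves. Consistently, the stability matrix `P` is
  **not** positive definite for the benchmark parameters (minimum
  symmetric-part eigenvalue ≈ −6.8 over the stimulation period): the
  sufficient condition simply does not certify the convergence that the
  simulation exhibits. Both verdicts are always reported, never asserted.

## Stability diagnostics

`V = (|e_x|² + |e_y|²)/2`; its derivative along runs is measured by
centered finite differences (no smoothing). The non-delayed `P` is
time-dependent through `sin ωt`/`cos ωt` entries and is swept over one
stimulation period (64 samples by default); the delayed `P` instead uses
trajectory bounds `q1 = max_i (max_t |x_i| + max_t |y_i|)` and
`q2 = max_{i,t} (x² + |x||y| + y²)` (the factor bounding `|x³-y³|/|x-y|`),
estimated from a simulated run with an optional safety margin. The
non-delayed `P` is built in its plain form by default; a variant weighting
its leading terms by `q1`/`q2` (consistent with the bound the blocks come
from) is available behind a flag, because the two formulations are not
mutually consistent and the choice should be visible.

Positive definiteness is decided two ways: Sylvester's leading-principal-
minors test applied to `P` exactly as assembled (conclusive only for
symmetric matrices — `P` is not symmetric), and the binding test on the
eigenvalues of `(P + Pᵀ)/2`. On symmetric inputs the two provably agree,
and the oracle test checks 200 seeded random symmetric matrices for exact
agreement. Scalars written against matrix blocks (`g_i1`, `b`, `c`, the
trigonometric terms) are broadcast as multiples of the identity block;
`neuron_index` selects which row supplies them, defaulting to neuron 1, and
the shared `r` of the reduction defaults to `r_1`.

## Numerical choices and degenerate inputs

* Convergence is operationalized as: max-norm error below `1e-3`
  sustained for 10 time units ("converged to zero" is otherwise
  unquantified); `convergence_time` is monotone in the tolerance.
* Trajectory CSV export prints 17 significant digits and reads back
  bit-exactly (`float_precision="round_trip"`); same-seed runs produce
  byte-identical CSV bodies.
* Neuron indices are 1-based in all user-facing outputs; array layout per
  network is `[membranes, recoveries]`, drive before slave.
* `ω` is always derived from `f`; a zero stimulation frequency is
  rejected rather than silently producing a division by zero.
* Sub-step delays (`0 < τ < dt`) are rejected; delays that are integer
  multiples of `dt` incur no interpolation error at grid points.

## What the benchmark does and does not show

The bundled scenarios exercise heterogeneous parameters across neurons,
chaotic forcing, delay mismatch and common noise, but they are still a
stylized five-neuron model: no chemical-synapse (directed) coupling, no
heterogeneous stimulation across neurons, no state-dependent or delayed
noise, and the delays/noise intensity are declared defaults rather than
physiologically fitted values. Passing tests demonstrate correctness of
the implementation and the behavior of these laws *on this model class*,
not biological realism, and the delayed-law and Lyapunov-descent findings
above are claims about the implemented designs under these conditions.
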