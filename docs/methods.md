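# Methods

## Model

The membrane follows the standard squid-axon Hodgkin-Huxley equation for
1 cm^2 of membrane,

    C dV/dt = -( g_m (V - E_L) + gK n^4 (V - E_K) + gNa m^3 h (V - E_Na) ) + I,

with C = 1 uF/cm^2, gNa = 120 mS/cm^2, gK = 36 mS/cm^2, g_m = 0.3 mS/cm^2,
E_Na = 50 mV, E_K = -77 mV, E_L = -54 mV, and the rate functions referenced
to V0 = -65 mV.  Gating kinetics are dx/dt = alpha_x(V)(1-x) - beta_x(V) x
for x in {n, m, h}.  Input currents carry the conventional "nA" label for
steps into 1 cm^2 of membrane; dimensionally they act as uA/cm^2 (1 uA/cm^2
through 1 uF/cm^2 gives 1 mV/ms), and every published number the package
reproduces is consistent under that reading.  The default initial state is
V = -65 mV with the gates at their exact equilibria (0.3177, 0.0529,
0.5961); at I = 0 the voltage stays within ~0.2 mV of rest (E_L = -54 means
-65 is not an exact fixed point of this parameter set).

One gating variable at a time may instead follow fractional-order
(power-law, history-dependent) kinetics,

    d^eta x / dt^eta = alpha_x(V)(1-x) - beta_x(V) x,   0 < eta <= 1,

with the Caputo derivative.  eta = 1 recovers the classic model exactly.

## Numerical scheme

The fractional gate is advanced by the L1 discretization on the uniform
grid t_k = k dt.  Solving the discrete Caputo equation for the newest
value gives

    x_N = dt^eta Gamma(2-eta) [alpha (1-x_{N-1}) - beta x_{N-1}] + x_{N-1} + M_N,

where the memory trace M_N = -sum_{k<=N-2} (x_{k+1}-x_k) [ (N-k)^{1-eta} -
(N-1-k)^{1-eta} ] feeds the entire past of the gate back into the update.
The weights depend only on the lag j = N-k, so one table b_j = j^{1-eta} -
(j-1)^{1-eta} serves every step, and the O(N) per-step sum is evaluated as
a contiguous BLAS dot product against the reversed table (the scheme
remains O(N^2) overall; a 300k-step run takes tens of seconds on one
core).  At eta = 1 every weight with lag >= 2 vanishes and the update is
exactly one forward-Euler step.

Coupling order per step: (1) the fractional gate is advanced with rates
evaluated at V(t_{N-1}) (fully explicit); (2) V and the two classic gates
take one RK4 step during which the fractional gate is held at its freshly
computed value.  Holding the fresh value keeps the splitting explicit and
makes the eta = 1 reduction exact in scheme terms.  The residual
difference from the all-RK4 classic integrator is then only the O(dt)
Euler gate step, which shows up as a slow spike-phase drift on long tonic
trains (< 0.05 ms per 500 ms at dt = 0.001) rather than any shape change.

Memory truncation: "full" history is the default and the authoritative
setting everywhere results are reported.  A window of K increments is
available for exploratory long runs; it reports a worst-case bound on the
neglected tail, max|dx| (N^{1-eta} - (K+1)^{1-eta}), on the returned trace.

Divergence handling: the explicit L1 step is unstable when
dt^eta Gamma(2-eta) (alpha+beta) is too large, which in practice means the
fast m gate at low eta (in the coupled model at eta <= 0.2 for dt = 0.001,
already at eta <= 0.3 for dt = 0.01; under hyperpolarized voltage clamps
the m gate can exceed the limit even at dt = 0.001).  The integrators
raise a `DivergenceError` carrying the (gate, eta, dt) triple and the
first bad time rather than clamping, and the phase-diagram sweep records
such cells with the distinct label "unstable".

There is no randomness anywhere: every run is a pure function of its
configuration.

## Mittag-Leffler function

Under a voltage clamp the fractional gate has the closed form

    x(t) = x_inf(V) + [x(0) - x_inf(V)] E_eta(-t^eta / tau_x(V)),

with x_inf = alpha/(alpha+beta), tau_x = 1/(alpha+beta), and E_eta the
one-parameter Mittag-Leffler function.  E_eta is evaluated on the
negative real axis by per-point regime selection with computed error
estimates rather than fixed argument splits:

- power series with compensated summation, accepted only when the largest
  summand (which grows like exp(|z|^{1/eta})) keeps the cancellation
  estimate below 1e-11 relative — the estimate includes the error the
  double rounding of eta*n injects through Gamma(eta*n+1), which
  dominates the plain unit-roundoff bound for large peak summands;
- the algebraic asymptotic expansion -sum z^{-n}/Gamma(1-eta*n) with
  optimal truncation (terms at Gamma poles are skipped, the smallest
  retained term bounds the error);
- for the remaining band (moderate |z| with eta near 1, where neither
  double-precision route certifies 1e-11) an arbitrary-precision series
  (mpmath, with exact-binary eta*n products and precision scaled to the
  peak summand) behind a per-eta Chebyshev interpolant of log E_eta, so
  dense time grids do not pay the mpmath cost per point.  Interpolating
  the logarithm makes the interpolation error uniformly relative.

Accuracy is better than 10 significant digits on z in [-50, 0] (verified
against exact-arithmetic series and against E_1 = exp and
E_{1/2}(-x) = e^{x^2} erfc(x)).

## Voltage-clamp characterization

Protocol: 25 ms at 0 mV (absolute, per the protocol definition;
configurable) followed by the target voltage.  The gate starts at its
steady state for the hold voltage, so the hold phase contributes no
increments to the L1 memory; the history therefore starts at target
onset, which is mathematically identical and avoids O(N^2) work on
constant samples.

The long-term response x_inf^eta is read at 90 ms (n), 40 ms (m), 110 ms
(h) after the step — times at which the traces change by less than 0.01%
per millisecond (the reader also verifies this criterion and flags
violations).  The h-gate read time forces the default target phase to
110 ms.

Exponential fits use the model x(t) = x_inf - A1 e^{-t/tau_fast} -
A2 e^{-t/tau_slow} (A2 = 0 for the single-component m-gate fit), sampled
log-uniformly in time (400 points): a power-law response spans
sub-millisecond to ~100-ms scales, and uniform sampling would bury the
fast component under the long tail (with uniform weights the fitted
tau_fast is not even monotone in eta; with log-spacing tau_fast falls
from 1.13 to 0.22 ms and tau_slow grows from 2.4 to 6.6 ms over eta
1 -> 0.4 at V = 30 mV for the n gate).  Two starting points
({0.3, 3} and {0.05, 10} x tau_classic) guard against local minima, and
the dual fit collapses to the single-exponential solution when one
exponential already explains the data to 1e-5 of the response amplitude
(the margin between eta = 1 and eta < 1 traces is ~8 orders of
magnitude).

The numeric-vs-analytic mean squared error averages per-trace m.s.e.
over an (eta, V) sweep of the target phase.  The L1 startup error is
concentrated in the first ~100 steps (up to ~1e-2 on fast traces) and
averages to 1e-11..1e-9 over the full grids — orders of magnitude below
historical reports for this comparison, which is expected when both
sides of the comparison are accurate; the error is asserted as an upper
bound, and decreases monotonically with dt.  Reported sweeps use
V in {-100, -60, -20, 20, 60, 100} (every 4th point of the 10-mV grid,
chosen once for single-core budgets) x eta 0.2..1.0 in 0.1 steps at
dt = 0.001, with the comparison grid subsampled 10x (the error profile
is smooth, so the mean is unchanged at the reported precision).

## Spike metrics

- Spike: upward 0-mV crossing followed by a local maximum, >= 2 ms
  between crossings.  Sub-threshold oscillations in this model stay well
  below -20 mV and are never detected as spikes.
- Firing rate: spike count / stimulus duration.  Persistent-activity
  rates use the full 3000-ms stimulus: fractional trains decelerate
  (ISIs at eta = 0.6, I = 18 grow from 14 to 118 ms), so the averaging
  window is part of the definition.
- Voltage threshold: V at the first upstroke sample with dV/dt > 20
  mV/ms (central differences).
- Half-width: time between the two crossings of baseline + (peak -
  baseline)/2, linearly interpolated.  The default baseline is the
  dV/dt > 20 mV/ms threshold voltage of that spike (spike amplitude
  measured from threshold, the common electrophysiological convention;
  it also reproduces the published classic half-width, which the
  pre-spike-trough convention does not).  The pre-spike trough (minimum
  V in the preceding 20 ms) remains available via `baseline="trough"`.
  A spike whose falling flank never re-crosses the half level raises
  `UndefinedWidthError` — the signature of a pseudo-plateau event.
- Rheobase: smallest current on the 1..24 nA grid (0.5-nA steps, 500-ms
  steps) eliciting >= 1 spike, and separately >= 2 spikes ("minimum
  current for repetitive spiking", at which the second spike is
  characterized).  Integration stops early once the answer for a grid
  point is decided.  Threshold-shift sweeps locate the rheobase at
  dt = 0.01 (falling back to dt = 0.005 where the coarse step is
  unstable, i.e. the m gate at eta = 0.3) and measure the threshold at
  dt = 0.001 on a window covering the first two spikes; the measured
  threshold is insensitive to dt (~0.1 mV).
- Phase plane: I_Na = gNa m^3 h (E_Na - V) against I_w = I_K + I_L +
  I_in, all as contributions to C dV/dt, so depolarizing I_Na is
  positive, C dV/dt = I_Na + I_w, and the balance line is I_Na + I_w = 0.
  At the sub-threshold attractors the imbalance hovers near zero while
  I_w is strongly repolarizing.

## Pattern classification

Six labels: RS (resting), PS (phasic), TS (tonic), MMO (mixed-mode
oscillations), SWB (square-wave bursting), PPB (pseudo-plateau
bursting).  Because fractional trains are non-stationary, the rules
weigh the short-term (< 500 ms) and long-term (> 1000 ms) windows
separately, in priority order:

1. PPB — any spike with undefined half-width or with V above -20 mV for
   >= 20 ms after the peak (plateau spans reach 125-136 ms for plateau
   patterns vs <= 5 ms for everything else).  Subtype: "pituitary" when
   the plateau carries >= 3 high-voltage ripples (non-spike maxima above
   -35 mV), else "cardiac".
2. RS — at most one spike.
3. PS — >= 2 spikes, all within the first 500 ms, none after 1000 ms.
4. SWB — long-window spikes group into >= 2 bursts (split at ISIs >
   75 ms), at least one burst has >= 2 spikes at intra-burst ISIs <
   60 ms, and a silent gap contains a sub-threshold oscillation.
5. MMO — at least half of the long-window inter-spike gaps contain a
   sub-threshold oscillation.
6. TS — otherwise (with a warning flag when some but too few gaps carry
   oscillations).

Sub-threshold oscillations are local maxima with prominence >= 1 mV and
peak V < -20 mV, >= 2 ms apart, outside +-3 ms masks around spikes.  All
numeric knobs live in `ClassifierConfig`; they were fixed once against
the five reference (gate, eta, I) exemplars of the non-trivial classes —
(n, 0.7, 23) MMO, (n, 0.4, 8) PS, (h, 0.4, 10) SWB, (h, 0.2, 20)
pituitary PPB, (h, 0.2, 9) cardiac PPB — and are not otherwise tuned.
Exact reproduction of manually drawn phase-diagram boundaries is a
non-goal; unstable cells are first-class outputs.

## Problem sizes and known limitations

- Persistent-activity runs: 1500-3000 ms at dt = 0.01 with full memory.
  Spike counts for the rate protocols are converged at this step
  (identical at dt = 0.005); spike *shape* metrics refine to dt = 0.001.
- The L1 scheme is explicit; its stability limit excludes the m gate at
  low eta (reported as errors, see above), matching the documented
  behavior of this model class.
- The classifier is a deterministic operationalization of a qualitative
  taxonomy; near class boundaries its labels depend on the documented
  thresholds.
- The half-width and threshold-shift conventions recover the published
  classic values, but the published fractional extremes (1.86 ms at
  eta = 0.2; threshold shifts of +2.14/-1.68 mV) are not recovered under
  any measurement convention we tested, with the underlying traces fully
  dt-converged; our measured values (2.24 ms; +1.60/-0.87 mV) reproduce
  every qualitative trend (broadening, threshold rise-then-fall in eta,
  m-gate narrowing and threshold increase, h-gate insensitivity).
- Multiple simultaneously fractional gates and distributed-order
  derivatives are out of scope; so are bifurcation-continuation analyses
  (the attractor language is treated descriptively via phase-plane
  exports).
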