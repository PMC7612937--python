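# Methods

## Signals, conventions, units

The analysis operates on one cardiac cycle of co-sampled central (aortic)
pressure P(t) and aortic flow velocity U(t) on a uniform grid.  A beat
starts at its pressure foot with time re-zeroed there; the diastolic
pressure DBP is the pressure at the foot, and the flow at the foot must
be (near) zero.  Fiducial landmarks are the foot, the peak-flow sample
and valve closure, detected as the first down-crossing of velocity
through 2% of its peak after peak flow (falling back to a dicrotic-notch
search on pressure: first local minimum 150–450 ms after the pressure
peak).  Traces are carried in clinical units — mmHg, m/s, seconds —
and converted to SI (1 mmHg = 133.322 Pa) inside every formula that is
dimensionally SI: the sum-of-squares wave speed, ρcU, and the γ
approximations.  Volumetric flow is converted to velocity with U = Q/A.

## Traditional wave separation

Parker's time-domain method accumulates first differences from the foot:
P_f = ½Σ(dP + ρc dU) + DBP/2 and P_b = ½Σ(dP − ρc dU) + DBP/2.  Both
components start at DBP/2 — the backward wave re-reflects against the
closed valve with unity coefficient in late diastole — and their sum
reconstructs P exactly at every sample, which the implementation asserts
(≤ 1e−9 of the pressure range).  First differences are plain
adjacent-sample differences, with no smoothing, precisely so that the
reconstruction identity is exact.  The wave speed defaults to the
single-site sum-of-squares estimate c = (1/ρ)·√(ΣdP²/ΣdU²) over the
whole beat (pressure in Pa).  On reflection-free input this recovers the
true wave speed to machine precision; with reflections present it is
biased (typically a few percent high on the reference phantom), which is
a known property of the estimator, not a defect — tests cover both
regimes, and every operation accepts an explicit `c` override.

## The five-component separation

1. **Diastolic fit.**  P_μ and the decay rate B come from least squares
   on the diastolic limb, window from 10 ms after valve closure (skipping
   notch oscillations) to the beat end, time re-zeroed at valve closure,
   model P_μ + amplitude·e^(−Bt) with P_μ constrained to (0, DBP).  The
   decay amplitude is a free third parameter rather than being pinned by
   the measured valve-closure pressure: pinning anchors the whole curve
   to a single sample and amplifies that sample's noise roughly
   seven-fold into P_μ (Monte-Carlo median error ≈ 3 mmHg at 0.5 mmHg
   noise), whereas the free-amplitude fit is identical for clean decays
   and keeps the median error at ≈ 0.6 mmHg.  The measured end-systolic
   pressure is still reported.  A flat diastole (< 0.05 mmHg range) or a
   collapsed decay rate raises a fit error rather than returning numbers.

2. **History.**  P_his(t) = (DBP − P_μ)·e^(−Bt) from the beat foot,
   using the previous beat's fit when a recording supplies one and the
   beat's own fit otherwise (periodic steady-state assumption).  At the
   foot P_μ + P_his equals DBP exactly, so the pre-ejection pressure is
   entirely microcirculation + history and the within-cycle pressure
   P_cc = P − P_his − P_μ starts at exactly zero.

3. **Within-cycle split.**  Applying the time-domain separation to
   (P_cc, U) gives P_down = ½Σ(dP_cc − ρc dU) (all downstream
   reflections of the current cycle) and P_cc,f = ½Σ(dP_cc + ρc dU);
   P_wh = ρcU and P_Ao = P_cc,f − P_wh.  Expanding the running sums
   shows P_Ao ≡ P_down whenever the foot velocity is zero; the code
   computes both independently and asserts their equality (≤ 1e−9 of
   range) rather than aliasing one to the other.  The five components
   therefore reconstruct P identically, asserted at 1e−6 of the range.

4. **Bookkeeping.**  Component contributions are trapezoidal areas from
   the foot to valve closure, as percentages of the area under the
   absolute pressure curve; P_μ contributes a rectangle P_μ·T_sys, and
   negative momentary values (P_down early in systole) enter
   algebraically, so the shares sum to exactly 100%.  Absolute pressure
   (not pressure above DBP) is the integration baseline, which is why
   P_μ dominates the shares.  Beats can be grouped into left-closed
   10-mmHg pulse-pressure spans (<30, 30–40, …, ≥70, with PP = 70 in the
   top span) with a duration-normalised ensemble average per span: each
   beat is mapped to relative time, resampled to the median beat length
   and averaged pointwise, fiducials re-detected on the average.

## Emission coefficient

γ(t) = P_f/P_b on samples where P_b exceeds a 1 mmHg guard (never
extrapolated elsewhere).  Because P_f,b = ±Z_c·Q_f,b, γ = 1 + Z_c·Q/P_b
identically — the implementation's primary self-test, which holds to
machine precision given the separation above — and with P_b ≈ DBP/2 in
early systole, γ ≈ 1 + 2·Z_c·Q/DBP with the flow-based peak
approximation γ_peak ≈ 1 + 2·Z_c·Q_peak/DBP (Z_c = ρc/A, all terms in
Pa).  For the γ-vs-flow comparison both waves are peak-normalised; γ is
first baseline-subtracted (its diastolic level is 1) because raw peak
scaling would leave an O(1/γ_peak) diastolic offset that has nothing to
do with wave shape.  Relative RMSE is 100·RMS of the normalised
difference over three windows — foot to peak flow, peak flow to valve
closure, whole beat — plus the timing offset of the two peaks.  The
measured-vs-approximated γ RMSE is normalised by peak γ.  Both
normalisation choices are conventions of this package (the comparison
windows are standard).

## The phantom

The ground-truth generator is a linear two-segment (configurably
N-segment) transmission line solved by a lattice of characteristics:
each segment carries forward/backward pressure characteristics f, b
(relative to P_μ) in delay lines whose transit times are integer
multiples of the 1 ms step by construction, so propagation is exact.
P = P_μ + f + b and Q = (f − b)/Z_c.  Junctions scatter with
R = (Z₂ − Z₁)/(Z₂ + Z₁); the inlet is a prescribed-flow source
(f = Z_c·Q + b — incoming waves re-reflect with +1, which reduces to the
closed valve when Q = 0); a distributed viscous loss attenuates
in-transit characteristics by e^(−λ_visc·dt) per step.

The terminal is a lumped leak: a series resistance R₁ — fixed by the
configured instantaneous reflection coefficient R_t via
R₁ = Z·(1 + R_t)/(1 − R_t) — feeding a compliance C that drains to P_μ
through a peripheral resistance R₂, with C = 1/(leak_rate·R₂).  The
compliance stores the ejected volume and re-emits it slowly, producing a
quasi-monoexponential diastolic decay; a bare coefficient terminal
instead yields a lumpy geometric staircase (one step per round trip) that
no monoexponential fits.  Setting the terminal reflection to 0 replaces
all of this with a perfectly matched absorber that returns nothing — the
"totally absorbent" boundary.  Two analytic checks pin the terminal
model down: on a lossless line the steady-state mean pressure equals
P_μ + (R₁ + R₂)·CO, and on a sealed line (terminal reflection 1) every
mode decays at exactly the distributed loss rate, which the diastolic
fit recovers within 1%.

Because the system is linear and the inlet rule is the same in systole
and diastole, superposition is exact: re-running the lattice with the
ejection drive masked to a single beat yields that beat's exact
contribution to the steady-state pressure, split by direction.  This
provides the forward/backward and beat-of-origin tags (current-cycle
content, history content, downstream-reflection content) against which
the analysis pipeline is verified, and it makes the boundary-condition
switch experiment exact: the composed beat is
P_μ + P_his(normal run) + P_cc(absorbent run).

### Reference configuration

Chosen once, on physiological grounds: proximal segment 0.27 m, c = 6
m/s, A = 4.5 cm² (aortic calibre); distal segment 0.96 m, c = 8 m/s,
A = 3.4 cm² (tapered, stiffer; junction reflection ≈ 0.28); terminal
reflection 0.6; distributed loss 7 s⁻¹; stroke volume 70 mL ejected as a
0.3 s half-sine every 0.85 s; P_μ = 55 mmHg; leak rate 0.7 s⁻¹
(diastolic time constant ≈ 1.4 s); R₂ = 2.5·10⁷ Pa·s/m³; 12 beats to
steady state (final beat-to-beat change ~1e−4 mmHg, warned above
0.1 mmHg).  The long, lossy distal segment means that what returns to
the root is dominated by the junction — an impedance-mismatch site —
while the terminal echo is strongly attenuated en route; this mirrors
the physiology in which terminal reflections are largely trapped in the
periphery, and it is what makes the emission coefficient nearly
insensitive to switching the terminal to totally absorbent.  The
resulting beat is 55/102 mmHg (MAP 68) with pulse pressure 46 mmHg and
peak γ 2.4 — a hypotensive-leaning but physiological operating point.

### What the phantom does and does not emulate

It emulates: wave propagation and partial reflection at an impedance
mismatch, closed-valve re-reflection, windkessel-like diastolic decay,
periodic steady state with history waves, and optional additive Gaussian
measurement noise on exported pressure (seeded).  It does not emulate:
nonlinear 1-D blood flow, visco-elastic wall dispersion (the loss here
is frequency-flat), anatomical branching, ventricular-valve interaction,
or measurement artefacts of tonometry/Doppler.  Passing tests therefore
demonstrate correctness of the decomposition algebra and robust recovery
of its parameters under the model's assumptions — not performance on
in vivo data, where fiducial detection, calibration and the
monoexponential assumption all degrade.

## Numerical choices and degenerate inputs

* Grid uniformity is enforced to a relative jitter of 1e−9; beats
  shorter than 16 samples are rejected.
* The diastolic fit needs ≥ 10 samples and a ≥ 0.05 mmHg diastolic
  range; solver tolerances are 1e−14 so "noiseless recovery" is limited
  by conditioning, not stopping rules.
* Beat segmentation detects feet as pressure minima within 200 ms before
  steep upstrokes (> 30% of the peak derivative), with a 250 ms
  refractory gap between distinct upstrokes; an explicit `beat_index`
  column overrides detection.  Segmentation is lossless from the first
  foot onward.
* γ is masked (NaN), never extrapolated, where P_b ≤ 1 mmHg; a beat
  whose P_b never clears the guard, a flat velocity trace, or a flow
  wave with no down-crossing each raise a specific error.
* Monte-Carlo studies in the tests run 100 fixed seeds; the phantom
  itself is deterministic, with the seed only feeding optional export
  noise.

## Problem sizes

All verification runs use single beats of 850–1200 samples at 1 ms,
phantoms of 5–15 beats, and sweeps of ≤ 7 stroke volumes; the full test
suite and the acceptance script each complete in well under a minute on
one core.

## Known limitations

* The sum-of-squares wave speed inherits its documented reflection bias;
  component traces (though not the additive identities) depend on c.
* The monoexponential model mis-specifies diastole whenever the decay is
  multi-compartment — including this package's own phantom at strongly
  reflective terminals, where line drainage and compliance discharge
  have distinct rates; the fit then lands between them.
* The first beat of a recording has no preceding cycle, so its history
  uses its own fit (periodicity assumption).
* Ensemble averaging assumes duration-normalised alignment; other
  alignment rules would give slightly different averaged morphology.
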