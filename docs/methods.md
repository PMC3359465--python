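# Methods

## The model

A BK-channel activation gate is represented by a single reaction
coordinate (RC) diffusing on integer lattice nodes between reflecting
boundaries.  A threshold point (TP) divides the lattice into a closed
manifold (RC < TP) and an open manifold (RC > TP); the channel's
dichotomous conductance state is read off the side the RC occupies.  The
TP node itself carries the peak of a small tent-shaped activation barrier
and is not occupiable: the jump TP−1 ↔ TP+1 crosses the barrier.

Per step the RC moves ±1 node with probabilities

    p = 1/2 − ΔU/4kT,   q = 1/2 + ΔU/4kT,

where ΔU is the potential difference across one lattice step centred on
the current node, `ΔU = U(x+½) − U(x−½)`.  The linearised rule is valid
for |ΔU| ≤ 2 kT; all configured parameter ranges stay far inside it
(probabilities are clamped, with a warning, outside it).  At the
barrier-adjacent nodes the crossing is decided by the uphill half-step
into the peak, `ΔU = U(TP) − U(TP∓½) = u_barrier/3`, so the barrier
height gates crossings in both directions equally.  A move past a
reflecting limit is rejected (the walker stays put for that step).

The potential U(x) is piecewise linear and continuous with `U(B1) = 0`:
outer segments of slope A, and a tent of slope ±`u_barrier/1.5` peaking
at TP.  The two variants differ in their slow degree of freedom:

* **Model 1 (fluctuating boundaries).** Both outer segments share the
  constant slope `A = f_d` (the sensor drift force; positive values tilt
  toward closed states).  The boundaries are symmetric, `b1 = −b2`, and
  every `t_b = 600` RC steps both half-spaces expand or shrink by one
  node with probability ½ each, reflecting at `b_max = 14` above and at a
  half-width of 2 below (so at least one non-barrier node survives per
  side; the source material states no minimum).  If a shrink strands the
  RC outside the new range it is clamped to the nearest in-range node.

* **Model 2 (fluctuating drift).** Boundaries fixed at ∓18; the outer
  slopes are antisymmetric, +A left of the barrier and −A right of it, so
  positive A pushes the RC away from the threshold on both sides and
  negative A pulls it in.  A performs its own unbiased walk: ±0.005
  kT/rcu every `t_df = 1200` RC steps, reflected at ±0.20 kT/rcu.  The
  slope is tracked internally as an integer multiple of the increment so
  reflection at the limits is exact.  Sensor bias is modelled by placing
  TP off-centre (±14, ±7, 0).

One step corresponds to `dt = 5×10⁻⁵ s` (20 kHz sampling), so 1 step =
0.05 ms and a 300 s recording is 6×10⁶ samples.  The RC starts at TP−1
(the closed substate nearest the threshold); no burn-in is discarded by
default (negligible at the study's trace lengths; a `burn_in` argument
exists).  Runs are reproducible bit-for-bit: a seeded generator pre-draws
the full uniform stream (one draw per RC step, one more per slow-process
event), and the compiled kernels are mirrored by a pure-Python reference
that the test suite checks for bit-identical output.  Setting the slow
period to 0 freezes the slow process (negative control).

## Why the memory arises, and what the dwell tails look like

With the slow process frozen both models are finite Markov chains: dwell
series are memoryless (H ≈ 0.5) and small-lattice occupancies and mean
dwell times match exact transition-matrix computations (tested).  The
slow fluctuation modulates the dwell-time scale of both states over
decades — e.g. under drift f_d the time to escape a well of half-width b2
scales like exp(|f_d|·b2) while b2 random-walks over 2..14 — and this
slow modulation is exactly what makes the dwell series persistent
(H ≈ 0.73–0.82).  A corollary the user should expect: the stimulus-
*favoured* state's dwell distribution is a broad mixture of exponentials,
which over the observable range is better described by a power law than
by any single exponential.  The disfavoured (short-dwell) state shows a
clean exponential tail.  Our simulations therefore reproduce a
power-law-like closed distribution and exponential closed tails exactly
where the mechanics put them, but not every qualitative tail label the
original study attached to its figures; `tail_fit_comparison` exposes the
comparison (r² of straight-line fits to the log-binned dwell density
against log t vs against t, full-range or tail-only with a cutoff at the
mean dwell time).

## Rescaled-range analysis

The Hurst input is the temporally ordered series of alternating open and
closed dwell durations.  For each window size w (powers of two from 8 to
n/4) the series is cut into disjoint blocks; per block the mean-adjusted
cumulative sum's range R is divided by the block SD S, and ⟨R/S⟩ is
averaged over blocks with S > 0.  H is the least-squares slope of
log⟨R/S⟩ against log w.  The plain estimator carries the well-known
small positive bias at finite n: i.i.d. input of ~3×10⁵ values reads
H ≈ 0.52–0.53, matching the study's own shuffled controls.  An
Anis–Lloyd correction (`corrected=True`) removes the i.i.d. expectation
before regression and is off by default to stay commensurable with the
published values.  Shuffle controls permute the series with a seeded
generator.

## Event detection

Idealization thresholds are estimated on current magnitudes |I| so
negative holding potentials need no special casing.

* **Kernel estimator.** An Epanechnikov KDE (statsmodels, Silverman
  bandwidth on |I|, 512-point grid, ≥100 samples required; traces beyond
  50 000 samples are subsampled) is examined in log|I|–log PDF space.
  On each inner flank of the two conductance modes a straight line is
  fitted to the window anchored at the inner end of the flank's support
  (the region the threshold must be extrapolated into), grown toward the
  mode while the fit keeps r² ≥ 0.98 (≥10 points; flank support is the
  contiguous run from the mode toward the inter-mode minimum, floored at
  10⁻⁴ of the modal density so a stray single-sample bump is not counted
  as flank).  The threshold is the abscissa of the two lines'
  intersection, required to lie strictly between the modes.
* **Double-Gaussian cross-check.** A two-component Gaussian mixture
  (scikit-learn) is fitted to the raw current amplitudes and the
  threshold is the equal-posterior crossing between the component means,
  returned as a magnitude.  Fitting the raw amplitudes (rather than |I|)
  avoids the folded-normal shrinkage of the closed component's SD, which
  would bias the crossing low.

On the package's standard synthetic fixture (18.85 pA open level, SNR
10) the two estimators agree to 3.5 %; across noise realizations the
kernel estimate scatters by up to ~10 % because at SNR 10 the inter-mode
region has no density support and the intersection is an extrapolation
over ~2 noise SD.  At SNR ≤ 7 — closer to the flank overlap of real
recordings, whose inter-mode densities genuinely follow power laws — the
agreement is robustly below 5 %.  Idealization itself is essentially
error-free at SNR 10 (misclassification ~3×10⁻⁷ per sample), so the
downstream dwell and Hurst statistics are insensitive to this scatter
(end-to-end H recovery is exact in the tests).

## Dwell statistics and the fit error

Dwell histograms are probability mass on log-spaced bins (default 20)
spanning the observed range; replicate aggregation uses shared edges and
reports the per-bin population SD.  The composite fit error is the sum of
four absolute relative deviations — Hurst exponent, open probability, and
the χ² figures of the open and closed histograms — where the reference χ²
is the mean squared per-bin replicate SD and the simulation χ² the mean
squared per-bin deviation from the reference histogram.  A candidate is
accepted when every term is below 5 % and the sum below 10 %.

One property of this functional worth knowing: the two χ² statistics
measure different things (scatter vs mismatch), so they coincide — and
the acceptance rule becomes reachable — only when replicate-to-replicate
variability dominates sampling noise, as it does for real patch-to-patch
recordings.  For self-consistent synthetic references the χ² terms have
a sampling-noise floor; the optimizer still descends the total error and
recovers generating parameters (tested to within ±50 % on the barrier
height and slow period), but E_total < 0.10 should not be expected there.

The optimizer is a derivative-free coordinate descent: each evaluation
averages ≥3 seeded simulations with common random numbers; each tunable
is perturbed ±10 % (relative), improving moves are kept, and steps shrink
×0.5 after a sweep without improvement; stopping on acceptance, step
underflow, or the evaluation budget.

## Physical-scale chain

`rcu_length`, `apparent_diffusion` (δ²/6τ), `mass_ratio_from_diffusion`
((D_fast/D_slow)^{3/5}, from D ∝ v·δ, τ ∝ m^{−2/3} and equipartition) and
the cylinder/slab volumes are plain closed forms.  The published chain
contains two internal inconsistencies, preserved deliberately: the
printed δ = 0.25 Å implies a lattice denominator of 80 whereas the
model's half-width (14) gives 0.357 Å, and the printed apparent gate
diffusivity 1.04×10⁻¹⁷ m²/s is not δ²/(6τ) with the printed δ, τ (which
gives 2.08×10⁻¹⁸).  `printed_chain()` replays the published numbers
(downstream values are internally consistent with the printed D_CG) and
`formula_chain()` recomputes everything from first inputs; both are
exposed on the CLI (`gatewalk estimates --chain {printed,formula}`).
The headline results — mass ratio 1.04×10⁵, volume ratio 5.09×10⁶, and
the ~2 % patch fraction — come out of the printed chain unchanged.

## Synthetic recordings

`synthetic_patch` emulates the recording conditions: Ohmic open level
I = g(V − V_rev) with g = 235.6 pS and V_rev = 0 (18.85 pA at +80 mV),
closed level 0 pA, additive Gaussian white noise, 20 kHz sampling, 300 s
default duration.  The recording noise SD is not published (only the
5×10⁻⁴ pA quantization step); the default gives SNR 10, at which
idealization is near-perfect while the analog stage is non-trivial.  Not
modelled: the rig's 10 kHz low-pass filter (and hence noise correlation),
1/f noise, baseline drift, capacitance transients, subconductance levels,
and multi-channel patches.  Passing tests on these fixtures therefore
validate the analysis chain's internal consistency, not its robustness to
every artefact of real recordings.

## Problem sizes and numerical choices

The acceptance suite and `scripts/acceptance.py` run the full study
scale — 5 replicates × 6×10⁶ samples for each of the five regulatory
values and both models — which the compiled kernels cover in well under a
minute.  Unit tests use 10⁴–2×10⁶ steps.  Degenerate inputs raise typed
errors (zero-variance KDE input, unimodal densities, all-degenerate R/S
windows, empty dwell states, invalid configurations).  Ties and edges:
histogram upper edges are nudged up by 10⁻⁹ relative so the maximum falls
in the last bin; drift reflection uses integer bookkeeping; boundary
shrink clamps the RC inward, never onto TP.

## Known limitations

* The favoured-state dwell tail is power-law-like by construction (see
  above); figure-level tail labels of the original study that conflict
  with this are not reproduced.
* Model 2's open probability at extreme thresholds (TP = ±14) has large
  run-to-run variability: the drift walk's relaxation time (~6.5×10³ slow
  steps) exceeds the 5×10³ slow steps in a 6×10⁶-sample run, so single
  runs can trap near one boundary.  Hurst statistics are much more
  stable than p_o there.
* The kernel threshold estimator is an extrapolation when the two
  current modes are widely separated relative to the noise; prefer the
  double-Gaussian method above SNR ~10.
* H estimates use the plain R/S regression; confidence beyond the ±0.1
  the estimator itself carries should not be read into single runs.
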