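# Methods

## The measurement being modeled

Nucleosomes exchange H2A-H2B dimers with one another spontaneously. The
experiment mixes two nucleosome pools 1:1 at 400 nM total: an
immobilizable pool labeled on DNA with a Cy3/Cy5 FRET pair, and a free
pool carrying Cy5.5 on H2B with labeling efficiency F = 0.537 per dimer.
Surface-immobilized molecules are imaged in three spectral channels under
532 nm excitation (200 ms frames), followed by a dark period and a 635 nm
phase that directly probes acceptor survival. An intact immobilized
nucleosome shows FRET_Cy5 ≈ 0.6 and zero FRET_Cy5.5. A Cy5.5-labeled
dimer acquired in the entry-proximal slot funnels nearly all transfer to
Cy5.5; one acquired in the entry-distal slot gives low-mid FRET_Cy5 with
clearly non-zero FRET_Cy5.5. Only distal events are counted: proximal
events put Cy5.5 in a high-transfer position and it photobleaches almost
immediately.

## Kinetic model

Let x(t) be the mole fraction of immobilized nucleosomes with exactly one
labeled dimer (half of which, by slot symmetry, are the countable distal
species e). Treating exchange between every nucleosome pair as a single
bimolecular channel with rate constant k, the counted fraction follows

    f_e(t) = x(t)/2 = A · (1 − exp(−c · k · C_total · t)),
    A = (F/2)(1 − F/2),      c = (1 + F)/2.

A is the probability that, at full randomization, a given slot carries a
label (F/2 of all dimers in the mix are labeled) while the other slot does
not; at F = 0.537, A = 0.196 and c = 0.77. The concentration enters the
exponent as C_total = 400 nM, so k carries M⁻¹s⁻¹ units. `kinetics`
also ships the six-term early-time rate equation for x as a printed
diagnostic (`ode_rhs_printed`, `integrate_printed_ode`). That equation
neglects every back-reaction that regenerates singly-labeled molecules, so
its long-time plateau (≈ 0.080 at F = 0.537) is *not* A; the closed form
above is the fitting model, and no equality between the two is asserted
anywhere.

Rate constants are estimated by Levenberg–Marquardt nonlinear least
squares with the amplitude fixed at A (a free-amplitude mode exists). The
reported error is the standard error of the fit: the square root of the
residual-variance-scaled covariance diagonal at the optimum. Fits are
unweighted by default, with an option to weight by replicate standard
deviations. The initial guess inverts the model at the first informative
time point. Degenerate inputs: an all-zero time course returns k = 0 with
a boundary flag; a time course whose points all sit at or above the
plateau leaves k unidentified and raises a diagnostic error rather than
returning an arbitrary large number. Two conditions are compared by the
difference-versus-sum-of-errors rule: |k₁ − k₂| > se₁ + se₂ ⇒
significant. The exchange timescale at a reference concentration is
1/(k·C_ref) with first-order error (se/k)·t; C_ref defaults to 70 μM
(nuclear nucleosome density), and timescales are reported to the nearest
second, rate constants to three significant figures.

## Collision Monte Carlo

The stochastic simulator represents N particles (N/2 per pool), each with
two boolean slot-label states. Collisions arrive as a Poisson process with
total propensity k·C_total·N/2; each collision picks an unordered particle
pair uniformly, picks one slot per partner (probability ½ each), and swaps
the two slots' label states. The per-pair collision rate is then
≈ k·C_total/N, and the ½ slot choices reproduce exactly the statistical
factors of the mean-field model (e.g., an unlabeled nucleosome colliding
with a singly-labeled one gains a label with probability ½). Swapping
conserves the total label count, which is asserted after every reporting
interval. Because only the product k·C_total·t matters, equilibration to
10–14 relaxation times τ = 1/(c·k·C_total) costs about 10·N/(1+F)
events regardless of k — roughly 80,000 swaps at N = 10,000, well under a
second. Equilibrium snapshots are taken one τ apart so they are close to
independent; the distal-only fraction of the DNA-labeled pool converges to
A = (F/2)(1−F/2) within binomial Monte-Carlo error.

The exchange event is modeled as a *swap* of slot occupants rather than a
unidirectional transfer; only the swap convention conserves dimer counts,
and it is the convention under which the combinatorial equilibrium above
holds.

## Trace synthesis

Each synthetic molecule draws a class (intact / proximal / distal) from
the population model — the closed form by default, the collision Monte
Carlo as an opt-in oracle — and emits per-frame intensities:

* signature FRET targets (FRET_Cy5, FRET_Cy5.5): intact (0.6, 0), proximal
  (0.05, 0.90), distal (0.35, 0.30); the remainder of a fixed emission
  budget (500 a.u./frame) stays in the Cy3 channel;
* independent exponential photobleaching per fluorophore with default mean
  lifetimes Cy3 60 s, Cy5 40 s, Cy5.5 12 s. Only the ordering (Cy5.5 much
  faster than Cy5) is physically constrained; the values are chosen so
  that a realistic majority of molecules survive the 10 s lifetime gate.
  When an acceptor bleaches, its FRET share is redistributed to the
  surviving fluorophores in proportion to their shares (the donor then
  recovers that emission); when Cy3 bleaches everything goes dark;
* acceptor cross-talk applied with the forward mixing matrix
  (r5 = 0.31, r5.5 = 0.27), constant per-channel backgrounds
  (50, 40, 30 a.u.), and zero-mean Gaussian noise (σ = 15 a.u., giving
  SNR ≈ 10–14 in the brightest channel);
* a 5 s dark phase and a 10 s red-excitation phase in which surviving
  acceptors emit under direct excitation.

Default scale: 9 time points (0–24 h), 4 replicates, 100 molecules per
replicate. Reproducibility uses one master seed with per-molecule child
seeds (`numpy.random.SeedSequence.spawn`), so any subset of molecules can
be regenerated identically.

What the generator does **not** emulate: camera-level effects (EM gain,
registration error, spot overlap), FRET dynamics within a trace (states
are static per molecule), donor→acceptor spectral leakage (assumed removed
upstream; only the Cy5↔Cy5.5 crosstalk pair is modeled), blinking, and
direct-excitation crosstalk during the green phase. Passing tests
therefore demonstrate correctness of the correction algebra, the
classification logic, and the kinetic inference under these idealized
corruptions — not robustness to camera artifacts or dye photophysics
beyond single-step bleaching.

## Correction

Backgrounds are constant per channel, estimated as the **median** of the
baseline segment (dark-phase frames when present, else the frames after
the last detected step of the summed intensity; at least 10 frames
required). The acceptor mixing system is inverted in closed form
(determinant 1 − r5 − r5.5 = 0.42 at the defaults; factors with
r5 + r5.5 ≥ 1 are rejected as singular). FRET is computed per frame and
then histogrammed (bin width 0.02), rather than averaging intensities
first. Noise-driven negative corrected intensities are retained
un-clamped (clamping would bias the efficiency denominators) and flagged;
the FRET ratios themselves are clipped into [0, 1] with a clip flag, and
frames with non-positive total intensity are marked undefined rather than
raising.

## QC and classification

Acceptance gates, per molecule: post-bleach residual within 3 noise SD of
zero in every stepped channel (single nucleosome), photobleaching lifetime
> 10 s, SNR > 4 (best channel's pre-bleach mean over its baseline noise
SD), and single-step bleaching in every channel. The lifetime gate applies
to the earliest bleach of the **DNA-label** fluorophores (Cy3/Cy5):
applying it to Cy5.5 would censor most exchanged molecules, which
contradicts how exchanged molecules are counted. Bleach steps are located
per channel by two-segment least-squares changepoint search (O(n) with
cumulative sums), recursively re-applied to both segments to flag
multi-step (aggregate) traces; a step must drop by more than 4 noise SD.

Classification uses pre-bleach medians: proximal requires median
FRET_Cy5.5 ≥ 0.6 with Cy3 and Cy5 shares ≤ 0.15; distal requires ≥ 5
consecutive frames (1 s) with FRET_Cy5.5 ≥ 0.15 and FRET_Cy5 ≤ 0.5
anywhere before the DNA fluorophores bleach; intact requires median
FRET_Cy5 within 0.6 ± 0.15 and FRET_Cy5.5 ≤ 0.1. Anything else is
ambiguous and excluded from counting. Proximal is tested before distal
(its signature is a subset of the distal window). A distal molecule whose
Cy5.5 dies within the first ~3 frames is observationally indistinguishable
from an intact one — the information is physically erased — so a few
percent of distal molecules are lost to the intact or ambiguous bins at
the default lifetimes. This depresses the fitted k by roughly 15–20%
relative to the generating value in full-noise end-to-end runs, within
the fit's 3-se band at the default scale; the same censoring operates in
the real measurement.

The census fraction is n_distal / n_qualifying per time point and
replicate. The default denominator counts all QC-passing unambiguous
molecules (intact + proximal + distal); a switch restricts it to
intact + distal. The replicate SD accompanies each time point (undefined
with fewer than two replicates).

## Numerical choices

* Leakage inversion uses the closed-form 2×2 inverse; a property test
  checks it against a generic linear solve.
* ODE integration: RK45, rtol 1e-8, from x(0) = 0, with x clipped to
  [0, 0.5] inside the right-hand side for solver robustness.
* curve_fit runs with xtol = ftol = 1e-14 so noiseless recovery is exact
  to ≲1e-6 relative.
* Histograms bin [0, 1] at width 0.02, which separates the 0.6 intact mode
  from the lowered distal mode.
* All file outputs use fixed float formatting and sorted JSON keys, so a
  rerun with the same configuration and seed is byte-identical.

## Problem sizes used in the shipped checks

Analytic identities run at trivial size. The collision simulator runs at
10,000 particles for equilibrium checks (≈ 0.2 s) and 4,000 in unit
tests. Parameter-recovery uses the 9 standard time points with 200
molecules × 6 replicates of binomial counting noise over 100 seeded
repetitions. The end-to-end check runs the full default scale — 3,600
traces of 375 frames — once, shared across tests (≈ 30 s).

## Known limitations

* Classification is a static per-molecule signature test; molecules whose
  FRET state changes mid-trace (real-time exchange during observation) are
  not modeled and would be flagged multi-step or ambiguous.
* The fixed-amplitude fit assumes the census denominator matches the
  population the amplitude A refers to; systematic losses of exchanged
  molecules (early Cy5.5 death) bias k downward as described above.
* The printed early-time rate equation is shipped for transparency only;
  its plateau disagrees with A by construction.
* se_k from the covariance of an unweighted fit treats time points as
  homoscedastic; with strongly unequal replicate counts, use the weighted
  mode.
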