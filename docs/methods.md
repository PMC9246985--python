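# Methods

## The problem

Amide-proton CEST experiments on perdeuterated, 15N-labelled proteins report
on sparsely populated conformational states through saturation-transfer dips
in the profile I(omega_offset)/I0.  Because the magnetization held during the
saturation period is anti-phase with respect to the attached 15N
(1J_HN ~ -93 Hz), each exchanging state contributes a broad doublet response
rather than a single absorptive dip, and the chemical shifts of the
exchanging states are not directly readable from the profile.  This package
implements an autonomous analysis: a spin-dynamics simulator generates
synthetic anti-phase (AP) and in-phase (IP) profile pairs; a transformation
network (`TransformationNetwork`) virtually decouples and upsamples AP
profiles into 128-point IP profiles; a chemical-shift network
(`ChemicalShiftNetwork`) reads up to three shifts with calibrated
uncertainties from the IP profile; and a least-squares fitter provides the
classical reference analysis.

## Spin dynamics

The exchange model is the forked three-site scheme E1 <=> G <=> E2 (two-site
and single-state systems are special cases).  Branch rates follow
kex = k_fwd + k_bwd with detailed balance against the global populations.

For AP simulation each state carries {Hx, Hy, Hz} in both 15N manifolds
(alpha/beta); the 15N spin shifts the 1H precession by +-pi*J and
longitudinal 15N relaxation interchanges the manifolds at R1_N/2 per
direction.  IP simulation uses the three-component J = 0 spin.  The
Liouvillian convention is d m/dt = -L m, so propagation over the CEST delay
is exp(-L T_ex).  The thermal-recovery (inhomogeneous) term is omitted: the
same omission applies to the I0 reference propagation, and the ratio I/I0 is
insensitive to it at the B1 fields and delays simulated here.

Ground-state relaxation rates derive from a single rotational correlation
time tau_M (rigid isotropic tumbling, J(w) = (2/5) tau/(1 + (w tau)^2)), the
one-bond dipolar coupling at r_HN = 1.02 A, and a 15N CSA of -164 ppm.
Remote protons are neglected (perdeuterated samples); the 1H CSA is
neglected.  These are standard substitutes for the unpublished rate
expressions behind the training distribution; their exact values are not
critical because the networks are trained across tau_M = 3-20 ns.

Smooth profiles are obtained with the real-eigenvalue dephasing propagator:
after L V = V D, only eigenvalues with |Im(lambda)| <= 1e-3 s^-1 are kept in
V_re exp(-T_ex D_re) V_re^-1.  This removes coherent nutation exactly as a
B1-inhomogeneity average would; the test suite verifies agreement within 1%
RMS against full matrix-exponential propagation averaged over a Gaussian B1
distribution of 10% fractional width.  Degenerate parameter sets (exactly
coincident shifts) are perturbed by 1e-6 ppm with a warning.

The AP experiment starts from the anti-phase order created by the first
INEPT (Hz_alpha = +a_s, Hz_beta = -a_s; a_s = p_s for an ideal element, or
attenuated through an explicit delay-180-delay INEPT with free evolution
under the full Liouvillian) and detects the ground-state manifold difference
at the end of T_ex, normalized by the identical propagation with B1 = 0
(equivalent to the -12 kHz reference experiment).  Within this model the AP
profile is the average of the two doublet-component saturation profiles: at
weak B1 the components resolve into two dips separated by |J|, at the
B1 = 15-50 Hz used for training they merge into the broad composite response
that motivates virtual decoupling.  With J = 0 (and an ideal INEPT) the AP
and IP simulations coincide to machine precision, a limit identity asserted
in the tests.

## Profile processing

Dip transform max(I/I0) - I/I0; forward-normalized real FFT keeping the
floor(N/2)+1 non-redundant coefficients; zero-fill to exactly 65 complex
points (the size forced by the 128-offset maximum); time axis t_k = k/SW
with SW the offset span in Hz (this carries the static-field information the
networks need).  The packed layout is real parts in slots 0-64 and imaginary
parts in 65-129, with the time axis replicated to the same shape.  The
128-point inverse real FFT is band-limited (sinc) interpolation; for even
original lengths the Nyquist coefficient is halved, the standard convention
that keeps the interpolant real and exact on band-limited input.  The
128-point target grid starts at the first offset with step N*d/128 (d the
original grid step), i.e. uniform samples of the DFT period, so the
network-free chain is self-consistent.

## The transformation network

Input: the two packed 130-vectors, reshaped to a 65-point sequence with
three channels (Re, Im, scaled time).  Architecture: a stack of dilated
gated convolution blocks (tanh * sigmoid with residual connections, the
spectral-decoupling building block), a bidirectional recurrent module, and a
dense head.  The default head emits 65 complex time-domain points that a
frozen inverse-FFT layer maps to the 128-point profile; a direct 128-point
frequency head is available (`head="freq"`).  Loss: mean squared error
against the clean IP profile.  Optimizer: ADAM with the loss-coupled decay
lr = base_lr * loss^(3/4) clipped to [lr_min, base_lr].  At full scale this
schedule reproduces a final learning rate of 1e-6; at reduced scale the
multiplier throttles training, so the reduced configurations raise the
lr_min floor (the schedule is also unstable upward - the lr grows with the
loss - which the clip at base_lr contains).  The networks here are written
in numpy with hand-derived backpropagation (no deep-learning framework is
assumed); all layer gradients are verified against central differences in
the test suite, and a fixed seed makes training bit-reproducible.

The default reduced configuration has ~4.3e5 parameters and trains on a few
thousand simulated profiles in minutes on one CPU.  This is a deliberate
scale-down: the reference full-scale system (millions of profiles, GPU
training, ~3.8e6 parameters) is out of scope, and the package asserts
recovery properties rather than full-scale error statistics.

## The chemical-shift network

Input: the 128-point IP profile.  A densely connected 1-D convolutional body
(concatenative skip connections, one transition/pooling stage) feeds two
heads: three position-logit maps read out by a soft-argmax, and pooled
confidence features.  The readout passes each slot's position as a logit, so
the final sigmoidal layer - which produces the 3 x 2 output of normalized
shifts f in (0,1) and confidences c in (0,1) - can represent the position
exactly; it also provides each heatmap's peakiness and the pairwise
distances between slot positions, the main observable drivers of prediction
difficulty.  Slot semantics are fixed: slot 0 is the ground state, slots 1-2
the excited states by descending population; for absent states f_true is
0.5 and the indicator entry is 0.

Training minimizes L_freq + L_uncer with k = 1:

    L_freq  = sum_i (f_pred,i - f_true,i)^2 / sigma_pred,i^2
    L_uncer = 1e-4 * sum_i 1_i sqrt(sigma_pred,i)
    sigma_pred = 1/c_pred - 1,   c_pred clamped to [1e-6, 1 - 1e-6]

The stationary point of this loss sets sigma ~ (4e4 * err^2)^(2/5) per
sample: uncertainties are monotone in the true error but not equal to it,
which is exactly why the calibration constant is rescaled after training to
k = (max offsets - min offsets) * sqrt(L_freq_final), giving L_freq an
expectation of 1 so that sigma_pred = k (1/c_pred - 1) reports the expected
shift error in ppm.  k is computed once from the final epoch's mean L_freq
(per-epoch recalibration would change nothing material).

Two optimization aids are needed at reduced scale and are plain training-
schedule choices, not changes to the loss: the confidence-head bias is
initialized positive (starting near c = 0.88), and the first
`warmup_epochs` hold sigma at its initial value with no gradient to the
confidence outputs.  Both counter a low-confidence local minimum: once c is
small, the 1/sigma^2 factor removes the gradient that teaches the shifts.

## Calibration and evaluation

`evaluate_calibration` simulates fresh scenarios, runs the full pipeline and
bins delta_pred - delta_true against c_pred (0.05 x 0.005-ppm bins),
reporting per-bin 68.3/95.4/99.7% envelopes, the sigma_pred overlay and the
fraction of predictions with |error| <= sigma_pred among c_pred >= 0.4.
Below c = 0.4 the mapped uncertainty stops being an accurate error measure;
such predictions are flagged, never dropped.  `consistency_analysis` pairs
predictions from two acquisitions of the same sites (full vs. half sampling,
or two B1 fields) and reports the RMSD over pairs with min(c) > 0.4.

## Least-squares oracle

`least_squares_fit` minimizes profile residuals of the simulator over
shifts, branch kex, excited-state populations and excited-state R2 offsets
(trust-region reflective, bounded), with base relaxation rates fixed from
tau_M.  Multiple profiles share all kinetic/thermodynamic parameters.
Shift uncertainties use the covariance at the optimum; they agree with
replicate scatter within a factor of ~2 in the tests (parameter correlations
at a single B1 account for the excess).

## What the synthetic world does and does not establish

The generator draws the stated training distribution: B0 from five fields
(14.1-23.5 T), B1 ~ U(15, 50) Hz, 50-128 points over a 3.4 ppm window,
T_ex = 0.4 s, d1 = 0.5 s, tau_M ~ U(3, 20) ns, J_HN ~ U(-95, -91) Hz,
R_ex = |N(1, 2)| s^-1, dR2_E ~ N(0, 2) s^-1, shifts uniform over the sweep,
kex ~ U(10, 300) s^-1, p_E ~ U(0.01, 0.15), three-site with probability
25%.  The absolute window position (6.6-10.0 ppm) is the amide region used
in the worked examples; only the span matters to the model.  Not emulated:
B0 drift, temperature instability, baseline/phasing artifacts, 1H-1H
cross-relaxation (removed by perdeuteration), and partial-volume effects -
green tests establish parameter recovery within the stated world, not
instrument-level robustness.

## Known limitations

- Reduced-scale networks: minor-state recovery and confidence separation are
  below the full-scale system's; ground-state recovery is the asserted
  property.  In particular, the stationary point of the two-part loss puts a
  confidence of 0.4 or more only on inputs whose conditional error is below
  about 0.008 of the sweep width with essentially no catastrophic-miss mass;
  CPU-minute training reaches median ground-state errors of ~0.015 ppm but a
  ~1-3% rate of ambiguous-profile misses, so the trained confidences saturate
  near 0.2 and the c >= 0.4 calibration regime stays unpopulated.  The
  corresponding calibration test documents this as an expected failure of
  scale, not of the machinery (the evaluator, thresholding and k-rescaling
  are exercised regardless).
- A maximum of three exchanging states is architectural; extension requires
  retraining.
- The kinetic parameters (kex, p_E) come only from the least-squares route;
  the networks report shifts and uncertainties.
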