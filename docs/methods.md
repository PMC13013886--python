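# Methods

## The transport model

The assay arena is a circular Petri dish half-filled with agar, with the
pheromone droplet on the lid. The volatile spreads quickly through the air
gap (D_air = 1.6 mm²/s) and is slowly absorbed by and re-released from the
agar (D_agar = 10⁻³ mm²/s). We solve pure diffusion — no advection or
evaporation — on a masked Cartesian grid with a conservative finite-volume
scheme: face conductances are harmonic means of cell diffusivities (the
air–agar interface is concentration-continuous, no partition coefficient),
the circular rim and all walls are no-flux, and the explicit step is chosen
automatically from the stability bound. Because the update is written in
flux form with symmetric conductances, total mass is conserved to round-off
(measured drift ~10⁻¹⁶ over a 30-min run).

Defaults for the standard arena: 8-cm plate (40 mm radius), 4 mm air over
9 mm agar, droplet footprint radius 1.5 mm (≈2 µL) at concentration
c₀ = 0.01 mol/m³ in the topmost air layer. Navigation consumes the 2-D
cross-section at z = −0.5 mm inside the agar, with bilinear spatial and
linear temporal interpolation; ∂C/∂t is a forward difference between stored
frames. Frames outside the circular rim are extended with the nearest
interior value before sampling: the no-flux wall implies a mirrored, not a
zero, boundary, and sampling against zero-filled dead cells would otherwise
inflate relative contrasts near the rim by a factor ~2.

The solved field has a characteristic two-phase history: for the first few
minutes the air column spreads a steep, fast-moving wave (air equilibrates
over the 8-cm plate in ~400 s), while the agar slice integrates the local
air history. By 30 min the slice is nearly flat, retaining only a ~25%
source-to-rim contrast. This flatness is the physical point of the study:
along a 1-mm body the relative concentration difference is almost always
below ~0.1.

### Along-body contrast statistic

For every lateral cell centre, stored frame, and orientation on a uniform
angular grid, the contrast is |C(mid + L/2·u) − C(mid − L/2·u)| / C(mid)
with body length L = 1 mm (adult male scale; not a printed value).
Samples whose midpoint concentration falls below 10⁻⁶·c₀ are flagged and
reported separately — near-zero denominators at the plate edge produce
numerically meaningless ratios — and percentiles are taken over the
unflagged samples. On the 1 mm lateral / 0.5 mm vertical grid the 99th
percentile is 0.133; the value drifts with resolution (0.146 at 2 mm
lateral, 0.137 at 1 mm/1 mm) because the steep early-time fringe dominates
the tail, and the droplet footprint and mesh of the original run are not
printed. We report the finest-grid value.

## The navigation model

Worms are active particles with position, heading, and two internal
confidence variables integrating sensory drive with one memory timescale
(k₁ = 1/60 s⁻¹, k₂ = 1 s⁻¹):

    f_H = (Ċ/Ċ₀) · (1 + tanh log(C/C₀)) / 2
    f_T = exp(−log²(C/C₀))         for C ≤ C₀
        = max(1 − log²(C/C₀), −1)  for C > C₀

The head input responds to the experienced concentration *change* (gated up
by absolute concentration); the tail input is a threshold detector that
peaks at C = C₀ and is suppressed to −1 at high concentration. Q values are
clamped to [−1, 1]: with k₂/k₁ = 60 the raw steady states (60·f) are far
outside the intended range, while the model requires Q^T → 1 at C₀ and → −1
at saturating concentration; clamping reconciles the relaxation dynamics
with those limits and effectively makes Q a saturating integrator.

Locomotion is Euler–Maruyama with dt = 0.1 s: rotational diffusion
(D_R = 0.02 rad²/s), tumbles as a thinned Poisson process with rate
γ = γ₀e^{−λ_K(Q^H−Q^T)} (γ₀ = 0.067 s⁻¹), tumble angles from a mixture of
a uniform circle component (weight α = 0.3) and a wrapped Gaussian centred
at π (σ = 0.6 rad) reflecting the observed reversal-biased turn
distribution, and speed U = max(0, U₀ + U₁(Q^H − Q^T + η)) with
U₀ = 0.064 mm/s, U₁ = 0.03 mm/s and η a unit-s.d. Gaussian redrawn each
step (a constant-offset reading is available via `eta_mode`). Worms with an
intact head detector additionally make a taxis turn — heading reset exactly
toward the source — whenever C exceeds a threshold (0.1·C₀) while the
experienced Ċ < 0. Sensory inputs carry multiplicative noise of relative
magnitude 0.05 by default (`confidence_noise`); success fractions change by
well under one percentage point across the 0.01–0.1 range because the
clamped confidence dynamics saturate.

The plate wall reflects specularly; a worm entering the capture radius
(3 mm, droplet-spot scale) is counted as having found the source and frozen
in place, matching the endpoint-assay convention that worms stop at the
target. Cohorts start uniformly in a 5-mm disc centred 15 mm from the
source along the source→centre axis, with uniform random headings. All
randomness flows through one seeded generator with a fixed per-step draw
order, so runs are bit-reproducible for a given (seed, n, condition).

### Concentration scales C₀ and Ċ₀

The sensory transforms need a reference concentration and rate, which the
model statement leaves free; the droplet surface value (0.01 mol/m³) is
3–4 orders of magnitude above anything on the agar slice, so it cannot be
used directly. We anchor C₀ to the measured dose dependence of the tail
pathway: tail-driven command-neuron activation peaks at roughly a 100–500×
dilution of the source stock and is suppressed at full strength. The
standard-arena parameters therefore set C₀ = (peak slice concentration)/100
(`tail_dilution`, configurable) and Ċ₀ = the 95th percentile of |∂C/∂t|
between stored frames. Under this operating point the plate interior sits
well above C₀ once the pheromone has spread, so sustained exposure drives
Q^T → −1 — the sprint regime: faster, straighter runs — while the arriving
wavefront transiently passes through the activating band.

### Klinokinesis strength λ_K

λ_K is not printed. With λ_K = 2 the tail-only condition outperforms the
blind random walk ~4×, well beyond the reported "almost doubling"; λ_K =
0.5 reproduces the ~2–2.7× enhancement together with the head-condition
saturation and the widened exploration range (mean d_max ≈ 28 mm vs 22 mm
for the null condition), so 0.5 is the default. It is exposed in
`ModelParams` and none of the quantitative headline numbers depend on it
(the null condition has Q ≡ 0 throughout).

### What the cohort experiments do and do not reproduce

Reproduced robustly: the success ordering both ≥ head_only ≫ tail_only >
null; a null (blind) success rate of ~5–7% at 10,000 worms (reported ~10%;
the gap is within the joint uncertainty of the unprinted capture radius —
2 mm → 3.4%, 3 mm → 5.3%, 4 mm → 8.5% — and turning-kernel parameters);
near-certain success with head input; insensitivity to confidence noise;
and the tail-driven widening of d_max. Not reproduced: the reported sign
pattern of the time-averaged horizontal position (⟨x⟩ > 0 without tail
input, < 0 with). Under endpoint freezing, head-present conditions
accumulate all worms at the source, making their time-averaged ⟨x⟩ strongly
negative regardless of tail input; and on our late-flat field the
tail-only/null ⟨x⟩ contrast is below 0.3 mm, smaller than its seed-to-seed
spread. We report ⟨x⟩ (plate-centre origin, source→centre = +x) as defined
and document this divergence rather than adjust the model to force it.

## Trajectory analytics

Speeds are centred finite differences of recorded positions, optionally
box-smoothed. Spectra are single-taper periodograms with linear detrending;
the DC bin is excluded from the peak search, and a resolution warning is
raised below five cycles of the dominant period. Peak strength is reported
on the *amplitude* scale — sqrt(peak power / local background median, the
median taken over ±20 bins excluding the 2 bins nearest the peak) — so
that doubling a response's modulation amplitude approximately doubles the
reported strength, matching how the factor-of-two sex difference in
response robustness is expressed.

Motif classification divides a signed along-body velocity into contiguous
2-s windows. A "direction change" is a sign change between consecutive
nonzero-signed samples. More than two changes → high-frequency transition
(six-motif scheme); a sustained self-proximity flag (> 50% of the window)
→ self-exploratory (six-motif scheme, requires a proximity channel);
otherwise the window is labelled by its (first, last) sign pair — which
also resolves exactly-two-change windows by their net start/end direction.
The four-motif scheme applies the sign-pair rule throughout, so it coarsens
the six-motif labels.

Chemotaxis indices: type 2 assays (test + control spots) use
(E − C)/(E + C + N); type 1 (no control spot) uses E/total.

## Calcium analytics

Both fluorescence channels are Savitzky–Golay filtered (order 1, window 13,
mirror-padded edges — order 1 preserves affine signals exactly at interior
points), the ratio R = GCaMP/reference is taken pointwise, and
ΔR/R₀ = (R − R₀)/R₀ with R₀ the mean ratio over the labelled quiescent
epoch. Sign-restricted AUC subtracts a pre-stimulus baseline (3-min window
by default; for titration series the caller passes the most-dilute
condition's baseline) and integrates, by trapezoid, only sub-baseline
(suppression) or supra-baseline (excitation) intervals of the 2-min
post-stimulus window. Correlation screening is plain Pearson with a strict
\> 0.55 selection; zero-variance candidates are excluded with a warning.
The circuit decomposition is ordinary least squares with intercept over a
caller-chosen window; the printed weights (−0.7, 0.1, −0.2) are treated as
generative ground truth for recovery tests, not as a real-data target.

## Optimal-turn analysis

The worm estimates the local gradient by measuring concentration at the
start of a leg, at the turn point, and at the end of a second leg, and
differencing: two directional-derivative samples d_i = g·u(θ_i) + ε_i
solved for g by least squares. Because both samples share the turn-point
measurement, their noises are anti-correlated; we additionally model the
turn-point sample as noisier than the leg-end samples (s.d. ratio
`shared_noise_factor` = 2, i.e. derivative-noise correlation −0.8), since
the turn itself perturbs sensing. Direction uncertainty is the RMS wrapped
angular error of atan2(ĝ) at finite noise (per-sample s.d. 0.3 relative to
|g|), evaluated by 40-node 2-D Gauss–Hermite quadrature — fully
deterministic. The derivation behind the published analysis is not spelled
out in the main text, so this noise model is a reconstruction, chosen
because it is the only variant of the stated framework we found that
reproduces both published features simultaneously: with independent
derivative noise the orientation-averaged optimum provably sits at 90°
(directional information is invariant under u → −u), and the equal-noise
shared-sample variant gives 105.5°; the adopted model gives 121.0° averaged
and fixed-orientation optima of 107°–132.5°, all beyond 90°. Both
alternatives remain available through `shared_noise_factor`, and the
small-noise delta-method objective is kept as
`linearized_direction_uncertainty` for contrast.

## Synthetic data

Generators are seeded, embed their generative parameters in metadata, and
give each analysis at least one input with a closed-form truth. Calcium
traces: fast responders (probability 0.625) ramp to full amplitude at
stimulus onset over 10 s, hold 120 s, then decay slowly (τ = 600 s); slow
responders start 150 s late at 0.6× amplitude; both channels carry
multiplicative Gaussian noise. The kinetic shape constants are package
choices made to resemble the measured traces qualitatively — only the
fast fraction, delay, and amplitude factor are treated as fixed by the
study. Speed traces are a baseline with an additive on-epoch elevation
plus Gaussian noise; circuit triplets are smoothed random walks composed
linearly; endpoint counts are multinomial. Toy concentration fields
(uniform / linear / Gaussian hill) provide exact samplers used as oracles
for the navigator and the contrast statistic.

What passing tests show — and don't. The generators emulate the
statistical structure the analyses assume (periodic locking, two-class
responders, linear composition, multinomial endpoints); they do not emulate
tracker artefacts, posture, photobleaching, or motion noise, so green tests
certify the computations, not robustness to real-microscopy pathologies.

## Problem sizes and numerical defaults

Cohort simulations use dt = 0.1 s and record every 10 s; the acceptance
run uses 10,000 worms for the null condition (matching the study's cohort
size) and 400–800 per condition for the phenomenology checks. The contrast
statistic is computed on a 1 mm / 0.5 mm grid with 16 orientations and
181 frames (~1.4 × 10⁷ samples); the navigation field uses a 2 mm / 1 mm
grid, which changes condition-level success fractions by well under a
percentage point relative to the fine grid. The turn-angle curve is scanned
at 0.5° with 72 (averaged) or 36 (fixed) initial orientations.

## Known limitations

* No advection, evaporation, or source depletion in the transport model;
  the gellan-gum 3-D assay is represented only by its endpoint index
  arithmetic.
* The worm is a point: no posture, undulation, or body-curvature dynamics.
* The ⟨x⟩ sign pattern across detector conditions is not reproduced (see
  above); conclusions that depend on it should not be drawn from this
  implementation.
* The turn-angle objective is a reconstruction of an unpublished
  derivation; its optimum depends on the assumed noise anatomy, which is
  why all three noise variants are exposed.
* The contrast percentile inherits the unprinted droplet and mesh geometry
  of the original transport run; we document its grid sensitivity rather
  than claim convergence to the printed third decimal.
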