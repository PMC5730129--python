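# Methods

`leafecho` simulates the ultrasonic echoes that an echolocating bat would
receive from foliage, and quantifies how unevenly those echoes distribute
energy over time.  This note records the model, its assumptions, the
numerical choices, and what the synthetic experiments do and do not show.

## The echo model

Every leaf is a rigid circular disc.  In the Mie regime relevant to bat
biosonar (leaf sizes comparable to the 4–6 mm wavelengths of a 60–80 kHz
pulse) the backscattered amplitude of a disc of radius `a` at incidence
angle `θ` is approximated by the cosine law

    A(f, a, θ) = (k a² / 2) · cos θ,      k = 2πf/c,

which has the correct high-frequency normal-incidence prefactor and the
correct size and frequency scaling.  The Kirchhoff (physical-optics) flat
plate solution, `A · |2 J₁(x)/x|` with `x = 2 k a sin θ`, is implemented
as a validation oracle and agrees at normal incidence; the exact
oblate-spheroidal disc solution is out of scope.  Multiple scattering and
shading between leaves are not modelled: every leaf contributes
independently regardless of what is in front of it.

The sonar is monostatic with a Gaussian beam, parameterised directly in
dB as a separable quadratic in azimuth and elevation so the two-sided
−3 dB beamwidth is exact by construction.  The transfer function of leaf
`i` at range `r` is

    Hᵢ(f) = g²·A(f, aᵢ, θᵢ)·10^(−2 r α(f)/20)·r⁻²·exp(−j 2πf·2r/c),

with one-way beam gain `g` applied on transmit and receive, two-way
spherical spreading `r⁻²`, optional ISO 9613-1 atmospheric absorption
`α(f)`, and the round-trip phase delay.  Echoes are the coherent sum of
all leaf transfer functions on 2000 evenly spaced frequencies across
60–80 kHz; the half-open grid (spacing exactly 10 Hz) makes every band
frequency a bin of the 40000-point FFT of a 0.1 s record, so a Hanning
window across the band followed by a conjugate-symmetric inverse FFT
yields the real impulse-response waveform at 400 kHz with no
interpolation.  The emitted pulse is an impulse; convolution with a
species-specific call is out of scope.

### Fast synthesis

Direct evaluation is O(leaves × frequencies) and infeasible for the
million-disc pine model.  The default fast path bins each leaf's
round-trip delay onto the output sample grid and expands the residual
sub-sample phase (and, when absorption is on, the deviation of `α(f)`
from its band-centre value, fitted by a quadratic in `f`) in a short
Taylor series about the band centre; the band spectrum is then read off a
handful of full-length FFTs of the binned moment arrays.  Agreement with
direct summation is ~1e-8 relative without absorption and better than
1e-3 with it, at O(leaves) cost.  Superposition is exactly linear in both
paths.

## Foliage geometries

**Uniform reference.**  Disc positions uniform in a rectangular box in
front of the sonar (leaf count Poisson with mean density × volume),
disc-normal zenith angles Gaussian (uniform azimuth), radii Gaussian
truncated at zero.  A sizing routine finds the smallest integer-metre box
enclosing the region where two-way spreading + absorption + two-way beam
attenuation stays within an 80 dB budget; with absorption on (the
default for sizing) the budget terminates near 11 m and a 30° beam gives
a box in the neighbourhood of 9×4×4 m.  Without absorption, pure
spreading would not reach 80 dB until 100 m, which is why absorption is
part of the loss budget throughout the scenario pipeline.

**Pine (eastern white pine).**  Bifurcating monopodial L-system, 13
growth levels.  One child continues the mother's direction; the other
deviates by an angle interpolated linearly from 90° (level 1) to 20°
(level 13), i.e. ≈5.8° less per level, in the plane through the mother
perpendicular to the plane of the mother and grandmother branch.  Along
a straight stem that plane is degenerate; the previous branching plane is
then rotated 90° about the branch axis, which spirals successive side
branches around the stem (the recursion is seeded with the world x–z
plane).  Contraction ratios: 0.9 (stem child), 0.7 (side child).  Each
terminal branch carries thirty 15-cm needle bundles spirally placed over
its distal 4.5 cm (golden-angle azimuth increment, 137.5°) at 75° from
the branch axis; each bundle becomes five discs uniform in a 1 cm cube on
the bundle tip, with the origin→point vector lying in the disc plane
(the normal is drawn uniformly perpendicular to it).  Disc radii:
Gaussian 2 mm ± 0.2 mm.  One realisation carries 2^12 × 150 = 614 400
discs.

**Ginkgo.**  Ternary L-system, 8 levels: one central child (contraction
0.83) and two side children at ±50° (contraction 0.62).  Four leaf nodes
divide every branch into equal parts with one node on the tip.  Tip nodes
of terminal branches align with the branch and hold four leaves uniform
in a 10×10×20 cm box (long axis along the branch); all other nodes are
perpendicular to their branch, the first at random azimuth and each
subsequent node rotated 90°, their four leaves displaced to alternating
sides by `0.10 m · (n̂ + 0.1·u)`, `u` uniform on [−1,1]³ (the
displacement length scale is half the tip box's long edge; the growth
rules give no unit for it, so it is exposed as a parameter).  Leaf
normals follow the displacement direction.  Radii: Gaussian
2.5 cm ± 0.25 cm.

**Densification.**  Each tree is unioned with a copy of itself rotated
about the vertical axis (180° pine, 90° ginkgo; the ginkgo copy is also
raised by half the trunk length), exactly doubling segment and leaf
counts.

Trunk lengths are not part of the growth rules; defaults (pine 1.6 m,
ginkgo 2.0 m) are chosen so the geometric series of stem contractions
reproduces the reference tree heights (≈12 m and ≈10 m).

## The temporal-inhomogeneity statistic

For one echo: Hilbert envelope → echo bounds by thresholding at a margin
(default 100 dB in amplitude) above the numerical noise floor → the
bounded segment is normalised by its mean amplitude, decimated to 50 kHz
(factor-8 FIR decimation with anti-alias filtering), padded with 50
zeros on each end, and split into 100 windows (remainder samples spread
one per window from the front).  The statistic is the RMS difference
between the per-window means and a uniformly random permutation of them;
its expected square over all permutations equals exactly twice the
population variance of the window means (verified by exhaustive
enumeration in the tests).  One permutation per echo is the default;
averaging over more is available for variance reduction.

Numerical choices that matter:

* **Noise floor.**  A noise-free simulation has no true noise; the floor
  is the mean envelope over the quieter of two echo-free regions — the
  record head before the earliest physically possible arrival (round
  trip to 1 m) and the final tenth of the record — and falls back to a
  machine-precision floor when that region is exactly silent.  Pipelines
  with a genuinely noisy head can pass an explicit head length.
* **Normalisation.**  Echo amplitudes across scenario conditions differ
  by orders of magnitude (leaf counts from hundreds to a million; ranges
  from 1 to 11 m), so the segment is normalised by its mean amplitude,
  making the statistic a dimensionless coefficient-of-variation-like
  quantity.  Peak normalisation and raw amplitudes remain available; the
  raw statistic is homogeneous of degree 1 in the envelope.
* **Degenerate inputs.**  Constant envelopes score exactly 0 under every
  permutation; an envelope with no sample above threshold raises a
  no-echo error rather than returning a number.

## Sonar-pose scenarios

Three sweeps, each regenerating the random leaf placement every
replicate (the deterministic skeleton is grown once and cached):

* **approach** — sonar aimed at the tree centre, distance 9.5 → 2.5 m in
  1 m steps (50° beam);
* **angular scan** — 2 m from the centre, 50° beam, aim rotated 0–90° in
  10° steps;
* **beam widening** — 2 m, facing the centre, two-sided beamwidth
  {1, 5, 10, 20, 30, 40, 50, 60}°.

Leaves contribute when their two-way spreading + absorption + two-way
beam attenuation is within 80 dB, they lie in the forward half-space, at
least 1 m away (the far-field validity limit of the transfer function —
poses sit inside the canopy, and sub-metre leaves would otherwise swamp
the echo through r⁻²), and within the record's unambiguous range window
(≈17 m).  The in-beam leaf count uses the same budget.  For every grid
point a matched uniform reference is built: box depth = c·duration/2
from the tree run's mean echo duration, near face at the tree echo's
onset range, cross-section covering the beam to the 80 dB attenuation
angle (capped at 45° off-axis), and density calibrated by Monte-Carlo
integration of the in-budget indicator so the expected in-beam count
equals the tree's.  Reference sonars always aim straight at the foliage.

Scale of the shipped experiments: 20 replicates per grid point (the
sweeps in the original study design use 100; the trends stabilise well
below that and 20 keeps a full six-sweep comparison within minutes on
one CPU).  Trees are always full size.

## What the synthetic experiments show — and what they do not

With these conditions the simulations reproduce the decrease of
inhomogeneity with beam widening for both species (a 1° pencil beam
returns a spiky, gap-ridden echo from a few hundred discs; a 60° beam
blends hundreds of thousands into a smooth envelope) and the
angular-scan increase towards 90° for the pine, together with the
negative metric–count relationship within those two sweeps.  Two
behaviours do **not** reproduce.  The approach sweep shows the metric
*rising* towards the foliage rather than falling: with per-leaf r⁻²
spreading and absorption inside the echo, the within-echo amplitude
decay spans the full 80 dB budget, so approaching front-loads the
normalised envelope; a range-flat amplitude weighting (losses used only
to select leaves) reverses the approach trend but then inverts the
angular-scan trend, and no weighting we examined reconciles all three
sweeps.  And the matched uniform reference is *not* consistently below
its L-system counterpart: it lacks clustering gaps, but its box
inherits the same steep in-echo budget decay, which raises its
CV-like score enough to offset that advantage at many grid points
(it does score clearly lower at narrow beamwidths, where tree clustering
matters most).  The shipped defaults keep the physically motivated
weighting; the acceptance tests assert the stronger published
behaviours and fail loudly where this implementation does not show
them.

The generator emulates geometry and coherent scattering, not real
foliage: no leaf-shape diversity, no shading or multiple scattering, no
wind motion, no receiver noise, and Gaussian leaf-size spread far
narrower than natural variability.  Passing tests therefore validate the
simulation pipeline and the statistic's behaviour on this model family,
not quantitative predictions for field recordings.

## Measurement utilities

The physical-measurement toolkit mirrors an impulse-response rig: MLS
excitation (Galois LFSR, default primitive polynomial
x⁸+x⁶+x⁵+x⁴+1 → period 255, 0.51 ms at 500 kHz; non-primitive tap sets
are detected by their short register cycle and rejected), impulse
recovery by circular cross-correlation, sub-sample peak refinement by a
2nd-order polynomial fit to an 11-point window of the Hilbert envelope
(median across repeats as the target-strength aggregate), equivalent
radius `√(area/π)` for measured leaf areas, and a closed-form scalar
least-squares fit (`Σmp/Σp²`) of disc-model predictions to measured
target strengths with the coefficient of determination about the
measurement mean.  A packaged table of equivalent leaf radii across ten
tree species supports the documentation example.

## Known limitations

* The approach-sweep discrepancy described above.
* Binned synthesis assumes the cosine disc law; physical-optics
  directivity always takes the direct path.
* The 100 dB detection margin on leakage-limited floors can sit within
  an order of magnitude of the echo peak for dense scenes; the min(head,
  tail) floor estimate keeps it robust for the shipped scenarios.
* In-branch ginkgo leaf nodes are placed on every branch including the
  trunk; the growth rules do not say whether the trunk bears short
  shoots.
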