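# leafecho

Simulation toolkit for the biosonar echoes of foliage: procedural leaf
geometries (uniform disc clouds and biomimetic L-system trees),
frequency-domain echo synthesis from circular-disc scatterers, and a
permutation-based statistic for the temporal inhomogeneity of echo
envelopes.

## Who this is for

Researchers in biosonar sensory ecology and bioacoustics who want to ask
how the structure of vegetation — leaf size, orientation, density, and
above all the *spatial clustering* imposed by branching patterns — shapes
the ultrasonic echoes an echolocating bat receives, and whether simple
echo statistics carry information about the relative pose of sonar and
foliage.

## The model in brief

Each leaf is a rigid circular disc whose monostatic backscatter follows
the cosine approximation `A(f, a, θ) = (k a²/2)·cos θ` (with the
physical-optics `|2J₁(x)/x|` form available as an oracle).  A Gaussian
beam with exact two-sided −3 dB widths weighs each leaf on transmit and
receive; two-way spherical spreading, optional ISO 9613-1 atmospheric
absorption, and the round-trip phase complete the per-leaf transfer
function

    Hᵢ(f) = g² · A(f, aᵢ, θᵢ) · 10^(−2rα(f)/20) · rᵢ⁻² · e^(−j2πf·2rᵢ/c).

Echoes are the coherent sum of all leaves on 2000 frequencies across
60–80 kHz (the strongest harmonic of a horseshoe-bat call), Hanning
windowed and inverse transformed to a 0.1 s impulse-response record at
400 kHz.  An O(leaves) delay-binned evaluation makes million-disc trees
practical on one CPU.

Foliage comes from three generators: a uniform box (the reference
model), an eastern white pine L-system (13 bifurcating levels, needle
discs in spiral bundles on every terminal branch), and a ginkgo
L-system (8 ternary levels, large leaf discs on short-shoot nodes along
every branch).  The temporal-inhomogeneity statistic of an echo is the
RMS difference between the per-window mean envelope amplitudes of the
detected echo segment (mean-normalised, decimated to 50 kHz, padded,
100 windows) and a randomly window-permuted replica.  See
`docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

Grow a ginkgo, look at its echo from 3 m, and score it:

```
$ leafecho grow-tree --species ginkgo --seed 1 -o ginkgo.csv
ginkgo: 6560 branches, 104960 leaf discs -> ginkgo.csv

$ leafecho synthesize ginkgo.csv --distance 3 --beamwidth 50 -o echo.wav
104960 discs -> echo.wav (100.0 ms record)

$ leafecho metric echo.wav
echo.wav: 1.18024
```

The tree carries 104 960 leaf discs (3280 branches × 4 nodes × 4 leaves,
doubled by the rotated-copy union).  The metric value ≈1.18 is the
dimensionless inhomogeneity of this echo: RMS window-mean deviation
≈1.2× the mean envelope amplitude, typical for a clustered foliage
observed from inside its canopy; a perfectly smooth echo would approach
0, while an echo concentrated in a single one of the 100 windows scores
≈14 (√(2·99), the extreme of the mean-normalised statistic).

The same sweep the library runs programmatically:

```python
from leafecho.experiments import ScenarioSpec, run_scenario

spec = ScenarioSpec("beam_widening", "pine", n_replicates=20, seed=1)
result = run_scenario(spec)
print(result.summary())      # per-width mean/min/max metric, leaf counts
print(result.max_min_ratio())
```

With seed 1 this prints a per-width mean inhomogeneity falling from 4.40
at a 1° beam (a pencil beam hits isolated needle clusters — a spiky,
gap-ridden echo from a few hundred discs) to ≈1.76 at 60° (≈700 000
discs blend into a smooth envelope), a max/min ratio of 2.94.

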