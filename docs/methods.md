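# Methods

## Model

### 1D loop extrusion

Condensin complexes are modelled as loop extruders on a genomic lattice
(default 1 kb per site, matching the 1-kb monomers of the 3D model). Each
extruder holds a left and a right anchor. One-sided extruders move a single
anchor, chosen uniformly at binding; two-sided extruders move both anchors
at half the extrusion rate, so the loop always grows at the nominal rate.
Anchor motion per 1-s timestep is rate x dt converted to lattice sites with
stochastic rounding (the fractional part becomes a Bernoulli extra step).
Under the default `free` traversal policy extruders pass through one
another, the property that lets loops overlap extensively; under `stall` an
anchor halts while its next site is occupied. Chromosome ends always stall.

Two species implement the mitotic schedule (2400 one-second steps,
prophase to metaphase):

| parameter | condensin II | condensin I |
|---|---|---|
| density (per Mb) | 2 | 10 |
| load time (s) | 0 | 600 (nuclear envelope breakdown) |
| residence time (s) | infinite (stable) | 120 |
| rate (kb/s) | Normal(4, 2), truncated at 0 | same |
| sidedness / traversal | one-sided, free | one-sided, free |

Rates are drawn once per (re)binding event and held fixed; the resulting
heterogeneous loop lengths are what produces a scaling dip rather than the
periodic undulations a uniform rate would give. Dynamic extruders unbind
with probability 1 - exp(-dt/tau) per step and rebind immediately at a
uniform random site with a fresh rate and direction (constant copy number).
The condensin I residence time is not a directly measured constant; 120 s
("bound for minutes") is the configurable default. Condensin II loads
instantaneously at t = 0. At steady state a dynamic species' mean loop
length is rate x tau x (1 - exp(-T/tau)), the closed form the tests check
against Monte-Carlo ensembles.

### 3D polymer

The chromosome is a chain of N monomers, default 1 kb per monomer at a bond
length b = 12 nm — the physical scale obtained by calibrating an
unconstrained chain against condensin-depleted high-resolution traces
(`calibrate_scaling` exposes this least-squares alignment). Forces:

- backbone bonds: U = (k/2)(r - b)^2 with k = 35 kT/b^2 (radial
  fluctuations ~ 0.17 b);
- extruder bonds: same form, rest length b/2, bridging the two anchor
  monomers of each non-zero loop (anchor bp -> monomer by integer
  division);
- self-repulsion between non-neighbouring monomers:
  U(r) = Emax (1 - (r/rc)^2)^3 for r < rc, with Emax = 1 kT and
  rc = 1.05 b. The potential is finite at the origin (U(0) = Emax), so
  chains can cross — implicit topoisomerase activity. Only the qualitative
  "polynomial repulsion" form is externally constrained; this particular
  polynomial is smooth, has U(rc) = U'(rc) = 0, and is the package's
  choice.

The TSA (histone hyperacetylation) variant multiplies Emax by 5 and widens
rc to 1.5 b, leaving everything else unchanged.

Dynamics are overdamped Langevin (Brownian): dx = F dt / gamma +
sqrt(2 kT dt / gamma) xi, at kT = 1, gamma = 1, with no confinement. The
default timestep resolves the bond relaxation time gamma/k by 12 steps; the
normative contract is statistical (equipartition of bond fluctuations
against a numerical Boltzmann-integral oracle, ideal-chain internal
distances, diffusive centre of mass), not the integration scheme.
Divergence (any coordinate beyond 10^9 nm, or a runaway neighbour grid) is
reported as an unstable timestep. Integration arithmetic runs in float32 —
rounding at cellular coordinates is sub-picometre, far below thermal noise
— with positions stored in float64. Non-bonded pairs come from a cell-list
neighbour search with a 0.3 b Verlet skin, rebuilt every 5 steps.

### Coupling and desk-scale configuration

A dynamic mitotic run equilibrates a random-walk chain, then walks through
the 1D trajectory's snapshots, replacing extruder bonds and relaxing the
polymer between updates. The bond-update cadence is configurable; the
default pace is ~125 updates per schedule. (The source protocol's two
stated step counts — an update every 5th extrusion step, and 2.5 M total
steps — are mutually inconsistent by a factor of ~4; the total is treated
as authoritative and the cadence derived from it.)

Full scale (100 Mb at 1 kb/monomer) is not desk-sized, so the standard
desk-scale configuration in `mitotrace.pipelines` is a 50-Mb chromosome at
g = 10 kb per monomer with the bond length scaled by sqrt(g) under the
equilibrium-globule assumption (b = 38 nm), five replicates, and metaphase
sampled as the experiments do: 100-kb probes at 1-Mb spacing, ten genomic
offsets per chromosome. Desk-scale numerical settings: 7,000 equilibration
steps, 60 bond updates of 700 steps each, and 100,000 further relaxation
steps at the final (metaphase) extruder configuration before sampling. The
settling phase compensates the shorter per-update relaxation of the
reduced-scale runs; without it the metaphase curve plateaus at the mean
loop size instead of developing its local minimum, the signature of
incomplete axial compaction. These sizes are stated here because every
simulated number in the tests and in `scripts/acceptance.py` is computed
under them.

## Trace analytics

- **Scaling curves** pool all within-trace pairs (traces with >= 30
  present points) and report the median distance per unique separation, or
  per logarithmic bin (30/decade) for pooled multiscale data. Exponents
  come from nonlinear least squares on y = a x^b, seeded by a log-log
  linear fit.
- **Loop calls**: contacts are point pairs closer than 100 nm spanning
  >= 30 kb. A contact (a,b) is *nested* when contacts matching (a,c) and
  (c,b) exist for some a < c < b (merged bases; anchors matched within one
  probe step); two contacts (a,b), (c,d) with a < c < b < d are *Z-loops*;
  the rest are *base* loops. Nested takes precedence over Z.
- **Metrics** (traces >= 80% complete and >= 80 points at 12-kb
  resolution): radius of gyration, elongation = sqrt(smallest/largest
  covariance eigenvalue) as the ellipsoid-fit proxy, contour length, loop
  class counts.
- **Axis geometry**: the chromosome axis is the 20-Mb centred genomic
  rolling mean of the trace (present points; truncated edge windows).
  Length is the axis arc length; width the median distance of trace points
  to the axis polyline, with the terminal segments extrapolated so a
  straight rod has zero width everywhere. Axial scaling slopes use
  Siegel's repeated-median regression on pooled pairs in 20-60 Mb
  (reduced to per-separation medians first when the pool exceeds ~2 x 10^4
  pairs, since the estimator is quadratic).
- **Helicity**: each point's radial angle is measured in a
  parallel-transported frame along the axis; the frame is built on a
  twice-smoothed axis because residual periodic wobble of the rolling mean
  would otherwise add spurious torsion and shift the apparent pitch.
  Angles live on [0, 2pi) and the profile is the plain SD of lagged angle
  differences: for a regular helix the angle is a sawtooth, so differences
  take two values 2pi apart — SD ~ 0 at multiples of the pitch, maximal at
  half-pitch, and flat at 2pi/sqrt(6) for featureless traces. (A rotation-
  invariant circular SD would be blind to the half-pitch maximum, which is
  why the plain SD of mod-2pi differences is used.)
- **Outlier filter**: a point is dropped when its distance to the median
  position of its centred 11-point window exceeds 3 x the RMS spread of
  the window about that median. Using the spread of positions (rather than
  the SD of the distance values) keeps the ends of smooth traces, whose
  windows are truncated and asymmetric, from being flagged.
- **Compartments**: square symmetric distance/contact matrices are
  normalized by their per-offset median/mean; the correlation matrix is
  the pairwise-complete Pearson correlation of the normalized columns.
- **P(s) comparison**: balanced contact tables are averaged per diagonal,
  aggregated to 1-Mb resolution, and aligned with the inverted (1/d)
  scaling curve; optional log-linear fits split at 1,000 nm. Raw-count
  tables are flagged, not balanced.
- **Dip localization**: strict interior local minima of the curve, ranked
  by prominence in log space — scaling curves rise overall, so the
  absolutely lowest local minimum would be dominated by noise at small
  separations. Pooled multi-replicate simulation curves are evaluated raw
  (each bin already averages ~10^5 pairs, and even light smoothing erases
  the genuinely shallow mitotic dip); an optional moving-average
  pre-smoothing is available for noisy single-ensemble curves.

## Assembly

Whole-chromosome spots carry a 15-Mb segment barcode and a spot barcode
repeating every 30 Mb. Segment assignment is by intensity z-score
(z_k = (I_k - mean I)/sd I; zero variance flags the fit ambiguous);
(segment, spot) pairs decode to a genomic coordinate when exactly one
repeat of the spot barcode falls inside the assigned segment. Regions with
several chromosome copies are split by spectral clustering
(nearest-neighbour affinity, 10 neighbours) on standardized
(x, y, z, genomic) features, raising k = 1..5 until at least 75% of
genomic coordinates have at most one fit per cluster; remaining duplicates
keep the highest z-score. Numeric QC thresholds (fit SD, signal/background)
are configuration, not constants.

## Synthetic data

Generators are seeded and emit ground truth. Helices default to 12-Mb
pitch, 300 nm radius, and a rise of 4 x 10^-5 nm/bp (a 100-Mb helix spans
4 um); localization noise is Gaussian, sigma = 200 nm per axis. Planted-loop
traces use a randomly oriented, lightly jittered straight backbone whose
step (160 nm) exceeds the contact cutoff plus the anchor distance, with the
anchors of each planted contact collapsed into small clusters at exactly
40 nm — this guarantees the specified contacts and only them, which the
generator verifies before returning. Localization-field copies are smoothed
random walks rescaled to a compact territory (RMS radius 800 nm) and
displaced by a configurable offset; intensity vectors carry planted noise,
optional segment mis-assignment, and dropout. Planted-dip curves place the
*realized* interior minimum at the requested position (the rising power law
would otherwise drag it left of the Gaussian's centre).

What the generators do not emulate: optical PSFs and detection noise
statistics of real microscopes, chromatic aberration, sister-chromatid
cross-talk, cell-to-cell variability of condensin abundance, and sequence-
dependent chromatin state. Tests passing on these fixtures therefore
validate the algorithms' correctness and the model's internal predictions,
not instrument-level robustness.

## Numerical and design choices

- Genomic coordinates are 0-based interval starts in bp; probe coordinates
  are interval midpoints; all spatial units nm; simulation time seconds.
- Loop-class precedence (nested over Z) follows from nesting being the
  stronger, merged-bases condition.
- k = 1 in disambiguation means "no clustering"; fewer spots than k caps k.
- Zero-length loops create no 3D bond.
- Known limitations: no sister chromatids, no explicit topoisomerase (the
  soft core stands in), no bending rigidity or confinement; desk-scale
  runs trade per-update relaxation for a final settling phase, so their
  pre-metaphase (prophase/prometaphase) conformations are less relaxed
  than their metaphase ones; the 1D stall policy resolves collisions in
  index order within a step.

## Problem sizes used by tests and the acceptance script

- Coupled simulation: 50 Mb, 10 kb/monomer (N = 5000), 5 WT replicates
  (plus TSA replicates at matched seeds for the repulsion-variant check),
  10 probe offsets each.
- 1D loop statistics: 100-Mb lattice, 10 seeds (2000 condensin II
  extruders pooled).
- Phantom-chain exponent: 1000 chains of 500 points, fitted over two
  decades of separation.
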