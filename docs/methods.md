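# Methods

## Model

The cell is a spherocylinder with its long axis along x and the origin at
the cell center; `L` is pole-to-pole (the 3.0 µm default includes both
hemispherical caps — the geometry block exposes `radius_nm`/`length_nm` if a
different reading is wanted). All internal lengths are nm; volumes are
reported in µm³ and diffusion coefficients accepted in µm²/s, converted once
at the API boundary.

Particles are hard spheres; the only interaction is pairwise exclusion per a
symmetric boolean species table. DNA is a single connected hyperbranched
bead–rod polymer. Each rod vertex carries two co-located beads: a *red* bead
(12 nm) that excludes other red beads, and a *gray* bead (25 nm) that is
invisible to all DNA beads but excludes ribosomal particles — the gray
envelope represents the plectoneme volume a ribosome cannot enter, while
red–red exclusion keeps the chain itself self-avoiding at a finer scale.
Ribosomal species exclude one another and the gray beads. The default radii
are: 70S 10 nm (so 7,500 copies total ≈ 0.031 µm³), 30S 7.0 nm and 50S
8.7 nm (chosen so V30S + V50S matches V70S to 0.15%), RNAP 5.2 nm (5,000
copies ≈ 0.0029 µm³). The DNA bead radii and the 86-nm rod length are
plectoneme-scale conventions, not measured quantities; they are exposed in
the species/build config and every result that depends on them says so.

### Topology and construction

Two chromosome equivalents default to 7000 rods (3500 per equivalent). The
backbone is a closed ring taking ~10% of the rod budget; branches of
geometric length (mean 9 rods) attach at uniformly chosen ring beads until
the budget is exhausted (the last branch is truncated). These topology
numbers are documented package defaults, not claims about the chromosome.

A closed loop of exact fixed-length rods cannot be grown by naive sequential
placement, so the ring is initialized as a serpentine space curve — straight
rows along x on a circle in the y–z plane, joined by two-rod corner apexes —
which closes exactly with every rod at 86 nm; a seeded random rotation about
x varies it between seeds. Branches, polysome chains and dissociated
subunits are placed by sequential random growth with per-bead retries
(growth raises a named error if a bead cannot be placed). Builds are
overlap-free by construction, verified by the brute-force scan, and
bit-for-bit reproducible under a fixed seed. 20,000 ribosomes at k = 13
give 1538 complete chains; the remainder of 6 is kept as one short chain
(flagged in the build report) so particle counts are conserved.

Volume-fraction bookkeeping counts self-excluding species only (red DNA
beads, ribosomal particles, RNAP): the gray envelope beads overlap the chain
contour and are phantom to themselves, so summing their sphere volumes would
double-count plectoneme volume (they alone would nominally be ~43% of the
cell). Under this bookkeeping the default full system is ~13%, comfortably
mobile.

## Monte Carlo engine

The system is athermal: Metropolis acceptance reduces to reject-on-violation
(overlap, wall crossing with margin = particle radius, or bond-length
change), and no temperature parameter exists. All proposals are symmetric,
so detailed balance holds and the chain samples the uniform measure over
allowed configurations — the maximum-entropy state.

Move set (one attempted move per mobile bead per sweep, chosen by bead
class):

* free spheres — cubic random displacement;
* polysome beads — crankshaft about the two bonded neighbors, terminal
  rotation at chain ends, pivot of the shorter chain side about its hinge,
  and occasional rigid whole-chain translation;
* DNA branch beads — crankshaft, and downstream pivot of the bead-to-tip
  segment about its parent;
* DNA ring beads — segment crankshaft: a short arc of the ring rotates about
  the axis through its two boundary beads, *carrying all branches attached
  to the arc rigidly*. Without this move the backbone would be nearly
  frozen, because most ring beads are branch points whose bonds a plain
  crankshaft cannot preserve.

Gray beads ride rigidly on their red twin and are checked against the same
wall margin and their own exclusions. Neighbor search uses a uniform cell
grid (55-nm cells ≥ the largest excluding-pair contact distance of 50 nm)
with linked cells updated per accepted move; the hot loop is compiled with
numba. A pure-Python cell-grid pair enumerator is kept as the user-facing
`cell_list_neighbors` and must agree exactly with the brute-force O(n²)
scan (tested). A full overlap/wall/bond audit runs every `audit_interval`
sweeps and raises on any violation.

Displacement and rotation amplitudes are tuned during burn-in toward a
30–50% acceptance band and then frozen, preserving detailed balance in
production. Convergence is monitored through the DNA radius of gyration and
the nucleoid length; a run is flagged stationary when the two half-series
means agree within two pooled standard deviations. Non-stationarity is a
flag, not an error.

## Observables

Projections are 50-nm-bin histograms (the localization-accuracy scale).
`L_DNA`/`W_DNA` use the *outside* FWHM: the distance between the leftmost
upward and rightmost downward crossings of half the **global** maximum with
linear interpolation between bin centers, so a bimodal nucleoid is measured
across both lobes. A profile that does not fall below half max at both ends
has no defined FWHM and raises. Peak-to-valley uses the two highest smoothed
local maxima separated by ≥ 4 bins over the minimum between them; fewer than
two peaks returns the degenerate value 1 with a flag.

"Within the nucleoid" is operationalized as a kernel-density envelope: DNA
positions are binned on a 25-nm grid, smoothed with a 50-nm Gaussian, and
thresholded at 0.5 of the density maximum (mirroring the FWHM convention;
threshold, bandwidth and grid are config). The envelope is this package's
proxy for the nucleoid region and is labeled as such in reports. Mixing is
quantified by the fraction of a species inside the envelope and by the
normalized inner product (cosine overlap) of matched axial profiles.

## Imaging

Widefield rendering bins projected (x, y) emitter positions into pixels
(65-nm default) and convolves with a Gaussian PSF of FWHM λ/2 (260 nm at
520 nm); flux is conserved before optional Poisson noise, and out-of-field
emitters are clipped with a count. Gaussian blur and axial projection
commute, which the tests exploit as an oracle. PALM rendering draws each
emitter's projected position plus independent per-coordinate Gaussian
localization error (σ = 30 nm default); the "~30 nm accuracy" is
interpreted as a Gaussian SD per coordinate, and photoswitching kinetics are
not modeled — sampling is an idealized sparse draw, which is all the
analyses need.

## Tracking

Trajectory lengths are geometric with mean 10 frames (per-frame bleaching
survival 0.9), so P(length > 18) = 0.9¹⁸ ≈ 0.15. Steps are Gaussian with
per-axis variance 2DΔt; confinement is enforced by resampling steps that
leave the region. Localization noise adds σ² to each coordinate
independently; for a static emitter the apparent displacement variance is
2σ² per axis, giving a noise floor of `D_app = σ²/Δt` (0.018 µm²/s at
σ = 30 nm, Δt = 50 ms) — this variance bookkeeping is frozen in the tests.

`D_i = msd_i(τ)/4τ` uses lag τ = 1 frame by default (config-exposed). At
lag 1 the overlapping windows are independent increments, so for free
diffusion `D_i | D ~ Gamma(shape = L−1, mean = D)`. The two-component
decomposition is an EM fit of the corresponding two-gamma mixture with
per-track shapes, 20 random restarts with fixed sub-seeds, ties broken by
likelihood then lower D_slow. With localization noise the gamma shape is
approximate (noise anticorrelates consecutive displacements), which is
adequate for fraction recovery — the regime the decomposition is used in.
The mixture's functional form is this package's choice.

First-passage times use Euler–Maruyama walkers absorbed at a disk boundary.
Discrete-time sampling misses continuous-path excursions between frames and
biases the FPT up by O(step SD); the detection radius is shrunk by the
Siegmund constant (0.5826 × step SD) and times shifted by half a step, which
removes the leading-order bias. The config errors out if the step SD exceeds
5% of the starting boundary distance. The disk-center closed form a²/(4D)
(0.98 s for a = 280 nm, D = 0.02 µm²/s) is the cross-check.

## Problem sizes and what the tests show

The segregation/mixing comparison runs in a half-length cell (L = 1.5 µm,
same radius) with particle counts scaled by the volume ratio (3205 rods,
9157 ribosomes), preserving every volume fraction; 1000 production sweeps
after a tuned burn-in give ~12k–22k mobile beads a robust demixed vs mixed
contrast (L_DNA gap ~90 nm, overlap gap ~0.12) while the slow residual
compaction drift is an order of magnitude smaller than the contrasts being
asserted. Full-size runs are available through the CLI. Tracking and
first-passage checks use 10³–10⁵ trajectories/walkers.

The synthetic readouts emulate projection, diffraction blur, sparse
localization and bleaching-limited track lengths. They do not emulate
photophysics (blinking, background, gain noise), drift, cell-to-cell
variability, or any biochemistry (no transertion forces, no drug kinetics,
no small-protein crowders — the model's point is what excluded volume and
entropy alone produce). Passing tests therefore validate the model's
internal physics and the estimator implementations, not quantitative
agreement with any particular experimental cell.

## Known limitations

* The DNA topology (ring fraction, branch statistics) and bead sizes are
  stated conventions; observables that depend on them are reported under
  the documented defaults.
* The serpentine ring initial condition is deterministic up to a seeded
  rotation; equilibration erases it, but very short runs retain memory of
  it.
* Degree-4+ ring beads (two branches at one anchor) move only through
  segment moves, slowing relaxation slightly.
* The gamma-mixture likelihood treats localization noise as a variance
  inflation; component D values for strongly noise-dominated populations
  are effective (apparent) coefficients, not corrected ones.
* `estimate_Di` is 2D/projected by convention; 3D trajectories are
  projected before analysis.
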