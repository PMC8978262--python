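# Methods

## Transport model

`tetradose` solves the radiative transport problem with weighted photon
packets (the MCML-style "hop / drop / spin" scheme) on an unstructured
tetrahedral mesh:

* **Hop.** Packet steps are sampled from the exponential free-path
  distribution, s = −ln(u)/μt with μt = μa + μs.  The dimensionless part
  of a step is preserved across region boundaries, so optical
  heterogeneity is handled exactly.  Between interactions the packet is
  traced tet-to-tet: the exit face is the first of the four face planes
  crossed by the ray, and the face-adjacency table makes each crossing
  O(1).
* **Drop.** At each interaction the packet deposits the fraction μa/μt of
  its current weight in the containing tet and keeps the rest (the
  single-scattering albedo).  Deposition at discrete interaction sites
  (rather than continuous absorption along the path) is the documented
  scheme; the two agree in expectation.
* **Spin.** Scattering angles come from the Henyey–Greenstein inverse
  CDF, cosθ = (1+g² − [(1−g²)/(1−g+2gu)]²)/(2g), with the exact isotropic
  branch used below |g| < 10⁻⁶ to avoid catastrophic cancellation.  The
  deflection is applied in the local frame of the current direction, with
  the z-aligned degenerate frame handled explicitly.
* **Interfaces.** Where the refractive index changes across a face
  (including the mesh boundary against the ambient index, default 1.0), a
  single RNG draw against the unpolarised Fresnel reflectance decides
  between specular reflection and Snell refraction; beyond the critical
  angle the reflectance is 1.  Matched-index faces are crossed without
  consuming randomness, which makes region splits with identical
  materials bitwise invisible to the simulation.
* **Termination.** Packets die by leaving the mesh (their remaining
  weight is scored on the exit boundary face), by full absorption, or by
  Russian roulette once the weight falls below 10⁻⁵: survivors (p = 0.1)
  have their weight divided by p, losers' weight is logged.  Both choices
  follow the common MCML convention; the roulette balance is tracked
  explicitly so termination is unbiased *and* auditable.

**Conservation ledger.** Every run records emitted, absorbed, exited and
net-roulette weight; the residual of the identity
emitted = absorbed + exited + roulette_net is checked on every simulation
and stays below 10⁻⁹ of the emitted energy (sums are accumulated
per-packet and reduced pairwise, so the identity is limited only by
floating-point rounding).

**Reproducibility.** Packet i draws from its own splitmix64 stream keyed
on (seed, packet index), and emission sampling uses a separate seeded
generator, so identical inputs and seed give bitwise-identical results
regardless of batching.  The `threads` field in `SimConfig` is a
forward-compatibility contract (threads = 1 bitwise deterministic;
threads > 1 would promise only statistical equivalence); the present
kernel always traces serially and is JIT-compiled with numba.

## Units

Lengths are mm internally (cm inputs are converted once at read time —
single-unit kernels avoid mixed-unit bugs), optical coefficients mm⁻¹,
powers mW, fluence rates mW/cm² (the mm⁻² → cm⁻² factor of 100 is applied
in the estimators).  Fluence in J/cm² is fluence rate × exposure time;
the engine keeps rate canonical and leaves exposure time to the workflow.

## Fluence estimators

* *Absorption estimator*: Φᵢ = P·Aᵢ/(μa,ᵢ·Vᵢ), with Aᵢ the absorbed
  energy fraction in tet i.  Undefined where μa = 0 (flagged).
* *Track-length estimator*: Φᵢ = P·Lᵢ/Vᵢ from the weighted path length —
  defined everywhere, including transparent regions, and the default for
  dose matrices and detectors.

The two agree within Monte Carlo error on absorbing phantoms (tested),
and the volume integral of Φ·μa reproduces the ledger's absorbed power
exactly for the absorption estimator.

## Geometry and numerical tolerances

* Face-plane intersections closer than 10⁻⁹ mm count as zero distance;
  after each crossing the packet is nudged 10⁻⁷ mm along its direction.
* A crossing through a mesh edge or vertex can seat a packet in a
  diagonal neighbour rather than the face neighbour.  When the traversal
  detects this (no forward face intersection), it relocates the packet by
  walking the adjacency graph to the containing tet and continues; only
  an unrecoverable failure raises a geometry error.  This makes sources
  placed exactly on mesh vertices safe.
* Tets with volume below 10⁻¹² mm³ are rejected as degenerate (they break
  the per-volume estimators).
* Point location uses a nearest-centroid k-d tree start plus an adjacency
  walk, with an exhaustive half-space scan as fallback.

## Phantoms

All test geometries are boxes subdivided into hexahedral cells, each
split into six tetrahedra (Freudenthal/Kuhn decomposition, conforming
across cells).  Features — spheres with optional concentric shells,
cylinders with optional walls, slab stacks — assign region labels by tet
*centroid*.  This emulates the topology of segmented clinical meshes
(tumour/OAR/vessel-wall regions) at desk scale; it does not reproduce
anatomically realistic organ shapes, curved conforming boundaries, or
graded mesh resolution.  Passing tests therefore demonstrate correctness
of the transport/dosimetry/planning machinery, not anatomical fidelity of
any particular clinical case.  Phantom generation is deterministic per
specification.

## Plan optimization

Powers p ≥ 0 for fixed source positions are found from the dose matrix
(one unit-power MC run per source; plan fields compose linearly) by a
hinge-loss linear program:

    minimize   Σ_{i∈OAR} w_r(i) V_i max(φᵢ·p − Tᵢ, 0)
             + w_t Σ_{i∈tumour} V_i max(Tᵢ − φᵢ·p, 0)

solved with HiGHS via slack variables.  Two refinements make the result
well-posed:

* **Two-phase solve.**  Once all hinge losses are zero the LP has a ray
  of equally good plans (more power is not objective-improving); a second
  phase minimises total power subject to the phase-1 optimum, so the
  reported plan is the least-power one (the one-source analytic case
  returns p = T/φ).
* **Coverage escalation.**  The tumour weight w_t starts at 1 and doubles
  until the recomposed field meets the coverage target (default: ≥ 98 %
  of tumour volume at or above threshold, exposed as a hard constraint
  with the achieved value reported), then a geometric bisection finds the
  smallest passing weight — less OAR damage at the same coverage.  An
  unreachable target raises an explicit infeasibility error rather than
  returning a silent best effort.  Elements the optimum places exactly at
  threshold are protected against floating-point round-down by a 10⁻¹²
  relative power bump, far below both solver tolerance (10⁻⁸) and MC
  noise.

Per-region OAR weights default to 1 (volume-weighted); `
pruning_normalization` multiplies all thresholds before solving.
Threshold comparisons use ≥ (boundary sets have measure ≈ 0).  Thresholds
are always user inputs — the workflows gate fluence *rate* by default,
with fluence gating obtained by scaling thresholds by exposure time.

**Surface limits.**  `enforce_surface_limit` rescales all powers by
limit/peak when a designated surface (e.g. the vessel intima, faces
between lumen and wall regions, with face fluence taken as the mean of
the two adjacent tet values) exceeds the cap; the global scale preserves
the relative allocation, and a 10⁻¹² relative shave keeps the recomposed
peak at or below the limit despite round-off.

**Placement annealing.**  Optional simulated annealing perturbs one
source position per iteration (Gaussian jitter, default σ = 2 mesh cells,
clipped to the tumour region), re-runs a reduced-packet dose matrix,
re-optimizes powers, and accepts by Metropolis on the LP objective with
geometric cooling (T₀ from ~20 probe moves unless given, factor 0.95).
The best-seen plan is returned; runs are deterministic per seed.

## Study conditions and problem sizes

* **Tumour plan**: 60 mm box at 15³ cells (20 250 tets), 10 mm sphere
  tumour + 3 mm OAR shell, three point sources on a 5 mm circle inside
  the tumour, homogeneous soft-tissue optics μa = 0.02, μs′ = 2 mm⁻¹,
  n = 1.37, uniform 20 mW/cm² fluence-rate threshold; dose matrices at
  2×10⁵ packets per source.
* **Liver lookup sweep**: 6×12×6 cm box, 2-cm diffuser at 100 mW/cm
  through the centre, μa ∈ [0.0005, 0.0631] mm⁻¹ × μs′ ∈ [6, 11] mm⁻¹
  (11 × 11 = 121 runs), n = 1.37.  Detectors sit 5/8/12 mm off the
  diffuser axis — radii chosen so that desk-scale packet counts
  (2 000/run in the bundled reproduction; `SweepSpec` defaults to 10⁴)
  retain usable signal-to-noise at the highest μeff of the grid.
* **Vessel escalation**: 30 mm block, axial vessel with 2 mm lumen
  (blood-like optics) and 1.5 mm wall (arterial optics), one 1 mm × 10 mm
  cylindrical diffuser in the lumen, 300 mW/cm² intima cap, 10⁵ packets.

Sweeps and study materials use g = 0 with the stated μs′: in the
diffusive regime transport depends on the optical properties only through
(μa, μs′) (similarity relation), and the g = 0 parameterisation makes the
per-packet cost proportional to μs′ rather than μs.  The
Henyey–Greenstein machinery itself is exercised with g up to 0.95 in the
conservation and sampling tests.

## Emission laws

Cylindrical diffusers emit from their lateral surface, by default
cosine-weighted about the outward surface normal (Lambertian surface
behaviour for a radially emitting fibre); a uniform outward-hemisphere
law is available via `emission_law="isotropic"`.  The diffuser interior
is not carved out of the mesh by default — a `vessel_in_box` phantom can
model it as a region when needed.  Surface emitters sample positions
area-weighted over their faces with Lambertian or isotropic-hemisphere
directions into the domain; volume emitters sample tets by volume with
uniform barycentric positions.  Packets are allocated to sources
proportionally to power (stratified, with remainders resolved by the
seeded generator).

## Known limitations

* No polarization, fluorescence re-emission, time-resolved transport, or
  alternative phase functions.
* Photosensitizer concentration and oxygen kinetics are outside the
  threshold dose model used here.
* DVH curves use 1 000 uniform bins and piecewise-constant per-tet dose
  (matching the scoring granularity); no intra-tet interpolation.
* Detector readout is the point fluence of the containing tet, so the
  effective detector aperture is the local tet size.
* Interface (intima) fluence is approximated by the mean of the two
  adjacent tet values rather than a dedicated surface-crossing tally.
* The annealer optimizes positions only; diffuser emission-profile
  manufacturability constraints and multi-plan trade-off presentation are
  out of scope.
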