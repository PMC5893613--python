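# Methods

## Scope and data model

The package reconstructs, for fly vertical-system (VS) cells and structurally
similar neurons, the chain from anatomy to output receptive field:

1. **Morphology** — a rooted tree of 3-D points with radii (canonical
   7-column SWC, '#' comments, radius in μm). The dendritic arbor is
   partitioned into *branchlets*: maximal unbranched sections running from a
   branch point (or the root) to the next branch point or terminal. This
   convention makes branchlet counts ≈ 2 × terminal counts on binary trees,
   consistent with the published per-cell counts for VS cells.
2. **Cable model** — a passive, steady-state compartmental model of the whole
   cell.
3. **Receptive fields** — per-branchlet vector maps on a fixed shared grid of
   visual-field locations, max-normalized.
4. **Integration** — transfer-resistance-weighted averaging with optional
   linear-nonlinear (LN) filtering; difference-index scoring; weight-shuffle
   permutation null.

## Cable model

*Equation.* Only the steady state of the one-dimensional passive cable
equation is solved: `(r_m/r_i) V'' − V = 0`, i.e. the capacitive term is
dropped. The justification is physiological — the membrane time constant of
VS cells (< 2 ms) is short relative to the time course of their synaptic
input — so `CableParams.cm_uf_cm2` is carried but unused.

*Discretization.* Each inter-node frustum is split into compartments no
longer than the resolution (default `min(2 μm, λ_local/50)`, configurable).
Membrane conductance is lateral frustum area / R_m; adjacent compartment
centres couple through the sum of their half-compartment axial resistances
`4 R_i (ℓ/2) / (π d²)`. Branch points and the root are explicit zero-area
junction unknowns, which makes star connections at branch points exact and
gives an exact measurement point at section ends. Per-segment diameter is the
mean of the endpoint diameters (exact for constant-diameter cylinders).
Sealed ends (zero axial flux) everywhere; the system `G V = I` is a
symmetric positive-definite tree Laplacian plus membrane diagonal, factorized
once (sparse LU) and reused across loci, so a pairwise transfer-resistance
matrix costs one solve per locus.

*Accuracy.* Against the closed-form Green's function of a finite sealed
cylinder, `R(X, X0) = R_inf cosh(X_<) cosh(L−X_>) / sinh(L)`, the solver is
within 0.2% at the default resolution; voltages at compartment centres
converge second-order, voltages at the zero-area end junctions first-order in
compartment length (tests use a finer grid when probing the semi-infinite
limit to 0.1%). A 3/2-power (Rall-matched) binary tree agrees with its
equivalent cylinder to ~1e-6.

*Units.* Geometry in μm at the interface, CGS internally (cm, Ω·cm),
resistances reported in MΩ, voltages mV, currents nA. Defaults
`R_m = 2,000 Ω·cm²`, `R_i = 40 Ω·cm` — the passive constants measured for
VS cells and used throughout.

*Axonal measurement point.* The experiments fixed an axonal recording site
without publishing coordinates, so the reference locus is explicit
configuration: `auto` (most distal axon-labelled node, else the root),
`root`, or any `(branchlet, fraction)`. Quantities referenced to the axon
(input resistance, electrotonic means) are sensitive to this choice, which
is why the reconstruction-based comparisons carry a ±10% tolerance.

*Electrotonic distance* is computed on the continuous morphology (not the
discretization) as `Σ seg_len / λ(seg_diameter)` along the unique tree path,
so a cylinder of length λ has electrotonic length exactly 1.

## Receptive-field algebra

Fields are compared location-id by location-id (the experimental grid is
fixed and shared; azimuth/elevation are metadata only — no angular
interpolation). Normalization divides by the largest magnitude, which
encodes the working assumption that maximal responses of different
branchlets are comparable. The difference index operates on the full
LMS-scaled vectors, not unit directions; it is a scaled metric: 0 for
identical fields, ≤ 2 for normalized ones.

The LN filter uses the nearest-rank percentile convention
(`Θ = sorted_magnitudes[ceil(δ/100·n)]`, 1-based): with magnitudes 1..50 and
δ = 98, Θ = 49 and only the strongest vector survives the strict `> Θ` rule.
δ = 0 is the identity. If all magnitudes tie and δ > 0, the ≤-rule removes
every vector; such fully-zeroed branchlets drop out of both numerator and
denominator of the weighted average (keeping it a convex combination of
survivors), and a prediction where *every* branchlet is zeroed is an error.
The predicted field is re-normalized before DI scoring, so the weighting is
scale-invariant.

## Shuffle test

The null reshuffles the weight vector uniformly at random among branchlets
(seeded generator, seed recorded in the report), recomputes the DI per
permutation, and summarizes the null by sample mean and SD (the
moment-matched normal fit); `z = (null_mean − true_di) / null_sd`. Default
1,000 permutations stabilizes mean/SD at the precision reported. Because
which branchlets survive the LN filter does not depend on the weights, the
implementation precomputes the filtered stack and re-weights it per
permutation — verified bit-identical to the naive per-permutation pipeline.
All-equal weights give a zero-spread null; the report flags this and returns
NaN for z rather than guessing.

## Synthetic data

The generators define the conditions under which the pipeline is exercised;
they are pure functions of (spec, seed) and byte-reproducible.

* `make_cylinder`, `make_binary_tree` — analytic fixtures. Branches carry a
  coincident zero-length lead-in node so each branch is a uniform cylinder
  of its own diameter; with Rall 3/2-power tapering the whole tree has a
  closed-form equivalent cylinder.
* `make_vs_like_tree` — a somatic root with two trunks (dorsal/ventral),
  balanced binary branching down to `n_terminals` (default 224), branch
  lengths ~N(10, 3) μm truncated, trunks ~N(80, 10) μm, geometric diameter
  taper 6 → 1 μm. Defaults land near the published VS-cell means: total
  dendritic length ≈ 4,600 μm and ≈ 450 branchlets. The generator does not
  attempt realistic membrane area or length-weighted mean diameter (real VS
  cells carry much thicker, longer primary branches), so only the length and
  branchlet-count scales — and ordering properties like decoupling — should
  be read as VS-like; absolute resistances differ from the real cells.
* `make_branchlet_rfs` — per branchlet: 1–2 dominant vectors with magnitude
  in (0.85, 1], background magnitudes uniform in (0, 0.28], uniform random
  background directions, coherent downward-tilted dominant directions. After
  normalization every field has exactly `n_dominant` vectors > 0.7 and
  > 80% below 0.4 — the published magnitude structure — by construction.
  Dominant locations march monotonically down the elevation axis with
  branchlet order (retinotopy). `noise_sd` is angular jitter (radians), so
  the magnitude contracts survive it exactly.
* `make_ground_truth_axon` — forward model: the noiseless prediction from
  known weights and δ, plus isotropic 2-D Gaussian vector noise, then
  re-normalized.

What passing tests on these data do **not** show: recovery of the published
difference-index values on real measurements (the dendritic/axonal vector
maps are not publicly deposited), calcium-to-voltage transduction effects,
gap-junction coupling between neighbouring VS cells, or active membrane.
The forward-model recovery shows the *method* is sound (z > 2 against the
shuffle null, δ recovered to one grid step under 0.05 vector noise), not
that real dendrites match it.

## Numerical and design choices

* Problem sizes: the test suite and reference computations run on trees of
  32–224 terminals, 13-branchlet field sets, 1,000-permutation nulls and a
  δ grid of 0,2,…,98 — sizes at which every check is deterministic and the
  whole suite completes in seconds.
* Locus resolution snaps a `(branchlet, fraction)` to the nearest
  compartment centre, with the section's end junctions as exact candidates
  at fractions 0/1.
* Point-to-branchlet mapping (for imaged ROIs) is nearest-node in Euclidean
  3-space with ties broken to the smallest node id.
* Sweep ties report the smallest δ; the DI is piecewise constant in δ
  (plateaus between rank changes), so ties are exact, not numerical.
* Whether the published "average diameter" of the reconstructions is
  length-weighted is not documented; the length-weighted choice is asserted
  only on synthetic fixtures and the diameter columns are treated as
  indicative.
* Zero-length segments (coincident nodes) carry no cable and no area; a
  section that is entirely zero-length is refused at model build.

## Known limitations

Steady state only (no transients, no Cm); passive membrane only; single
cells (no gap-junction network); SWC is the only morphology format; no
repair of broken reconstructions; receptive fields are consumed as vector
maps, never estimated from raw recordings.
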