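# Methods

`dimerint` reimplements, as a tested library, the computational layer used in
studies of cholesterol–palmitoyl stabilization of a G-protein-coupled receptor
(GPCR) homodimer — concretely the μ-opioid receptor (OPRM1) TMH4–TMH4
interface: Conformational-Memories helix sampling, kinked-helix geometry
descriptors, residue-level nonbonded interface energetics, and the
sensitized-emission FRET statistics used to quantify dimerization in cells.
No coordinates of the original receptor model are deposited anywhere, so the
package is *method-faithful* rather than *value-faithful* wherever the
original inputs would be required: every algorithm is exercised on synthetic
constructions with known ground truth, plus the one published artifact that
is fully self-contained — the transcribed per-residue interface energy table.

## Interface energy decomposition

The nonbonded interaction energy between two atom groups is

    ΔE_ab = Σ_i Σ_j  k·q_i·q_j / (ε(r_ij)·r_ij)  +  A_ij/r_ij¹² − C_ij/r_ij⁶

with k = 332.0636 kcal·Å/(mol·e²), geometric combining rules
A_ij = √(A_ii·A_jj), C_ij = √(C_ii·C_jj) (the OPLS convention), and, by
default, a distance-dependent dielectric ε(r) = ε₀·r (ε₀ = 1), matching the
force-field setup of the original minimization protocol; a constant-ε mode is
switchable because the dielectric used for the decomposition step itself is
not recorded. Per-residue rows evaluate one interface residue of protomer A
against every residue of protomer B whose minimum interatomic distance is
within 7.0 Å (boundary inclusive — the most permissive common reading of
"within a radius"; both radius and mode are options). Rows are
one-directional (A vs B): by the symmetry of the dimer this already equals
the full protomer–protomer interface energy, and mirror rows would double
count. Cholesterol cross terms (cholesterol A vs protomer B and vice versa)
are added to the grand total; cholesterol–cholesterol and
palmitoyl–palmitoyl pairs are never summed (in the physical model they are
sterically separated by the apposed helices), and palmitoyl–opposite-protomer
terms are computed but reported separately, outside the grand total, because
the published total comprises only the protomer–protomer sum plus the two
cholesterol cross terms.

Numerical conventions worth noting:

- Subtotals are accumulated in full precision and rounded only at rendering
  (2 decimals for energies, 1 for the percentage). A rounded subtotal may
  therefore differ from the sum of the rounded rows by up to 0.02 kcal/mol;
  the renderer appends a note when this happens.
- The packaged reference table is transcribed from a published decomposition
  whose "Total" column was itself rounded from full precision, so a printed
  total can differ from the sum of the printed Coulombic and VDW cells by
  0.01 kcal/mol. Transcribed terms carry the printed total as an explicit
  override; terms computed by this package never do, and for them
  total = coulombic + vdw holds exactly.
- Coincident atoms (r = 0) raise rather than returning ±inf.

The decomposition is a pure function of the input coordinates; no
minimization is performed (the original minimization protocol is provenance,
not part of this package's scope).

## Conformational Memories sampling

CM is a two-phase Monte-Carlo/simulated-annealing exploration of a single
helix's backbone torsions (φ, ψ) and N–Cα–C bond angles. Defaults follow the
published protocol: torsions vary ±10° around their starting values (±50° in
a declared flexible region, e.g. the Pro-kink neighbourhood i−4..i), bond
angles ±8°; each MC step perturbs two torsions and one bond angle chosen at
random; moves are accepted by the Metropolis criterion with
k_B = 0.0019872 kcal/(mol·K). The exploratory phase cools 3000 K → 310 K in
18 stages and the biased phase 749.4 K → 310 K in 7 stages, emitting 105
structures at 310 K.

Choices the protocol leaves open, decided here:

- **Cooling law**: geometric, T_j = T₀·(T_f/T₀)^(j/(K−1)), endpoints
  inclusive — standard for MC/SA, monotone, and hits the stated endpoints
  exactly.
- **Memory representation**: per-variable histograms by temperature stage,
  bin widths 5° (torsions) and 2° (bond angles), i.e. at least 4 bins across
  the narrowest (±10°) window; configurable.
- **What a "memory" records**: the full angle state of each accepted
  conformation, not only the moved variables. This matches the reading that
  accepted *conformations* create the memories, and it guarantees every
  variable has a populated 310 K space whenever any move is accepted there.
- **Biased proposals**: uniform over the occupied 310 K bins, then uniform
  within the chosen bin; the sampler counts proposals and asserts none leave
  the populated space.
- **Objective function**: pluggable. The default (`IntraNonbondedModel`) is
  the same Coulomb + 12-6 pair function as the interface decomposition,
  applied within the helix with 1-2/1-3 pairs excluded and 1-4 pairs scaled
  by 0.5, using generic per-element Lennard-Jones parameters and zero
  charges. It is a smooth steric term that penalizes self-clashes, not a
  calibrated force field: the original study's CM objective (force field,
  solvation) is unrecorded, so ensembles here are method-faithful, not
  value-faithful. Angle-space toy models (flat, harmonic, rugged) are
  provided for statistical tests and skip coordinate rebuilding entirely.
- **Step counts**: "50,000 MC steps applied to each torsion or bond angle
  variation" is implemented as `steps_per_variable` trial steps per
  temperature stage, scaled by a single desk-scale multiplier
  (`CmSchedule.scale`) that preserves the schedule's shape. Library-scale
  runs in the test suite and the acceptance script use multipliers of
  0.001–0.002 (50–100 steps per stage) on 6–20-residue polyalanine helices;
  these sizes exercise every code path and all the statistical properties
  that are checked, while a production run would simply set `scale=1`.

Helix Cartesians are rebuilt deterministically from internal coordinates by
natural-extension-of-reference-frame (NeRF) placement with standard backbone
bond lengths and angles; ω is fixed at 180° and only declared variables
move. The ideal transmembrane helix (φ = −63°, ψ = −41.6°) reproduces the
canonical ~1.5 Å/residue Cα rise.

`select_fitting_conformer` mirrors the original acceptance rule for putting
a sampled helix back into a receptor bundle: first candidate, in input
order, with no interatomic distance below a clash cutoff against the other
helices after Kabsch superposition onto the template position; exhaustion is
reported as an explicit none-found outcome, not an error.

## Kinked-helix descriptors

A kink at hinge residue *i* (with flexible span i−4..i excluded from both
fits) is described by three angles computed from the pre- and post-kink
segment axes (default 7 Cα each):

- **bend** — angle between the two axes;
- **wobble** — azimuth of the post-segment axis about the pre-segment axis,
  zero at the radial direction of the hinge residue's Cα, counterclockwise
  positive looking N→C;
- **face shift** — observed minus extrapolated azimuth of the first
  post-segment Cα: pre-segment Cα phases (≈100°/residue) are unwrapped and
  linearly extrapolated across the hinge, and the observed position is taken
  after rotating the post segment back by the bend about the hinge.

The original analysis names these descriptors without defining them, and its
helix coordinates are not deposited, so the published values (e.g. 35.2°,
−105.8°, 40.3° for TMH2) are not reproducible by construction; the test
surface is internal consistency — synthetic kinks of known bend/wobble are
recovered within 2°/5°, and all three descriptors are invariant under
rigid-body motion and equivariant (bend even, wobble/face-shift odd) under
mirror reflection.

Axis fitting uses the second-difference estimator: for points on an ideal
helix the discrete second difference p(k−1) − 2p(k) + p(k+1) is purely
radial, so the axis is the null-space direction of the stacked second
differences (smallest singular vector). This is exact for ideal helices and
well-behaved on ~2-turn segments, where plain PCA tilts by >10° whenever the
segment covers a non-integer number of turns. The returned axis point is a
least-squares (Kåsa) circle centre in the plane normal to the axis, which
makes the wobble zero-reference exact for ideal geometry.

## FRET and colocalization statistics

Three-cube sensitized-emission FRET with bleed-through coefficients from
single-fluorophore controls (CoA = I_FRET/I_CFP in donor-only cells,
CoB = I_FRET/I_YFP in acceptor-only cells):

    NFRET = (I_FRET − CoA·I_CFP − CoB·I_YFP) / √(I_CFP·I_YFP)

The √(I_CFP·I_YFP) scaling removes the dependence on fluorophore expression
levels, making NFRET invariant under uniform intensity rescaling. The
formula as printed in the source protocol is internally inconsistent (its
left-hand symbol is also defined as the raw FRET-channel intensity, and the
measured FRET term is absent from the numerator); the standard three-cube
form above is the only reading consistent with the CoA/CoB definitions and
with the stated purpose of the square root. The literal printed variant
remains available behind `formula="as_printed"` for audit, clearly marked as
not a FRET estimate.

Summaries report mean ± SD (not SEM) across all ROIs, following the source
protocol's ≥20 membrane ROIs per cell and ≥12 cells per condition; smaller
samples produce a summary flagged with a warning rather than an error.
`pipeline_standard_error` gives the standard error of the mean-NFRET
estimate including the propagated CoA/CoB control uncertainty — a shared
error that shifts every ROI coherently and that the naive sd/√N term
misses; recovery tests use this SE.

Pixel colocalization is 2·N_yellow/(N_red + N_green) over pixels above a
per-channel threshold. The threshold is an input (the source protocol calls
it "pre-defined" without stating it); the counts object enforces
N_yellow ≤ min(N_red, N_green), which bounds the index to [0, 1].

## Synthetic data

The generators are first-class, tested code and define the study conditions
the tests run under:

- `make_kinked_helix` — ideal helix with an exact rigid-body kink of known
  bend/wobble about the hinge Cα (the oracle for the geometry module).
  Noise-free and deterministic; its internal coordinates describe the
  unkinked parent, so its Cartesians are flagged as overridden.
- `make_dimer_fixture` — two parallel toy protomers with declared charges
  (zero / alternating / seeded-random) and uniform Lennard-Jones
  coefficients, optional 3-site uncharged cholesterol proxies in the
  inter-protomer gap, and sequential Ballesteros–Weinstein labels so the
  decomposition can address residues. The cholesterol proxy tests summation
  and exclusion logic, not sterol chemistry.
- `make_fret_rois` — lognormal channel intensities (strictly positive,
  CV 0.30 around 1000 a.u.), FRET channel built as
  CoA·I_CFP + CoB·I_YFP + μ·√(I_CFP·I_YFP) with multiplicative noise
  (CV 0.05), defaults of 12 cells × 20 ROIs plus 50 control ROIs per
  single-fluorophore condition, and bleed-through defaults CoA = 0.30,
  CoB = 0.15 — typical CFP/YFP three-cube magnitudes consistent with the
  protocol's sample-size thresholds and with reported condition means
  μ ∈ {0.07, 0.27, 0.30, 0.49} and SDs of a few hundredths.

What the generators do *not* emulate: real membranes (no spatial
correlation between ROIs, no cell-to-cell heterogeneity beyond sampling
noise, no detector offsets or photobleaching), real sterol conformers, and
real force-field parameters. Passing tests therefore demonstrate that the
arithmetic, selection rules, samplers and estimators are correct, not that
the package reproduces wet-lab numbers — the study's binding, signaling and
cell-imaging values derive from undeposited experimental data and are out of
scope by design.

## Known limitations

- PDB only (no mmCIF); no hydrogen placement or protonation assignment;
  nonbonded parameters must be supplied by the user table.
- The energy model has no bonded terms, cutoff smoothing, periodicity or
  Ewald electrostatics; it is a decomposition tool, not a simulation engine.
- The CM sampler treats one helix at a time; loops and side chains are not
  modeled (side-chain-free backbone representation: N, Cα, C, O).
- Wobble is reported as 0 when the bend is numerically zero (the azimuth of
  a zero-length tilt is undefined); face shift uses the pre-segment phase
  fit and degrades gracefully, not catastrophically, for bends approaching
  90°.
- A palmitoyl may be supplied either as a separate HETATM residue or as
  extra cysteine atoms; only the ligand tag decides how it is treated.
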