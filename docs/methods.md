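# Methods

## Orientation and distance analysis

The binding orientation of the protein is defined by three reference
residues whose designated backbone particles span a plane chosen to lie
roughly parallel to the membrane-binding face (for the PLCγ1 catalytic core:
residues 416, 1011 and 1194).  With n = (p₂−p₁)×(p₃−p₁) and the membrane
normal ẑ,

    θ_uncorrected = arccos(n̂ · ẑ) ∈ [0°, 180°].

The cross-product point order is fixed and the normal is never
absolute-valued; folding θ to [0°, 90°] would make the periodic-boundary
correction meaningless.  The separation is the z component of the
protein–membrane centre-of-mass difference, folded by the box length into
(−Lz/2, Lz/2] (the analysis convention of a protein centred in the box).
Whenever z-dist < 0 — the protein reached the far leaflet through the
periodic z boundary — the frame is corrected as

    θ = 180° − θ_uncorrected,    z-dist = −z-dist.

The corrected pair is exactly invariant under a 180° rotation of the whole
system about an in-plane axis, (x, y, z) → (x, −y, −z), which is the
transformation that carries a top-leaflet-bound configuration into the
equivalent far-leaflet one.  A plain sign flip of z alone is *not* an
invariance of θ: under z → −z the cross-product normal maps
(nx, ny, nz) → (−nx, −ny, nz), leaving θ_uncorrected unchanged while the
separation flips, so the literally mirrored system describes the
enantiomeric protein, not the same protein on the other leaflet.  The
property tests therefore use the rotation.

Degenerate geometry (collinear reference points, |n| < 1e-9 nm²) raises an
error rather than returning an arbitrary angle.

**Bound-state selection.**  A replicate counts as bound in the preferred
orientation iff its final-frame corrected θ lies in the closed window
[6°, 12°] and its final-frame z-dist is strictly below 4.5 nm — closed
window, strict inequality, matching the stated criteria.  "Final frame" is
read literally; a trailing-window mean is available as an option
(`BoundSelection(endpoint="window_mean")`) for noisy series.

**Density of states.**  The (z-dist, θ) histogram defaults to 0.1 nm × 2°
bins (no bin width is prescribed by the source analysis; 2° resolves the
6°–12° selection window with three bins).  Counts are conserved: frames
outside user-supplied edges land in a reported overflow count, never
silently vanish.  Reported density is normalised over the binned counts.

**z-density profiles.**  Number densities (particles·nm⁻³), not mass
densities: coarse-grained bead masses are near-uniform and the profile is
read as a distribution, not calibrated mass.  Per frame, group z coordinates
are taken relative to that frame's membrane centre of mass (all lipid
particles including cholesterol — "the bilayer" with no exclusions),
minimum-imaged, histogrammed over bins symmetric about z = 0, averaged over
the frames of the final 500 ns window of each qualifying replicate
(per-replicate windows), then symmetrised, ρ_sym(z) = (ρ(z) + ρ(−z))/2.
Symmetrisation is exact bin-by-bin because the bin edges are mirror pairs.
The profile integral times bin volume recovers each group's particle count.
Zero qualifying replicates yield an explicit empty-result profile.

## Contact fingerprints

Contacts are counted at molecule level with a closed 0.55 nm cutoff: a lipid
molecule contributes at most one contact to a (residue, lipid group) cell
per frame if *any* particle of its tested subset lies within the cutoff of
*any* particle of the residue.  Tested subsets are the per-type phospholipid
headgroups and the whole cholesterol molecule; the protein side is every
particle of the residue.  Distances use the minimum-image convention in all
three box dimensions; the neighbour search is a periodic cKDTree whose
output is re-checked on squared distances, so the closed-boundary convention
is bit-identical to the brute-force all-pairs oracle the tests compare
against.  Totals accumulate over frames of the final 1000 ns (the full
trajectory, flagged in metadata, when the run is shorter).

Normalisation divides each residue's total by the maximum total within its
lipid group, so the top residue scores exactly 1; groups with no contacts at
all come out zero and flagged.  Hotspots are residues strictly above the
0.8 threshold for the PIP2 (POP2) headgroup group, per the printed "above
0.8" wording.  Pooling happens before normalisation (totals summed over all
replicates, then normalised); a per-replicate mode is available.

**Convergence.**  For each subset size k ≤ ⌊n/2⌋, pairs of disjoint
k-replicate subsets are drawn, each subset's pooled totals are normalised,
and the Pearson correlation between the paired profiles is recorded
(mean ± sd over draws, seeded).  Pearson correlation is an explicit design
choice; the reference analysis names no metric.

## Model preparation

Formal charges use the standard coarse-grained side-chain convention at
pH 7: Lys/Arg +1, Asp/Glu −1, His neutral, neutral termini for internal
excisions.  Under this convention the two excised linker loops
(471–488 "AYEEVPTSVMYSENDISN", net −4; 934–947 "DARLTEGKMMERRK", net +2)
carry −2 net, so two counter-cations leave with them — reproducing the known
ion bookkeeping is the consistency check on the convention.  Sequences are
verified against the topology before excision, with the first mismatching
position named.  Net-positive excisions warn and remove zero cations (anion
bookkeeping is out of scope).

Variant presets: core P = alanine at {41, 42, 45}; core E adds
{166, 175, 195, 204, 990}.  Substitution keeps the backbone representation
(plus CB for atomistic residues) and renames the residue; no side-chain
remodelling is attempted.

The four active-site restraints (PIP2 P1–His380:NE2, P1–His335:NE2,
P4–Lys462:NZ, O3–Arg988:CZ) are emitted in that order with user-supplied
target distances; the shipped 0.35 nm default is a documented placeholder,
not a reference value, because the reference distances are not available in
the source text.

## The synthetic generator

The generator produces trajectories with the statistical structure the
analysis assumes — free 3D diffusion, stable one-leaflet association, an
emergent preferred orientation, lateral lipid diffusion, planted local
enrichment — with no force-field realism: no solvent, no thermostat, no
inter-lipid forces, energies in units of kT.

*Membrane.*  Two mirrored leaflets of a flat bilayer (half-thickness
2.0 nm), lipids on a lateral grid at 0.40 nm² per lipid, types apportioned
by largest remainder from the mole fractions (ties broken in the fixed
order POPE, CHOL, POPS, POPC, POP2, POP3) and assigned to sites by a seeded
permutation.  Phospholipids are one headgroup bead at the surface plus two
tail beads inward; the phosphoinositides carry a laterally extended
four-bead headgroup (the inositol-phosphate group is much bulkier than a
PE/PC/PS headgroup, and the lateral spread also smooths the discreteness of
contact counts on the site lattice); cholesterol is a single mid-leaflet
bead.  Lipid molecules perform lateral Brownian motion
(D = 5×10⁻⁵ nm²/ns — deliberately slow so that planted local composition
persists over a run; real lipids at ~5×10⁻³ nm²/ns would homogenise it) with
periodic wrapping.

*Protein.*  A rigid body with one bead per residue: a flat circular binding
patch (centre + ring of 5 + ring of 6, radii 2.2/3.6 nm) on the underside
of an ellipsoid (semi-axes 3.8, 3.8, 1.5 nm), upper-surface beads, and
three reference residues forming a horizontal triangle ordered so the plane
normal is body +z (each with a separate designated backbone bead, offset
uniformly along body +z so the plane is unchanged).  The planted bound
orientation θ* is found by brute-force grid search over ~4000 directions on
the sphere (rest the body on its lowest bead, minimise the mean patch
height); for the default geometry θ* ≈ 1.3° (grid resolution ≈ 2°).

*Dynamics.*  Overdamped Langevin steps (dt = 0.05 ns) for translation
(D_t = 0.05 nm²/ns) and rotation (D_r = 0.05 rad²/ns), free while docking.
Patch beads feel a Gaussian well toward the nearer leaflet surface (depth
6 kT per bead, width σ = 0.7 nm); all beads feel a soft harmonic wall
inside the bilayer slab (50 kT/nm²) — the wall is excluded-volume geometry
and remains in the ε = 0 control, which is therefore the pure-diffusion
limit.  Once the patch is seated (mean |Δz| < σ) the replicate latches and
membrane drag applies: translational mobility ×0.001, rotational ×0.0004
(lipid-like bound diffusion; the weaker rotational drag also keeps planted
residues from arcing far off their enrichment discs).  With ~11 engaged
beads the total well depth ≈ 60 kT, so unbinding never occurs on these
time scales; a per-step displacement above half the box raises a stability
error advising a smaller dt.

*Enrichment.*  At the moment of first stable binding, lateral lipid sites
are swapped — type assignment in space, never biased forces — so that the
local mole fraction of each planted lipid type within its disc
(radius 1.35 nm, γ = 13, capped at 0.9) reaches min(γ·f_global, 0.9).
Allocation is round-robin, one swap per site per pass, so the finite donor
pool (POP2 is only 7% of the leaflet) is shared evenly between sites rather
than exhausted by whichever site is planted first; takers are filled
nearest-first so the contact-reach core of every disc is enriched with
certainty.  Swapping conserves the composition exactly, and the slow lipid
diffusion preserves the enrichment over the bound window while still
averaging over lattice alignment.

*Reference conditions.*  Eight replicates of 1200 ns in a
20 × 20 × 26 nm box (the analysed systems used 21 × 21 × 26 nm) with 1000
lipids per leaflet of the standard composition and five planted POP2 sites
on the inner patch ring.  Under these conditions all replicates bind
(typically 8/8; the selection machinery is exercised by the ε = 0 control
and by short runs where some replicates stay unbound), the circular mean of
the final orientation sits within ~2° of θ*, and hotspot calling at 0.8
recovers the five planted residues with no spurious extras at the tested
seeds (occasionally one planted residue lands just below 0.8 at an
untested seed — the max-normalised statistic over eight replicates retains
~5% relative noise).

*What the generator does not emulate* — and hence what passing tests do not
show about real data: force-field energetics and specific lipid–protein
chemistry, membrane undulations and thickness fluctuations, protein
flexibility (the body is rigid; real elastic-network proteins fluctuate),
lipid flip-flop, realistic lipid mixing rates, crowding and solvent
effects.  Recovery tests validate the *analysis machinery* against a known
ground truth, not the biology.

## Numerical choices

* Internal units are nm and ns everywhere; Å/ps dialects are converted on
  load (so the contact cutoff is stored as 0.55 nm).
* Closed cutoffs and closed θ windows; strict z-dist and hotspot
  thresholds — all matching the printed inequality forms, and all compared
  on exact or squared-distance arithmetic so boundary cases are
  well-defined.
* Residue numbering is 1-based canonical PLCγ1 numbering; the two-segment
  core keeps its gap (489–933 absent) through every operation.
* Side-chain particles are all particles of a residue except its designated
  backbone particle (coarse-grained), or all atoms except N/CA/C/O
  (atomistic).
* All randomness flows from a single seed through
  `numpy.random.SeedSequence` spawning; trajectories are bitwise
  reproducible for a given seed, and pipeline outputs carry a configuration
  hash that changes with any analysis parameter.

## Known limitations

* The generator's membrane is geometric: lipids never leave their leaflet
  or their z template, so z-profiles of lipid groups are sums of sharp
  bands rather than smooth distributions.
* Loaded trajectories are assumed orthorhombic; triclinic boxes are not
  supported.
* DCD files carry no usable time information; frames are assigned 1-ns
  spaced synthetic times on load.
* Restraint serialisation uses the package's own plain-text table; export
  to specific MD engine dialects is left to the user.
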