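# Methods

This note documents the models, conventions and numerical choices behind
`solvshell`, and what its validation does and does not demonstrate.

## Units and conventions

Lengths in Å, times in ps, angles in degrees, wavenumbers in cm⁻¹, energies
in kJ/mol, surface areas in nm², masses in amu. Atom indexing is 0-based
internally. All histograms use half-open bins `[lo, hi)`; consequently a
ligand sitting exactly on a shell boundary belongs to the shell whose lower
edge that boundary is (the outer one). The minimum-image convention maps each
displacement component into `[−L/2, +L/2)`, with the tie at exactly +L/2
resolved deterministically to the negative image. Only cubic periodic boxes
are supported; trajectories may be wrapped or unwrapped (pair statistics
minimum-image everything, and `wrap_coordinates` is available on demand).

## Pair statistics

`compute_rdf` histograms center–target minimum-image distances per frame and
normalizes by ideal-gas shell counts at ρ = N_target/V (periodic) or a
user-supplied ρ (non-periodic; there is no meaningful V). The cumulative
coordination number is accumulated from the same raw pair counts rather than
by quadrature of the binned g(r), so `integrate_coordination` is exact for
counting questions: a snapshot with exactly two first-shell waters integrates
to exactly 2.0 at any cutoff between the occupied bin and the next occupied
one. Self-pairs are excluded, which reproduces the (n−1)/n finite-size factor
of the ideal gas.

Default bins are dr = 0.05 Å and 2° (angular): fine enough to resolve
first-shell peak widths of ~0.5 Å and angle peaks of ~10° without starving
the per-bin statistics at desk-scale trajectory lengths.

### Shell boundaries

No standard exists for turning g(r) into shell limits; published values
depend on the (usually unstated) smoothing. The rule here: smooth g with a
5-bin moving average, locate maxima, and take boundaries at minima between
successive maxima. A boundary lying on a contiguous run of g = 0 is placed at
the run's midpoint and flagged *zero minimum* — the diagnostic for a
non-exchanging shell — otherwise the smoothed minimum is used and flagged
nonzero. Two guards make the rule robust on sparse synthetic data: zero runs
are scanned only after the first *occupied* bin of the first peak (smoothing
widens a one-bin spike into a plateau whose left edge sits on empty bins),
and a nonzero minimum counts only when some preceding peak exceeds twice its
depth, so statistical ripple on a flat ideal-gas profile yields "no shell
structure" rather than noise boundaries. Boundary positions therefore carry
an uncertainty of order the smoothing window (±0.1–0.25 Å); occupancy and
exchange counting are insensitive to this when the inter-shell region is
empty or sparse.

## Geometry statistics

ADF registers, per frame and center, the angle at the center for every
unordered pair of ligands within the cutoff; the histogram is normalized over
registered angles, and raw counts are kept so combinatorial fingerprints
(octahedron 12:3 at 90°/180° over 15 pairs; square pyramid 8:2 over 10) can
be asserted exactly. CND counts targets strictly inside the cutoff per frame,
which makes the distribution mean identical (to round-off) to the cumulative
RDF integral at the same cutoff — the same counting through two routes. The
N···H_w hydrogen-bond criterion is a pure distance cutoff (default 2.5 Å,
no angular term): each water hydrogen counts once if it is within the cutoff
of any ring nitrogen.

## Aligned-frame densities

Alignment is a standard Kabsch SVD superposition (proper rotations only, with
the determinant correction) onto a reference frame over the ring heavy atoms.
The porphyrin plane is the least-squares plane of the four ring nitrogens
only — the nitrogens define the coordination plane; including the carbons
would mix ruffling modes into it. The normal's sign is carried from frame to
frame (first frame: +z) so near-planar wobbling cannot flip θ ↔ 180°−θ.

The ARD histogram is normalized per azimuthally integrated volume element
(2π/3)(r_hi³−r_lo³)(cos θ_lo−cos θ_hi), which is exact in the polar bins
where a naive 2πr² sin θ dr dθ weight diverges. First-shell subtraction
zeroes every radial bin overlapping [0, r_limit) — a radius-band reading;
identity-tracked removal of specific coordinated molecules is deliberately
not implemented, and the operation says so in its docstring.

## Exchange dynamics (direct method)

Shell occupancy is the per-frame shell index of each ligand's minimum-image
distance to the center. A *departure* is a transition out of the probed shell
whose subsequent absence lasts strictly longer than t\*; run-length encoding
guarantees a single continuous absence is one event no matter how it rattles
between frames, and a run truncated by the end of the trajectory counts once
its observed length already exceeds t\*. Entries are counted symmetrically
and reported separately. Persistence is measured in sampled frames: more than
⌊t\*/dt⌋ consecutive frames outside.

The mean residence time is τ = CN · t_sim / N_ex with CN the *mean* occupancy
of the probed shell over the analyzed window (not the modal integer), and
N_ex = 0 returns a "no exchange observed (τ > t_sim)" sentinel rather than a
number. R_ex = N_ex^0.0/N_ex^0.5; both R_ex and its reciprocal (the
sustainability coefficient) are reported, since either convention appears in
the literature.

## Synthetic generators

The generators define the validation conditions; their defaults mirror the
reference hydrated-porphyrin setting: metal–N distance 2.0 Å, first shell
1.93–2.67 Å (axial waters nominally at 2.2 Å), second shell 3.27–5.03 Å,
bulk water at 2000 molecules in a 39.28 Å cubic box (ρ = 0.033 Å⁻³),
T = 298.15 K. Water geometry is rigid (O–H 0.957 Å, H–O–H 104.5°) with
orientation either uniform or "away" — hydrogens pointing away from the
metal, emulating the metal's preference for the oxygen lone pairs. A 2.4 Å
minimum O–O separation prevents unphysical overlaps from distorting pair
statistics.

**Exchange.** Ground truth is generated in shell-index space and only then
embedded in 3D, so the true event log is exact by construction and
independent of the geometry code under test. The jump process is simulated on
the frame grid — each stored frame the ligand moves to an adjacent shell with
probability 1−exp(−k·dt) (edge shells have one neighbour, keeping the total
transition rate k everywhere) — so crossing times and dwells are exact
multiples of dt and the frame-sampled occupancy series reproduces the log
*exactly*; a continuous-time process would hide sub-frame events from any
frame-based counter. At the dt used (dt ≪ 1/k) the dt-discretised dwell
distribution is statistically indistinguishable from the exponential with
mean 1/k (KS test at α = 0.01 in the suite).

**Oscillators.** Harmonic modes are evaluated analytically at every frame
(phase-space rotation; no integrator error), with thermal initial conditions
or a pinned amplitude. A guard rejects dt ≥ 1/(10·c·ν̃).

**Rigid body / jitter.** Random proper rotations and translations per frame;
optional isotropic Gaussian jitter of known σ turns the rigid null model into
a fluctuation model with closed-form RMSF σ√3·√((n−1)/n).

What the generators do *not* emulate: liquid water–water structure (no
g_OO(r)), force-field dynamics, polarization, or any electronic structure.
Passing parameter-recovery tests therefore demonstrates the correctness of
the *analysis* algorithms under controlled statistics, not the physics of any
particular simulation.

## Vibrational analysis

C(t) is averaged over evenly spaced origins and the selected atoms
(hydrogens excluded by default, the convention for trajectories with
constrained H), normalized to C(0) = 1. Velocities absent from the input are
derived by central differences with minimum-image frame-to-frame
displacements (no box-length spikes at boundary crossings); the finite
difference attenuates a mode at ω by sinc(ω dt) — under 1% for dt ≤ T/40.

The spectrum is the real part of the one-sided transform of the tapered C(t)
(default Hann; none/Blackman selectable — the appropriate window is a user
choice, not a physical one), clipped at zero and plotted against ν̃ = f/c.
Zero padding (×4) refines peak *positions* only; the reported resolution is
the honest 1/(2·c·T_corr) from the correlation length, ~8.3 cm⁻¹ at 2.0 ps.
Mass weighting is off by default and available by selection of equal-mass
subsets (the unweighted sum is the printed convention for heavy-atom solute
spectra).

## Energetics and flexibility

**PMF.** w(r) = −RT ln g(r) with R = 8.314 J·K⁻¹·mol⁻¹; bins with g = 0 are
masked (NaN), not ±∞ — at finite sampling they mean "unvisited", not
"infinitely repulsive". Depths are relative to the w = 0 bulk reference
(g → 1), so negative wells read directly as binding free energies of the
corresponding shell.

**SASA.** Shrake–Rupley with a golden-spiral point lattice (deterministic;
960 points, probe 1.4 Å, Bondi radii with 2.0 Å for Co, which Bondi does not
tabulate). Decomposition assigns C and ring H to the hydrophobic class and
metal, N, O (and water H) to the hydrophilic class; the class map is
configurable since conventions differ. Two numerical notes: (i) a sample
point exactly on a neighbour's surface (degenerate contact, e.g. coincident
spheres) is kept by the lower-index atom only, so shared surface is counted
once; (ii) the sample lattice is fixed in the lab frame, leaving an
O(1/√n_points) orientation dependence — about 1% of the total at 960 points —
which bounds the rigid-motion invariance one can assert. Absolute totals
depend on the radius set and on whether axial waters are counted as solute;
both are configurable, and comparisons across programs should expect
systematic offsets.

**RMSF.** Computed after Kabsch alignment over ring heavy atoms; the default
selection is the heavy ring atoms with the metal excluded. Alignment absorbs
six rigid degrees of freedom, deflating the recovered σ√3 by roughly
√(1−6/(3N)) — ~3% for the 33-heavy-atom macrocycle — which is inside the 5%
recovery tolerance used.

**Torsions.** Signed dihedrals use the standard atan2 (Praxeolitic/IUPAC)
formulation on (−180°, 180°], with an exact −180° folded to +180°.
The macrocycle set is one proper N–N–N–N quadruple (nitrogens in azimuthal
order) and four improper metal–Cα–Cα–N quadruples, one per pyrrole; the
averaged histogram carries a circular 5-bin running average (the ±180° seam
wraps).

## Pipeline

`run_full_analysis` executes rdf → shells → adf/cnd → align → sdf/ard →
occupancy/mrt → vacf/spectrum → pmf/sasa/rmsf/torsions, logging every
parameter actually used at INFO. Config files are strict: unknown keys are
errors. If the requested number of shells cannot be found the stage retries
with fewer, and a profile with no significant structure at all flags
"no shell structure detected" and skips the occupancy analyses instead of
failing. The report contains no timestamps; with a fixed config and seed a
rerun is byte-identical.

## Problem sizes in the validation battery

The test and acceptance runs use desk-scale sizes chosen so each statistical
assertion has comfortable power: 100-atom frames for bit-exact pair-count
equivalence; 2000 points × 100 frames (200 centers) for ideal-gas
normalization; 20 ligands × 200 ps at k = 0.5/ps (~1000 events) for
direct-method recovery within 10%; 5000 origins × 2.0 ps for oscillator
spectra (the oscillator is sampled at dt = T/40, making the origin average
over whole half-periods cancel the cross term exactly, so C(t) matches
cos(2πcν̃t) to round-off); 2000 frames for σ√3 RMSF recovery within 5%.

## Known limitations

- Cubic boxes only; no triclinic cells, no binary trajectory formats.
- ARD subtraction is radius-band, not molecule-identity based.
- SASA totals are radius-set dependent (see above); no analytic surface.
- The survival-function (correlation-decay) residence time is not
  implemented — only the direct method.
- Synthetic water carries no realistic solvent–solvent structure, so
  water–water observables (e.g. O_w–O_w RDFs) are out of scope for the
  generators.
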