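# Methods

`kinodyn` implements three methodological arms that together probe how a
regulatory domain docked on a kinase catalytic domain reshapes its
dynamics: (1) elastic-network normal-mode analysis with residue-level
allosteric coupling maps, (2) essential-dynamics analytics for
trajectories, and (3) a dual-basin structure-based coarse-grained model
sampled with parallel-tempering metadynamics, from which open↔closed
free-energy surfaces and barriers are computed. This note records the
models, their assumptions, the defaults and why, and what the synthetic
study systems do and do not establish.

## Elastic network and allosteric coupling

The anisotropic network model places a Hookean spring of uniform
stiffness γ between every Cα pair within a cutoff R_c. Defaults are
R_c = 10 Å and γ = 1 (energy/Å²): standard Cα-network practice, where
mode shapes are insensitive to R_c in the 8–13 Å range and γ only sets
the overall scale (all flexibility profiles are reported up to a global
constant). Both are config-exposed. A connected 3-D network has exactly
six zero modes; collinear toy geometries have five. The zero-mode
threshold is relative (λ < 1e-8·λ_max), which is scale-free.

Allosteric coupling between residues i and j is the normalised
mode-restricted covariance

    C(i,j) = Σ_k u_k(i)·u_k(j)/λ_k,
    A(i,j) = |C(i,j)| / sqrt(C(i,i)·C(j,j)),

summed over residue 3-vector blocks of the softest non-rigid modes.
The default range is the 20 softest modes: the 1/λ weighting makes the
measure low-frequency dominated, and restricting to the soft end keeps
it focused on collective (rather than local vibrational) communication.
Over the full spectrum C equals the block structure of the Hessian
pseudo-inverse, which the tests verify against an independent
pseudo-inverse computation. Coupling of a residue *to a region* (e.g. a
docked SH2-like domain) is the mean of A over region members;
max-aggregation is available as an option. The exact historical
weighting conventions for such maps vary between implementations; the
block-covariance form used here is documented rather than claimed to
reproduce any particular published map pixel-for-pixel, and the mode
range is the sensitivity knob to vary.

## Trajectory analytics

Superposition uses the SVD (Kabsch) solution with the determinant
correction. RMSF/PCA discard an equilibration prefix (default 25% of
frames, matching the common practice of dropping the first quarter of a
production run) and operate on the remaining window. PCA is computed
via SVD of the centred coordinate matrix (numerically kinder than
forming the covariance). Cross-construct projection first maps common
residues by exact (chain, number, insertion-code) identity — no
alignment heuristics — and refits each frame onto the PCA mean over the
mapped atoms, so rigid-body drift cannot leak into the essential
coordinates; projecting a model's own source trajectory reproduces the
eigenvalues exactly and is tested to 1e-6.

Conformational clustering is the neighbour-counting leader algorithm on
the pairwise RMSD matrix of the already-superposed trajectory (no
per-pair refitting), with deterministic lowest-index tie-breaking and a
2 Å default cutoff. Atom-pair distance series (e.g. an αC-helix salt
bridge, or an inter-lobe Cα–Cα "hinge" distance) resolve selectors to
exactly one atom and refuse ambiguity; a side-chain selector on a
Cα-only trajectory is an error, never a silent substitution. Reported
means/SDs cover a declared tail window (default: final 75%).

## Coarse-grained force field

Single-basin topologies are Gō models: harmonic bonds E = K_b(Δr)² and
angles E = K_a(Δθ)², the 1+3 cosine dihedral, 12-10 native contacts
ε[5(r0/r)¹² − 6(r0/r)¹⁰], and excluded volume for non-native pairs.
Defaults K_b = 100, K_a = 20, K_d1 = 1, K_d3 = 0.5, ε = 1 kcal/mol,
contact cutoff 8 Å with sequence separation ≥ 3, σ = 4 Å: conventional
Cα Gō scales in which the folded state is stable at ~300 K and bonded
terms are far stiffer than contacts. The excluded-volume core is the
(σ/r)¹² repulsion smoothly truncated to zero value *and slope* at
r = σ (a WCA-style cap); an untruncated tail would exert small residual
forces at the native coordinates and no reference structure would be an
exact stationary point of its own model. Bonds/angles/dihedrals are only
built within a chain, so a separate-chain domain couples purely through
contacts and excluded volume.

The dual-basin ("hybrid") variant takes a closed and an open reference
sharing residue numbering. Contacts in both maps are kept once (r0 from
closed); contacts exclusive to one reference that involve the declared
switch region carry their own r0 and a mixing weight on ε (default 1.0,
symmetric basins); exclusive contacts *not* involving the switch region
are treated as shared peripheral differences. Dihedrals with any bead
in the switch region are softened (K halved) so the backbone can
actually flip; with identical references nothing is softened and the
hybrid reduces exactly to the single-basin model. Shared contacts must
have one well-defined native distance — the synthetic generators are
constructed so that no pair is within the cutoff in both references at
different distances, and the same property should be checked for any
real structure pair.

## Sampling

The integrator is BAOAB Langevin splitting; for a harmonic potential its
configurational sampling error is O(dt²) and the harmonic-variance test
holds to 2% at the defaults. Timesteps are validated against the
stiffest bond (dt·ω ≤ 0.7). Bead mass is 1 and time is in internal
units: the coarse-grained kinetics are not calibrated, only sampled
ensembles matter. One root seed drives per-replica
`numpy.random.Generator` child streams, making every run bitwise
reproducible.

Collective variables are contact-map distances with the rational
switching function (n = 6, m = 10, γ_s = 1.2 — common contact-map
conventions; the removable singularity at r = γ_s·r0 is handled by its
analytic limit). Metadynamics deposits Gaussians on (D_closed, D_open);
well-tempered scaling is available but off by default. Parallel
tempering swaps configurations between neighbouring replicas with the
bias-aware Metropolis criterion and rescales velocities by
sqrt(T_j/T_i). Optional half-harmonic upper walls on the CVs confine
sampling to the transition-relevant part of contact-map space; without
them the walker spends most of the bias budget exploring the vast
fully-unfolded region. Walls are placed relative to the *opposite*
reference's CV value (default: +4 CV units), never inside a basin.

The free-energy estimate is the negative accumulated bias (rescaled by
γ/(γ−1) if well-tempered), evaluated on a grid and averaged over
snapshots spanning the final 40% of hill deposition to suppress the
O(hill-height) oscillation of the instantaneous estimator. Cells never
within 3 hill-widths of any hill are flagged unvisited and excluded from
basin and barrier analysis — no extrapolation. Basins are local minima
of the visited region (plateau-merged within a 2-cell radius), labelled
by proximity to the known reference points in CV space; the barrier is
the flood-fill (minimax-path) saddle, verified in tests against an
exhaustive path-enumeration oracle. ΔG values use minimum-depth basin
free energies ("deepest minimum" convention); catchment-integrated
−kT·ln Σ exp(−F/kT) values are reported alongside because the choice is
genuinely ambiguous in how such numbers are usually quoted.

## Synthetic study systems

The generators are pure functions of (parameters, seed) and define the
study conditions the tests and the reproduction script run under.

**Two-lobe hinge toy.** A small mobile lobe and a ~1.7× heavier anchor
lobe, both flattened along z, joined by a neck that is wide in y and
two-layered in z. The geometry is chosen so the softest internal mode is
the out-of-plane "book-fold" opening of the mobile lobe (overlap with
the constructed hinge displacement ≳ 0.9, required > 0.6): the neck
width suppresses twist and in-plane scissor, the neck's thin double
layer suppresses local flapping, and the mass asymmetry keeps the
anchor-side neck — the exposed `hinge` fulcrum — quieter than the mobile
lobe's tips. An optional rigid clamp chain bridging the lobes on one
face is the regulatory-domain stand-in; it suppresses the hinge-mode
amplitude of the contacted lobes several-fold. A genuinely symmetric
dumbbell was rejected during design: after rigid-body projection, the
symmetric closing fold necessarily carries a net-translation
compensation that makes the crease move *more* than the tips, which is
not what kinase hinge modes look like.

**Planted-covariance trajectories.** Frames = base + Σ a_k(t)·mode_k
with independent Gaussian amplitudes of chosen variances, optional
isotropic noise, optional random rigid-body motion per frame. At 5000
frames the sampling error of a variance is ~2% (χ² with n−1 dof), so
the 5% recovery tolerance leaves honest headroom.

**Analytic double well.** F(x) = h((x/a)²−1)², default h = 5 kcal/mol:
minima at ±a, barrier h at 0 — the metadynamics oracle. With 0.1
kcal/mol hills every 100 steps for 4·10⁵ steps at 300 K the
reconstruction RMSE over |x| ≤ 1.25a is well under 0.5 kcal/mol.

**Two-state chain.** A hairpin sheet of two strands per layer, two
layers at z = ±2.3 Å (the top layer an exact mirror copy of the
bottom), a mid-plane stalk, and a mobile segment (two descender beads
plus four docked beads) that lies under the bottom sheet in the closed
state and, mirrored through z = 0, over the top sheet in the open
state. Because the docking sites are congruent, the closed-only and
open-only contact sets are equal in size and native-distance multiset
(18 each at the defaults), every bond and angle is state-symmetric, and
the docked run lies in a constant-y plane so its dihedrals are 0/π and
mirror-symmetric. The single irreducible asymmetry is the dihedral
window crossing the scaffold plane; with the toy-chain dihedral
constants (K_d1 = 0.3, K_d3 = 0.15, chosen to keep this residual below
~0.5 kcal/mol while leaving the docked state stiff enough) the relaxed
open-minus-closed energy difference is +0.45 kcal/mol. That bound, plus
~1–1.5 kcal/mol of sampling noise in the basin estimates, is why the
"symmetric basins" acceptance bound is 2.5 kcal/mol per seed.

The clamped variant adds a rigid 5-bead chain docked over the *open*
face in both references: its scaffold anchors are shared contacts, its
contacts to the mobile segment exist only in the open reference (11 at
the defaults, ~−5 kcal/mol of open-basin stabilisation after
relaxation) — a regulatory domain whose interface is native to the
active-like arrangement. The directional expectations are that the
clamp shifts ΔG_O-C toward the open state and lowers the closed→open
activation barrier; both are tested as sign effects over three seeds
(≥ 2 of 3), because at desk scale the barrier change (≈ −1 kcal/mol) is
comparable to the seed-to-seed spread.

**Free-energy study conditions.** ε = 0.8 kcal/mol (exclusive-contact
docking energy ≈ 14 kcal/mol, the scale of activation-loop barriers in
kinases), replica pair 250/340 K, dt = 0.02, friction 1.0, plain (not
well-tempered) hills of 0.5 kcal/mol and width 0.5 every 200 steps,
exchange every 500 steps, CV walls at the cross-reference value + 4,
4·10⁵ steps per run, 64² grid, tail-averaged estimator. 250 K (≈ 0.5
kcal/mol per k_BT) keeps the docked states cooperative: at 300 K the
short tail frays and the basins blur. Problem sizes (≈ 40 beads, ≈ 10⁶
total force evaluations per paired comparison) are the package's chosen
desk scale; the same pipeline runs unchanged on larger inputs.

## What the synthetic tests do not show

The toys validate the *machinery*: eigen-solvers against dense oracles,
estimators against planted parameters, thermostats and exchange against
closed forms, free-energy reconstruction against an analytic potential,
and the directional response of a dual-basin system to a stabilising
partner domain. They do not demonstrate that any particular real kinase
shows these effects at particular magnitudes: real activation-loop
transitions involve side-chain packing, electrostatics and solvent that
a Cα Gō model represents only through its native-contact topology, and
published free-energy values for such transitions come from much longer
sampling with system-specific force-field calibration. Quantitative
agreement with any experimental or all-atom number should be read as
out of scope for the synthetic study systems.

## Known limitations

* The dual-basin recipe keeps shared contacts at the closed reference's
  r0; structure pairs whose "shared" contacts differ substantially in
  distance need a per-basin treatment the package does not implement.
* The negative-bias estimator (even tail-averaged) carries
  O(hill-height) roughness; basin *shapes* are less reliable than basin
  depths and saddle levels.
* Replicas run interleaved in one process; the exchange contract is
  exact but there is no true parallel execution.
* The contact-map CV's rational switching decays slowly (as r⁻⁴ for
  n = 6, m = 10), so detached intermediates can score partial credit on
  both maps; the basin labelling therefore uses explicit reference
  points rather than axis minima.
* Checkpoint/resume of a metadynamics run is limited to what the hills
  and CV series files provide; there is no mid-run binary snapshot.
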