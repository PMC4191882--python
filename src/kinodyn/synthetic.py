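"""Synthetic fixtures with known ground truth.

Every generator is a pure function of its parameters and seed, and each
emulates one statistical feature the analysis pipeline assumes:

* :func:`make_two_lobe` — a two-lobe "dumbbell" whose softest elastic-network
  mode is the lobe-opening (hinge) motion, optionally clamped by a rigid
  block bridging the lobes (the regulatory-domain stand-in);
* :func:`make_planted_traj` — trajectories with planted covariance structure
  for PCA/RMSF recovery tests;
* :func:`make_double_well` — an analytic 1-D double well with known minima
  and barrier, the metadynamics oracle;
* :func:`make_two_state_chain` — a bead chain whose terminal segment docks
  onto either face of a scaffold sheet, giving two reference states with a
  controlled shared/exclusive contact split for dual-basin force-field and
  free-energy tests.  The two states are exact mirror images, so the
  symmetric hybrid model has (near-)degenerate basins by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kinodyn.structure import Structure

__all__ = [
    "TwoLobeToy", "TwoStateChain", "DoubleWell",
    "make_two_lobe", "make_planted_traj", "make_double_well",
    "make_two_state_chain",
]


def _structure_from_beads(xyz: np.ndarray, chain_ids, res_numbers,
                          title: str) -> Structure:
    n = len(xyz)
    return Structure(
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        res_numbers=np.asarray(res_numbers, dtype=int),
        icodes=np.array([""] * n),
        res_names=np.array(["ALA"] * n),
        chain_ids=np.asarray(chain_ids),
        coords=xyz[None],
        title=title,
    )


# ---------------------------------------------------------------------------
# two-lobe hinge toy
# ---------------------------------------------------------------------------

@dataclass
class TwoLobeToy:
    structure: Structure
    hinge_displacement: np.ndarray   # (3N,), unit norm, rigid-body-free
    lobe1: np.ndarray                # bead indices of the mobile lobe
    lobe2: np.ndarray                # the heavy anchor lobe
    neck: np.ndarray
    hinge: np.ndarray                # anchor-side neck beads: the fulcrum
    clamp: np.ndarray                # empty if unclamped

    def lobe_tips(self, n: int = 8) -> np.ndarray:
        """Outermost beads of the mobile lobe (largest amplitude region)."""
        xyz = self.structure.xyz
        order = np.argsort(np.abs(xyz[self.lobe1, 0]))
        return self.lobe1[order[-n:]]


def _rigid_body_basis(xyz: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body displacements, (3N, 6)."""
    n = len(xyz)
    c = xyz - xyz.mean(0)
    basis = np.zeros((3 * n, 6))
    for d in range(3):
        basis[d::3, d] = 1.0
    axes = np.eye(3)
    for d in range(3):
        rot = np.cross(np.broadcast_to(axes[d], (n, 3)), c)
        basis[:, 3 + d] = rot.reshape(-1)
    q, _ = np.linalg.qr(basis)
    return q


def _remove_rigid(disp: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    q = _rigid_body_basis(xyz)
    d = disp - q @ (q.T @ disp)
    return d / np.linalg.norm(d)


def _fill_blob(rng, center, radius, thickness, count):
    """Jittered two-layer triangular grid filling a flat elliptical blob.

    Grid placement keeps the beads well spaced (no rejection sampling);
    the jitter breaks lattice symmetries that would produce degenerate
    normal modes.
    """
    spacing = 3.6
    candidates = []
    ny = int(radius // (spacing * 0.87)) + 1
    nx = int(radius // spacing) + 1
    for layer, z in enumerate((-1.0, 1.0)):
        for iy in range(-ny, ny + 1):
            for ix in range(-nx, nx + 1):
                x = (ix + 0.5 * (iy % 2) + 0.25 * layer) * spacing
                y = iy * spacing * 0.87
                if (x / radius) ** 2 + (y / radius) ** 2 <= 1.0:
                    candidates.append([x, y, z * thickness])
    if len(candidates) < count:
        raise RuntimeError(
            f"lobe radius {radius} too small for {count} beads; "
            f"grid offers {len(candidates)} sites")
    # innermost sites first so the blob stays compact, then jitter
    candidates.sort(key=lambda p: p[0] ** 2 + p[1] ** 2)
    pts = np.array(candidates[:count])
    pts += rng.uniform(-0.6, 0.6, size=pts.shape)
    return list(pts + np.asarray(center))


def make_two_lobe(n_per_lobe: int = 32, hinge_width: float = 3.5,
                  lobe_radius: float = 8.0, seed: int = 2024,
                  clamp: bool = False) -> TwoLobeToy:
    """Two flattened bead blobs joined by a narrow neck.

    The structure is thin along z, so the softest internal elastic-network
    deformation is the "book-fold" opening of the two lobes about the neck
    (rotation of each lobe about the y axis in opposite senses).  The
    returned hinge displacement is that opening motion, orthogonalised
    against rigid-body components and normalised.

    With ``clamp=True`` a rigid bar of beads (separate chain, residue
    numbers from 1001) bridges the two lobes on the +z side — restraining
    the hinge the way a domain docked across the lobes would.
    """
    if n_per_lobe < 10:
        raise ValueError("n_per_lobe must be >= 10")
    rng = np.random.default_rng(seed)
    gap = lobe_radius + hinge_width
    # lobe 2 is the heavy anchor (like a kinase C-lobe): with most of the
    # mass on one side, the fold expressed in the centre-of-mass frame is
    # dominated by lobe-1 motion and the crease stays nearly still
    n_lobe2 = int(round(1.7 * n_per_lobe))
    radius2 = 1.3 * lobe_radius
    centers = np.array([[-gap, 0.0, 0.0],
                        [radius2 + hinge_width, 0.0, 0.0]])

    # neck block: wide in y (stiff against twist and in-plane bend) and
    # two z-layers (stiff against local flapping), yet much narrower than
    # the lobes — the soft deformation left is the book-fold hinge motion
    neck = [np.array([x + rng.uniform(-0.3, 0.3),
                      y + rng.uniform(-0.3, 0.3),
                      z + rng.uniform(-0.3, 0.3)])
            for x in np.linspace(-hinge_width, hinge_width, 3)
            for y in (-2.5, 2.5)
            for z in (-0.6, 0.6)]
    lobe1 = _fill_blob(rng, centers[0], lobe_radius, 1.5, n_per_lobe)
    lobe2 = _fill_blob(rng, centers[1], radius2, 1.5, n_lobe2)
    beads = lobe1 + neck + lobe2
    idx1 = np.arange(len(lobe1))
    idx_neck = np.arange(len(lobe1), len(lobe1) + len(neck))
    idx2 = np.arange(len(lobe1) + len(neck), len(beads))

    clamp_pts = []
    if clamp:
        xs = np.linspace(-gap - 2.0, gap + 2.0, 8)
        zs = np.full_like(xs, 6.0)
        zs[0] = zs[-1] = 4.0          # anchors dip toward the lobes
        clamp_pts = [np.array([x, 0.0, z]) for x, z in zip(xs, zs)]
    idx_clamp = np.arange(len(beads), len(beads) + len(clamp_pts))
    xyz = np.array(beads + clamp_pts)

    n_prot = len(beads)
    chain_ids = ["A"] * n_prot + ["B"] * len(clamp_pts)
    res_numbers = list(range(1, n_prot + 1)) + \
        list(range(1001, 1001 + len(clamp_pts)))
    structure = _structure_from_beads(xyz, chain_ids, res_numbers,
                                      "two-lobe hinge toy")

    # opening motion: the mobile lobe rotates about a y axis through the
    # neck while the anchor lobe stays put; rigid-body components of the
    # combined displacement are then projected out
    disp = np.zeros_like(xyz)
    disp[idx1] = np.cross(np.array([0.0, 1.0, 0.0]), xyz[idx1])
    hinge = _remove_rigid(disp.reshape(-1), xyz)
    # the fulcrum: neck beads on the anchor side, embedded against the
    # heavy lobe — the quiet "hinge residues" of the fold
    anchor_side = idx_neck[xyz[idx_neck, 0] > 1.0]
    return TwoLobeToy(structure=structure, hinge_displacement=hinge,
                      lobe1=idx1, lobe2=idx2, neck=idx_neck,
                      hinge=anchor_side, clamp=idx_clamp)


# ---------------------------------------------------------------------------
# planted-covariance trajectories
# ---------------------------------------------------------------------------

def make_planted_traj(base: Structure, modes: np.ndarray, variances,
                      n_frames: int, seed: int = 7,
                      rigid_motion: bool = False,
                      noise: float = 0.0):
    """Frames = base + Σ_k a_k(t) · mode_k with a_k ~ N(0, variance_k).

    ``modes`` is (3N, K) with orthonormal columns (checked).  Optional
    isotropic positional noise of the given standard deviation is added on
    top, and with ``rigid_motion`` every frame is additionally rotated and
    translated at random — PCA/RMSF after superposition must not care.
    """
    from kinodyn.trajectory import Trajectory

    modes = np.asarray(modes, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if modes.ndim != 2 or modes.shape[1] != len(variances):
        raise ValueError("modes must be (3N, K) matching variances")
    gram = modes.T @ modes
    if not np.allclose(gram, np.eye(modes.shape[1]), atol=1e-8):
        raise ValueError("mode vectors must be orthonormal")
    rng = np.random.default_rng(seed)
    amplitudes = rng.standard_normal((n_frames, len(variances))) \
        * np.sqrt(variances)
    flat = base.xyz.reshape(-1)
    frames = flat[None, :] + amplitudes @ modes.T
    frames = frames.reshape(n_frames, -1, 3)
    if noise > 0:
        frames = frames + noise * rng.standard_normal(frames.shape)
    if rigid_motion:
        for t in range(n_frames):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            frames[t] = frames[t] @ q.T + rng.uniform(-10, 10, size=3)
    return Trajectory(template=base, coords=frames,
                      source=f"planted(seed={seed})")


# ---------------------------------------------------------------------------
# analytic double well
# ---------------------------------------------------------------------------

@dataclass
class DoubleWell:
    """F(x) = h ((x/a)² − 1)²: minima at ±a (F = 0), barrier h at x = 0."""

    h: float                        # kcal/mol
    a: float                        # Å

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.h * ((x / self.a) ** 2 - 1.0) ** 2

    def force(self, x):
        x = np.asarray(x, dtype=float)
        return -4.0 * self.h * x * ((x / self.a) ** 2 - 1.0) / self.a ** 2

    def force_fn(self):
        """(energy, force) callable for :func:`kinodyn.sampler.langevin_run`."""
        def fn(x):
            return float(self.energy(x).sum()), self.force(x)
        return fn


def make_double_well(h: float = 5.0, a: float = 1.0) -> DoubleWell:
    if h <= 0 or a <= 0:
        raise ValueError("h and a must be positive")
    return DoubleWell(h=h, a=a)


# ---------------------------------------------------------------------------
# two-state chain
# ---------------------------------------------------------------------------

@dataclass
class TwoStateChain:
    closed: Structure
    open: Structure
    switch_region: set               # residue numbers of the mobile segment
    clamp_residues: set              # empty if unclamped


def make_two_state_chain(n_tail: int = 4, seed: int = 11,
                         clamp: bool = False,
                         dock_height: float = 6.6) -> TwoStateChain:
    """A two-layer scaffold with a terminal segment docked under either face.

    The scaffold is a hairpin of two stacked strands at z = ±2.3 — the top
    strand an exact z-mirror copy of the bottom one — joined by a turn bead
    and followed by a two-bead stalk, both on the mid-plane z = 0.  The
    mobile segment (one descender bead plus ``n_tail`` docked beads at
    constant |z| = ``dock_height``) lies below the bottom strand in the
    closed state and, mirrored through z = 0, above the top strand in the
    open state.

    Because the two docking sites are congruent, the closed-only and
    open-only contact sets have identical sizes and native-distance
    multisets, every bond and angle is state-symmetric, and the docked
    run is planar so its dihedrals are 0/π and symmetric too: the only
    energetic asymmetry between the two minima of the hybrid model is a
    couple of near-trans dihedral windows crossing the mid-plane (a
    fraction of a kcal/mol).  |z| separations are chosen so no
    segment-scaffold pair is within the contact cutoff in both states —
    shared contacts keep one well-defined native distance.

    With ``clamp=True`` a rigid 5-bead block (chain C, residues from 101)
    docks over the *open* face in both references: its scaffold/stalk
    contacts are shared while its contacts to the mobile segment exist
    only in the open reference — a regulatory domain whose interface is
    native to the active-like arrangement.
    """
    if n_tail < 3:
        raise ValueError("need at least 3 docked tail beads")
    rng = np.random.default_rng(seed)
    jxy = rng.uniform(-0.15, 0.15, size=(14, 2))

    def strand(x0, dx, y0, jslice):
        return np.array(
            [[x0 + dx * k + jxy[j, 0], y0 + 0.6 * (-1) ** k + jxy[j, 1]]
             for k, j in enumerate(jslice)])

    # bottom sheet (z = -2.3): strand A along +x at y≈0, strand B back
    # along -x at y≈4.5; top sheet is the exact z-mirror copy
    a_xy = strand(0.0, 3.6, 0.0, range(7))
    b_xy = strand(21.6, -3.6, 4.5, range(7, 14))
    z_bot = np.full(7, -2.3)
    bottom = np.vstack([
        np.column_stack([a_xy, z_bot]),
        [[24.9, 2.25, -2.3]],                       # turn 1
        np.column_stack([b_xy, z_bot]),
    ])
    riser = np.array([[-2.6, 4.5, 0.0]])            # mid-plane link
    top = bottom[::-1].copy()        # congruent mirror copy, reversed order
    top[:, 2] = 2.3
    # stalk on the mid-plane AND in the y = 2.25 plane of the mobile path
    stalk = np.array([[-3.3, 2.25, 0.0], [-6.9, 2.25, 0.0]])
    scaffold = np.vstack([bottom, riser, top, stalk])
    n_scaffold = len(scaffold)       # 33 beads, indices 0..32

    # mobile segment: everything in the vertical plane y = 2.25, so all its
    # dihedrals are 0/π and exactly mirror-symmetric; the zig-zag needed to
    # avoid collinear windows is in z.  Docked beads sit between the strand
    # lines of the near sheet, contacting both strands.
    seg = [[-8.9, 2.25, -0.36 * dock_height],
           [-7.3, 2.25, -0.86 * dock_height]]
    for k in range(n_tail):
        seg.append([-3.9 + 3.6 * k, 2.25,
                    -dock_height + 0.45 * (-1) ** k])
    seg = np.array(seg)

    closed_xyz = np.vstack([scaffold, seg])
    open_xyz = closed_xyz.copy()
    open_xyz[n_scaffold:, 2] *= -1.0

    n_prot = len(closed_xyz)
    chain_ids = ["A"] * n_prot
    res_numbers = list(range(1, n_prot + 1))
    switch = set(range(n_scaffold + 1, n_prot + 1))

    clamp_res: set = set()
    if clamp:
        arm_z = dock_height + 4.2
        clamp_xyz = np.array([
            [3.7, 2.25, arm_z],
            [7.3, 2.25, arm_z + 0.35],
            [10.9, 2.25, arm_z],
            [13.3, 2.25, 7.6],
            [15.4, 2.25, 4.6],
        ])
        closed_xyz = np.vstack([closed_xyz, clamp_xyz])
        open_xyz = np.vstack([open_xyz, clamp_xyz])
        chain_ids += ["C"] * len(clamp_xyz)
        clamp_res = set(range(101, 101 + len(clamp_xyz)))
        res_numbers += sorted(clamp_res)

    closed = _structure_from_beads(closed_xyz, chain_ids, res_numbers,
                                   "two-state chain, closed")
    open_ = _structure_from_beads(open_xyz, chain_ids, res_numbers,
                                  "two-state chain, open")
    return TwoStateChain(closed=closed, open=open_, switch_region=switch,
                         clamp_residues=clamp_res)
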