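"""Structure-based (Gō-type) Cα coarse-grained force field, single- and
dual-basin.

Functional forms
----------------
* bonds:      E = K_b (r − r0)²
* angles:     E = K_a (θ − θ0)²
* dihedrals:  E = K_d1 [1 − cos(φ − φ0)] + K_d3 [1 − cos 3(φ − φ0)]
* native contacts (12-10):  E = ε [5 (r0/r)¹² − 6 (r0/r)¹⁰]
  (minimum −ε at r = r0, zero slope there)
* excluded volume: a purely repulsive core that is exactly zero with zero
  slope at r = σ, E = ε_rep [(σ/r)¹² − 2 (σ/r)⁶ + 1] for r < σ.  The smooth
  truncation keeps every reference structure an exact stationary point of
  its own single-basin model (an untruncated 1/r¹² tail would exert small
  residual forces at the native coordinates).

The *hybrid* (dual-basin) variant encodes two reference conformations of a
switch region (e.g. a kinase activation loop, open vs. closed): contacts
present in both references are kept once ("shared", r0 from the closed
reference); contacts exclusive to one reference and involving the switch
region are kept with their own r0 and a mixing weight on ε; dihedrals inside
the switch region are softened (K halved) so the backbone can actually make
the transition.  Bonded reference values otherwise come from the closed
structure.

Bonds/angles/dihedrals are only built between consecutive beads of the same
chain, so a regulatory domain supplied as a separate chain interacts purely
through contacts and excluded volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kinodyn.structure import Structure, compute_contact_map

__all__ = [
    "CGTopology", "EnergyReport", "build_single_basin", "build_hybrid",
    "energy_forces", "energy_forces_numpy", "write_topology",
    "read_topology",
]

# default Gō-model scales (kcal/mol, Å, radians)
DEFAULT_KB = 100.0
DEFAULT_KA = 20.0
DEFAULT_KD1 = 1.0
DEFAULT_KD3 = 0.5
DEFAULT_SIGMA = 4.0
DEFAULT_EPS_REP = 1.0

SHARED, CLOSED_ONLY, OPEN_ONLY = "shared", "closed-only", "open-only"


@dataclass
class EnergyReport:
    bond: float
    angle: float
    dihedral: float
    contact: float
    repulsion: float

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral
                + self.contact + self.repulsion)


@dataclass
class CGTopology:
    """Beads plus all interaction terms of the coarse-grained model.

    Treat instances as immutable once energies have been evaluated: the
    compiled kernel caches typed views of the term arrays.
    """

    n_beads: int
    # bonded terms; reference values measured from the source structure
    bonds: np.ndarray               # (nb, 2) int
    bond_r0: np.ndarray             # Å
    bond_k: np.ndarray
    angles: np.ndarray              # (na, 3) int
    angle_t0: np.ndarray            # rad
    angle_k: np.ndarray
    dihedrals: np.ndarray           # (nd, 4) int
    dihedral_p0: np.ndarray         # rad
    dihedral_k1: np.ndarray
    dihedral_k3: np.ndarray
    # contacts
    contact_i: np.ndarray
    contact_j: np.ndarray
    contact_r0: np.ndarray          # Å
    contact_eps: np.ndarray         # kcal/mol
    contact_tag: np.ndarray         # str: shared / closed-only / open-only
    # excluded volume
    rep_i: np.ndarray
    rep_j: np.ndarray
    sigma: float = DEFAULT_SIGMA
    eps_rep: float = DEFAULT_EPS_REP
    res_numbers: np.ndarray | None = None
    chain_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def contact_pairs(self, tag: str | None = None) -> set[tuple[int, int]]:
        pairs = zip(self.contact_i.tolist(), self.contact_j.tolist())
        if tag is None:
            return set(pairs)
        return {p for p, t in zip(pairs, self.contact_tag) if t == tag}


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

def _geometry_terms(xyz: np.ndarray, chains: np.ndarray,
                    kb: float, ka: float, kd1: float, kd3: float):
    """Bond/angle/dihedral index lists and reference values, chain-aware."""
    n = len(xyz)
    runs: list[list[int]] = []
    for a in range(n):
        if runs and chains[a] == chains[runs[-1][-1]]:
            runs[-1].append(a)
        else:
            runs.append([a])

    bonds, angles, dihedrals = [], [], []
    for run in runs:
        bonds += [run[k:k + 2] for k in range(len(run) - 1)]
        angles += [run[k:k + 3] for k in range(len(run) - 2)]
        dihedrals += [run[k:k + 4] for k in range(len(run) - 3)]

    bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    angles = np.array(angles, dtype=int).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=int).reshape(-1, 4)

    bond_r0 = np.linalg.norm(xyz[bonds[:, 1]] - xyz[bonds[:, 0]], axis=1) \
        if len(bonds) else np.empty(0)
    angle_t0 = _angle_values(xyz, angles) if len(angles) else np.empty(0)
    dihedral_p0 = _dihedral_values(xyz, dihedrals) if len(dihedrals) \
        else np.empty(0)
    return (bonds, bond_r0, np.full(len(bonds), kb),
            angles, angle_t0, np.full(len(angles), ka),
            dihedrals, dihedral_p0,
            np.full(len(dihedrals), kd1), np.full(len(dihedrals), kd3))


def _angle_values(xyz: np.ndarray, triples: np.ndarray) -> np.ndarray:
    u = xyz[triples[:, 0]] - xyz[triples[:, 1]]
    v = xyz[triples[:, 2]] - xyz[triples[:, 1]]
    cos = (u * v).sum(1) / (np.linalg.norm(u, axis=1)
                            * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(cos, -1.0, 1.0))


def _dihedral_values(xyz: np.ndarray, quads: np.ndarray) -> np.ndarray:
    b1 = xyz[quads[:, 1]] - xyz[quads[:, 0]]
    b2 = xyz[quads[:, 2]] - xyz[quads[:, 1]]
    b3 = xyz[quads[:, 3]] - xyz[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = (n1 * n2).sum(1)
    y = (m * n2).sum(1)
    return np.arctan2(y, x)


def _repulsion_pairs(n: int, chains: np.ndarray, min_seq_sep: int,
                     contact_pairs: set[tuple[int, int]]):
    ii, jj = np.triu_indices(n, k=1)
    same = chains[ii] == chains[jj]
    eligible = (jj - ii >= min_seq_sep) | ~same
    keep = [k for k in np.nonzero(eligible)[0]
            if (int(ii[k]), int(jj[k])) not in contact_pairs]
    return ii[keep], jj[keep]


def build_single_basin(structure: Structure, contact_cutoff: float = 8.0,
                       min_seq_sep: int = 3, epsilon: float = 1.0,
                       kb: float = DEFAULT_KB, ka: float = DEFAULT_KA,
                       kd1: float = DEFAULT_KD1, kd3: float = DEFAULT_KD3,
                       sigma: float = DEFAULT_SIGMA,
                       eps_rep: float = DEFAULT_EPS_REP) -> CGTopology:
    """Gō model with a single reference structure.

    At the reference coordinates every contact sits at its minimum (−ε) and
    all bonded terms are zero, so the total energy is −ε × (number of
    contacts) and the gradient vanishes.
    """
    xyz = structure.xyz
    if len(xyz) < 4:
        raise ValueError("need at least 4 beads for a chain topology")
    chains = structure.chain_ids
    cmap = compute_contact_map(structure, contact_cutoff, min_seq_sep)
    terms = _geometry_terms(xyz, chains, kb, ka, kd1, kd3)
    bond_pairs = {tuple(b) for b in terms[0].tolist()}
    keep = [k for k in range(len(cmap))
            if (int(cmap.i[k]), int(cmap.j[k])) not in bond_pairs]
    ci, cj, cr0 = cmap.i[keep], cmap.j[keep], cmap.r0[keep]
    rep_i, rep_j = _repulsion_pairs(
        len(xyz), chains, min_seq_sep,
        set(zip(ci.tolist(), cj.tolist())) | bond_pairs)
    return CGTopology(
        n_beads=len(xyz),
        bonds=terms[0], bond_r0=terms[1], bond_k=terms[2],
        angles=terms[3], angle_t0=terms[4], angle_k=terms[5],
        dihedrals=terms[6], dihedral_p0=terms[7],
        dihedral_k1=terms[8], dihedral_k3=terms[9],
        contact_i=ci, contact_j=cj, contact_r0=cr0,
        contact_eps=np.full(len(ci), epsilon),
        contact_tag=np.array([SHARED] * len(ci)),
        rep_i=rep_i, rep_j=rep_j, sigma=sigma, eps_rep=eps_rep,
        res_numbers=structure.res_numbers, chain_ids=chains,
        meta={"contact_cutoff": contact_cutoff, "min_seq_sep": min_seq_sep,
              "epsilon": epsilon},
    )


def build_hybrid(closed: Structure, open_: Structure,
                 switch_region: set[int], contact_cutoff: float = 8.0,
                 min_seq_sep: int = 3, epsilon: float = 1.0,
                 mixing_weight: float = 1.0,
                 **kw) -> CGTopology:
    """Dual-basin model from a closed and an open reference.

    ``switch_region`` is the set of residue numbers that change conformation
    (e.g. the activation loop).  Exclusive contacts that do not involve the
    switch region are treated like shared ones (kept at full ε with the r0
    of the reference that has them) — they encode peripheral differences,
    not the transition itself.  Both structures must share residue
    numbering over the modeled range.
    """
    keys_c = closed.residue_keys()
    keys_o = open_.residue_keys()
    if keys_c != keys_o:
        common = set(keys_c) & set(keys_o)
        if not common:
            raise ValueError("closed/open references share no residues")
        raise ValueError(
            "closed/open references must list the same residues in the "
            f"same order ({len(common)} shared of {len(keys_c)}/"
            f"{len(keys_o)})")

    top = build_single_basin(closed, contact_cutoff, min_seq_sep, epsilon,
                             **kw)
    cmap_o = compute_contact_map(open_, contact_cutoff, min_seq_sep)
    bond_pairs = {tuple(b) for b in top.bonds.tolist()}
    open_pairs = {p: r for p, r in zip(
        zip(cmap_o.i.tolist(), cmap_o.j.tolist()), cmap_o.r0)
        if p not in bond_pairs}
    closed_pairs = dict(zip(
        zip(top.contact_i.tolist(), top.contact_j.tolist()),
        top.contact_r0))

    resnum = closed.res_numbers
    switch = set(int(r) for r in switch_region)
    if not switch:
        raise ValueError("switch_region is empty")

    def touches_switch(pair):
        return int(resnum[pair[0]]) in switch or \
            int(resnum[pair[1]]) in switch

    ci, cj, cr0, ceps, ctag = [], [], [], [], []
    for pair in sorted(set(closed_pairs) | set(open_pairs)):
        in_c, in_o = pair in closed_pairs, pair in open_pairs
        if in_c and in_o:
            r0, eps, tag = closed_pairs[pair], epsilon, SHARED
        elif touches_switch(pair):
            r0 = closed_pairs[pair] if in_c else open_pairs[pair]
            eps = epsilon * mixing_weight
            tag = CLOSED_ONLY if in_c else OPEN_ONLY
        else:
            r0 = closed_pairs[pair] if in_c else open_pairs[pair]
            eps, tag = epsilon, SHARED
        ci.append(pair[0]); cj.append(pair[1])
        cr0.append(r0); ceps.append(eps); ctag.append(tag)

    top.contact_i = np.array(ci, dtype=int)
    top.contact_j = np.array(cj, dtype=int)
    top.contact_r0 = np.array(cr0)
    top.contact_eps = np.array(ceps)
    top.contact_tag = np.array(ctag)

    # soften dihedrals whose beads enter the switch region; with identical
    # references there is no transition to soften and the hybrid must
    # reduce exactly to the single-basin model
    any_exclusive = any(t != SHARED for t in ctag)
    in_switch = np.isin(resnum, list(switch))
    if len(top.dihedrals) and any_exclusive:
        soft = in_switch[top.dihedrals].any(axis=1)
        top.dihedral_k1 = np.where(soft, top.dihedral_k1 / 2,
                                   top.dihedral_k1)
        top.dihedral_k3 = np.where(soft, top.dihedral_k3 / 2,
                                   top.dihedral_k3)

    top.rep_i, top.rep_j = _repulsion_pairs(
        top.n_beads, closed.chain_ids, min_seq_sep,
        set(zip(ci, cj)) | bond_pairs)
    top.meta.update({"hybrid": True, "mixing_weight": mixing_weight,
                     "switch_region": sorted(switch)})
    return top


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------

def energy_forces(top: CGTopology, coords: np.ndarray
                  ) -> tuple[EnergyReport, np.ndarray]:
    """Total energy by term plus analytic forces (−gradient), kcal/mol, Å.

    Dispatches to a compiled kernel when numba is available; the numpy
    implementation (:func:`energy_forces_numpy`) is the reference and the
    two are asserted equal in the test suite.
    """
    from kinodyn import _kernels
    if not _kernels.HAVE_NUMBA:                          # pragma: no cover
        return energy_forces_numpy(top, coords)
    x = np.ascontiguousarray(np.asarray(coords, dtype=float).reshape(-1, 3))
    if len(x) != top.n_beads:
        raise ValueError(
            f"coords for {len(x)} beads, topology has {top.n_beads}")
    eb, ea, ed, ec, er, f = _kernels.ff_energy_forces(
        x, *_packed_arrays(top))
    return EnergyReport(bond=eb, angle=ea, dihedral=ed, contact=ec,
                        repulsion=er), f


def _packed_arrays(top: CGTopology) -> tuple:
    """Contiguous, correctly-typed views for the compiled kernel (cached)."""
    packed = getattr(top, "_packed", None)
    if packed is None:
        packed = (
            np.ascontiguousarray(top.bonds, dtype=np.int64),
            np.ascontiguousarray(top.bond_r0, dtype=np.float64),
            np.ascontiguousarray(top.bond_k, dtype=np.float64),
            np.ascontiguousarray(top.angles, dtype=np.int64),
            np.ascontiguousarray(top.angle_t0, dtype=np.float64),
            np.ascontiguousarray(top.angle_k, dtype=np.float64),
            np.ascontiguousarray(top.dihedrals, dtype=np.int64),
            np.ascontiguousarray(top.dihedral_p0, dtype=np.float64),
            np.ascontiguousarray(top.dihedral_k1, dtype=np.float64),
            np.ascontiguousarray(top.dihedral_k3, dtype=np.float64),
            np.ascontiguousarray(top.contact_i, dtype=np.int64),
            np.ascontiguousarray(top.contact_j, dtype=np.int64),
            np.ascontiguousarray(top.contact_r0, dtype=np.float64),
            np.ascontiguousarray(top.contact_eps, dtype=np.float64),
            np.ascontiguousarray(top.rep_i, dtype=np.int64),
            np.ascontiguousarray(top.rep_j, dtype=np.int64),
            float(top.sigma), float(top.eps_rep),
        )
        object.__setattr__(top, "_packed", packed)
    return packed


def energy_forces_numpy(top: CGTopology, coords: np.ndarray
                        ) -> tuple[EnergyReport, np.ndarray]:
    """Reference vectorised-numpy implementation of :func:`energy_forces`."""
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(x) != top.n_beads:
        raise ValueError(
            f"coords for {len(x)} beads, topology has {top.n_beads}")
    f = np.zeros_like(x)

    e_bond = 0.0
    if len(top.bonds):
        d = x[top.bonds[:, 1]] - x[top.bonds[:, 0]]
        r = np.linalg.norm(d, axis=1)
        dr = r - top.bond_r0
        e_bond = float((top.bond_k * dr ** 2).sum())
        g = (2 * top.bond_k * dr / r)[:, None] * d    # dE/dx_j
        np.add.at(f, top.bonds[:, 0], g)
        np.add.at(f, top.bonds[:, 1], -g)

    e_angle = 0.0
    if len(top.angles):
        i, j, k = top.angles.T
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh, vh = u / nu[:, None], v / nv[:, None]
        cos = np.clip((uh * vh).sum(1), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.clip(1 - cos ** 2, 1e-16, None))
        dt = theta - top.angle_t0
        e_angle = float((top.angle_k * dt ** 2).sum())
        dEdt = 2 * top.angle_k * dt
        gi = (dEdt / (nu * sin))[:, None] * (cos[:, None] * uh - vh)
        gk = (dEdt / (nv * sin))[:, None] * (cos[:, None] * vh - uh)
        np.add.at(f, i, -gi)
        np.add.at(f, k, -gk)
        np.add.at(f, j, gi + gk)

    e_dih = 0.0
    if len(top.dihedrals):
        a1, a2, a3, a4 = top.dihedrals.T
        b1 = x[a2] - x[a1]
        b2 = x[a3] - x[a2]
        b3 = x[a4] - x[a3]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m = np.cross(n1, b2 / nb2[:, None])
        phi = np.arctan2((m * n2).sum(1), (n1 * n2).sum(1))
        dphi = phi - top.dihedral_p0
        e_dih = float((top.dihedral_k1 * (1 - np.cos(dphi))
                       + top.dihedral_k3 * (1 - np.cos(3 * dphi))).sum())
        dEdp = (top.dihedral_k1 * np.sin(dphi)
                + 3 * top.dihedral_k3 * np.sin(3 * dphi))
        n1sq = (n1 ** 2).sum(1)
        n2sq = (n2 ** 2).sum(1)
        g1 = (nb2 / n1sq)[:, None] * n1             # dphi/dx_1
        g4 = (-nb2 / n2sq)[:, None] * n2            # dphi/dx_4
        p = (b1 * b2).sum(1) / nb2 ** 2
        q = (b3 * b2).sum(1) / nb2 ** 2
        g2 = -(1 + p)[:, None] * g1 + q[:, None] * g4
        g3 = p[:, None] * g1 - (1 + q)[:, None] * g4
        np.add.at(f, a1, -dEdp[:, None] * g1)
        np.add.at(f, a2, -dEdp[:, None] * g2)
        np.add.at(f, a3, -dEdp[:, None] * g3)
        np.add.at(f, a4, -dEdp[:, None] * g4)

    e_contact = 0.0
    if len(top.contact_i):
        d = x[top.contact_j] - x[top.contact_i]
        r = np.linalg.norm(d, axis=1)
        if (r < 1e-6).any():
            raise FloatingPointError("overlapping beads in contact pair")
        s = top.contact_r0 / r
        s10 = s ** 10
        s12 = s10 * s * s
        e_contact = float((top.contact_eps * (5 * s12 - 6 * s10)).sum())
        dEdr = top.contact_eps * 60 * s10 * (1 - s * s) / r
        g = (dEdr / r)[:, None] * d
        np.add.at(f, top.contact_i, g)
        np.add.at(f, top.contact_j, -g)

    e_rep = 0.0
    if len(top.rep_i):
        d = x[top.rep_j] - x[top.rep_i]
        r2 = (d ** 2).sum(1)
        if (r2 < 1e-12).any():
            raise FloatingPointError("overlapping beads in repulsion pair")
        inside = r2 < top.sigma ** 2
        if inside.any():
            d = d[inside]
            r2 = r2[inside]
            s6 = (top.sigma ** 2 / r2) ** 3
            e_rep = float((top.eps_rep * (s6 * s6 - 2 * s6 + 1)).sum())
            dEdr_over_r = top.eps_rep * 12 * (s6 - s6 * s6) / r2
            g = dEdr_over_r[:, None] * d
            np.add.at(f, top.rep_i[inside], g)
            np.add.at(f, top.rep_j[inside], -g)

    report = EnergyReport(bond=e_bond, angle=e_angle, dihedral=e_dih,
                          contact=e_contact, repulsion=e_rep)
    return report, f


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def write_topology(top: CGTopology, path) -> None:
    """Serialize to a documented plain-text format, readable back exactly."""
    with open(Path(path), "w") as fh:
        fh.write(f"# kinodyn CG topology\nNBEADS {top.n_beads}\n")
        fh.write(f"SIGMA {float(top.sigma)!r}\nEPSREP {float(top.eps_rep)!r}\n")
        fh.write(f"BONDS {len(top.bonds)}\n")
        for (i, j), r0, k in zip(top.bonds, top.bond_r0, top.bond_k):
            fh.write(f"{i} {j} {float(r0)!r} {float(k)!r}\n")
        fh.write(f"ANGLES {len(top.angles)}\n")
        for (i, j, k), t0, ka in zip(top.angles, top.angle_t0, top.angle_k):
            fh.write(f"{i} {j} {k} {float(t0)!r} {float(ka)!r}\n")
        fh.write(f"DIHEDRALS {len(top.dihedrals)}\n")
        for quad, p0, k1, k3 in zip(top.dihedrals, top.dihedral_p0,
                                    top.dihedral_k1, top.dihedral_k3):
            fh.write(" ".join(str(int(q)) for q in quad)
                     + f" {float(p0)!r} {float(k1)!r} {float(k3)!r}\n")
        fh.write(f"CONTACTS {len(top.contact_i)}\n")
        for i, j, r0, e, t in zip(top.contact_i, top.contact_j,
                                  top.contact_r0, top.contact_eps,
                                  top.contact_tag):
            fh.write(f"{i} {j} {float(r0)!r} {float(e)!r} {t}\n")
        fh.write(f"REPULSION {len(top.rep_i)}\n")
        for i, j in zip(top.rep_i, top.rep_j):
            fh.write(f"{i} {j}\n")


def read_topology(path) -> CGTopology:
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln and not ln.startswith("#")]
    it = iter(lines)

    def expect(tag):
        parts = next(it).split()
        assert parts[0] == tag, f"expected {tag}, got {parts[0]}"
        return parts[1]

    n_beads = int(expect("NBEADS"))
    sigma = float(expect("SIGMA"))
    eps_rep = float(expect("EPSREP"))

    def block(tag, n_idx, n_float, has_tag=False):
        count = int(expect(tag))
        idx = np.empty((count, n_idx), dtype=int)
        vals = np.empty((count, n_float))
        tags = []
        for r in range(count):
            parts = next(it).split()
            idx[r] = [int(v) for v in parts[:n_idx]]
            vals[r] = [float(v) for v in parts[n_idx:n_idx + n_float]]
            if has_tag:
                tags.append(parts[n_idx + n_float])
        return idx, vals, np.array(tags) if has_tag else None

    bonds, bvals, _ = block("BONDS", 2, 2)
    angles, avals, _ = block("ANGLES", 3, 2)
    dihedrals, dvals, _ = block("DIHEDRALS", 4, 3)
    cidx, cvals, ctags = block("CONTACTS", 2, 2, has_tag=True)
    ridx, _, _ = block("REPULSION", 2, 0)

    return CGTopology(
        n_beads=n_beads,
        bonds=bonds, bond_r0=bvals[:, 0], bond_k=bvals[:, 1],
        angles=angles, angle_t0=avals[:, 0], angle_k=avals[:, 1],
        dihedrals=dihedrals, dihedral_p0=dvals[:, 0],
        dihedral_k1=dvals[:, 1], dihedral_k3=dvals[:, 2],
        contact_i=cidx[:, 0], contact_j=cidx[:, 1],
        contact_r0=cvals[:, 0], contact_eps=cvals[:, 1],
        contact_tag=ctags if ctags is not None else np.array([]),
        rep_i=ridx[:, 0], rep_j=ridx[:, 1],
        sigma=sigma, eps_rep=eps_rep,
    )
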