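"""Essential-dynamics analytics for multi-model trajectories.

Implements the standard battery used to compare a kinase domain simulated
alone and in complex with a regulatory domain: least-squares superposition,
RMSD/RMSF, principal component analysis of the positional covariance with
cross-construct projection, eigenvalue spectra, GROMOS-style leader
clustering and atom-pair distance series (e.g. the αC-helix E305(Cδ)–
K290(Nζ) salt bridge, or the V299–Y530 Cα hinge distance).

Trajectories are exchanged as multi-model PDB; distances are in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from kinodyn.structure import Structure, parse_pdb, write_pdb

__all__ = [
    "Trajectory", "PCAModel", "ProjectionSeries", "ClusterResult",
    "DistanceSeries", "read_trajectory", "write_trajectory",
    "superpose", "rmsf", "pca", "project", "eigen_spectrum_fractions",
    "cluster_leader", "distance_series", "kabsch",
]


@dataclass
class Trajectory:
    """T frames over a fixed atom list.

    ``template`` carries the atom metadata (names, residues, chains);
    ``coords`` has shape (T, n_atoms, 3) in Å.
    """

    template: Structure
    coords: np.ndarray
    frame_period: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("coords must be (T>=1, n_atoms, 3)")
        if self.coords.shape[1] != self.template.n_atoms:
            raise ValueError("frame atom count does not match template")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_structure(cls, structure: Structure, **kw) -> "Trajectory":
        """Interpret the models of a multi-model Structure as frames."""
        return cls(template=structure.subset(np.arange(structure.n_atoms)),
                   coords=structure.coords.copy(), **kw)

    def to_structure(self) -> Structure:
        return replace(self.template, coords=self.coords.copy())


def read_trajectory(path, chain_filter: str | None = None) -> Trajectory:
    """Read a multi-model PDB trajectory."""
    return Trajectory.from_structure(parse_pdb(path, chain_filter),
                                     source=str(path))


def write_trajectory(traj: Trajectory, path, stride: int = 1) -> None:
    sub = replace(traj.template, coords=traj.coords[::stride].copy())
    write_pdb(sub, path)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising |R·mobile + t − target|.

    Standard SVD solution with the determinant correction that excludes
    improper rotations.
    """
    cm, ct = mobile.mean(0), target.mean(0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, ct - R @ cm


def _resolve_selection(traj_or_struct, selection) -> np.ndarray:
    n = (traj_or_struct.n_atoms if hasattr(traj_or_struct, "n_atoms")
         else len(traj_or_struct))
    if selection is None:
        return np.arange(n)
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    if sel.min() < 0 or sel.max() >= n:
        raise ValueError("selection index out of range")
    return sel


def superpose(traj: Trajectory, reference: np.ndarray | Structure,
              selection=None) -> tuple[Trajectory, np.ndarray]:
    """Least-squares fit every frame onto the reference over a selection.

    Returns the fitted trajectory (all atoms moved) and the per-frame RMSD
    over the selection after fitting.
    """
    ref = reference.xyz if isinstance(reference, Structure) else \
        np.asarray(reference, dtype=float)
    sel = _resolve_selection(traj, selection)
    if len(sel) < 3:
        raise ValueError("need at least 3 selected atoms to superpose")
    ref_sel = ref[sel]
    # collinearity check: rank of centred selection must be >= 2
    if np.linalg.matrix_rank(ref_sel - ref_sel.mean(0), tol=1e-8) < 2:
        raise ValueError("selected reference atoms are collinear")

    fitted = np.empty_like(traj.coords)
    rmsd = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        R, tvec = kabsch(traj.coords[t, sel], ref_sel)
        fitted[t] = traj.coords[t] @ R.T + tvec
        delta = fitted[t, sel] - ref_sel
        rmsd[t] = np.sqrt((delta ** 2).sum() / len(sel))
    return replace(traj, coords=fitted), rmsd


def _window(n_frames: int, discard_fraction: float) -> slice:
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    start = int(round(discard_fraction * n_frames))
    return slice(start, n_frames)


def rmsf(traj: Trajectory, selection=None, discard_fraction: float = 0.25,
         per_residue: bool = False) -> np.ndarray:
    """Root-mean-square fluctuation about the windowed mean position.

    The first ``discard_fraction`` of frames is treated as equilibration and
    excluded.  The trajectory must already be superposed.  With
    ``per_residue`` the atomic MSFs are averaged within each residue before
    the square root.
    """
    sel = _resolve_selection(traj, selection)
    win = _window(traj.n_frames, discard_fraction)
    x = traj.coords[win][:, sel]
    if x.shape[0] < 2:
        raise ValueError("analysis window has fewer than 2 frames")
    msf = ((x - x.mean(0)) ** 2).sum(-1).mean(0)
    if not per_residue:
        return np.sqrt(msf)
    keys = [traj.template.residue_keys()[i] for i in sel]
    order: dict = {}
    for pos, key in enumerate(keys):
        order.setdefault(key, []).append(pos)
    return np.sqrt(np.array([msf[idx].mean() for idx in order.values()]))


# ---------------------------------------------------------------------------
# PCA / projections
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Eigen-decomposition of the positional covariance of a trajectory."""

    mean: np.ndarray                # (M, 3) Å
    eigenvectors: np.ndarray        # (3M, K) orthonormal columns
    eigenvalues: np.ndarray         # (K,) Å², descending
    selection: np.ndarray           # atom indices the model was fitted on
    discard_fraction: float


@dataclass
class ProjectionSeries:
    projections: np.ndarray         # (T, n_vectors) Å
    eigenvector_ids: tuple[int, ...]
    source: str = ""


def pca(traj: Trajectory, selection=None,
        discard_fraction: float = 0.25) -> PCAModel:
    """PCA of the selected coordinates over the analysis window.

    Eigenvalues are the variances (Å²) along each eigenvector, descending;
    their sum equals the total positional variance of the fitted selection.
    """
    sel = _resolve_selection(traj, selection)
    win = _window(traj.n_frames, discard_fraction)
    x = traj.coords[win][:, sel].reshape(win.stop - win.start, -1)
    if x.shape[0] < 2:
        raise ValueError("analysis window has fewer than 2 frames")
    mean = x.mean(0)
    xc = x - mean
    if not np.any(xc):
        raise ValueError("trajectory has zero positional variance")
    # SVD of the centred data is numerically kinder than forming C explicitly
    _, s, Vt = np.linalg.svd(xc, full_matrices=False)
    evals = s ** 2 / x.shape[0]
    return PCAModel(mean=mean.reshape(-1, 3), eigenvectors=Vt.T,
                    eigenvalues=evals, selection=sel,
                    discard_fraction=discard_fraction)


def project(traj: Trajectory, model: PCAModel,
            eigenvector_ids=(0, 1), mapping=None) -> ProjectionSeries:
    """Project frames onto PCA eigenvectors, refitting each frame first.

    Without a mapping the trajectory is taken to be the PCA's own construct,
    already superposed exactly as when the model was fitted, and the dot
    products are computed directly (so the projection variance along
    eigenvector k reproduces eigenvalue k).  For cross-construct projection
    (different atom lists), ``mapping`` is a list of (traj_atom, pca_atom)
    index pairs covering the *entire* PCA selection — from
    :func:`kinodyn.structure.map_common_residues` when the beads are
    residues — and each frame is first superposed onto the PCA mean over
    the mapped atoms, so rigid-body drift does not leak into the essential
    coordinates.
    """
    ids = tuple(int(k) for k in eigenvector_ids)
    for k in ids:
        if not 0 <= k < model.eigenvectors.shape[1]:
            raise ValueError(f"eigenvector id {k} out of range")

    if mapping is None:
        traj_idx = model.selection
        pca_idx = np.arange(len(model.selection))
    else:
        pairs = np.asarray(mapping, dtype=int)
        pca_sel_pos = {atom: pos for pos, atom in enumerate(model.selection)}
        traj_idx, pca_idx = [], []
        for t_at, p_at in pairs:
            if p_at in pca_sel_pos:
                traj_idx.append(t_at)
                pca_idx.append(pca_sel_pos[p_at])
        missing = set(range(len(model.selection))) - set(pca_idx)
        if missing:
            raise ValueError(
                f"mapping does not cover PCA selection positions "
                f"{sorted(missing)}")
        traj_idx = np.asarray(traj_idx)
        pca_idx = np.asarray(pca_idx)

    vecs = model.eigenvectors[:, list(ids)]
    mean_flat = model.mean.reshape(-1)
    out = np.empty((traj.n_frames, len(ids)))
    refit = mapping is not None
    for t in range(traj.n_frames):
        frame = traj.coords[t, traj_idx]
        if refit:
            R, tv = kabsch(frame, model.mean[pca_idx])
            frame = frame @ R.T + tv
        disp = np.zeros_like(model.mean)
        disp[pca_idx] = frame
        delta = disp.reshape(-1) - mean_flat
        out[t] = delta @ vecs
    return ProjectionSeries(projections=out, eigenvector_ids=ids,
                            source=traj.source)


def eigen_spectrum_fractions(model: PCAModel, k: int) -> np.ndarray:
    """Fraction of total positional variance carried by each of the top k
    eigenvectors (Fig.-style spectrum); monotone non-increasing."""
    if not 1 <= k <= len(model.eigenvalues):
        raise ValueError("k out of range")
    total = model.eigenvalues.sum()
    return model.eigenvalues[:k] / total


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    cutoff: float
    assignment: np.ndarray          # frame -> cluster id (0 = largest first)
    representatives: list[int]      # medoid frame per cluster
    sizes: list[int]                # descending


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-vs-all coordinate RMSD of an already-superposed trajectory."""
    t, m, _ = coords.shape
    flat = coords.reshape(t, -1)
    sq = (flat ** 2).sum(1)
    d2 = sq[:, None] + sq[None, :] - 2 * flat @ flat.T
    np.maximum(d2, 0, out=d2)
    return np.sqrt(d2 / m)


def cluster_leader(traj: Trajectory, cutoff: float = 2.0,
                   selection=None) -> ClusterResult:
    """Neighbour-counting leader clustering on pairwise RMSD.

    Repeatedly the frame with the most neighbours within ``cutoff`` becomes
    a medoid; it and its neighbours are removed.  Ties go to the lowest
    frame index, making the result deterministic.  Medoids of distinct
    clusters are guaranteed > cutoff apart.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sel = _resolve_selection(traj, selection)
    dist = _pairwise_rmsd(traj.coords[:, sel])
    n = traj.n_frames
    neighbors = dist <= cutoff
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    reps: list[int] = []
    cluster = 0
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(1)
        counts[~remaining] = -1
        leader = int(counts.argmax())          # argmax takes lowest index tie
        members = neighbors[leader] & remaining
        assignment[members] = cluster
        reps.append(leader)
        remaining &= ~members
        cluster += 1
    sizes = [int((assignment == c).sum()) for c in range(cluster)]
    order = sorted(range(cluster), key=lambda c: (-sizes[c], reps[c]))
    relabel = {old: new for new, old in enumerate(order)}
    assignment = np.array([relabel[a] for a in assignment])
    reps = [reps[c] for c in order]
    sizes = [sizes[c] for c in order]
    return ClusterResult(cutoff=cutoff, assignment=assignment,
                         representatives=reps, sizes=sizes)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    distances: np.ndarray           # (T,) Å
    selector_a: tuple
    selector_b: tuple
    tail_fraction: float
    mean: float                     # over the tail window, Å
    sd: float


def _resolve_atom(traj: Trajectory, selector) -> int:
    """Selector (chain, residue number, atom name) -> unique atom index."""
    chain, resnum, atom_name = selector
    tpl = traj.template
    hits = np.nonzero(
        (tpl.chain_ids == chain)
        & (tpl.res_numbers == int(resnum))
        & (tpl.atom_names == atom_name))[0]
    if len(hits) == 0:
        raise ValueError(f"selector {selector} matches no atom")
    if len(hits) > 1:
        raise ValueError(f"selector {selector} is ambiguous "
                         f"({len(hits)} atoms)")
    return int(hits[0])


def distance_series(traj: Trajectory, selector_a, selector_b,
                    tail_fraction: float = 0.75) -> DistanceSeries:
    """Per-frame distance between two uniquely-selected atoms.

    ``tail_fraction`` is the fraction of the trajectory, counted from the
    end, over which the reported mean/SD are computed (the equilibrated
    tail).  Selectors name atoms explicitly — Cα is never substituted for a
    missing side-chain atom.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    ia = _resolve_atom(traj, selector_a)
    ib = _resolve_atom(traj, selector_b)
    d = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)
    start = traj.n_frames - int(round(tail_fraction * traj.n_frames))
    tail = d[start:]
    return DistanceSeries(distances=d, selector_a=tuple(selector_a),
                          selector_b=tuple(selector_b),
                          tail_fraction=tail_fraction,
                          mean=float(tail.mean()), sd=float(tail.std()))
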