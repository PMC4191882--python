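"""Cα elastic networks: normal modes, flexibility and allosteric coupling.

The anisotropic network model places a Hookean spring of uniform stiffness γ
between every Cα pair closer than a cutoff R_c.  The 3N×3N Hessian has
superelements

    H_ij = -γ (r_ij r_ijᵀ) / |r_ij|²     for an edge (i, j),
    H_ii = -Σ_{j≠i} H_ij,

so each row block sums to zero (translation invariance) and a connected
network has exactly six zero modes (3 translations + 3 rotations).

Allosteric coupling between residues i and j is measured from the
mode-restricted covariance

    C(i, j) = Σ_{k ∈ range} u_k(i)·u_k(j) / λ_k,

where u_k(i) is residue i's 3-vector block of eigenvector u_k, normalised to

    A(i, j) = |C(i, j)| / sqrt(C(i, i) C(j, j)) ∈ [0, 1].

Low-frequency modes dominate this measure, so the default mode range is the
softest 20 non-rigid modes; over the full non-rigid spectrum C equals the
residue block trace structure of the Hessian pseudo-inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from kinodyn.structure import Structure

__all__ = [
    "ElasticNetwork", "ModeSet", "FlexibilityProfile", "CouplingMatrix",
    "build_network", "normal_modes", "mode_fluctuations", "mode_overlap",
    "coupling_matrix", "coupling_to_region",
]

ZERO_MODE_REL_THRESHOLD = 1e-8  # eigenvalue < threshold × λ_max ⇒ rigid body


@dataclass
class ElasticNetwork:
    """Bead coordinates plus the spring topology within the cutoff."""

    beads: np.ndarray               # (N, 3) Å
    cutoff: float                   # Å
    gamma: float                    # spring constant, energy/Å²
    edges: np.ndarray               # (n_edges, 2) int, i < j
    connected: bool
    res_numbers: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class ModeSet:
    """Non-rigid normal modes, softest first.

    ``eigenvalues`` are ascending (energy/Å²); ``eigenvectors`` has shape
    (3N, n_modes) with orthonormal columns; ``n_zero`` rigid-body modes were
    discarded before selecting these.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    n_beads: int
    res_numbers: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def residue_blocks(self, k: int) -> np.ndarray:
        """Eigenvector k reshaped to per-residue 3-vectors, (N, 3)."""
        return self.eigenvectors[:, k].reshape(self.n_beads, 3)


@dataclass
class FlexibilityProfile:
    """Per-residue mean-square fluctuation over a stated mode range."""

    msf: np.ndarray                 # (N,) ≥ 0, arbitrary units
    mode_range: tuple[int, int]
    res_numbers: np.ndarray | None = None

    @property
    def normalized(self) -> np.ndarray:
        return self.msf / self.msf.max()


@dataclass
class CouplingMatrix:
    """Symmetric residue-residue allosteric coupling, unit diagonal."""

    A: np.ndarray                   # (N, N) in [0, 1]
    mode_range: tuple[int, int]
    weighting: str = "inverse-eigenvalue"
    res_numbers: np.ndarray | None = None


def build_network(structure_or_coords, cutoff: float = 10.0,
                  gamma: float = 1.0) -> ElasticNetwork:
    """Connect all Cα pairs within ``cutoff`` Å with springs of stiffness γ.

    Accepts a Cα-reduced :class:`~kinodyn.structure.Structure` or a plain
    (N, 3) coordinate array.  A disconnected network is flagged (and refused
    later by :func:`normal_modes`) rather than silently decomposed.
    """
    if isinstance(structure_or_coords, Structure):
        beads = structure_or_coords.xyz
        res_numbers = structure_or_coords.res_numbers
    else:
        beads = np.asarray(structure_or_coords, dtype=float)
        res_numbers = None
    if beads.ndim != 2 or beads.shape[1] != 3 or len(beads) < 2:
        raise ValueError("need an (N>=2, 3) coordinate array")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    n = len(beads)
    diff = beads[:, None] - beads[None, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    ii, jj = np.triu_indices(n, k=1)
    keep = dist[ii, jj] <= cutoff
    edges = np.column_stack([ii[keep], jj[keep]])

    adj = scipy.sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n))
    n_comp, _ = scipy.sparse.csgraph.connected_components(
        adj, directed=False)
    return ElasticNetwork(beads=beads, cutoff=cutoff, gamma=gamma,
                          edges=edges, connected=(n_comp == 1),
                          res_numbers=res_numbers)


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Dense 3N×3N anisotropic-network Hessian."""
    n = network.n_beads
    H = np.zeros((3 * n, 3 * n))
    xyz = network.beads
    for i, j in network.edges:
        rij = xyz[j] - xyz[i]
        d2 = rij @ rij
        block = -network.gamma * np.outer(rij, rij) / d2
        H[3*i:3*i+3, 3*j:3*j+3] += block
        H[3*j:3*j+3, 3*i:3*i+3] += block
        H[3*i:3*i+3, 3*i:3*i+3] -= block
        H[3*j:3*j+3, 3*j:3*j+3] -= block
    return H


def normal_modes(network: ElasticNetwork,
                 n_modes: int | None = None) -> ModeSet:
    """Diagonalise the network Hessian; return the softest non-rigid modes.

    A connected 3-D network must show exactly six eigenvalues below
    ``ZERO_MODE_REL_THRESHOLD × λ_max`` (three translations, three
    rotations); collinear bead geometries have five (rotation about the
    axis is not a motion).  Any other count indicates disconnection or a
    threshold problem and is refused.
    """
    if not network.connected:
        raise ValueError(
            "elastic network is disconnected; normal modes undefined "
            "(increase the cutoff or split the components)")
    centred = network.beads - network.beads.mean(0)
    rank = np.linalg.matrix_rank(centred, tol=1e-8)
    expected_zero = 6 if rank >= 2 else 5
    H = hessian(network)
    evals, evecs = scipy.linalg.eigh(H)
    thresh = ZERO_MODE_REL_THRESHOLD * max(evals[-1], 1e-300)
    n_zero = int((evals < thresh).sum())
    if n_zero != expected_zero:
        raise ValueError(
            f"expected {expected_zero} rigid-body modes, found {n_zero} "
            f"(threshold {thresh:.3e}); check connectivity/geometry")
    evals = evals[n_zero:]
    evecs = evecs[:, n_zero:]
    if n_modes is not None:
        evals = evals[:n_modes]
        evecs = evecs[:, :n_modes]
    return ModeSet(eigenvalues=evals, eigenvectors=evecs, n_zero=n_zero,
                   n_beads=network.n_beads,
                   res_numbers=network.res_numbers)


def _check_mode_range(modes: ModeSet,
                      mode_range: tuple[int, int] | None) -> tuple[int, int]:
    if mode_range is None:
        mode_range = (0, modes.n_modes)
    lo, hi = mode_range
    if not (0 <= lo < hi <= modes.n_modes):
        raise ValueError(
            f"mode_range {mode_range} outside available modes "
            f"[0, {modes.n_modes})")
    return lo, hi


def mode_fluctuations(modes: ModeSet,
                      mode_range: tuple[int, int] | None = None
                      ) -> FlexibilityProfile:
    """Per-residue MSF(i) ∝ Σ_k |u_k(i)|² / λ_k over the mode range.

    Over the full non-rigid range this equals the residue-block trace of the
    Hessian pseudo-inverse (up to the global 3 k_B T / γ prefactor, which is
    omitted — profiles are reported up to a constant).
    """
    lo, hi = _check_mode_range(modes, mode_range)
    blocks = modes.eigenvectors[:, lo:hi].reshape(modes.n_beads, 3, hi - lo)
    msf = np.einsum("iak,iak,k->i", blocks, blocks,
                    1.0 / modes.eigenvalues[lo:hi])
    return FlexibilityProfile(msf=msf, mode_range=(lo, hi),
                              res_numbers=modes.res_numbers)


def mode_overlap(modes: ModeSet, displacement: np.ndarray) -> np.ndarray:
    """|u_k · d| / |d| per mode, for a 3N displacement d.

    Over any orthonormal subset the squared overlaps sum to at most 1.
    """
    d = np.asarray(displacement, dtype=float).ravel()
    if d.shape[0] != 3 * modes.n_beads:
        raise ValueError(
            f"displacement length {d.shape[0]} != 3N = {3 * modes.n_beads}")
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("zero displacement vector")
    return np.abs(modes.eigenvectors.T @ d) / norm


def coupling_matrix(modes: ModeSet,
                    mode_range: tuple[int, int] | None = (0, 20)
                    ) -> CouplingMatrix:
    """Normalised residue-residue coupling over the chosen mode range.

    C(i,j) = Σ_k u_k(i)·u_k(j)/λ_k;  A(i,j) = |C(i,j)|/sqrt(C(i,i)C(j,j)).
    """
    if mode_range is not None:
        lo, hi = mode_range
        hi = min(hi, modes.n_modes)
        mode_range = (lo, hi)
    lo, hi = _check_mode_range(modes, mode_range)
    blocks = modes.eigenvectors[:, lo:hi].reshape(modes.n_beads, 3, hi - lo)
    w = 1.0 / modes.eigenvalues[lo:hi]
    C = np.einsum("iak,jak,k->ij", blocks, blocks, w, optimize=True)
    diag = np.diag(C).copy()
    if (diag <= 0).any():
        bad = np.nonzero(diag <= 0)[0]
        raise ValueError(
            f"residues decoupled in mode range {mode_range}: "
            f"indices {bad.tolist()}")
    A = np.abs(C) / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(A, 1.0)
    return CouplingMatrix(A=A, mode_range=(lo, hi),
                          res_numbers=modes.res_numbers)


def coupling_to_region(coupling: CouplingMatrix,
                       region: set[int] | np.ndarray,
                       aggregate: str = "mean") -> np.ndarray:
    """Coupling of every residue outside ``region`` to the region.

    ``region`` is a set of residue numbers when the coupling matrix carries
    residue numbering, else a set of bead indices.  Returns a structured
    array of (residue, coupling) pairs ordered as in the matrix, with
    region members assigned NaN.
    """
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    n = coupling.A.shape[0]
    numbers = (coupling.res_numbers if coupling.res_numbers is not None
               else np.arange(n))
    in_region = np.isin(numbers, list(region))
    if not in_region.any():
        raise ValueError("region has no residues in the coupling matrix")
    sub = coupling.A[:, in_region]
    profile = sub.mean(axis=1) if aggregate == "mean" else sub.max(axis=1)
    profile = profile.astype(float)
    profile[in_region] = np.nan
    out = np.empty(n, dtype=[("residue", int), ("coupling", float)])
    out["residue"] = numbers
    out["coupling"] = profile
    return out
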