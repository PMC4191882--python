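"""Molecular structures: PDB I/O, residue selection and native contact maps.

Coordinates are kept in Å throughout (the native PDB unit); any nm conversion
happens only at reporting boundaries.  Residue numbering is taken verbatim
from the file; insertion codes are part of the residue key and only the first
alternate location of a disordered atom is kept, so parsing is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

__all__ = [
    "Structure",
    "RegionAnnotation",
    "ContactMap",
    "parse_pdb",
    "write_pdb",
    "select_calpha",
    "map_common_residues",
    "compute_contact_map",
    "DEFAULT_REGIONS",
]


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclass
class Structure:
    """A parsed molecular model: per-atom metadata plus one or more frames.

    ``coords`` has shape ``(n_models, n_atoms, 3)`` in Å.  All models share
    the atom list; this is validated at construction.
    """

    atom_names: np.ndarray          # (n_atoms,) str
    elements: np.ndarray            # (n_atoms,) str
    res_numbers: np.ndarray         # (n_atoms,) int
    icodes: np.ndarray              # (n_atoms,) str ('' if none)
    res_names: np.ndarray           # (n_atoms,) str
    chain_ids: np.ndarray           # (n_atoms,) str
    coords: np.ndarray              # (n_models, n_atoms, 3) float, Å
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        n = len(self.atom_names)
        for name in ("elements", "res_numbers", "icodes", "res_names",
                     "chain_ids"):
            if len(getattr(self, name)) != n:
                raise StructureError(f"{name} length mismatch: expected {n}")
        if self.coords.shape[1:] != (n, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{n} atoms")

    # -- basic queries -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def xyz(self) -> np.ndarray:
        """Coordinates of the first model, shape (n_atoms, 3)."""
        return self.coords[0]

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Per-atom (chain, residue number, insertion code) keys."""
        return list(zip(self.chain_ids, (int(r) for r in self.res_numbers),
                        self.icodes))

    def unique_residues(self) -> list[tuple[str, int, str]]:
        """Residue keys in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for key in self.residue_keys():
            seen.setdefault(key, None)
        return list(seen)

    def subset(self, index: np.ndarray) -> "Structure":
        """New Structure restricted to the given atom indices (all models)."""
        index = np.asarray(index)
        return Structure(
            atom_names=self.atom_names[index],
            elements=self.elements[index],
            res_numbers=self.res_numbers[index],
            icodes=self.icodes[index],
            res_names=self.res_names[index],
            chain_ids=self.chain_ids[index],
            coords=self.coords[:, index],
            title=self.title,
        )


@dataclass
class RegionAnnotation:
    """Named residue regions (e.g. ``P-loop``, ``alphaC``, ``A-loop``).

    ``regions`` maps a unique name to a non-empty set of residue numbers.
    Region definitions are deliberately config-supplied: numbering schemes
    differ between isoforms and constructs.
    """

    regions: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, residues in self.regions.items():
            if not residues:
                raise StructureError(f"region {name!r} is empty")
            self.regions[name] = set(int(r) for r in residues)

    def __getitem__(self, name: str) -> set[int]:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RegionAnnotation":
        """Build from a plain dict, expanding ``[lo, hi]`` range pairs."""
        regions = {}
        for name, value in mapping.items():
            if (isinstance(value, (list, tuple)) and len(value) == 2
                    and all(isinstance(v, int) for v in value)
                    and value[0] < value[1] - 1):
                regions[name] = set(range(value[0], value[1] + 1))
            else:
                regions[name] = set(value)
        return cls(regions)


# Approximate default regions for the Abl kinase domain, isoform Ib
# numbering (anchored on K290/E294/M297/V299/E305, the P328/P329/F330
# β4-β5 strand, the Y339/G340 hinge, Y412 in the A-loop and Y530).  Real
# analyses should supply their own annotation; these are sensible defaults
# for that numbering scheme only.
DEFAULT_REGIONS = {
    "P-loop": [268, 276],
    "beta3-alphaC-loop": [291, 298],
    "alphaC": [299, 312],
    "hinge": [337, 342],
    "A-loop": [398, 424],
    "SH2": [140, 236],
}


@dataclass
class ContactMap:
    """Native contacts of a Cα structure.

    ``i``/``j`` are bead indices (i < j, ``j - i >= min_seq_sep``), ``r0``
    the native distance in Å (``r0 <= cutoff`` for every pair).
    """

    i: np.ndarray
    j: np.ndarray
    r0: np.ndarray
    cutoff: float
    min_seq_sep: int

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.r0 = np.asarray(self.r0, dtype=float)
        if not (self.i < self.j).all():
            raise StructureError("contact pairs must satisfy i < j")
        if (self.r0 > self.cutoff + 1e-9).any():
            raise StructureError("contact r0 exceeds cutoff")

    def __len__(self) -> int:
        return len(self.i)

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def parse_pdb(path, chain_filter: str | None = None,
              model_index: int | None = None) -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM/HETATM record.
    chain_filter:
        If given, keep only atoms whose chain id is in this string
        (e.g. ``"B"`` or ``"AB"``).
    model_index:
        If given, keep only this 0-based model; otherwise all models are
        retained and must agree in atom count and ordering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_struct = parser.get_structure(path.stem, str(path))

    models = list(bio_struct.get_models())
    if model_index is not None:
        if not 0 <= model_index < len(models):
            raise StructureError(
                f"model_index {model_index} out of range "
                f"(file has {len(models)} models)")
        models = [models[model_index]]
    if not models:
        raise StructureError(f"no models in {path}")

    def atom_records(model):
        for chain in model:
            if chain_filter is not None and chain.id not in chain_filter:
                continue
            for residue in chain:
                het, resseq, icode = residue.id
                for atom in residue:
                    if isinstance(atom, DisorderedAtom):
                        # deterministic: keep first altloc by id
                        alts = sorted(atom.disordered_get_id_list())
                        atom = atom.disordered_get(alts[0])
                    yield (atom.get_name(),
                           (atom.element or "").strip(),
                           int(resseq), icode.strip(), residue.resname.strip(),
                           chain.id, atom.get_coord())

    first = list(atom_records(models[0]))
    if not first:
        raise StructureError(
            f"no atoms selected from {path} "
            f"(chain_filter={chain_filter!r})")

    meta = [rec[:6] for rec in first]
    frames = [np.array([rec[6] for rec in first], dtype=float)]
    for k, model in enumerate(models[1:], start=1):
        recs = list(atom_records(model))
        if [r[:6] for r in recs] != meta:
            raise StructureError(
                f"model {k} of {path} has inconsistent atoms "
                f"({len(recs)} vs {len(first)})")
        frames.append(np.array([r[6] for r in recs], dtype=float))

    names, elements, resnums, icodes, resnames, chains = map(
        np.array, zip(*meta))
    return Structure(
        atom_names=names, elements=elements,
        res_numbers=resnums.astype(int), icodes=icodes,
        res_names=resnames, chain_ids=chains,
        coords=np.stack(frames), title=path.stem,
    )


def write_pdb(structure: Structure, path) -> None:
    """Write all models of a Structure as a standard multi-model PDB file."""
    path = Path(path)
    multi = structure.n_models > 1
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title[:60]}\n")
        for m in range(structure.n_models):
            if multi:
                fh.write(f"MODEL     {m + 1:4d}\n")
            for a in range(structure.n_atoms):
                name = structure.atom_names[a]
                # PDB column convention: 1-3 char names start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = structure.coords[m, a]
                fh.write(
                    "ATOM  {serial:5d} {name:<4s}{alt}{res:<3s} {ch}"
                    "{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    "{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=(a + 1) % 100000, name=name_field, alt=" ",
                        res=structure.res_names[a][:3],
                        ch=(structure.chain_ids[a] or "A")[:1],
                        resseq=int(structure.res_numbers[a]),
                        icode=(structure.icodes[a] or " ")[:1],
                        x=x, y=y, z=z, occ=1.0, b=0.0,
                        el=structure.elements[a][:2]))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# selections and mappings
# ---------------------------------------------------------------------------

def select_calpha(structure: Structure,
                  residues: set[int] | None = None) -> Structure:
    """Reduce to one Cα bead per residue, ordered by (chain, residue number).

    Raises if a requested residue has no Cα or more than one.
    """
    is_ca = structure.atom_names == "CA"
    keys = structure.residue_keys()

    wanted: dict[tuple[str, int, str], list[int]] = {}
    for idx in np.nonzero(is_ca)[0]:
        key = keys[idx]
        if residues is not None and key[1] not in residues:
            continue
        wanted.setdefault(key, []).append(int(idx))

    if residues is not None:
        present = {k[1] for k in keys}
        have_ca = {k[1] for k in wanted}
        missing = sorted((set(residues) & present) - have_ca)
        if missing:
            raise StructureError(
                f"residues lacking a CA atom: {missing}")
    dupes = sorted({k[1] for k, v in wanted.items() if len(v) > 1})
    if dupes:
        raise StructureError(f"residues with multiple CA atoms: {dupes}")
    if not wanted:
        raise StructureError("no CA atoms selected")

    order = sorted(wanted, key=lambda k: (k[0], k[1], k[2]))
    index = np.array([wanted[k][0] for k in order], dtype=int)
    return structure.subset(index)


def map_common_residues(a: Structure, b: Structure) -> list[tuple[int, int]]:
    """Index pairs of beads sharing (chain, residue number, icode).

    Both inputs must be one-bead-per-residue (e.g. from
    :func:`select_calpha`).  Unmatched residues are dropped; the mapping is
    ordered by position in ``a``.
    """
    keys_a = a.residue_keys()
    keys_b = b.residue_keys()
    pos_b = {key: idx for idx, key in enumerate(keys_b)}
    if len(pos_b) != len(keys_b):
        raise StructureError("structure b has duplicate residue keys")
    pairs = [(ia, pos_b[key]) for ia, key in enumerate(keys_a)
             if key in pos_b]
    if not pairs:
        raise StructureError("no common residues between the two structures")
    return pairs


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def compute_contact_map(structure: Structure, cutoff: float = 8.0,
                        min_seq_sep: int = 3) -> ContactMap:
    """All Cα pairs with sequence separation ≥ ``min_seq_sep`` and distance
    ≤ ``cutoff`` Å in the first model; ``r0`` is the observed distance.

    The sequence-separation filter applies within a chain only: pairs from
    different chains are always eligible (they have no covalent
    connectivity), which is what a native contact map of a multi-domain
    assembly needs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_seq_sep < 1:
        raise ValueError("min_seq_sep must be >= 1")
    xyz = structure.xyz
    n = len(xyz)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    ii, jj = np.triu_indices(n, k=1)
    same_chain = structure.chain_ids[ii] == structure.chain_ids[jj]
    sep_ok = (jj - ii >= min_seq_sep) | ~same_chain
    keep = sep_ok & (dist[ii, jj] <= cutoff)
    return ContactMap(i=ii[keep], j=jj[keep], r0=dist[ii, jj][keep],
                      cutoff=cutoff, min_seq_sep=min_seq_sep)
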