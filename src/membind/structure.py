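"""Minimal rigid structure container with PDB read/write via gemmi."""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import MissingAtomError


@dataclass
class StructureModel:
    """Rigid point-set of atoms indexed by (residue number, atom name).

    coords is an (n_atoms, 3) array in angstroms; ``index`` maps
    (residue, atom name) to the row in ``coords``. Residue numbers are
    integers; atom names are PDB-style strings ("CA", "CB", ...).
    """

    coords: np.ndarray
    index: dict[tuple[int, str], int]
    residue_names: dict[int, str] = field(default_factory=dict)
    chain: str = "A"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.index) != len(self.coords):
            raise ValueError("index does not cover coords")

    # -- accessors ---------------------------------------------------------
    def atom(self, residue: int, name: str) -> np.ndarray:
        try:
            return self.coords[self.index[(residue, name)]]
        except KeyError:
            raise MissingAtomError(f"residue {residue} has no atom {name!r}") from None

    def has_atom(self, residue: int, name: str) -> bool:
        return (residue, name) in self.index

    @property
    def residues(self) -> list[int]:
        return sorted({r for r, _ in self.index})

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates rotation @ x + translation."""
        new = self.coords @ np.asarray(rotation, dtype=float).T + np.asarray(translation, dtype=float)
        return StructureModel(coords=new, index=dict(self.index),
                              residue_names=dict(self.residue_names), chain=self.chain)

    def radius_of_gyration(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c ** 2).sum(axis=1).mean()))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_atoms(cls, atoms) -> "StructureModel":
        """Build from an iterable of (residue:int, atom_name:str, xyz) records."""
        coords, index, names = [], {}, {}
        for i, (res, name, xyz) in enumerate(atoms):
            key = (int(res), str(name))
            if key in index:
                raise ValueError(f"duplicate atom {key}")
            index[key] = i
            coords.append(np.asarray(xyz, dtype=float))
            names.setdefault(int(res), "ALA")
        return cls(coords=np.array(coords), index=index, residue_names=names)


def read_structure(path, model: int = 1) -> StructureModel:
    """Read the given model (1-based) of a PDB file into a StructureModel.

    Only ATOM/HETATM coordinate records are consumed; the first altloc of
    each atom wins.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if not 1 <= model <= len(st):
        raise ValueError(f"model {model} out of range (file has {len(st)})")
    mdl = st[model - 1]
    coords, index, names = [], {}, {}
    chain_name = "A"
    for chain in mdl:
        chain_name = chain.name or "A"
        for res in chain:
            rnum = res.seqid.num
            names[rnum] = res.name
            for atom in res:
                key = (rnum, atom.name)
                if key in index:
                    continue
                index[key] = len(coords)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # single-chain convention
    if not coords:
        raise ValueError(f"no atoms read from {path}")
    return StructureModel(coords=np.array(coords), index=index,
                          residue_names=names, chain=chain_name)


def write_structure(model: StructureModel, path, remarks: list[str] | None = None) -> None:
    """Write a StructureModel as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = "membind"
    mdl = gemmi.Model("1")
    chain = gemmi.Chain(model.chain)
    for rnum in model.residues:
        res = gemmi.Residue()
        res.name = model.residue_names.get(rnum, "ALA")
        res.seqid = gemmi.SeqId(rnum, " ")
        for (r, aname), i in sorted(model.index.items(), key=lambda kv: kv[1]):
            if r != rnum:
                continue
            at = gemmi.Atom()
            at.name = aname
            at.element = gemmi.Element(aname[:1])
            x, y, z = model.coords[i]
            at.pos = gemmi.Position(x, y, z)
            res.add_atom(at)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    doc = st.make_pdb_string()
    text = ""
    if remarks:
        text = "".join(f"REMARK 999 {r}\n" for r in remarks)
    with open(path, "w") as fh:
        fh.write(text + doc)
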