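"""Reading, writing and selecting macromolecular structures.

Structures are held as a flat, ordered list of :class:`Atom` records — one
model at a time — which keeps every downstream geometric operation a plain
array computation.  Parsing of PDB and mmCIF files is delegated to ``gemmi``;
this module fixes the policies the analyses rely on:

* alternate locations are resolved to a single conformer (highest occupancy,
  ties broken in favour of altloc ``A``),
* waters and other heteroatoms are retained but flagged, so that contact
  detection can use them while superposition selections exclude them,
* residues are addressed by author numbering (rabbit SERCA1a numbering for
  the structures this package was written around), 1-based, inclusive ranges.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Selection",
    "PairingReport",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "select",
    "pair_common_atoms",
    "MAIN_CHAIN_ATOMS",
]

#: Backbone atom names used whenever an analysis asks for "main chain" atoms.
#: The carbonyl oxygen is included by default; pass ``atom_set="CA"`` to the
#: comparison routines for a Cα-only variant.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O"})

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be read or a model is missing."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom record of one model.

    ``hetero`` marks HETATM records (ligands, ions, waters); ``is_water``
    additionally marks solvent by residue name.
    """

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    element: str
    hetero: bool = False

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    def key(self) -> tuple:
        """Identity of the atom across structures: (chain, resseq, icode, name)."""
        return (self.chain, self.resseq, self.icode, self.name)

    def residue_key(self) -> tuple:
        return (self.chain, self.resseq, self.icode)


@dataclasses.dataclass
class Structure:
    """An ordered collection of atoms from a single model."""

    atoms: list[Atom]
    model_index: int = 0
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) array of coordinates in Å, in atom order."""
        out = np.empty((len(self.atoms), 3), dtype=float)
        for i, a in enumerate(self.atoms):
            out[i, 0], out[i, 1], out[i, 2] = a.x, a.y, a.z
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with every coordinate replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            dataclasses.replace(a, x=float(c[0]), y=float(c[1]), z=float(c[2]))
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms=atoms, model_index=self.model_index, source_id=self.source_id)

    def atom(self, chain: str, resseq: int, name: str, icode: str = "") -> Atom:
        """Look up a single atom; raises KeyError naming the residue if absent."""
        for a in self.atoms:
            if (a.chain == chain and a.resseq == resseq and a.icode == icode
                    and a.name == name):
                return a
        raise KeyError(
            f"atom {name!r} of residue {chain}/{resseq}{icode} not found in "
            f"{self.source_id or 'structure'}"
        )

    def find_atom(self, resseq: int, name: str, chain: Optional[str] = None) -> Atom:
        """Look up an atom by residue number and name, in any chain if unspecified."""
        for a in self.atoms:
            if a.resseq == resseq and a.name == name and (chain is None or a.chain == chain):
                return a
        where = f"chain {chain}" if chain else "any chain"
        raise KeyError(f"atom {name!r} of residue {resseq} ({where}) not found")

    def residues(self) -> list[tuple]:
        """Ordered unique residue keys (chain, resseq, icode)."""
        seen: dict = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key(), None)
        return list(seen)

    def has_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)


@dataclasses.dataclass(frozen=True)
class Selection:
    """Declarative atom filter.

    An empty selection (all fields ``None``) matches every non-hetero atom;
    set ``heteroatoms=True`` to include ligands and waters.  Residue ranges
    are inclusive on both ends and use author numbering.
    """

    chains: Optional[frozenset[str]] = None
    residue_ranges: Optional[tuple[tuple[int, int], ...]] = None
    atom_names: Optional[frozenset[str]] = None
    heteroatoms: bool = False

    def __post_init__(self):
        if self.residue_ranges is not None:
            for start, end in self.residue_ranges:
                if start > end:
                    raise ValueError(f"residue range {start}-{end} has start > end")

    def matches(self, atom: Atom) -> bool:
        if atom.hetero and not self.heteroatoms:
            return False
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.residue_ranges is not None:
            if not any(s <= atom.resseq <= e for s, e in self.residue_ranges):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True

    def with_atom_names(self, names: Iterable[str]) -> "Selection":
        return dataclasses.replace(self, atom_names=frozenset(names))

    def union(self, other: "Selection") -> "Selection":
        """Union of two residue-range selections (chains/atom names must agree)."""
        if self.chains != other.chains or self.atom_names != other.atom_names:
            raise ValueError("can only union selections with identical chain/atom filters")
        ranges = tuple(sorted((self.residue_ranges or ()) + (other.residue_ranges or ())))
        return dataclasses.replace(self, residue_ranges=ranges)

    @staticmethod
    def from_ranges(*ranges: tuple[int, int], chains: Optional[Iterable[str]] = None,
                    atom_names: Optional[Iterable[str]] = None) -> "Selection":
        return Selection(
            chains=frozenset(chains) if chains is not None else None,
            residue_ranges=tuple((int(s), int(e)) for s, e in ranges),
            atom_names=frozenset(atom_names) if atom_names is not None else None,
        )


@dataclasses.dataclass
class PairingReport:
    """Bookkeeping of an atom pairing between two structures."""

    n_paired: int
    dropped_a: list[tuple]
    dropped_b: list[tuple]


# ---------------------------------------------------------------------------
# Reading / writing


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom site: highest occupancy, tie -> altloc 'A'."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        k = a.key()
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            # Higher occupancy wins; on a tie the lexicographically smaller
            # altloc (i.e. 'A') wins.
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                best[k] = a
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # '' sorts above any letter; otherwise 'A' is preferred over 'B', etc.
    if altloc == "":
        return 0.0
    return -ord(altloc)


def read_structure(path, format: str = "auto", model_index: int = 0) -> Structure:
    """Read one model of a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension/content).
    model_index:
        0-based index into the file's models.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path} contains no models")
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range: {path} has {len(st)} model(s)"
        )
    st.setup_entities()
    model = st[model_index]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        altloc=at.altloc if at.altloc != "\0" else "",
                        resname=res.name,
                        chain=chain.name,
                        resseq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        occupancy=at.occ,
                        element=at.element.name,
                        hetero=het,
                    )
                )
    atoms = _resolve_altlocs(atoms)
    atoms.sort(key=lambda a: (a.chain, a.resseq, a.icode, a.serial))
    if not atoms:
        raise StructureParseError(f"{path} model {model_index} contains no atoms")
    return Structure(atoms=atoms, model_index=model_index, source_id=path.stem.upper())


def write_structure(structure: Structure, path) -> None:
    """Write a structure as a single-model PDB file (via gemmi)."""
    st = to_gemmi(structure)
    st.write_pdb(str(path))


def to_gemmi(structure: Structure) -> gemmi.Structure:
    """Convert to a gemmi.Structure (one model)."""
    st = gemmi.Structure()
    st.name = structure.source_id or "pumpgeom"
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    current_res: dict[str, tuple] = {}
    for a in structure.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
            current_res[a.chain] = None
        chain = chains[a.chain]
        rkey = (a.resseq, a.icode, a.resname)
        if current_res[a.chain] != rkey:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resseq, a.icode or " ")
            res.het_flag = "H" if a.hetero else "A"
            chain.add_residue(res)
            current_res[a.chain] = rkey
        res = chain[len(chain) - 1]
        at = gemmi.Atom()
        at.name = a.name
        at.altloc = a.altloc or "\0"
        at.pos = gemmi.Position(a.x, a.y, a.z)
        at.occ = a.occupancy
        at.serial = a.serial
        at.element = gemmi.Element(a.element)
        res.add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


# ---------------------------------------------------------------------------
# Selection and pairing


def select(structure: Structure, sel: Selection) -> Structure:
    """Subset of ``structure`` matching ``sel``, preserving atom order.

    Idempotent; an empty result is returned as an empty structure, never an
    error.
    """
    atoms = [a for a in structure.atoms if sel.matches(a)]
    return Structure(atoms=atoms, model_index=structure.model_index,
                     source_id=structure.source_id)


def pair_common_atoms(
    a: Structure, b: Structure
) -> tuple[np.ndarray, np.ndarray, PairingReport]:
    """Pair atoms present in both structures under (chain, resseq, icode, name).

    Returns coordinate arrays of equal length (ordered as in ``a``) and a
    report of atoms dropped from each side.  Raises ``ValueError`` if the two
    structures share no atoms.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot pair atoms of an empty structure")
    index_b = {atom.key(): atom for atom in b.atoms}
    keys_a = {atom.key() for atom in a.atoms}
    coords_a, coords_b = [], []
    dropped_a = []
    for atom in a.atoms:
        other = index_b.get(atom.key())
        if other is None:
            dropped_a.append(atom.key())
        else:
            coords_a.append((atom.x, atom.y, atom.z))
            coords_b.append((other.x, other.y, other.z))
    dropped_b = [k for k in index_b if k not in keys_a]
    if not coords_a:
        raise ValueError(
            f"no common atoms between {a.source_id or 'A'} and {b.source_id or 'B'}"
        )
    report = PairingReport(n_paired=len(coords_a), dropped_a=dropped_a, dropped_b=dropped_b)
    return np.array(coords_a), np.array(coords_b), report


def parse_selection_expr(expr: str) -> Selection:
    """Parse a compact selection expression.

    Grammar (clauses joined by ``and``): ``chain A[,B]``,
    ``resi 750-994[,337-344]``, ``name N,CA,C,O``, ``hetero``.
    """
    chains = None
    ranges = None
    names = None
    hetero = False
    for clause in expr.split(" and "):
        clause = clause.strip()
        if not clause:
            continue
        if clause.startswith("chain "):
            chains = frozenset(c.strip() for c in clause[6:].split(","))
        elif clause.startswith("resi "):
            parsed = []
            for part in clause[5:].split(","):
                part = part.strip()
                if "-" in part[1:]:
                    lo, hi = part.rsplit("-", 1)
                    parsed.append((int(lo), int(hi)))
                else:
                    parsed.append((int(part), int(part)))
            ranges = tuple(parsed)
        elif clause.startswith("name "):
            names = frozenset(n.strip().upper() for n in clause[5:].split(","))
        elif clause == "hetero":
            hetero = True
        else:
            raise ValueError(f"cannot parse selection clause {clause!r}")
    return Selection(chains=chains, residue_ranges=ranges, atom_names=names,
                     heteroatoms=hetero)
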