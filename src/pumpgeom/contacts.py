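"""Polar-contact and hydrogen-bond detection between atom groups.

Two criteria are supported, matching the two kinds of input this package
sees:

* crystal structures without hydrogens — a heavy-atom distance criterion:
  any N/O (or S as acceptor) pair across the two groups within a cutoff
  (default 3.5 Å) counts as a polar contact;
* MD frames with explicit hydrogens — a geometric hydrogen-bond criterion:
  D–H···A with H···A ≤ 2.5 Å and angle(D–H···A) ≥ 120°.

Optionally, contacts bridged by a single water molecule are reported: both
donor–water and water–acceptor legs must satisfy the heavy-atom cutoff.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Selection, Structure, select

__all__ = [
    "ContactCriterion",
    "ContactPair",
    "find_polar_contacts",
    "count_hbonds",
]

POLAR_ELEMENTS = frozenset({"N", "O", "S"})
#: Sulfur is accepted only as an acceptor, never as a donor.
DONOR_ELEMENTS = frozenset({"N", "O"})
_COVALENT_H_CUTOFF = 1.25  # Å, D–H bond detection


@dataclasses.dataclass(frozen=True)
class ContactCriterion:
    """Geometric criterion for a polar contact / hydrogen bond."""

    heavy_cutoff: float = 3.5          # Å, donor–acceptor heavy-atom distance
    h_acceptor_cutoff: float = 2.5     # Å, H···A distance (H-aware mode)
    dha_angle_min: float = 120.0       # degrees, D–H···A angle (H-aware mode)

    def __post_init__(self):
        if self.heavy_cutoff <= 0 or self.h_acceptor_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.dha_angle_min <= 180:
            raise ValueError("D–H···A angle threshold must be in (0, 180]")


@dataclasses.dataclass(frozen=True)
class ContactPair:
    """One polar contact; atoms identified by (chain, resseq, icode, name)."""

    atom_a: tuple
    atom_b: tuple
    distance: float           # direct heavy-atom distance, Å
    water_mediated: bool = False
    water: Optional[tuple] = None
    leg_a: Optional[float] = None  # Å, A–water (water-mediated only)
    leg_b: Optional[float] = None  # Å, water–B


def _polar_atoms(s: Structure, sel: Selection) -> list:
    sub = select(s, sel)
    return [a for a in sub.atoms if a.element in POLAR_ELEMENTS and not a.is_water]


def find_polar_contacts(
    s: Structure,
    group_a: Selection,
    group_b: Selection,
    crit: ContactCriterion = ContactCriterion(),
    allow_water_bridge: bool = False,
) -> list[ContactPair]:
    """All polar heavy-atom contacts between two groups, optionally via water.

    Pairs within ``crit.heavy_cutoff`` are returned sorted by the identity of
    the first atom.  With ``allow_water_bridge``, single-water bridges in which
    both legs satisfy the cutoff are appended, flagged, regardless of the
    direct distance of the bridged pair.
    """
    atoms_a = _polar_atoms(s, group_a)
    atoms_b = _polar_atoms(s, group_b)
    contacts: list[ContactPair] = []
    if atoms_a and atoms_b:
        xyz_a = np.array([a.pos for a in atoms_a])
        xyz_b = np.array([b.pos for b in atoms_b])
        tree_b = cKDTree(xyz_b)
        for i, lists in enumerate(tree_b.query_ball_point(xyz_a, crit.heavy_cutoff)):
            for j in lists:
                a, b = atoms_a[i], atoms_b[j]
                if a.key() == b.key():
                    continue
                d = float(np.linalg.norm(a.pos - b.pos))
                contacts.append(ContactPair(atom_a=a.key(), atom_b=b.key(), distance=d))
    if allow_water_bridge and atoms_a and atoms_b:
        waters = [a for a in s.atoms if a.is_water and a.element == "O"]
        if waters:
            xyz_w = np.array([w.pos for w in waters])
            tree_w = cKDTree(xyz_w)
            near_a = tree_w.query_ball_point(np.array([a.pos for a in atoms_a]),
                                             crit.heavy_cutoff)
            near_b = tree_w.query_ball_point(np.array([b.pos for b in atoms_b]),
                                             crit.heavy_cutoff)
            by_water_b: dict[int, list[int]] = {}
            for j, ws in enumerate(near_b):
                for w in ws:
                    by_water_b.setdefault(w, []).append(j)
            for i, ws in enumerate(near_a):
                for w in ws:
                    for j in by_water_b.get(w, ()):
                        a, b, wat = atoms_a[i], atoms_b[j], waters[w]
                        if a.key() == b.key():
                            continue
                        contacts.append(ContactPair(
                            atom_a=a.key(), atom_b=b.key(),
                            distance=float(np.linalg.norm(a.pos - b.pos)),
                            water_mediated=True, water=wat.key(),
                            leg_a=float(np.linalg.norm(a.pos - wat.pos)),
                            leg_b=float(np.linalg.norm(b.pos - wat.pos)),
                        ))
    contacts.sort(key=lambda c: (c.atom_a, c.atom_b, c.water_mediated))
    return contacts


def _bonded_hydrogens(s: Structure) -> dict[tuple, list]:
    """Map heavy-atom key -> hydrogens covalently bonded to it (same residue)."""
    hydro = [a for a in s.atoms if a.element == "H"]
    heavy = [a for a in s.atoms if a.element in DONOR_ELEMENTS]
    out: dict[tuple, list] = {}
    if not hydro or not heavy:
        return out
    tree_h = cKDTree(np.array([h.pos for h in hydro]))
    for a in heavy:
        for idx in tree_h.query_ball_point(a.pos, _COVALENT_H_CUTOFF):
            h = hydro[idx]
            if h.residue_key() == a.residue_key():
                out.setdefault(a.key(), []).append(h)
    return out


def count_hbonds(
    frame: Structure,
    group_a: Selection,
    group_b: Selection,
    crit: ContactCriterion = ContactCriterion(),
) -> int:
    """Number of distinct donor–acceptor hydrogen bonds between two groups.

    If the frame carries explicit hydrogens the geometric D–H···A criterion
    is applied in both directions (A donating to B and vice versa); each
    donor–acceptor pair is counted once even if two hydrogens satisfy the
    criterion.  Without hydrogens the heavy-atom distance criterion of
    :func:`find_polar_contacts` is used as a fallback.
    """
    from .geometry_core import point_angle

    if not frame.has_hydrogens():
        pairs = find_polar_contacts(frame, group_a, group_b, crit)
        return len({frozenset((c.atom_a, c.atom_b)) for c in pairs})

    h_of = _bonded_hydrogens(frame)
    bonds: set[frozenset] = set()
    for donors_sel, acceptors_sel in ((group_a, group_b), (group_b, group_a)):
        donors = [a for a in _polar_atoms(frame, donors_sel) if a.key() in h_of]
        acceptors = _polar_atoms(frame, acceptors_sel)
        if not donors or not acceptors:
            continue
        tree_acc = cKDTree(np.array([a.pos for a in acceptors]))
        for d in donors:
            for h in h_of[d.key()]:
                for idx in tree_acc.query_ball_point(h.pos, crit.h_acceptor_cutoff):
                    acc = acceptors[idx]
                    if acc.key() == d.key() or acc.residue_key() == d.residue_key():
                        continue
                    if point_angle(d.pos, h.pos, acc.pos) >= crit.dha_angle_min:
                        bonds.add(frozenset((d.key(), acc.key())))
    return len(bonds)
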