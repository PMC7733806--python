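"""Least-squares superposition and scalar geometric observables.

The central operation is the Kabsch superposition: the closed-form rigid-body
fit that minimises the RMSD between two paired point sets.  On top of it sit
the comparisons used to contrast two conformations of the same pump:

* :func:`compare_structures` — fit once on a named segment, then report the
  RMSD of any number of other segments *in that fitted frame* (no refitting),
  which is what makes statements like "M1–M4 deviates by 0.56 Å after fitting
  on M5–M10" meaningful;
* triplet angles between Cα atoms (headpiece inclination, M1 kink);
* named inter-residue distances;
* the in-line phosphoryl-transfer geometry at the catalytic aspartate.

All observables are invariant under a common rigid transform of the input —
a property the test suite exercises.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .segments import SegmentRegistry, default_registry
from .structure_io import (
    MAIN_CHAIN_ATOMS,
    Atom,
    Selection,
    Structure,
    pair_common_atoms,
    select,
)

__all__ = [
    "Transform",
    "DomainRmsdReport",
    "CatalyticGeometry",
    "kabsch_superpose",
    "rmsd",
    "compare_structures",
    "point_angle",
    "residue_triplet_angle",
    "residue_pair_distance",
    "catalytic_geometry",
]


@dataclasses.dataclass
class Transform:
    """Rigid-body transform ``y ≈ R @ x + t`` from a least-squares fit."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    fit_rmsd: float
    n_fit_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))


@dataclasses.dataclass
class DomainRmsdReport:
    """Per-segment RMSDs evaluated in a single fitted frame."""

    fit_segment: str
    atom_set: str
    transform: Transform
    segments: dict[str, tuple[float, int]]  # name -> (rmsd Å, n_atoms)
    errors: dict[str, str] = dataclasses.field(default_factory=dict)

    def rmsd(self, name: str) -> float:
        return self.segments[name][0]


@dataclasses.dataclass
class CatalyticGeometry:
    """In-line phosphoryl-transfer geometry at the catalytic aspartate.

    ``d_od_pg`` is the distance from the closer carboxyl oxygen (Oδ) of the
    aspartate to the γ-phosphorus analogue (Pγ of ATP/AMPPCP, or Al of an
    AlF₄⁻ transition-state mimic); ``theta_deg`` is the angle at that
    analogue between Oδ and the bridging atom of the terminal
    phosphoanhydride bond.  A perfectly in-line associative geometry gives
    θ = 180°.
    """

    d_od_pg: float
    theta_deg: float
    od_atom: tuple
    pg_atom: tuple
    bridge_atom: tuple


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between paired coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Transform:
    """Optimal rigid-body fit of ``mobile`` onto ``reference``.

    Returns the rotation/translation minimising the RMSD between the
    transformed mobile coordinates and the reference (SVD closed form, with
    the determinant correction that excludes reflections).

    Raises ``ValueError`` on length mismatch, fewer than 3 points, or a
    degenerate (collinear) configuration for which the rotation is not
    unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to superpose, got {n}")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    # Collinear (rank < 2) point sets leave a rotation about the line free.
    if np.linalg.matrix_rank(np.vstack([x, y]), tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    fitted = mobile @ rot.T + trans
    return Transform(rotation=rot, translation=trans,
                     fit_rmsd=rmsd(fitted, reference), n_fit_atoms=n)


_ATOM_SETS = {
    "mainchain": MAIN_CHAIN_ATOMS,
    "main-chain": MAIN_CHAIN_ATOMS,
    "CA": frozenset({"CA"}),
    "ca": frozenset({"CA"}),
    "all": None,
}


def _segment_selection(name: Optional[str], registry: SegmentRegistry,
                       atom_names) -> Selection:
    if name is None or name.upper() == "ALL":
        sel = Selection()
    else:
        sel = registry.get_segment(name)
    if atom_names is not None:
        sel = sel.with_atom_names(atom_names)
    return sel


def compare_structures(
    ref: Structure,
    mobile: Structure,
    fit_segment: Optional[str],
    report_segments: Sequence[str],
    atom_set: str = "mainchain",
    registry: Optional[SegmentRegistry] = None,
) -> DomainRmsdReport:
    """Fit ``mobile`` onto ``ref`` on one segment; report RMSDs of many.

    A single superposition is computed on the atoms of ``fit_segment``
    (``None`` or ``"ALL"`` fits on every paired atom of the chosen atom set)
    and every segment in ``report_segments`` is then evaluated in that fixed
    frame.  The fit segment's own RMSD is always included in the report.

    A segment that yields no paired atoms produces an entry in
    ``report.errors`` rather than failing the whole comparison.
    """
    if registry is None:
        registry = default_registry()
    if atom_set not in _ATOM_SETS:
        raise ValueError(f"unknown atom_set {atom_set!r}; use mainchain|CA|all")
    atom_names = _ATOM_SETS[atom_set]

    fit_sel = _segment_selection(fit_segment, registry, atom_names)
    ref_fit = select(ref, fit_sel)
    mob_fit = select(mobile, fit_sel)
    if len(ref_fit) == 0 or len(mob_fit) == 0:
        raise ValueError(f"fit segment {fit_segment!r} selects no atoms")
    mob_xyz, ref_xyz, _ = pair_common_atoms(mob_fit, ref_fit)
    transform = kabsch_superpose(mob_xyz, ref_xyz)

    fit_name = fit_segment if fit_segment is not None else "ALL"
    names = [fit_name] + [s for s in report_segments if s != fit_name]
    segments: dict[str, tuple[float, int]] = {}
    errors: dict[str, str] = {}
    for name in names:
        try:
            sel = _segment_selection(None if name == "ALL" else name,
                                     registry, atom_names)
            mob_seg = select(mobile, sel)
            ref_seg = select(ref, sel)
            if len(mob_seg) == 0 or len(ref_seg) == 0:
                raise ValueError("segment selects no atoms")
            m_xyz, r_xyz, _rep = pair_common_atoms(mob_seg, ref_seg)
            segments[name] = (rmsd(transform.apply(m_xyz), r_xyz), len(m_xyz))
        except (ValueError, KeyError) as exc:
            errors[name] = str(exc)
    return DomainRmsdReport(fit_segment=fit_name, atom_set=atom_set,
                            transform=transform, segments=segments, errors=errors)


def point_angle(p1, p2, p3) -> float:
    """Angle in degrees at ``p2`` formed by ``p1–p2–p3``; in [0, 180]."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("angle undefined: coincident points (zero-length arm)")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def residue_triplet_angle(
    s: Structure,
    r1: int,
    r2: int,
    r3: int,
    atom: str = "CA",
    chain: Optional[str] = None,
) -> float:
    """Angle at residue ``r2`` between residues ``r1`` and ``r3``.

    Measured between the named atom (Cα by default) of the three residues;
    the vertex is the middle residue.  This is the metric used both for the
    headpiece inclination (Leu13–Thr86–Leu98) and the M1 kink
    (Trp50–Arg63–Val74).
    """
    pts = []
    for r in (r1, r2, r3):
        try:
            pts.append(s.find_atom(r, atom, chain=chain).pos)
        except KeyError as exc:
            raise KeyError(f"triplet angle: {exc}") from exc
    return point_angle(*pts)


def residue_pair_distance(
    s: Structure,
    res_a: int,
    res_b: int,
    atom_a: str = "CA",
    atom_b: str = "CA",
    chain: Optional[str] = None,
) -> float:
    """Euclidean distance in Å between two named atoms of two residues."""
    a = s.find_atom(res_a, atom_a, chain=chain)
    b = s.find_atom(res_b, atom_b, chain=chain)
    return float(np.linalg.norm(a.pos - b.pos))


#: Residue names recognised as carrying the γ-phosphate or its analogue.
#: maps resname -> (Pγ-analogue atom, bridging atom of the terminal
#: phosphoanhydride in that residue, or None if the bridge lives in a
#: partner nucleotide as for AlF₄⁻).
_NUCLEOTIDE_ATOMS = {
    "ATP": ("PG", "O3B"),
    "ANP": ("PG", "N3B"),   # AMPPNP
    "ACP": ("PG", "C3B"),   # AMPPCP: methylene carbon bridges Pβ and Pγ
    "ALF": ("AL", None),    # AlF4- transition-state mimic; bridge = O3B of ADP
    "AF3": ("AL", None),
}


def catalytic_geometry(
    s: Structure,
    asp_resseq: int = 351,
    chain: Optional[str] = None,
    nuc_resnames: Optional[frozenset] = None,
) -> CatalyticGeometry:
    """In-line geometry between the catalytic aspartate and the γ-phosphate.

    Locates the γ-phosphorus analogue (Pγ of a triphosphate nucleotide, or
    the Al atom of an AlF₄⁻/AlF₃ mimic), picks the aspartate carboxyl oxygen
    (OD1/OD2) closer to it, and returns that distance together with the
    angle Oδ–Pγ–bridge, where the bridge is the atom linking the terminal
    phosphoanhydride (O3B for ATP or an ADP·AlFx complex, the methylene
    carbon for AMPPCP).
    """
    names = nuc_resnames if nuc_resnames is not None else frozenset(_NUCLEOTIDE_ATOMS)
    candidates: list[Atom] = []
    for a in s.atoms:
        if a.resname in names and a.resname in _NUCLEOTIDE_ATOMS:
            if a.name == _NUCLEOTIDE_ATOMS[a.resname][0]:
                if chain is None or a.chain == chain:
                    candidates.append(a)
    if not candidates:
        raise ValueError(
            f"no γ-phosphate analogue found (looked for {sorted(names)})"
        )
    if len(candidates) > 1:
        listing = ", ".join(f"{c.resname} {c.chain}/{c.resseq}" for c in candidates)
        raise ValueError(f"multiple nucleotide analogues found: {listing}")
    pg = candidates[0]

    # Carboxyl oxygens of the aspartate; pick the one closer to the analogue.
    od_atoms = [
        a for a in s.atoms
        if a.resseq == asp_resseq and a.name in ("OD1", "OD2")
        and (chain is None or a.chain == chain)
    ]
    if not od_atoms:
        raise ValueError(f"no carboxyl oxygen (OD1/OD2) on residue {asp_resseq}")
    od = min(od_atoms, key=lambda a: np.linalg.norm(a.pos - pg.pos))

    bridge_name = _NUCLEOTIDE_ATOMS[pg.resname][1]
    if bridge_name is not None:
        bridge = s.atom(pg.chain, pg.resseq, bridge_name, pg.icode)
    else:
        # AlFx mimic: the bridging oxygen is O3B of the adjacent ADP.
        o3b = [a for a in s.atoms if a.name == "O3B" and a.resname in ("ADP", "ATP")]
        if not o3b:
            raise ValueError("AlFx mimic present but no ADP O3B bridging atom found")
        bridge = min(o3b, key=lambda a: np.linalg.norm(a.pos - pg.pos))

    d = float(np.linalg.norm(od.pos - pg.pos))
    theta = point_angle(od.pos, pg.pos, bridge.pos)
    return CatalyticGeometry(
        d_od_pg=d,
        theta_deg=theta,
        od_atom=od.key(),
        pg_atom=pg.key(),
        bridge_atom=bridge.key(),
    )
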