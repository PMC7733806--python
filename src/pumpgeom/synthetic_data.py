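"""Seeded generators for every fixture class the analyses need.

Each generator builds a minimal, fully controlled artifact — a poly-alanine
pseudo-structure, a time series, a fluorescence trace — together with a
machine-readable ``truth`` dict sufficient to predict every observable the
test suite evaluates on it.  Identical seeds reproduce artifacts exactly.

The structures are deliberately schematic: chains of single-Cα "residues"
(plus the specific donor/acceptor or phosphate atoms a given observable
needs).  They emulate the *geometry* of the analyses — rigid-body motions,
hinge angles, hydrogen-bond counts, bimodal distance distributions, one-way
state switches, association kinetics — not protein chemistry or dynamics.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .kinetics_chem import t_half_two_phase, two_phase_model
from .structure_io import Atom, Selection, Structure
from .trajectory_obs import TimeSeries

__all__ = [
    "make_rigid_pair",
    "make_hinged_structure",
    "make_switch_trace",
    "make_bimodal_trace",
    "make_fluorescence_trace",
    "make_hbond_toy",
]


def _ca_structure(coords: np.ndarray, chain: str = "A", start_res: int = 1,
                  source_id: str = "SYNTH") -> Structure:
    """Poly-alanine chain with one Cα per residue at the given coordinates."""
    atoms = [
        Atom(serial=i + 1, name="CA", altloc="", resname="ALA", chain=chain,
             resseq=start_res + i, icode="", x=float(c[0]), y=float(c[1]),
             z=float(c[2]), occupancy=1.0, element="C")
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ]
    return Structure(atoms=atoms, source_id=source_id)


def _rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    ux, uy, uz = axis / n
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer([ux, uy, uz], [ux, uy, uz])


def make_rigid_pair(
    n_atoms: int = 100,
    rotation_deg: float = 30.0,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    translation: Sequence[float] = (5.0, -3.0, 2.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Structure, dict]:
    """Pair of structures related by a known rigid motion plus isotropic noise.

    The second structure is ``R @ x + t`` of the first with i.i.d. Gaussian
    noise of standard deviation ``noise_sd`` per coordinate added.  The truth
    records the applied transform and the exact expected post-fit RMSD

        E[rmsd²] = σ² · (3n − 6) / n,

    i.e. 3 coordinates per atom minus the 6 rigid degrees of freedom the fit
    absorbs (noise on one copy only).
    """
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    base = rng.normal(scale=10.0, size=(n_atoms, 3))
    rot = _rotation_matrix(axis, rotation_deg)
    moved = base @ rot.T + np.asarray(translation, dtype=float)
    if noise_sd > 0:
        moved = moved + rng.normal(scale=noise_sd, size=moved.shape)
    expected = noise_sd * math.sqrt((3.0 * n_atoms - 6.0) / n_atoms)
    truth = {
        "rotation_deg": rotation_deg,
        "axis": list(np.asarray(axis, dtype=float)),
        "translation": list(np.asarray(translation, dtype=float)),
        "noise_sd": noise_sd,
        "n_atoms": n_atoms,
        "expected_fit_rmsd": expected,
        "seed": seed,
    }
    return (_ca_structure(base, source_id="RIGID_REF"),
            _ca_structure(moved, source_id="RIGID_MOB"), truth)


def make_hinged_structure(hinge_angle_deg: float, seed: int = 0,
                          arm_length: float = 10.0) -> tuple[Structure, dict]:
    """Two-armed structure whose Cα triplet angle equals ``hinge_angle_deg``.

    Residues 1..10 form arm A, 11 is the hinge vertex, 12..21 arm B; the
    truth names the triplet (tip A, vertex, tip B) on which
    ``residue_triplet_angle`` returns the hinge angle exactly.  Remaining
    residues are filler along each arm with small seeded jitter off-axis so
    the structure is not degenerate.
    """
    if not 0.0 < hinge_angle_deg < 180.0:
        raise ValueError("hinge angle must be in (0, 180)")
    rng = np.random.default_rng(seed)
    th = math.radians(hinge_angle_deg)
    dir_a = np.array([1.0, 0.0, 0.0])
    dir_b = np.array([math.cos(th), math.sin(th), 0.0])
    coords = []
    # arm A: residues 1..10, tip (residue 1) exactly at arm_length
    for i in range(10):
        frac = 1.0 - i / 10.0
        p = dir_a * arm_length * frac
        if i > 0:  # keep the tip exact
            p = p + rng.normal(scale=0.05, size=3) * np.array([0, 0, 1])
        coords.append(p)
    coords.append(np.zeros(3))  # residue 11: vertex
    # arm B: residues 12..21, tip (residue 21) exactly at arm_length
    for i in range(10):
        frac = (i + 1) / 10.0
        p = dir_b * arm_length * frac
        if i < 9:
            p = p + rng.normal(scale=0.05, size=3) * np.array([0, 0, 1])
        coords.append(p)
    truth = {
        "hinge_angle_deg": hinge_angle_deg,
        "triplet": (1, 11, 21),
        "segments": {"armA": (1, 10), "vertex": (11, 11), "armB": (12, 21)},
        "seed": seed,
    }
    return _ca_structure(np.array(coords), source_id="HINGE"), truth


def make_switch_trace(
    n_frames: int = 500,
    switch_frame: int = 250,
    low_level: float = 7.0,
    high_level: float = 13.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    thresholds: tuple[float, float] = (10.0, 12.0),
    dt_ns: float = 0.4,
) -> tuple[TimeSeries, dict]:
    """Step time series emulating a one-way conformational switch.

    Values sit at ``low_level`` before ``switch_frame`` and at ``high_level``
    from it on, with Gaussian noise.  The generator refuses levels inside the
    hysteresis band of the intended classifier thresholds — such a switch is
    undetectable by construction.  The truth records the largest plausible
    detection lag (frames whose noise could delay the threshold crossing).
    """
    low_thr, high_thr = thresholds
    if not 0 < switch_frame <= n_frames:
        raise ValueError("switch_frame must be in (0, n_frames]")
    if low_thr <= low_level <= high_thr or low_thr <= high_level <= high_thr:
        raise ValueError(
            f"levels {low_level}/{high_level} fall inside the hysteresis band "
            f"{thresholds}; the switch would be undetectable by design"
        )
    rng = np.random.default_rng(seed)
    values = np.where(np.arange(n_frames) < switch_frame, low_level, high_level)
    values = values + rng.normal(scale=noise_sd, size=n_frames)
    times = np.arange(n_frames) * dt_ns
    # frames the noise could plausibly delay the crossing by (4-sigma margin)
    margin = high_thr - high_level
    lag = 0 if noise_sd == 0 else (
        0 if margin < -4.0 * noise_sd else int(math.ceil(4.0 * noise_sd / max(abs(margin), 1e-9)))
    )
    truth = {
        "switch_frame": None if switch_frame == n_frames else switch_frame,
        "low_level": low_level,
        "high_level": high_level,
        "noise_sd": noise_sd,
        "thresholds": thresholds,
        "detection_lag_frames": lag,
        "seed": seed,
    }
    return TimeSeries(times=times, values=values, unit="Å", label="switch"), truth


def make_bimodal_trace(
    means: Sequence[float] = (7.5, 8.8),
    sds: Sequence[float] = (0.3, 0.3),
    weights: Sequence[float] = (0.5, 0.5),
    n: int = 100_000,
    seed: int = 0,
    dt_ns: float = 0.01,
) -> tuple[TimeSeries, dict]:
    """Samples from a Gaussian mixture, emulating a multi-modal distance trace.

    The truth records the component means and a mode-recovery tolerance that
    accounts for kernel smoothing bias (0.35·σ, floored at 0.05), plus a
    warning flag when components overlap within one standard deviation.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not math.isclose(weights.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(means), size=n, p=weights)
    values = rng.normal(loc=means[comp], scale=sds[comp])
    overlap = any(
        abs(means[i] - means[j]) < max(sds[i], sds[j])
        for i in range(len(means)) for j in range(i + 1, len(means))
    )
    truth = {
        "means": list(means),
        "sds": list(sds),
        "weights": list(weights),
        "n": n,
        "mode_tolerance": max(0.05, 0.35 * float(sds.max())),
        "overlapping_modes": overlap,
        "seed": seed,
    }
    return (TimeSeries(times=np.arange(n) * dt_ns, values=values, unit="Å",
                       label="bimodal"), truth)


def make_fluorescence_trace(
    F0: float = 1.0,
    A1: float = 0.15,
    k1: float = 0.5,
    A2: float = 0.15,
    k2: float = 0.05,
    noise_sd: float = 0.0,
    dt: float = 2.0,
    duration: float = 120.0,
    seed: int = 0,
    t_half_target: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Fluorescence trace from the two-phase association law plus noise.

    ``dt`` defaults to the 2-s signal integration time of the fluorimeter
    protocol it emulates.  If ``t_half_target`` is given, both rates are
    rescaled by a common factor so the *exact* half-time of the noiseless
    model (computed by root finding) equals the target; the truth always
    records that exact half-time.

    Returns ``(t, F, truth)``.
    """
    if t_half_target is not None:
        base = t_half_two_phase(F0, A1, k1, A2, k2)
        scale = base / t_half_target
        k1, k2 = k1 * scale, k2 * scale
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    F = two_phase_model(t, F0, A1, k1, A2, k2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(scale=noise_sd, size=F.shape)
    truth = {
        "F0": F0, "A1": A1, "k1": k1, "A2": A2, "k2": k2,
        "noise_sd": noise_sd, "dt": dt, "duration": duration,
        "t_half": t_half_two_phase(F0, A1, k1, A2, k2),
        "seed": seed,
    }
    return t, F, truth


def make_hbond_toy(n_pairs_in: int, n_pairs_out: int, seed: int = 0
                   ) -> tuple[Structure, Selection, Selection, dict]:
    """Toy donor/acceptor system with an exact cross-group hydrogen-bond count.

    ``n_pairs_in`` donor–acceptor pairs are placed 2.8–3.2 Å apart (inside
    the default 3.5-Å criterion) and ``n_pairs_out`` pairs 4.5–6.5 Å apart,
    on a 15-Å grid so no accidental cross-pair contact can occur.  Donors
    (backbone-like N) live on chain A, acceptors (O) on chain B; the returned
    selections pick the two chains.
    """
    if n_pairs_in < 0 or n_pairs_out < 0:
        raise ValueError("pair counts must be non-negative")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1
    total = n_pairs_in + n_pairs_out
    side = max(1, math.ceil(total ** (1.0 / 3.0)))
    for idx in range(total):
        gx, gy, gz = idx % side, (idx // side) % side, idx // (side * side)
        origin = np.array([gx, gy, gz], dtype=float) * 15.0
        d = rng.uniform(2.8, 3.2) if idx < n_pairs_in else rng.uniform(4.5, 6.5)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos_n = origin
        pos_o = origin + direction * d
        resseq = idx + 1
        atoms.append(Atom(serial=serial, name="N", altloc="", resname="ALA",
                          chain="A", resseq=resseq, icode="",
                          x=pos_n[0], y=pos_n[1], z=pos_n[2],
                          occupancy=1.0, element="N"))
        serial += 1
        atoms.append(Atom(serial=serial, name="O", altloc="", resname="ALA",
                          chain="B", resseq=resseq, icode="",
                          x=pos_o[0], y=pos_o[1], z=pos_o[2],
                          occupancy=1.0, element="O"))
        serial += 1
    atoms.sort(key=lambda a: (a.chain, a.resseq, a.icode, a.serial))
    structure = Structure(atoms=atoms, source_id="HBOND_TOY")
    sel_a = Selection(chains=frozenset({"A"}))
    sel_b = Selection(chains=frozenset({"B"}))
    truth = {"n_hbonds": n_pairs_in, "n_pairs_out": n_pairs_out, "seed": seed}
    return structure, sel_a, sel_b, truth
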