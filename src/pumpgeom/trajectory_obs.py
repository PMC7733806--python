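"""Per-frame observables over trajectories, plus distribution, two-state
switch and correlation analyses.

A trajectory is a topology :class:`~pumpgeom.structure_io.Structure` plus a
stack of coordinate frames with strictly increasing times (ns).  Observables
(distances, Cα-triplet angles, hydrogen-bond counts, catalytic-site
geometry) are evaluated once per frame with the same routines used on static
structures, so a one-frame trajectory reproduces the static value exactly.

The analysis layer implements what conformational MD studies of ion pumps
typically report from such series: kernel-density or fixed-bin histograms,
mode (peak) finding, Pearson correlation between two traces, medians, and a
hysteretic two-state classifier used to detect one-way switching events
(e.g. a side chain that swings from an "in" to an "out" position and never
returns).
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import signal, stats

from .contacts import ContactCriterion, count_hbonds
from .structure_io import Selection, Structure
from . import geometry_core

__all__ = [
    "Trajectory",
    "TimeSeries",
    "ObservableSpec",
    "StateTrace",
    "DensityCurve",
    "read_multimodel_pdb",
    "evaluate_observable",
    "histogram_density",
    "find_modes",
    "classify_two_state",
    "is_irreversible",
    "trace_correlation",
    "series_median",
]


@dataclasses.dataclass
class Trajectory:
    """Topology plus per-frame coordinates (Å) and frame times (ns)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray   # (n_frames,), ns

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology)}"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames differ in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclasses.dataclass
class TimeSeries:
    """Scalar observable per frame."""

    times: np.ndarray
    values: np.ndarray
    unit: str = ""
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in time series")

    def __len__(self) -> int:
        return len(self.values)


@dataclasses.dataclass
class ObservableSpec:
    """What to measure per frame.

    kind:
        - ``distance``: params ``res_a``, ``res_b``, optional ``atom_a``,
          ``atom_b`` (default CA), optional ``chain``;
        - ``triplet_angle``: params ``r1``, ``r2``, ``r3``, optional ``atom``;
        - ``hbond_count``: params ``group_a``, ``group_b`` (Selections),
          optional ``criterion``;
        - ``catalytic_distance`` / ``catalytic_angle``: optional
          ``asp_resseq`` (default 351).
    """

    kind: Literal["distance", "triplet_angle", "hbond_count",
                  "catalytic_distance", "catalytic_angle"]
    params: dict = dataclasses.field(default_factory=dict)
    label: str = ""


@dataclasses.dataclass
class StateTrace:
    """Hysteretic two-state labelling of a time series.

    ``labels`` holds one of ``"low"``, ``"high"``, ``"undecided"`` per
    frame; ``transitions`` lists ``(frame_index, direction)`` with direction
    ``"low->high"`` or ``"high->low"``.
    """

    labels: list[str]
    transitions: list[tuple[int, str]]
    low_threshold: float
    high_threshold: float


@dataclasses.dataclass
class DensityCurve:
    """Density estimate on a regular grid; integrates to 1."""

    x: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.x))


# ---------------------------------------------------------------------------
# Trajectory input


def read_multimodel_pdb(path, dt_ns: float = 1.0, times: Optional[Sequence[float]] = None,
                        ) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (model order = frame order)."""
    import gemmi

    from .structure_io import read_structure

    st = gemmi.read_structure(str(path))
    n_models = len(st)
    if n_models == 0:
        raise ValueError(f"{path} contains no models")
    topology = read_structure(path, model_index=0)
    frames = np.empty((n_models, len(topology), 3))
    for i in range(n_models):
        frames[i] = read_structure(path, model_index=i).coords()
    if times is None:
        times = np.arange(n_models) * dt_ns
    return Trajectory(topology=topology, frames=frames, times=np.asarray(times))


def read_mdanalysis(topology_path, trajectory_path, dt_ns: Optional[float] = None
                    ) -> Trajectory:
    """Optional XTC/DCD reader backed by MDAnalysis (extra dependency)."""
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "reading XTC/DCD trajectories requires MDAnalysis "
            "(pip install pumpgeom[traj])"
        ) from exc
    from .structure_io import read_structure

    topology = read_structure(topology_path)
    u = mda.Universe(str(topology_path), str(trajectory_path))
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if dt_ns is not None:
        times = np.arange(len(frames)) * dt_ns
    else:
        times = np.array([ts.time / 1000.0 for ts in u.trajectory])  # ps -> ns
    return Trajectory(topology=topology, frames=frames, times=times)


# ---------------------------------------------------------------------------
# Per-frame evaluation


def _atom_index(top: Structure, resseq: int, name: str, chain=None) -> int:
    for i, a in enumerate(top.atoms):
        if a.resseq == resseq and a.name == name and (chain is None or a.chain == chain):
            return i
    raise KeyError(f"atom {name!r} of residue {resseq} not found in topology")


def evaluate_observable(traj: Trajectory, spec: ObservableSpec) -> TimeSeries:
    """One value of ``spec`` per frame.

    Atom existence is checked against the topology before any frame is
    touched, so a bad spec fails fast.
    """
    p = spec.params
    top = traj.topology
    if spec.kind == "distance":
        ia = _atom_index(top, p["res_a"], p.get("atom_a", "CA"), p.get("chain"))
        ib = _atom_index(top, p["res_b"], p.get("atom_b", "CA"), p.get("chain"))
        diffs = traj.frames[:, ia, :] - traj.frames[:, ib, :]
        values = np.linalg.norm(diffs, axis=1)
        unit = "Å"
    elif spec.kind == "triplet_angle":
        atom = p.get("atom", "CA")
        idx = [_atom_index(top, p[k], atom, p.get("chain")) for k in ("r1", "r2", "r3")]
        v1 = traj.frames[:, idx[0], :] - traj.frames[:, idx[1], :]
        v2 = traj.frames[:, idx[2], :] - traj.frames[:, idx[1], :]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        values = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        unit = "degrees"
    elif spec.kind == "hbond_count":
        ga: Selection = p["group_a"]
        gb: Selection = p["group_b"]
        crit = p.get("criterion", ContactCriterion())
        values = np.array([
            count_hbonds(traj.frame_structure(i), ga, gb, crit)
            for i in range(len(traj))
        ], dtype=float)
        unit = "count"
    elif spec.kind in ("catalytic_distance", "catalytic_angle"):
        asp = p.get("asp_resseq", 351)
        # Fail fast on the topology before looping over frames.
        geometry_core.catalytic_geometry(top, asp_resseq=asp, chain=p.get("chain"))
        values = np.empty(len(traj))
        for i in range(len(traj)):
            g = geometry_core.catalytic_geometry(
                traj.frame_structure(i), asp_resseq=asp, chain=p.get("chain"))
            values[i] = g.d_od_pg if spec.kind == "catalytic_distance" else g.theta_deg
        unit = "Å" if spec.kind == "catalytic_distance" else "degrees"
    else:
        raise ValueError(f"unknown observable kind {spec.kind!r}")
    return TimeSeries(times=traj.times, values=values, unit=unit,
                      label=spec.label or spec.kind)


# ---------------------------------------------------------------------------
# Distribution analysis


def histogram_density(
    ts: TimeSeries,
    method: Literal["kde", "bins"] = "kde",
    bins: int = 50,
    bandwidth: Optional[float] = None,
    grid_points: int = 512,
) -> DensityCurve:
    """Normalised density estimate of a series' value distribution.

    ``kde`` uses a Gaussian kernel with Silverman's bandwidth (or an explicit
    one); ``bins`` uses a fixed-bin histogram.  A (near-)constant series is
    handled by the histogram path, yielding a single occupied bin.
    """
    v = np.asarray(ts.values, dtype=float)
    if len(v) < 10:
        raise ValueError(f"need at least 10 samples for a density, got {len(v)}")
    spread = np.ptp(v)
    if method == "kde" and spread > 1e-12:
        kde = stats.gaussian_kde(v, bw_method=bandwidth or "silverman")
        pad = 3.0 * np.std(v)
        x = np.linspace(v.min() - pad, v.max() + pad, grid_points)
        y = kde(x)
    else:
        lo, hi = v.min(), v.max()
        if spread <= 1e-12:
            lo, hi = lo - 0.5, hi + 0.5
        counts, edges = np.histogram(v, bins=bins, range=(lo, hi), density=True)
        # render the histogram as a step function on a fine grid so the
        # trapezoidal integral (and hence the normalisation) is faithful
        x = np.linspace(lo, hi, bins * 20)
        y = counts[np.clip(np.searchsorted(edges, x, side="right") - 1,
                           0, bins - 1)]
    integral = np.trapezoid(y, x)
    if integral <= 0:
        raise ValueError("degenerate density estimate")
    return DensityCurve(x=x, density=y / integral)


def find_modes(density: DensityCurve, min_prominence: float = 0.05) -> list[float]:
    """Positions of local density maxima, sorted by position.

    ``min_prominence`` is a fraction of the maximum density; peaks less
    prominent than that are ignored.  Boundary maxima are detected by
    zero-padding the curve.
    """
    y = np.concatenate([[0.0], density.density, [0.0]])
    prominence = min_prominence * float(density.density.max())
    peaks, _ = signal.find_peaks(y, prominence=prominence)
    return sorted(float(density.x[p - 1]) for p in peaks)


# ---------------------------------------------------------------------------
# Two-state switch analysis


def classify_two_state(ts: TimeSeries, low_thr: float, high_thr: float) -> StateTrace:
    """Hysteretic two-state labelling.

    A frame is ``low`` below ``low_thr`` and ``high`` above ``high_thr``;
    inside the band the previous state persists.  Frames before the first
    decided one are ``undecided``.  The hysteresis band suppresses
    noise-driven flickering: a low→high transition requires crossing the
    *high* threshold, and vice versa.
    """
    if not low_thr < high_thr:
        raise ValueError(f"thresholds inverted: low {low_thr} >= high {high_thr}")
    labels: list[str] = []
    transitions: list[tuple[int, str]] = []
    state: Optional[str] = None
    for i, v in enumerate(ts.values):
        if v < low_thr:
            new = "low"
        elif v > high_thr:
            new = "high"
        else:
            new = state  # persist inside the band
        if state is not None and new is not None and new != state:
            transitions.append((i, f"{state}->{new}"))
        if new is not None:
            state = new
        labels.append(new if new is not None else "undecided")
    return StateTrace(labels=labels, transitions=transitions,
                      low_threshold=low_thr, high_threshold=high_thr)


def is_irreversible(st: StateTrace) -> tuple[bool, Optional[int]]:
    """Whether the trace never reverts after its first low→high switch.

    Returns ``(flag, first_switch_frame)``; a trace without any low→high
    transition is vacuously irreversible with frame ``None``.
    """
    first_up: Optional[int] = None
    for frame, direction in st.transitions:
        if direction == "low->high" and first_up is None:
            first_up = frame
        elif direction == "high->low" and first_up is not None:
            return False, first_up
    return True, first_up


# ---------------------------------------------------------------------------
# Scalar summaries


def trace_correlation(a: TimeSeries, b: TimeSeries) -> float:
    """Pearson correlation between two equally sampled series."""
    if len(a) != len(b):
        raise ValueError("series differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    va, vb = np.asarray(a.values), np.asarray(b.values)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(np.corrcoef(va, vb)[0, 1])


def series_median(ts: TimeSeries) -> float:
    if len(ts) == 0:
        raise ValueError("empty series")
    return float(np.median(ts.values))
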