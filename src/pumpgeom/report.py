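"""Consolidated comparison report between two conformations of the pump.

:func:`run_compare_report` executes the whole battery of structural
comparisons between a reference and a mobile structure — segment-decomposed
RMSDs, the two diagnostic triplet angles, the named inter-residue distances,
interdomain polar contacts with presence flags, and the catalytic-site
geometry — and collects them into a JSON-serialisable
:class:`ComparisonReport`.  Stage failures are captured per entry so one
missing ligand does not void the rest of the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Optional

from . import geometry_core
from .contacts import ContactCriterion, find_polar_contacts
from .segments import SegmentRegistry, default_registry, load_registry_overrides
from .structure_io import Structure, read_structure

logger = logging.getLogger("pumpgeom")

REPORT_SCHEMA_VERSION = 1

#: Segments reported in the RMSD decomposition after fitting on M5-M10.
DEFAULT_REPORT_SEGMENTS = (
    "M5M10", "M1M4", "A", "N", "P", "HEADPIECE", "NP_BODY", "NA_BODY",
)

#: (label, r1, r2, r3) — vertex is the middle residue; Cα atoms.
TRIPLET_ANGLES = (
    ("headpiece", 13, 86, 98),
    ("m1_kink", 50, 63, 74),
)

#: (label, res_a, atom_a, res_b, atom_b)
NAMED_DISTANCES = (
    ("P337_P312", 337, "CA", 312, "CA"),
    ("L249_res340", 249, "CA", 340, "CA"),
)


@dataclasses.dataclass
class ComparisonReport:
    """Everything the WT-vs-mutant structural comparison computes."""

    reference: str
    mobile: str
    schema_version: int
    rmsd_fit_segment: dict
    rmsd_global: dict
    angles: dict
    distances: dict
    contacts: dict
    catalytic: dict
    errors: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    def to_tsv(self) -> str:
        rows = [("quantity", "reference", "mobile")]
        for name, pair in self.angles.items():
            rows.append((f"angle:{name} (deg)", pair.get("reference"), pair.get("mobile")))
        for name, pair in self.distances.items():
            rows.append((f"distance:{name} (A)", pair.get("reference"), pair.get("mobile")))
        for name, (r, n) in self.rmsd_fit_segment.get("segments", {}).items():
            rows.append((f"rmsd:{name} (A, n={n})", "", r))
        return "\n".join("\t".join("" if v is None else str(v) for v in row)
                         for row in rows)


def _try(errors: dict, key: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # capture per stage, keep going
        logger.warning("%s failed: %s", key, exc)
        errors[key] = str(exc)
        return None


def run_compare_report(
    ref: Structure | str,
    mobile: Structure | str,
    config: Optional[str] = None,
    registry: Optional[SegmentRegistry] = None,
    fit_segment: str = "M5M10",
    atom_set: str = "mainchain",
    contact_criterion: ContactCriterion = ContactCriterion(),
) -> ComparisonReport:
    """Full structural comparison battery between two structures.

    ``ref``/``mobile`` may be paths or already-loaded structures; ``config``
    is an optional TOML file whose ``[segments]`` section overrides the
    configurable segment boundaries.
    """
    if isinstance(ref, (str,)) or hasattr(ref, "__fspath__"):
        ref = read_structure(ref)
    if isinstance(mobile, (str,)) or hasattr(mobile, "__fspath__"):
        mobile = read_structure(mobile)
    if registry is None:
        registry = load_registry_overrides(config) if config else default_registry()

    errors: dict[str, str] = {}

    rep = _try(errors, "rmsd_decomposition", geometry_core.compare_structures,
               ref, mobile, fit_segment, DEFAULT_REPORT_SEGMENTS,
               atom_set=atom_set, registry=registry)
    rmsd_fit = {}
    if rep is not None:
        rmsd_fit = {
            "fit_segment": rep.fit_segment,
            "atom_set": rep.atom_set,
            "segments": {k: [round(v, 4), n] for k, (v, n) in rep.segments.items()},
            "segment_errors": rep.errors,
        }
        for name, (v, n) in rep.segments.items():
            logger.info("rmsd[%s] = %.3f A over %d atoms (fit on %s)",
                        name, v, n, rep.fit_segment)

    glob = _try(errors, "rmsd_global", geometry_core.compare_structures,
                ref, mobile, None, (), atom_set=atom_set, registry=registry)
    rmsd_global = {}
    if glob is not None:
        v, n = glob.segments["ALL"]
        rmsd_global = {"rmsd": round(v, 4), "n_atoms": n, "atom_set": atom_set}
        logger.info("global %s rmsd = %.3f A over %d atoms", atom_set, v, n)

    angles: dict[str, dict] = {}
    for label, r1, r2, r3 in TRIPLET_ANGLES:
        pair = {}
        for which, s in (("reference", ref), ("mobile", mobile)):
            val = _try(errors, f"angle:{label}:{which}",
                       geometry_core.residue_triplet_angle, s, r1, r2, r3)
            if val is not None:
                pair[which] = round(val, 2)
                logger.info("angle[%s] %s = %.1f deg", label, which, val)
        angles[label] = pair

    distances: dict[str, dict] = {}
    for label, ra, aa, rb, ab in NAMED_DISTANCES:
        pair = {}
        for which, s in (("reference", ref), ("mobile", mobile)):
            val = _try(errors, f"distance:{label}:{which}",
                       geometry_core.residue_pair_distance, s, ra, rb, aa, ab)
            if val is not None:
                pair[which] = round(val, 2)
                logger.info("distance[%s] %s = %.2f A", label, which, val)
        distances[label] = pair

    contacts: dict[str, dict] = {}
    for ga, gb in (("A", "N"), ("A", "P")):
        entry: dict = {"pairs": {}}
        for which, s in (("reference", ref), ("mobile", mobile)):
            found = _try(errors, f"contacts:{ga}-{gb}:{which}", find_polar_contacts,
                         s, registry.get_segment(ga), registry.get_segment(gb),
                         contact_criterion)
            if found is None:
                continue
            for c in found:
                key = f"{c.atom_a[1]}{c.atom_a[3]}-{c.atom_b[1]}{c.atom_b[3]}"
                entry["pairs"].setdefault(key, {})[which] = round(c.distance, 2)
            logger.info("contacts[%s-%s] %s: %d pairs", ga, gb, which, len(found))
        for key, presence in entry["pairs"].items():
            presence["in_both"] = "reference" in presence and "mobile" in presence
        contacts[f"{ga}-{gb}"] = entry

    catalytic: dict[str, dict] = {}
    for which, s in (("reference", ref), ("mobile", mobile)):
        g = _try(errors, f"catalytic:{which}", geometry_core.catalytic_geometry, s)
        if g is not None:
            catalytic[which] = {"d_od_pg": round(g.d_od_pg, 2),
                                "theta_deg": round(g.theta_deg, 1)}
            logger.info("catalytic %s: d = %.2f A, theta = %.1f deg",
                        which, g.d_od_pg, g.theta_deg)

    return ComparisonReport(
        reference=ref.source_id,
        mobile=mobile.source_id,
        schema_version=REPORT_SCHEMA_VERSION,
        rmsd_fit_segment=rmsd_fit,
        rmsd_global=rmsd_global,
        angles=angles,
        distances=distances,
        contacts=contacts,
        catalytic=catalytic,
        errors=errors,
    )
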