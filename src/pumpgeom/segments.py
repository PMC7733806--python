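"""Named segment and domain definitions for rabbit SERCA1a.

Every analysis that talks about "M5–M10", "the headpiece" or "L6-7" resolves
the name through a :class:`SegmentRegistry`, so the residue boundaries live
in exactly one place.

Three boundary sets are fixed by the structural literature on this pump and
are treated as immutable:

* ``M5M10`` — C-terminal transmembrane bundle, residues 750–994,
* ``P1``   — the short P1 helix Pro337–Cys344 (337–344),
* ``L6_7`` — the cytosolic M6–M7 loop Phe809–Ser830 (809–830).

The remaining boundaries (A/N/P domains, M1–M4) are conventional choices
informed by SERCA domain annotations and are configurable through
:func:`load_registry_overrides`; composite bodies (HEADPIECE, NP_BODY,
NA_BODY, M1M4) are unions of their members and follow any override.
"""

from __future__ import annotations

import dataclasses
import tomllib
import warnings
from typing import Iterable, Mapping

from .structure_io import Selection

__all__ = ["SegmentRegistry", "default_registry", "load_registry_overrides"]

Ranges = tuple[tuple[int, int], ...]

#: Boundaries fixed by the literature; overriding them is refused.
PAPER_STATED: dict[str, Ranges] = {
    "M5M10": ((750, 994),),
    "P1": ((337, 344),),
    "L6_7": ((809, 830),),
}

#: Conventional defaults for boundaries that are configurable.
DEFAULT_CONFIGURABLE: dict[str, Ranges] = {
    "A": ((1, 43), (124, 235)),
    "N": ((360, 600),),
    "P": ((330, 359), (601, 739)),
    "M1": ((49, 73),),
    "M2": ((89, 124),),
    "M3": ((254, 273),),
    "M4": ((291, 313),),
}

#: Composite bodies as unions of member segments.
COMPOSITES: dict[str, tuple[str, ...]] = {
    "HEADPIECE": ("A", "N", "P"),
    "NP_BODY": ("N", "P"),
    "NA_BODY": ("N", "A"),
    "M1M4": ("M1", "M2", "M3", "M4"),
}


@dataclasses.dataclass
class SegmentRegistry:
    """Mapping from segment names to residue-range selections."""

    entries: dict[str, Ranges]

    def names(self) -> list[str]:
        return sorted(self.entries) + sorted(COMPOSITES)

    def ranges(self, name: str) -> Ranges:
        """Residue ranges for a segment, resolving composites to unions."""
        if name in self.entries:
            return self.entries[name]
        if name in COMPOSITES:
            out: list[tuple[int, int]] = []
            for member in COMPOSITES[name]:
                out.extend(self.ranges(member))
            return tuple(sorted(out))
        raise KeyError(
            f"unknown segment {name!r}; available: {', '.join(self.names())}"
        )

    def get_segment(self, name: str) -> Selection:
        return Selection(residue_ranges=self.ranges(name))

    def provenance(self, name: str) -> str:
        if name in PAPER_STATED:
            return "literature-stated"
        if name in COMPOSITES:
            return "composite"
        return "default-configurable"

    def n_residues(self, name: str) -> int:
        """Residue count of the segment assuming a gap-free chain."""
        return sum(e - s + 1 for s, e in self.ranges(name))

    def to_dict(self) -> dict[str, str]:
        """Serializable form, ``name -> "start-end[,start-end]"``."""
        return {
            name: ",".join(f"{s}-{e}" for s, e in ranges)
            for name, ranges in sorted(self.entries.items())
        }

    @staticmethod
    def from_dict(d: Mapping[str, str]) -> "SegmentRegistry":
        reg = default_registry()
        for name, spec in d.items():
            reg._set(name, _parse_ranges(name, spec))
        return reg

    def _set(self, name: str, ranges: Ranges) -> None:
        if name in PAPER_STATED and ranges != PAPER_STATED[name]:
            warnings.warn(
                f"segment {name!r} has a literature-fixed definition "
                f"{PAPER_STATED[name]}; override ignored",
                stacklevel=3,
            )
            return
        if name in COMPOSITES:
            warnings.warn(
                f"segment {name!r} is a composite of {COMPOSITES[name]}; "
                "override its members instead; ignored",
                stacklevel=3,
            )
            return
        self.entries[name] = ranges


def default_registry() -> SegmentRegistry:
    entries = dict(PAPER_STATED)
    entries.update(DEFAULT_CONFIGURABLE)
    return SegmentRegistry(entries=entries)


def _parse_ranges(key: str, spec) -> Ranges:
    if isinstance(spec, str):
        parts = [p.strip() for p in spec.split(",") if p.strip()]
    elif isinstance(spec, Iterable):
        parts = list(spec)
    else:
        raise ValueError(f"segments.{key}: cannot parse range spec {spec!r}")
    out = []
    for part in parts:
        try:
            if isinstance(part, str):
                lo, hi = part.split("-")
                lo, hi = int(lo), int(hi)
            else:
                lo, hi = (int(x) for x in part)
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"segments.{key}: malformed range {part!r} (expected 'start-end')"
            ) from exc
        if lo > hi:
            raise ValueError(f"segments.{key}: range {lo}-{hi} has start > end")
        out.append((lo, hi))
    return tuple(out)


def load_registry_overrides(config_path) -> SegmentRegistry:
    """Registry with defaults replaced by a ``[segments]`` TOML section.

    Overrides of literature-fixed segments are ignored with a warning;
    malformed ranges raise ``ValueError`` naming the offending key.
    """
    with open(config_path, "rb") as fh:
        cfg = tomllib.load(fh)
    section = cfg.get("segments", {})
    reg = default_registry()
    for name, spec in section.items():
        reg._set(name, _parse_ranges(name, spec))
    return reg
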