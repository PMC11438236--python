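"""Whole-body models from per-segment convex hulls.

A body is assembled from named segments (skull, neck, trunk, tail, the
twelve limb segments, optionally a dorsal sail and/or subdivided tail
hulls), each carrying a hull volume, centroid, density, and a dimensionless
expansion factor.  From the assembly we compute whole-body volume, mass,
the centre of mass (CoM), and two positional CoM proxies:

* ``%C(AG)`` — CoM position as percent cranial along the transect from the
  acetabulum (hip socket) to the glenoid (shoulder socket);
* ``DCA/FL`` — distance of the CoM cranial to the acetabulum divided by
  femur length (values >= 1 have been read as consistent with quadrupedal
  posture).

Expansion factors (MEF: mammal-derived; SEF: sauropsid-derived) convert
convex-hull volumes to fleshed-out volumes per segment; inflation is
modelled as uniform about each segment's centroid, so centroids do not
move.  Trunk deflation (90/80/70% of hull volume) probes the sensitivity
of the CoM to non-uniform segment density.
"""

from __future__ import annotations

import csv
import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .published import DEFAULT_DENSITY

__all__ = [
    "BodySegment",
    "Landmarks",
    "BodyModel",
    "ExpansionFactorTable",
    "CoMMetrics",
    "SegmentValidationError",
    "CANONICAL_SEGMENTS",
    "assemble_body",
    "body_volume",
    "body_mass_direct",
    "apply_expansion",
    "compute_expansion_factors",
    "deflate_trunk",
    "center_of_mass",
    "com_metrics",
    "load_landmarks_json",
    "load_expansion_table",
    "write_com_report",
]

_LIMB_SEGMENTS = tuple(
    f"{girdle}_{side}_{part}"
    for girdle in ("fore", "hind")
    for side in ("left", "right")
    for part in ("stylopod", "zeugopod", "autopod")
)

#: The minimum 16-segment inventory: skull, neck, trunk, tail, and
#: stylopod/zeugopod/autopod for each of the four limbs.
CANONICAL_SEGMENTS = ("skull", "neck", "trunk", "tail") + _LIMB_SEGMENTS

_AXIAL_SEGMENTS = frozenset({"skull", "neck", "trunk", "tail", "sail"})
_TAIL_SUB_RE = re.compile(r"^tail_sub_\d+$")

_CLADES = ("mammal", "crocodylian", "other_reptile", "fossil")


class SegmentValidationError(ValueError):
    """A segment name, factor, or assembly constraint is invalid."""


def _valid_segment_name(name: str) -> bool:
    return name in _AXIAL_SEGMENTS or name in _LIMB_SEGMENTS or bool(_TAIL_SUB_RE.match(name))


@dataclass(frozen=True)
class BodySegment:
    """One hulled body segment.

    ``effective mass = volume * expansion_factor * density``; the expansion
    factor defaults to 1.0 (bare convex hull).
    """

    name: str
    volume: float  # m^3
    centroid: np.ndarray  # (3,) metres
    density: float = DEFAULT_DENSITY  # kg/m^3
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        if not _valid_segment_name(self.name):
            raise SegmentValidationError(
                f"unknown segment name {self.name!r}; expected one of the canonical "
                f"segments, 'sail', or 'tail_sub_<k>'"
            )
        if not self.volume > 0:
            raise SegmentValidationError(f"{self.name}: volume must be > 0, got {self.volume}")
        if not self.density > 0:
            raise SegmentValidationError(f"{self.name}: density must be > 0, got {self.density}")
        if self.expansion_factor < 0:
            raise SegmentValidationError(
                f"{self.name}: expansion factor must be >= 0, got {self.expansion_factor}"
            )
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float).reshape(3))

    @property
    def mass(self) -> float:
        """Effective segment mass in kg."""
        return self.volume * self.expansion_factor * self.density


@dataclass(frozen=True)
class Landmarks:
    """Acetabulum and glenoid landmarks plus femur length, all in metres."""

    acetabulum: np.ndarray
    glenoid: np.ndarray
    femur_length: float

    def __post_init__(self) -> None:
        ace = np.asarray(self.acetabulum, dtype=float).reshape(3)
        gle = np.asarray(self.glenoid, dtype=float).reshape(3)
        if np.allclose(ace, gle):
            raise SegmentValidationError("acetabulum and glenoid coincide")
        if not self.femur_length > 0:
            raise SegmentValidationError(f"femur length must be > 0, got {self.femur_length}")
        object.__setattr__(self, "acetabulum", ace)
        object.__setattr__(self, "glenoid", gle)


@dataclass(frozen=True)
class BodyModel:
    """A specimen's assembled multi-segment body."""

    specimen: str
    clade: str
    segments: tuple[BodySegment, ...]
    landmarks: Landmarks | None = None

    def segment(self, name: str) -> BodySegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def has_segment(self, name: str) -> bool:
        return any(seg.name == name for seg in self.segments)

    @property
    def tail_volume(self) -> float:
        """Total tail volume: a single straightened tail hull or the sum of
        subdivided tail hulls (both conventions are in use)."""
        return sum(s.volume for s in self.segments if s.name == "tail" or _TAIL_SUB_RE.match(s.name))


@dataclass(frozen=True)
class ExpansionFactorTable:
    """Per-segment hull-to-skin volume multipliers (MEF or SEF)."""

    factors: dict[str, float]
    label: str = "MEF"  # "MEF" (mammal-derived) or "SEF" (sauropsid-derived)

    def __post_init__(self) -> None:
        for name, f in self.factors.items():
            if not f > 0:
                raise SegmentValidationError(f"expansion factor for {name!r} must be > 0, got {f}")

    def get(self, segment_name: str) -> float:
        """Factor for a segment; segments absent from the table stay at 1.0."""
        if segment_name in self.factors:
            return self.factors[segment_name]
        # Subdivided tail hulls inherit the tail factor.
        if _TAIL_SUB_RE.match(segment_name) and "tail" in self.factors:
            return self.factors["tail"]
        return 1.0


@dataclass(frozen=True)
class CoMMetrics:
    """Positional CoM proxies for one body model.

    ``pct_AG = 100 * dca / |AG|`` and ``dca_fl = dca / femur_length``, where
    ``dca`` is the CoM's projection onto the acetabulum->glenoid (cranial)
    axis measured from the acetabulum.  ``log10_skull_tail`` is the log10
    ratio of skull to total tail volume, or None when either segment is
    absent (tailless taxa are excluded from the proportion analysis).
    """

    com: np.ndarray
    pct_AG: float
    dca_fl: float
    log10_skull_tail: float | None


def assemble_body(
    segments,
    landmarks: Landmarks | None = None,
    clade: str = "fossil",
    specimen: str = "specimen",
) -> BodyModel:
    """Assemble validated segments into a :class:`BodyModel`.

    Segment names must be unique except for the ``tail_sub_<k>`` series.
    Missing canonical segments produce a warning (partial skeletons are
    common for fossils) rather than an error.
    """
    segs = tuple(segments)
    if not segs:
        raise SegmentValidationError("a body needs at least one segment")
    if clade not in _CLADES:
        raise SegmentValidationError(f"unknown clade {clade!r}; expected one of {_CLADES}")
    seen: set[str] = set()
    for seg in segs:
        if _TAIL_SUB_RE.match(seg.name):
            if seg.name in seen:
                raise SegmentValidationError(f"duplicate tail sub-hull name {seg.name!r}")
        elif seg.name in seen:
            raise SegmentValidationError(f"duplicate segment name {seg.name!r}")
        seen.add(seg.name)
    has_tail = any(n == "tail" or _TAIL_SUB_RE.match(n) for n in seen)
    missing = [n for n in CANONICAL_SEGMENTS if n not in seen and not (n == "tail" and has_tail)]
    if missing:
        warnings.warn(
            f"{specimen}: {len(missing)} of the 16 canonical segments absent "
            f"({', '.join(missing[:4])}{'...' if len(missing) > 4 else ''})",
            stacklevel=2,
        )
    return BodyModel(specimen=specimen, clade=clade, segments=segs, landmarks=landmarks)


def body_volume(model: BodyModel) -> float:
    """Whole-body hull volume (m^3): the exact sum of segment hull volumes.

    Expansion factors are deliberately NOT applied — this is the raw
    convex-hull volume that enters the predictive scaling equation.
    """
    return math.fsum(seg.volume for seg in model.segments)


def body_mass_direct(model: BodyModel) -> float:
    """Direct volumetric mass (kg): sum of volume x expansion factor x density.

    With all factors 1 and uniform density 1000 kg/m^3 this equals
    ``body_volume(model) * 1000``.
    """
    return math.fsum(seg.mass for seg in model.segments)


def apply_expansion(model: BodyModel, table: ExpansionFactorTable) -> BodyModel:
    """Return a new model with per-segment expansion factors set from ``table``.

    Inflation is uniform about each segment centroid, so centroids are
    unchanged; segments missing from the table keep factor 1.0.
    """
    new_segments = tuple(
        replace(seg, expansion_factor=table.get(seg.name)) for seg in model.segments
    )
    return replace(model, segments=new_segments)


def compute_expansion_factors(
    hull_volumes: dict[str, list[float]],
    skin_volumes: dict[str, list[float]],
    label: str = "MEF",
) -> ExpansionFactorTable:
    """Derive per-segment expansion factors from paired hull and skin volumes.

    For each segment the factor is the arithmetic mean over reference
    specimens of the skin/hull volume ratio.
    """
    if set(hull_volumes) != set(skin_volumes):
        raise SegmentValidationError(
            f"segment sets differ: {sorted(set(hull_volumes) ^ set(skin_volumes))}"
        )
    factors: dict[str, float] = {}
    for name, hulls in hull_volumes.items():
        skins = skin_volumes[name]
        if len(hulls) != len(skins):
            raise SegmentValidationError(
                f"{name}: {len(hulls)} hull vs {len(skins)} skin volumes (must be paired)"
            )
        if not hulls:
            raise SegmentValidationError(f"{name}: no reference specimens")
        ratios = []
        for h, s in zip(hulls, skins):
            if not (h > 0 and s > 0):
                raise SegmentValidationError(f"{name}: volumes must be positive, got ({h}, {s})")
            ratios.append(s / h)
        factors[name] = float(np.mean(ratios))
    return ExpansionFactorTable(factors=factors, label=label)


def deflate_trunk(model: BodyModel, fraction: float) -> BodyModel:
    """Scale the trunk's effective volume to ``fraction`` of its hull volume.

    Implemented by multiplying the trunk's expansion factor, leaving every
    other segment untouched; fractions of 0.9/0.8/0.7 bracket measured
    segment-density variation.
    """
    if not 0 < fraction <= 1:
        raise SegmentValidationError(f"deflation fraction must be in (0, 1], got {fraction}")
    if not model.has_segment("trunk"):
        raise SegmentValidationError(f"{model.specimen}: no trunk segment to deflate")
    new_segments = tuple(
        replace(seg, expansion_factor=seg.expansion_factor * fraction)
        if seg.name == "trunk"
        else seg
        for seg in model.segments
    )
    return replace(model, segments=new_segments)


def center_of_mass(model: BodyModel) -> np.ndarray:
    """Mass-weighted mean of segment centroids (metres).

    CoM = sum(m_i c_i) / sum(m_i) with m_i = V_i * EF_i * rho_i; it always
    lies in the convex hull of the segment centroids, and is invariant to
    any global rescaling of density.
    """
    masses = np.array([seg.mass for seg in model.segments])
    total = masses.sum()
    if total <= 0:
        raise SegmentValidationError(f"{model.specimen}: total effective mass is zero")
    centroids = np.vstack([seg.centroid for seg in model.segments])
    return (masses[:, None] * centroids).sum(axis=0) / total


def com_metrics(model: BodyModel) -> CoMMetrics:
    """Compute ``%C(AG)``, ``DCA/FL`` and the log10 skull:tail volume ratio.

    The cranial direction is the acetabulum->glenoid unit vector; both
    positional proxies are the CoM's projection onto that single axis,
    which makes them exactly invariant under rigid motion of the whole
    model and under uniform density rescaling.
    """
    if model.landmarks is None:
        raise SegmentValidationError(f"{model.specimen}: landmarks required for CoM metrics")
    lm = model.landmarks
    com = center_of_mass(model)
    axis = lm.glenoid - lm.acetabulum
    ag_length = float(np.linalg.norm(axis))
    axis_unit = axis / ag_length
    dca = float(np.dot(com - lm.acetabulum, axis_unit))
    pct_ag = 100.0 * dca / ag_length
    dca_fl = dca / lm.femur_length

    log10_skull_tail: float | None = None
    tail_vol = model.tail_volume
    if model.has_segment("skull") and tail_vol > 0:
        log10_skull_tail = math.log10(model.segment("skull").volume / tail_vol)
    return CoMMetrics(com=com, pct_AG=pct_ag, dca_fl=dca_fl, log10_skull_tail=log10_skull_tail)


# --- serialization helpers ---------------------------------------------------


def load_landmarks_json(path: str | Path) -> Landmarks:
    """Read landmarks from JSON: {"acetabulum": [x,y,z], "glenoid": [x,y,z],
    "femur_length_m": f}."""
    with open(path) as fh:
        data = json.load(fh)
    return Landmarks(
        acetabulum=data["acetabulum"],
        glenoid=data["glenoid"],
        femur_length=float(data["femur_length_m"]),
    )


def load_expansion_table(path: str | Path) -> ExpansionFactorTable:
    """Read an expansion-factor table from JSON ({"label": ..., "factors":
    {segment: factor}}) or two-column CSV (segment,factor)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        return ExpansionFactorTable(
            factors={k: float(v) for k, v in data["factors"].items()},
            label=data.get("label", "MEF"),
        )
    factors: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            factors[row["segment"]] = float(row["factor"])
    label = "SEF" if "sef" in path.stem.lower() else "MEF"
    return ExpansionFactorTable(factors=factors, label=label)


def write_com_report(rows: list[dict], path: str | Path) -> None:
    """Write per-specimen CoM metrics as CSV (one row per model variant)."""
    fieldnames = ["specimen", "clade", "pct_AG", "dca_fl", "log10_skull_tail", "variant"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in fieldnames})
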