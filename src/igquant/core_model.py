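"""Shared data model for immunogold particle analysis.

Freeze-fracture replica immunogold labelling marks membrane proteins with
gold spheres of two nominal diameters (5 nm and 10 nm).  Every analysis in
this package operates on the types defined here: particle records with
continuous nm coordinates, polygonal membrane-profile regions of interest,
single-linkage clusters, Monte Carlo simulation ensembles, and the
association/dissociation inference results built from them.

Coordinate convention: continuous nanometres, origin at the image top-left
corner, y increasing downward.  Pixel index ``i`` maps to nm coordinate
``(i + 0.5) * scale_nm_per_px`` (pixel centres).  Distances are Euclidean
between particle centres; the 5/10 nm size class is nominal and never
enters distance computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

SIZE_CLASSES = (5, 10)
SOURCES = ("real", "simulated")
COMPARTMENTS = (
    "soma",
    "apical_dendrite",
    "oblique_dendrite",
    "spine",
    "axon_terminal",
    "active_zone",
    "extrasynaptic",
    "e_face_background",
)
FACES = ("P", "E")

NM2_PER_UM2 = 1.0e6


@dataclass
class Particle:
    """One gold-particle record.

    Positions are in nanometres from the image top-left corner.
    ``confidence`` is the classifier posterior for automatically detected
    particles and 1.0 for manually clicked or imported ones.
    """

    id: str
    x_nm: float
    y_nm: float
    radius_nm: float
    size_class: int
    source: str = "real"
    confidence: float = 1.0


@dataclass
class ProfileROI:
    """Polygonal membrane profile with compartment label and area.

    ``polygon`` is an ordered vertex list in nm forming a simple closed
    polygon.  ``area_um2`` is the shoelace area divided by 1e6
    (1 um^2 = 1e6 nm^2); it is computed on construction when not given.
    """

    id: str
    polygon: list[tuple[float, float]]
    compartment: str
    face: str = "P"
    area_um2: float | None = None

    def __post_init__(self) -> None:
        if self.area_um2 is None:
            self.area_um2 = shoelace_area_nm2(self.polygon) / NM2_PER_UM2

    def shapely_polygon(self) -> Polygon:
        return Polygon(self.polygon)

    def contains(self, x_nm: float, y_nm: float) -> bool:
        # boundary counts as inside
        return self.shapely_polygon().covers(Point(x_nm, y_nm))


@dataclass
class ImageRecord:
    """One micrograph's worth of data: scale, profile ROIs, particles."""

    id: str
    scale_nm_per_px: float
    rois: list[ProfileROI] = field(default_factory=list)
    particles: list[Particle] = field(default_factory=list)
    animal_id: str = ""

    def particles_of_class(self, size_class: int, source: str = "real") -> list[Particle]:
        return [p for p in self.particles if p.size_class == size_class and p.source == source]


@dataclass
class ClusterRecord:
    """Single-linkage cluster of particles of one size class.

    ``hull_area_nm2`` is the convex-hull area of the member positions
    (0 for collinear members).  Clusters with fewer than the minimum
    member count (default 3) are discarded at construction time by the
    clustering routine, never here.
    """

    member_ids: list[str]
    size_class: int
    n_particles: int
    hull_area_nm2: float
    centroid_nm: tuple[float, float]
    member_xy: np.ndarray | None = None  # (n, 2) positions, kept for distance queries


@dataclass
class NNDResult:
    """Nearest-neighbour distances from one particle class to another.

    intra: from each particle of a class to its nearest same-class
    neighbour (itself excluded).  inter: from each particle of
    ``from_class`` to the nearest particle of ``to_class``.
    """

    kind: str  # "intra" | "inter"
    from_class: int
    to_class: int
    distances_nm: np.ndarray
    mean_nm: float


@dataclass
class SimulationEnsemble:
    """Per-image set of simulated mean NNDs under one null mode."""

    mode: str  # "random" | "fitted"
    n_sims: int
    seed: int
    sim_mean_nnds: np.ndarray
    hard_core_nm: float = 10.0
    ks_alpha: float | None = None  # fitted mode only


@dataclass
class AssociationResult:
    """Per-image association/dissociation verdict against an ensemble."""

    image_id: str
    real_mean_nm: float
    n_lower: int
    n_upper: int
    verdict: str  # "associated" | "dissociated" | "ns"
    alpha: float = 0.05
    p_low: float = math.nan
    p_high: float = math.nan


@dataclass
class CompartmentResult:
    """Compartment-level summary row (one line of the NND summary table)."""

    compartment: str
    molecule_pair: str
    n_images: int
    real_mean_of_means: float
    real_sd_of_means: float
    sim_mean_of_means: float
    sim_sd_of_means: float
    t_statistic: float
    p_raw: float
    p_adjusted: float
    pct_associated: float
    pct_dissociated: float


def shoelace_area_nm2(vertices: Sequence[tuple[float, float]]) -> float:
    """Unsigned polygon area in nm^2 by the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_is_simple(vertices: Sequence[tuple[float, float]]) -> bool:
    """True iff the closed polygon does not self-intersect."""
    if len(vertices) < 3:
        return False
    return Polygon(vertices).is_valid


def validate_image_record(record: ImageRecord) -> list[str]:
    """Check every type invariant; return one descriptor per violation.

    Validation never raises — each returned string names the offending
    field and the rule broken.  An empty list means the record is
    well-formed.
    """
    violations: list[str] = []
    if not record.scale_nm_per_px > 0:
        violations.append(f"ImageRecord.scale_nm_per_px: must be > 0, got {record.scale_nm_per_px}")

    polygons = []
    for roi in record.rois:
        if len(roi.polygon) < 3:
            violations.append(f"ProfileROI[{roi.id}].polygon: needs >= 3 vertices, got {len(roi.polygon)}")
            continue
        if not polygon_is_simple(roi.polygon):
            violations.append(f"ProfileROI[{roi.id}].polygon: self-intersecting")
            continue
        if roi.compartment not in COMPARTMENTS:
            violations.append(f"ProfileROI[{roi.id}].compartment: unknown label {roi.compartment!r}")
        if roi.face not in FACES:
            violations.append(f"ProfileROI[{roi.id}].face: unknown face {roi.face!r}")
        expected = shoelace_area_nm2(roi.polygon) / NM2_PER_UM2
        if not math.isclose(roi.area_um2, expected, rel_tol=1e-9, abs_tol=1e-15):
            violations.append(
                f"ProfileROI[{roi.id}].area_um2: stored {roi.area_um2} != shoelace {expected}"
            )
        polygons.append(Polygon(roi.polygon))

    for p in record.particles:
        if not (math.isfinite(p.x_nm) and math.isfinite(p.y_nm) and p.x_nm >= 0 and p.y_nm >= 0):
            violations.append(f"Particle[{p.id}].x_nm/y_nm: must be finite and >= 0")
        if not p.radius_nm > 0:
            violations.append(f"Particle[{p.id}].radius_nm: must be > 0, got {p.radius_nm}")
        if p.size_class not in SIZE_CLASSES:
            violations.append(f"Particle[{p.id}].size_class: must be 5 or 10, got {p.size_class}")
        if p.source not in SOURCES:
            violations.append(f"Particle[{p.id}].source: unknown source {p.source!r}")
        if not 0.0 <= p.confidence <= 1.0:
            violations.append(f"Particle[{p.id}].confidence: must be in [0, 1], got {p.confidence}")
        if polygons and math.isfinite(p.x_nm) and math.isfinite(p.y_nm):
            pt = Point(p.x_nm, p.y_nm)
            if not any(poly.covers(pt) for poly in polygons):
                violations.append(f"Particle[{p.id}]: out-of-roi (centre inside no ROI polygon)")
    return violations


def particles_xy(particles: Sequence[Particle]) -> np.ndarray:
    """Stack particle centres into an (n, 2) float array."""
    if not particles:
        return np.empty((0, 2))
    return np.array([[p.x_nm, p.y_nm] for p in particles], dtype=float)
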