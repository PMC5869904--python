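"""Ground-truthed synthetic point patterns and rendered replica images.

Replica micrographs with usable ground truth are essentially never
available, so every analysis in this package is exercised on synthetic
data whose ground truth is known exactly.
Two generators are provided:

point patterns
    Uniform hard-core CSR and Thomas-style Poisson cluster processes
    (Gaussian-dispersed children around uniform parents), in univariate
    and bivariate flavours: co-clustered (shared parents), segregated
    (disjoint parent sets kept apart by parent-level inhibition), and
    independent.  The 10 nm hard core is enforced by rejection in every
    mode, matching the physical exclusion between gold particles.

rendered images
    Dark anti-aliased disks of each particle's radius over a textured,
    noisy background, with a few non-circular dark artefacts so the
    detection classifier has something to reject.  Ground truth is the
    exact input coordinate table.

Defaults emulate the labelling regimes reported for replica micrographs:
profile areas around 1 um^2, densities of tens to a few hundred particles
per um^2, and clusters of mostly 3-8 particles (~8 parents x ~6 children
with 15 nm dispersion in a 1 um^2 profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .core_model import ImageRecord, Particle, ProfileROI
from .io_formats import write_image, write_particles, write_roi
from .simulation import PackingInfeasibleError, _place_hard_core, _RoiSampler

PROCESSES = (
    "csr",
    "clustered",
    "bivariate_coclustered",
    "bivariate_segregated",
    "bivariate_independent",
)


@dataclass
class PatternSpec:
    """Parameters of one synthetic point pattern.

    For ``csr`` / ``bivariate_independent`` the particle count per class
    is Poisson(intensity x area).  For the clustered processes the count
    comes from ``n_parents`` parents with Poisson(``mean_children``)
    children each (truncated at >= 1), displaced by an isotropic Gaussian
    of SD ``dispersion_nm``.  ``offset_nm`` displaces the second class's
    cluster centres in co-clustered mode.

    Segregated mode keeps the class-2 parents at least
    ``segregation_inhibition_nm`` away from every class-1 parent.  For
    segregation to be more than nominal this exclusion must exceed the
    typical nearest cross-parent distance under random placement
    (~0.5 / sqrt(n_parents / area) — about 180 nm at the defaults), so
    the default is 150 nm; values below the 4 x dispersion floor (where
    clusters would simply overlap) are rejected.
    """

    process: str = "csr"
    width_nm: float = 1000.0
    height_nm: float = 1000.0
    intensity_per_um2: dict = field(default_factory=lambda: {10: 50.0, 5: 50.0})
    n_parents: int = 8
    mean_children: float = 6.0
    dispersion_nm: float = 15.0
    hard_core_nm: float = 10.0
    offset_nm: float = 0.0
    segregation_inhibition_nm: float = 150.0
    compartment: str = "spine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}")
        if self.dispersion_nm <= 0 or self.width_nm <= 0 or self.height_nm <= 0:
            raise ValueError("dispersion and ROI dimensions must be positive")
        if any(v <= 0 for v in self.intensity_per_um2.values()):
            raise ValueError("intensities must be positive")
        if self.process == "bivariate_segregated" and (
            self.segregation_inhibition_nm < 4.0 * self.dispersion_nm
        ):
            raise ValueError(
                "segregation_inhibition_nm must be >= 4 x dispersion_nm"
            )


@dataclass
class PatternTruth:
    """Ground truth of a generated pattern."""

    parent_xy: dict  # class -> (n_parents, 2) array
    parent_index: dict  # class -> per-particle parent index (-1 for CSR)


def _rect_roi(spec: PatternSpec, roi_id: str = "roi0") -> ProfileROI:
    w, h = spec.width_nm, spec.height_nm
    return ProfileROI(
        id=roi_id,
        polygon=[(0.0, 0.0), (w, 0.0), (w, h), (0.0, h)],
        compartment=spec.compartment,
    )


def _csr_count(rng: np.random.Generator, intensity: float, area_um2: float) -> int:
    return max(2, int(rng.poisson(intensity * area_um2)))


def _place_children(
    parents: np.ndarray,
    parent_of: np.ndarray,
    spec: PatternSpec,
    existing: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Gaussian-dispersed children with in-ROI + hard-core rejection."""
    hc2 = spec.hard_core_nm**2
    placed = np.empty((len(parent_of), 2))
    n_placed = 0
    for idx in parent_of:
        for attempt in range(max_tries):
            pt = parents[idx] + rng.normal(0.0, spec.dispersion_nm, 2)
            if not (0 <= pt[0] <= spec.width_nm and 0 <= pt[1] <= spec.height_nm):
                continue
            if len(existing) and (((existing - pt) ** 2).sum(axis=1) < hc2).any():
                continue
            if n_placed and (((placed[:n_placed] - pt) ** 2).sum(axis=1) < hc2).any():
                continue
            placed[n_placed] = pt
            n_placed += 1
            break
        else:
            raise PackingInfeasibleError(
                f"could not place child of parent {idx} within {max_tries} tries"
            )
    return placed


def _children_counts(rng: np.random.Generator, n_parents: int, mean_children: float) -> np.ndarray:
    """Poisson(mean) truncated at >= 1, one count per parent."""
    counts = rng.poisson(mean_children, n_parents)
    return np.maximum(counts, 1)


def gen_pattern(spec: PatternSpec) -> tuple[ImageRecord, PatternTruth]:
    """Generate one ground-truthed bivariate (or univariate) pattern.

    Returns an :class:`ImageRecord` (rectangular ROI, particle list) plus
    the generator's ground truth (parent positions and per-particle
    parent assignments).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    roi = _rect_roi(spec)
    polygon = Polygon(roi.polygon)
    sampler = _RoiSampler(polygon)
    area_um2 = roi.area_um2
    w, h = spec.width_nm, spec.height_nm
    hc = spec.hard_core_nm
    parent_xy: dict = {}
    parent_index: dict = {}
    xy_by_class: dict[int, np.ndarray] = {}

    def uniform_parents(n: int) -> np.ndarray:
        return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])

    if spec.process == "csr":
        n = _csr_count(rng, spec.intensity_per_um2[10], area_um2)
        xy_by_class[10] = _place_hard_core(n, sampler, np.empty((0, 2)), hc, rng, 1_000_000)
        parent_index[10] = np.full(n, -1)
    elif spec.process == "bivariate_independent":
        existing = np.empty((0, 2))
        for cls in (10, 5):
            n = _csr_count(rng, spec.intensity_per_um2[cls], area_um2)
            xy = _place_hard_core(n, sampler, existing, hc, rng, 1_000_000)
            xy_by_class[cls] = xy
            parent_index[cls] = np.full(n, -1)
            existing = np.vstack([existing, xy])
    elif spec.process == "clustered":
        parents = uniform_parents(spec.n_parents)
        counts = _children_counts(rng, spec.n_parents, spec.mean_children)
        parent_of = np.repeat(np.arange(spec.n_parents), counts)
        xy_by_class[10] = _place_children(parents, parent_of, spec, np.empty((0, 2)), rng)
        parent_xy[10] = parents
        parent_index[10] = parent_of
    elif spec.process == "bivariate_coclustered":
        parents = uniform_parents(spec.n_parents)
        counts1 = _children_counts(rng, spec.n_parents, spec.mean_children)
        parent_of1 = np.repeat(np.arange(spec.n_parents), counts1)
        xy1 = _place_children(parents, parent_of1, spec, np.empty((0, 2)), rng)
        # class-2 cluster centres displaced by offset_nm in a random direction
        theta = rng.uniform(0, 2 * np.pi, spec.n_parents)
        parents2 = parents + spec.offset_nm * np.column_stack([np.cos(theta), np.sin(theta)])
        parents2 = np.clip(parents2, [0, 0], [w, h])
        counts2 = _children_counts(rng, spec.n_parents, spec.mean_children)
        parent_of2 = np.repeat(np.arange(spec.n_parents), counts2)
        xy2 = _place_children(parents2, parent_of2, spec, xy1, rng)
        xy_by_class[10], xy_by_class[5] = xy1, xy2
        parent_xy[10], parent_xy[5] = parents, parents2
        parent_index[10], parent_index[5] = parent_of1, parent_of2
    elif spec.process == "bivariate_segregated":
        inhibition = spec.segregation_inhibition_nm
        parents1 = uniform_parents(spec.n_parents)
        parents2 = np.empty((spec.n_parents, 2))
        placed = 0
        tries = 0
        while placed < spec.n_parents:
            if tries > 100_000:
                raise PackingInfeasibleError("segregated parent placement infeasible")
            cand = np.array([rng.uniform(0, w), rng.uniform(0, h)])
            tries += 1
            if (((parents1 - cand) ** 2).sum(axis=1) < inhibition**2).any():
                continue
            parents2[placed] = cand
            placed += 1
        counts1 = _children_counts(rng, spec.n_parents, spec.mean_children)
        parent_of1 = np.repeat(np.arange(spec.n_parents), counts1)
        xy1 = _place_children(parents1, parent_of1, spec, np.empty((0, 2)), rng)
        counts2 = _children_counts(rng, spec.n_parents, spec.mean_children)
        parent_of2 = np.repeat(np.arange(spec.n_parents), counts2)
        xy2 = _place_children(parents2, parent_of2, spec, xy1, rng)
        xy_by_class[10], xy_by_class[5] = xy1, xy2
        parent_xy[10], parent_xy[5] = parents1, parents2
        parent_index[10], parent_index[5] = parent_of1, parent_of2

    particles = []
    for cls in sorted(xy_by_class, reverse=True):  # 10 nm first, stable ids
        for i, (x, y) in enumerate(xy_by_class[cls]):
            particles.append(
                Particle(
                    id=f"c{cls}_{i}",
                    x_nm=float(x),
                    y_nm=float(y),
                    radius_nm=cls / 2.0,
                    size_class=cls,
                    source="real",
                    confidence=1.0,
                )
            )
    record = ImageRecord(
        id=f"{spec.process}_{spec.seed}",
        scale_nm_per_px=1.0,
        rois=[roi],
        particles=particles,
        animal_id="synthetic",
    )
    return record, PatternTruth(parent_xy=parent_xy, parent_index=parent_index)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderSpec:
    """Parameters of the replica-like renderer.

    Gold particles render as dark disks (intensity dip ``particle_depth``)
    with a Gaussian-soft edge; the background is a mid-grey with smooth
    correlated texture (``texture_sd``, ~3 px correlation length) plus
    per-pixel shot noise (``noise_sd``).  ``n_artifacts`` elongated dark
    blobs of particle-like size are added as classifier negatives.
    The reference noise level used by the detection fixtures is the
    default (texture 0.05, shot noise 0.03).
    """

    scale_nm_per_px: float = 1.0
    width_px: int = 600
    height_px: int = 600
    background_mean: float = 0.6
    texture_sd: float = 0.05
    noise_sd: float = 0.03
    particle_depth: float = 0.45
    edge_softness_px: float = 0.8
    n_artifacts: int = 0
    artifact_depth: float = 0.3

    def __post_init__(self) -> None:
        for name in ("texture_sd", "noise_sd", "edge_softness_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def render_image(
    particles: list[Particle], spec: RenderSpec, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Render particles onto a noisy background.

    Returns (image in [0, 1], ground-truth table with exact nm input
    coordinates, artefact centre array in nm).  Artefacts are anisotropic
    Gaussian dark blobs placed uniformly at least 3 particle diameters
    from every true particle.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    img = np.full((h, w), spec.background_mean)
    if spec.texture_sd > 0:
        texture = gaussian_filter(rng.normal(0, 1, (h, w)), sigma=3.0)
        texture *= spec.texture_sd / max(texture.std(), 1e-12)
        img += texture

    yy, xx = np.mgrid[0:h, 0:w]
    for p in particles:
        cx = p.x_nm / spec.scale_nm_per_px - 0.5
        cy = p.y_nm / spec.scale_nm_per_px - 0.5
        r = p.radius_nm / spec.scale_nm_per_px
        x0, x1 = max(0, int(cx - r - 4)), min(w, int(cx + r + 5))
        y0, y1 = max(0, int(cy - r - 4)), min(h, int(cy + r + 5))
        if x1 <= x0 or y1 <= y0:
            continue
        dist = np.hypot(xx[y0:y1, x0:x1] - cx, yy[y0:y1, x0:x1] - cy)
        # smooth-edged disk coverage in [0, 1]
        soft = max(spec.edge_softness_px, 1e-6)
        coverage = 1.0 / (1.0 + np.exp((dist - r) / (0.5 * soft)))
        img[y0:y1, x0:x1] -= spec.particle_depth * coverage

    particle_xy = np.array([[p.x_nm, p.y_nm] for p in particles]) if particles else np.empty((0, 2))
    artifact_xy = []
    guard = 3 * 10.0  # stay clear of true particles
    tries = 0
    while len(artifact_xy) < spec.n_artifacts and tries < 100_000:
        tries += 1
        cand = np.array(
            [rng.uniform(30, (w - 30) * spec.scale_nm_per_px),
             rng.uniform(30, (h - 30) * spec.scale_nm_per_px)]
        )
        if len(particle_xy) and (((particle_xy - cand) ** 2).sum(axis=1) < guard**2).any():
            continue
        artifact_xy.append(cand)
        cx = cand[0] / spec.scale_nm_per_px - 0.5
        cy = cand[1] / spec.scale_nm_per_px - 0.5
        sx = rng.uniform(2.0, 6.0)
        sy = rng.uniform(1.0, 3.0)
        angle = rng.uniform(0, np.pi)
        x0, x1 = max(0, int(cx - 20)), min(w, int(cx + 21))
        y0, y1 = max(0, int(cy - 20)), min(h, int(cy + 21))
        dx = xx[y0:y1, x0:x1] - cx
        dy = yy[y0:y1, x0:x1] - cy
        u = dx * np.cos(angle) + dy * np.sin(angle)
        v = -dx * np.sin(angle) + dy * np.cos(angle)
        img[y0:y1, x0:x1] -= spec.artifact_depth * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))

    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, (h, w))
    img = np.clip(img, 0.0, 1.0)

    truth = pd.DataFrame(
        [
            {
                "particle_id": p.id,
                "x_nm": p.x_nm,
                "y_nm": p.y_nm,
                "radius_nm": p.radius_nm,
                "size_class": p.size_class,
            }
            for p in particles
        ],
        columns=["particle_id", "x_nm", "y_nm", "radius_nm", "size_class"],
    )
    return img, truth, np.asarray(artifact_xy) if artifact_xy else np.empty((0, 2))


# ---------------------------------------------------------------------------
# fixture suite


def make_fixture_suite(
    out_dir: str | Path,
    seed: int = 0,
    n_detection: int = 12,
    n_null: int = 400,
    n_coclustered: int = 30,
    n_segregated: int = 30,
) -> dict:
    """Write the deterministic on-disk fixture dataset.

    Rendered images for detection, null bivariate patterns for
    calibration, and co-clustered / segregated patterns for power tests,
    plus a manifest listing every file with its generator parameters.
    Rerunning with the same seed reproduces the manifest byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "groups": {}}

    det_dir = out / "detection"
    det_dir.mkdir(exist_ok=True)
    det_entries = []
    for i in range(n_detection):
        pat_spec = PatternSpec(
            process="csr",
            width_nm=600.0,
            height_nm=600.0,
            intensity_per_um2={10: 80.0},
            seed=seed + 1000 + i,
        )
        record, _ = gen_pattern(pat_spec)
        render = RenderSpec(n_artifacts=8)
        img, truth, _ = render_image(record.particles, render, seed=seed + 2000 + i)
        name = f"det_{i:02d}"
        write_image(img, det_dir / f"{name}.tiff", render.scale_nm_per_px)
        truth.to_csv(det_dir / f"{name}_truth.csv", index=False)
        det_entries.append(
            {"file": f"{name}.tiff", "pattern_seed": pat_spec.seed, "render_seed": seed + 2000 + i,
             "n_particles": len(record.particles)}
        )
    manifest["groups"]["detection"] = det_entries

    def write_group(name: str, process: str, n_images: int, seed0: int, **kw) -> None:
        group_dir = out / name
        group_dir.mkdir(exist_ok=True)
        by_image = {}
        entries = []
        roi_written = False
        for i in range(n_images):
            spec = PatternSpec(process=process, seed=seed0 + i, **kw)
            record, _ = gen_pattern(spec)
            by_image[record.id] = record.particles
            if not roi_written:
                write_roi(record.rois, group_dir / "roi.json")
                roi_written = True
            entries.append({"image_id": record.id, "seed": spec.seed,
                            "n_particles": len(record.particles)})
        write_particles(by_image, group_dir / "particles.csv")
        manifest["groups"][name] = entries

    write_group("null", "bivariate_independent", n_null, seed + 10_000)
    write_group("coclustered", "bivariate_coclustered", n_coclustered, seed + 20_000)
    write_group("segregated", "bivariate_segregated", n_segregated, seed + 30_000)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def detection_training_set(
    n_images: int = 4,
    seed: int = 0,
    render_spec: RenderSpec | None = None,
    match_radius_nm: float = 5.0,
) -> tuple[np.ndarray, list[str]]:
    """Labelled candidate features for training the detection classifier.

    Renders ``n_images`` ground-truthed fixtures, runs the Hough stage,
    and labels each candidate "particle" iff it falls within
    ``match_radius_nm`` of a true 10 nm particle centre (else "artefact").
    """
    from .detection import detect_circles, extract_features

    render_spec = render_spec or RenderSpec(n_artifacts=8)
    feats: list[np.ndarray] = []
    labels: list[str] = []
    for i in range(n_images):
        record, _ = gen_pattern(
            PatternSpec(
                process="csr",
                width_nm=render_spec.width_px * render_spec.scale_nm_per_px,
                height_nm=render_spec.height_px * render_spec.scale_nm_per_px,
                intensity_per_um2={10: 80.0},
                seed=seed + i,
            )
        )
        img, truth, _ = render_image(record.particles, render_spec, seed=seed + 5000 + i)
        txy = truth[["x_nm", "y_nm"]].to_numpy()
        for cand in detect_circles(img, 10.0, render_spec.scale_nm_per_px):
            fv = extract_features(img, cand, render_spec.scale_nm_per_px)
            if not fv.in_bounds:
                continue
            d = np.hypot(txy[:, 0] - cand.x_nm, txy[:, 1] - cand.y_nm).min() if len(txy) else np.inf
            feats.append(fv.values)
            labels.append("particle" if d <= match_radius_nm else "artefact")
    return np.asarray(feats), labels
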