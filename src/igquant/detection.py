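"""Automated immunogold particle detection in replica micrographs.

Gold particles appear as dark, near-circular disks of a known nominal
diameter (5 or 10 nm) on the shadowed replica texture.  Detection is a
two-stage procedure: a circular Hough transform proposes candidate
circles of the target diameter, and a supervised classifier (Gaussian
Naive Bayes by default) separates actual particles from dark artefacts
of similar size.  Accepted detections are then refined to the
intensity-weighted centroid of their neighbourhood.

Fully automated detection needs the particle to span at least 4 pixels in
diameter; below that the Hough transform is unreliable, so small (5 nm)
particles at coarse scales go through the manual-import path instead:
clicked coordinates are read from a particle table and only the position
refinement is applied.

Pixel index i corresponds to nm coordinate (i + 0.5) * scale_nm_per_px.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .core_model import Particle

FEATURE_NAMES = [
    "interior_mean",
    "interior_sd",
    "ring_contrast",
    "radial_gradient",
    "circularity",
    "background_sd",
]

MIN_DIAMETER_PX = 4.0


class DiameterTooSmallError(ValueError):
    """Target diameter spans too few pixels for automated detection."""


@dataclass
class CandidateCircle:
    x_nm: float
    y_nm: float
    radius_nm: float
    hough_score: float


@dataclass
class FeatureVector:
    values: np.ndarray  # len(FEATURE_NAMES) floats
    in_bounds: bool = True


# ---------------------------------------------------------------------------
# stage 1: circle detection


def detect_circles(
    image: np.ndarray,
    target_diameter_nm: float,
    scale_nm_per_px: float,
    radius_tolerance: float = 0.2,
    max_candidates: int = 2000,
) -> list[CandidateCircle]:
    """Hough-transform candidates of the target diameter.

    Candidates are returned sorted by descending accumulator score after
    non-maximum suppression at one radius (no two candidates closer than
    the particle radius); ties break by lower y then lower x.
    """
    diameter_px = target_diameter_nm / scale_nm_per_px
    if diameter_px < MIN_DIAMETER_PX:
        raise DiameterTooSmallError(
            f"{target_diameter_nm} nm spans {diameter_px:.2f} px at "
            f"{scale_nm_per_px} nm/px; automated detection needs >= "
            f"{MIN_DIAMETER_PX:g} px — use the manual-import path"
        )
    r_px = diameter_px / 2.0
    radii = np.arange(
        max(2, int(np.floor(r_px * (1 - radius_tolerance)))),
        int(np.ceil(r_px * (1 + radius_tolerance))) + 1,
    )
    edges = canny(image, sigma=1.0)
    if not edges.any():
        return []
    accum = hough_circle(edges, radii)
    scores, cx, cy, rad = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=1,
        min_ydistance=1,
        total_num_peaks=max_candidates,
    )
    order = np.lexsort((cx, cy, -scores))  # score desc, then y, then x
    kept: list[CandidateCircle] = []
    kept_xy: list[tuple[float, float]] = []
    for i in order:
        x, y = float(cx[i]), float(cy[i])
        if any((x - kx) ** 2 + (y - ky) ** 2 < r_px**2 for kx, ky in kept_xy):
            continue
        kept_xy.append((x, y))
        kept.append(
            CandidateCircle(
                x_nm=(x + 0.5) * scale_nm_per_px,
                y_nm=(y + 0.5) * scale_nm_per_px,
                radius_nm=float(rad[i]) * scale_nm_per_px,
                hough_score=float(scores[i]),
            )
        )
    return kept


# ---------------------------------------------------------------------------
# stage 2: features + classifier


def extract_features(
    image: np.ndarray, candidate: CandidateCircle, scale_nm_per_px: float
) -> FeatureVector:
    """Six intensity/shape features of a candidate circle.

    interior mean/SD over the candidate disk; ring contrast = annulus
    mean - interior mean (annulus from r to 2r); mean radial intensity
    step across the disk boundary; circularity (4 pi A / P^2) of the blob
    thresholded at the interior/annulus midpoint; and annulus SD as the
    local background roughness.  A candidate whose 2-radius neighbourhood
    leaves the image is flagged ``in_bounds=False`` (features from the
    clipped window), never an exception.
    """
    cx = candidate.x_nm / scale_nm_per_px - 0.5
    cy = candidate.y_nm / scale_nm_per_px - 0.5
    r = candidate.radius_nm / scale_nm_per_px
    h, w = image.shape
    in_bounds = (cx - 2 * r >= -0.5) and (cy - 2 * r >= -0.5) and (
        cx + 2 * r <= w - 0.5
    ) and (cy + 2 * r <= h - 0.5)

    x0, x1 = max(0, int(np.floor(cx - 2 * r))), min(w, int(np.ceil(cx + 2 * r)) + 1)
    y0, y1 = max(0, int(np.floor(cy - 2 * r))), min(h, int(np.ceil(cy + 2 * r)) + 1)
    window = image[y0:y1, x0:x1]
    lcx, lcy = cx - x0, cy - y0
    yy, xx = np.mgrid[0 : window.shape[0], 0 : window.shape[1]]
    dist = np.hypot(xx - lcx, yy - lcy)

    interior = window[dist <= r]
    annulus = window[(dist > r) & (dist <= 2 * r)]
    if interior.size == 0 or annulus.size == 0:
        return FeatureVector(values=np.zeros(len(FEATURE_NAMES)), in_bounds=False)

    interior_mean = float(interior.mean())
    interior_sd = float(interior.std())
    annulus_mean = float(annulus.mean())
    ring_contrast = annulus_mean - interior_mean
    inner_ring = window[(dist > max(r - 1.5, 0)) & (dist <= r)]
    outer_ring = window[(dist > r) & (dist <= r + 1.5)]
    radial_gradient = float(outer_ring.mean() - inner_ring.mean()) if (
        inner_ring.size and outer_ring.size
    ) else 0.0

    thresh = 0.5 * (interior_mean + annulus_mean)
    blob = (window <= thresh) & (dist <= 2 * r)
    area = float(blob.sum())
    if area >= 1:
        # perimeter: count of blob pixels with a non-blob 4-neighbour
        padded = np.pad(blob, 1)
        boundary = blob & ~(
            padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
        )
        perimeter = max(float(boundary.sum()), 1.0)
        circularity = min(4.0 * np.pi * area / perimeter**2, 2.0)
    else:
        circularity = 0.0
    background_sd = float(annulus.std())

    return FeatureVector(
        values=np.array(
            [interior_mean, interior_sd, ring_contrast, radial_gradient, circularity, background_sd]
        ),
        in_bounds=in_bounds,
    )


@dataclass
class ClassifierModel:
    """Gaussian Naive Bayes over the candidate features.

    Per-class Gaussian likelihood per feature, with a per-feature variance
    floor of 1e-6 x the feature's variance across all training data to
    prevent degenerate likelihoods.  The positive class is "particle";
    ``threshold`` is the posterior cut-off (posterior >= threshold keeps
    the candidate).  The instantiation shipped here is trained on rendered
    fixtures; a differently trained model can be loaded from JSON.
    """

    kind: str = "gaussian_naive_bayes"
    classes: tuple[str, str] = ("artefact", "particle")
    priors: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    means: np.ndarray = field(default_factory=lambda: np.zeros((2, len(FEATURE_NAMES))))
    variances: np.ndarray = field(default_factory=lambda: np.ones((2, len(FEATURE_NAMES))))
    threshold: float = 0.5

    def posterior_particle(self, features: np.ndarray) -> np.ndarray:
        """P(particle | features) for an (n, d) or (d,) feature array."""
        x = np.atleast_2d(np.asarray(features, float))
        log_lik = np.empty((x.shape[0], 2))
        for c in range(2):
            var = self.variances[c]
            log_lik[:, c] = (
                -0.5 * np.sum(np.log(2 * np.pi * var) + (x - self.means[c]) ** 2 / var, axis=1)
                + np.log(self.priors[c])
            )
        log_lik -= log_lik.max(axis=1, keepdims=True)
        lik = np.exp(log_lik)
        post = lik[:, self.classes.index("particle")] / lik.sum(axis=1)
        return post if post.size > 1 else post

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "classes": list(self.classes),
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "threshold": self.threshold,
            "feature_names": FEATURE_NAMES,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("feature_names") != FEATURE_NAMES:
            raise ValueError("model was trained on a different feature set")
        return cls(
            kind=payload["kind"],
            classes=tuple(payload["classes"]),
            priors=np.asarray(payload["priors"]),
            means=np.asarray(payload["means"]),
            variances=np.asarray(payload["variances"]),
            threshold=float(payload["threshold"]),
        )


def train_classifier(
    features: np.ndarray, labels: Sequence[str], threshold: float = 0.5
) -> ClassifierModel:
    """Fit the Gaussian Naive Bayes from labelled candidate features.

    ``labels`` are "particle" / "artefact"; at least 10 examples of each
    class are required.  Training is deterministic and order-independent
    (class means/variances are sufficient statistics).
    """
    x = np.asarray(features, float)
    y = np.asarray(labels)
    classes = ("artefact", "particle")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 10:
        raise ValueError(f"need >= 10 examples per class, got {counts}")
    floor = 1e-6 * x.var(axis=0)
    floor = np.where(floor > 0, floor, 1e-12)
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    variances = np.stack([np.maximum(x[y == c].var(axis=0), floor) for c in classes])
    priors = np.array([counts[c] / len(y) for c in classes])
    return ClassifierModel(
        classes=classes, priors=priors, means=means, variances=variances, threshold=threshold
    )


def classify_candidates(
    candidates: Sequence[CandidateCircle],
    features: Sequence[FeatureVector],
    model: ClassifierModel,
    size_class: int,
    id_prefix: str = "p",
) -> list[Particle]:
    """Keep candidates with particle posterior >= the model threshold.

    Emitted particles carry the posterior as their confidence; candidates
    flagged out-of-bounds by feature extraction are dropped.
    """
    kept: list[Particle] = []
    usable = [(c, f) for c, f in zip(candidates, features) if f.in_bounds]
    if not usable:
        return kept
    post = model.posterior_particle(np.stack([f.values for _, f in usable]))
    for (cand, _), p in zip(usable, np.atleast_1d(post)):
        if p >= model.threshold:
            kept.append(
                Particle(
                    id=f"{id_prefix}{len(kept)}",
                    x_nm=cand.x_nm,
                    y_nm=cand.y_nm,
                    radius_nm=cand.radius_nm,
                    size_class=size_class,
                    source="real",
                    confidence=float(p),
                )
            )
    return kept


# ---------------------------------------------------------------------------
# stage 3: position refinement


def refine_position(
    image: np.ndarray, particle: Particle, scale_nm_per_px: float
) -> Particle:
    """Move a particle to the intensity-weighted centroid of its
    neighbourhood.

    Weights are the intensities inverted about the local maximum
    (max - I) over a disk of radius particle radius + 2 px: gold
    particles are dark, so the centroid gravitates to the particle body
    while near-background pixels contribute almost nothing.  On a flat
    region every weight is zero and the position is unchanged.
    Displacement is capped at one particle radius.
    """
    r_px = particle.radius_nm / scale_nm_per_px
    win_r = r_px + 2.0
    cx = particle.x_nm / scale_nm_per_px - 0.5
    cy = particle.y_nm / scale_nm_per_px - 0.5
    h, w = image.shape
    x0, x1 = max(0, int(np.floor(cx - win_r))), min(w, int(np.ceil(cx + win_r)) + 1)
    y0, y1 = max(0, int(np.floor(cy - win_r))), min(h, int(np.ceil(cy + win_r)) + 1)
    if x1 <= x0 or y1 <= y0:
        return particle
    window = image[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = np.hypot(xx - cx, yy - cy) <= win_r
    weights = (window.max() - window) * mask
    total = weights.sum()
    if total <= 0:
        return particle
    new_cx = float((weights * xx).sum() / total)
    new_cy = float((weights * yy).sum() / total)
    dx, dy = new_cx - cx, new_cy - cy
    shift = np.hypot(dx, dy)
    if shift > r_px:  # cap displacement at one radius
        dx *= r_px / shift
        dy *= r_px / shift
    return Particle(
        id=particle.id,
        x_nm=(cx + dx + 0.5) * scale_nm_per_px,
        y_nm=(cy + dy + 0.5) * scale_nm_per_px,
        radius_nm=particle.radius_nm,
        size_class=particle.size_class,
        source=particle.source,
        confidence=particle.confidence,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


def detect_particles(
    image: np.ndarray,
    target_diameter_nm: float,
    scale_nm_per_px: float,
    model: ClassifierModel,
    radius_tolerance: float = 0.2,
    hard_core_nm: float = 10.0,
    refine: bool = True,
    id_prefix: str = "p",
) -> list[Particle]:
    """Full automated pipeline: Hough -> classify -> refine -> suppress.

    After refinement, a final suppression pass guarantees that no two
    emitted particles are closer than ``hard_core_nm`` (the physical gold
    exclusion distance); the higher-confidence particle wins.
    """
    size_class = int(round(target_diameter_nm))
    candidates = detect_circles(image, target_diameter_nm, scale_nm_per_px, radius_tolerance)
    feats = [extract_features(image, c, scale_nm_per_px) for c in candidates]
    particles = classify_candidates(candidates, feats, model, size_class, id_prefix)
    if refine:
        particles = [refine_position(image, p, scale_nm_per_px) for p in particles]
    particles.sort(key=lambda p: (-p.confidence, p.y_nm, p.x_nm))
    kept: list[Particle] = []
    for p in particles:
        if all(np.hypot(p.x_nm - q.x_nm, p.y_nm - q.y_nm) >= hard_core_nm for q in kept):
            kept.append(p)
    for i, p in enumerate(kept):
        p.id = f"{id_prefix}{i}"
    return kept


def import_manual_particles(
    image: np.ndarray,
    clicked_xy_nm: np.ndarray,
    size_class: int,
    scale_nm_per_px: float,
    id_prefix: str = "m",
) -> list[Particle]:
    """Manual-detection path: imported click coordinates, refined in place.

    Used for particles too small for the automated path (5 nm gold at
    coarse scales).  Confidence is 1.0 for manually placed particles.
    """
    out = []
    for i, (x, y) in enumerate(np.atleast_2d(np.asarray(clicked_xy_nm, float))):
        p = Particle(
            id=f"{id_prefix}{i}",
            x_nm=float(x),
            y_nm=float(y),
            radius_nm=size_class / 2.0,
            size_class=size_class,
            source="real",
            confidence=1.0,
        )
        out.append(refine_position(image, p, scale_nm_per_px))
    return out


def match_detections(
    detected_xy: np.ndarray, truth_xy: np.ndarray, match_radius_nm: float = 5.0
) -> tuple[int, np.ndarray]:
    """Greedy one-to-one matching of detections to ground-truth positions.

    Returns (number of true positives, localization errors of the matched
    pairs in nm).  Each detection matches at most one truth point within
    ``match_radius_nm``.
    """
    detected_xy = np.atleast_2d(np.asarray(detected_xy, float)) if len(detected_xy) else np.empty((0, 2))
    truth_xy = np.atleast_2d(np.asarray(truth_xy, float)) if len(truth_xy) else np.empty((0, 2))
    used: set[int] = set()
    errors = []
    for t in range(len(truth_xy)):
        if len(detected_xy) == 0:
            break
        d = np.hypot(detected_xy[:, 0] - truth_xy[t, 0], detected_xy[:, 1] - truth_xy[t, 1])
        for j in used:
            d[j] = np.inf
        j = int(np.argmin(d))
        if d[j] <= match_radius_nm:
            used.add(j)
            errors.append(float(d[j]))
    return len(errors), np.asarray(errors)
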