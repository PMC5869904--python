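"""Deterministic geometry and point-pattern statistics.

Nearest-neighbour distances (NNDs) between gold particles, single-linkage
clustering with the mean + 2 SD distance threshold, convex-hull cluster
areas, labelling densities per membrane profile, Ripley's K, inter-cluster
distances, and the cluster area-vs-count correlation.

All distances are Euclidean between particle centres, in nm.  Estimators
are uncorrected for edge effects by default; a toroidal variant of the
NND/K estimators exists for self-tests on rectangular regions, where
closed forms under complete spatial randomness (CSR) are available:
mean intra-NND -> 1/(2 sqrt(lambda)) and K(r) -> pi r^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import cdist, pdist

from .core_model import ClusterRecord, NNDResult, Particle, ProfileROI, particles_xy


class InsufficientParticlesError(ValueError):
    """Too few particles for the requested statistic; the image is excluded."""


@dataclass
class DensityRecord:
    image_id: str
    roi_id: str
    compartment: str
    size_class: int
    n_particles: int
    area_um2: float
    density_per_um2: float


@dataclass
class RipleyCurve:
    radii_nm: np.ndarray
    k_values: np.ndarray
    estimator: str  # "naive" | "toroidal"


# ---------------------------------------------------------------------------
# nearest-neighbour distances


def nnd_from_xy(
    from_xy: np.ndarray,
    to_xy: np.ndarray,
    same_set: bool,
    period: tuple[float, float] | None = None,
) -> np.ndarray:
    """One NND per from-point, to the nearest to-point (self excluded
    when the sets coincide).  ``period`` wraps distances on a torus."""
    from_xy = np.asarray(from_xy, float)
    to_xy = np.asarray(to_xy, float)
    boxsize = None
    if period is not None:
        boxsize = np.asarray(period, float)
        from_xy = np.mod(from_xy, boxsize)
        to_xy = np.mod(to_xy, boxsize)
    tree = cKDTree(to_xy, boxsize=boxsize)
    if same_set:
        d, _ = tree.query(from_xy, k=2)
        return d[:, 1]
    d, _ = tree.query(from_xy, k=1)
    return d


def nnd(
    particles: Sequence[Particle],
    kind: str,
    from_class: int,
    to_class: int,
    period: tuple[float, float] | None = None,
) -> NNDResult:
    """Intra- or inter-type nearest-neighbour distances.

    intra (from_class == to_class): per particle of the class, distance to
    its nearest same-class neighbour; requires >= 2 particles of the class.
    inter: per particle of ``from_class``, distance to the nearest particle
    of ``to_class``; requires >= 1 particle of each class.
    """
    if kind == "intra":
        if from_class != to_class:
            raise ValueError("intra NND requires from_class == to_class")
        pts = [p for p in particles if p.size_class == from_class]
        if len(pts) < 2:
            raise InsufficientParticlesError(
                f"intra NND needs >= 2 particles of class {from_class}, got {len(pts)}"
            )
        xy = particles_xy(pts)
        d = nnd_from_xy(xy, xy, same_set=True, period=period)
    elif kind == "inter":
        if from_class == to_class:
            raise ValueError("inter NND requires from_class != to_class")
        src = [p for p in particles if p.size_class == from_class]
        dst = [p for p in particles if p.size_class == to_class]
        if not src or not dst:
            raise InsufficientParticlesError(
                f"inter NND needs >= 1 particle of each class ({len(src)} vs {len(dst)})"
            )
        d = nnd_from_xy(particles_xy(src), particles_xy(dst), same_set=False, period=period)
    else:
        raise ValueError(f"kind must be 'intra' or 'inter', got {kind!r}")
    return NNDResult(
        kind=kind,
        from_class=from_class,
        to_class=to_class,
        distances_nm=d,
        mean_nm=float(np.mean(d)),
    )


# ---------------------------------------------------------------------------
# clustering


def cluster_threshold(nnd_result: NNDResult, rule: str = "mean_plus_2sd",
                      fixed_nm: float | None = None) -> float:
    """Clustering distance threshold from the intra-type NND distribution.

    The default rule is mean + 2 x sample SD (n-1 denominator) of the
    NNDs; ``mean`` and ``mean_plus_1sd`` are the alternatives that were
    considered before mean + 2 SD was adopted, and ``fixed`` bypasses the
    data-driven rule entirely.
    """
    if rule == "fixed":
        if fixed_nm is None or fixed_nm <= 0:
            raise ValueError("rule='fixed' requires positive fixed_nm")
        return float(fixed_nm)
    d = np.asarray(nnd_result.distances_nm, float)
    if d.size < 2:
        raise InsufficientParticlesError("threshold needs >= 2 NND values")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if rule == "mean":
        return mean
    if rule == "mean_plus_1sd":
        return mean + sd
    if rule == "mean_plus_2sd":
        return mean + 2.0 * sd
    raise ValueError(f"unknown threshold rule {rule!r}")


def cluster_area(member_xy: np.ndarray) -> float:
    """Convex-hull area (nm^2) of member positions; 0 for collinear sets."""
    pts = np.asarray(member_xy, float)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:  # collinear / duplicate points -> degenerate hull
        return 0.0


def single_linkage_clusters(
    particles: Sequence[Particle],
    threshold_nm: float,
    min_cluster_size: int = 3,
) -> list[ClusterRecord]:
    """Single-linkage clusters of one particle class at a distance cut.

    Any pair of particles at centre distance <= ``threshold_nm`` ends up in
    the same cluster (connected components of the threshold graph, which is
    what cutting an agglomerative single-linkage dendrogram at the
    threshold produces).  Components smaller than ``min_cluster_size``
    (default 3, i.e. one- and two-particle clusters) are discarded;
    their particles still count in every non-cluster analysis.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be > 0")
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    pts = list(particles)
    if not pts:
        return []
    classes = {p.size_class for p in pts}
    sources = {p.source for p in pts}
    if len(classes) > 1 or len(sources) > 1:
        raise ValueError("clustering operates on a single size class and source at a time")

    xy = particles_xy(pts)
    if len(pts) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(xy), method="single")
        labels = fcluster(z, t=threshold_nm, criterion="distance")

    records = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_cluster_size:
            continue
        member_xy = xy[idx]
        records.append(
            ClusterRecord(
                member_ids=[pts[i].id for i in idx],
                size_class=pts[0].size_class,
                n_particles=len(idx),
                hull_area_nm2=cluster_area(member_xy),
                centroid_nm=(float(member_xy[:, 0].mean()), float(member_xy[:, 1].mean())),
                member_xy=member_xy,
            )
        )
    # deterministic order: by centroid, top-left first
    records.sort(key=lambda c: (c.centroid_nm[1], c.centroid_nm[0]))
    return records


def inter_cluster_distances(
    clusters_from: Sequence[ClusterRecord],
    clusters_to: Sequence[ClusterRecord],
    metric: str = "min_member",
) -> np.ndarray:
    """Per from-cluster distance to its nearest to-cluster.

    The default cluster-pair distance is the minimum member-to-member
    centre distance, consistent with single-linkage geometry;
    ``metric='centroid'`` uses centroid-to-centroid instead.  When the two
    lists are the same objects, a cluster is not its own neighbour.
    """
    if not clusters_from or not clusters_to:
        raise InsufficientParticlesError("inter-cluster distances need non-empty cluster lists")
    same = [[a is b for b in clusters_to] for a in clusters_from]
    if len(clusters_from) == 1 and all(same[0]):
        raise InsufficientParticlesError("a single cluster has no neighbouring cluster")

    out = np.empty(len(clusters_from))
    for i, cf in enumerate(clusters_from):
        best = np.inf
        for j, ct in enumerate(clusters_to):
            if same[i][j]:
                continue
            if metric == "min_member":
                d = float(cdist(cf.member_xy, ct.member_xy).min())
            elif metric == "centroid":
                d = float(np.hypot(cf.centroid_nm[0] - ct.centroid_nm[0],
                                   cf.centroid_nm[1] - ct.centroid_nm[1]))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            best = min(best, d)
        if not np.isfinite(best):
            raise InsufficientParticlesError("cluster has no valid neighbour")
        out[i] = best
    return out


# ---------------------------------------------------------------------------
# densities


def density(
    particles: Sequence[Particle],
    roi: ProfileROI,
    size_class: int,
    image_id: str = "",
) -> DensityRecord:
    """Labelling density: in-polygon particles of the class per um^2.

    A particle whose centre lies on the polygon boundary counts as inside.
    """
    if roi.area_um2 is None or roi.area_um2 <= 0:
        raise ValueError(f"ROI {roi.id} has zero area")
    poly = roi.shapely_polygon()
    from shapely.geometry import Point

    n = sum(
        1
        for p in particles
        if p.size_class == size_class and poly.covers(Point(p.x_nm, p.y_nm))
    )
    return DensityRecord(
        image_id=image_id,
        roi_id=roi.id,
        compartment=roi.compartment,
        size_class=size_class,
        n_particles=n,
        area_um2=roi.area_um2,
        density_per_um2=n / roi.area_um2,
    )


# ---------------------------------------------------------------------------
# Ripley's K


def ripley_k(
    particles_or_xy,
    roi: ProfileROI | None,
    radii_nm: Sequence[float],
    estimator: str = "naive",
    area_nm2: float | None = None,
    period: tuple[float, float] | None = None,
) -> RipleyCurve:
    """Ripley's K function, K(r) = A / (n (n-1)) * sum_{i != j} 1[d_ij <= r].

    ``naive`` applies no edge correction; ``toroidal`` wraps distances on
    the rectangle given by ``period`` (only valid for rectangular regions)
    so that K(r) = pi r^2 holds exactly in expectation under CSR.
    """
    radii = np.asarray(radii_nm, float)
    if radii.size == 0 or np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly ascending")
    if isinstance(particles_or_xy, (list, tuple)) and particles_or_xy and isinstance(
        particles_or_xy[0], Particle
    ):
        xy = particles_xy(particles_or_xy)
    else:
        xy = np.asarray(particles_or_xy, float)
    n = len(xy)
    if n < 2:
        raise InsufficientParticlesError("Ripley's K needs >= 2 particles")
    if area_nm2 is None:
        if estimator == "toroidal":
            if period is None:
                raise ValueError("toroidal estimator needs the rectangle period")
            area_nm2 = float(period[0] * period[1])
        else:
            if roi is None:
                raise ValueError("naive estimator needs an ROI (or explicit area)")
            area_nm2 = roi.area_um2 * 1e6

    if estimator == "toroidal":
        delta = np.abs(xy[:, None, :] - xy[None, :, :])
        delta = np.minimum(delta, np.asarray(period) - delta)
        dmat = np.hypot(delta[..., 0], delta[..., 1])
        d = dmat[np.triu_indices(n, k=1)]
    elif estimator == "naive":
        d = pdist(xy)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    counts = np.searchsorted(np.sort(d), radii, side="right") * 2  # i!=j ordered pairs
    k = area_nm2 * counts / (n * (n - 1))
    return RipleyCurve(radii_nm=radii, k_values=k, estimator=estimator)


# ---------------------------------------------------------------------------
# correlations


def area_count_correlation(clusters: Sequence[ClusterRecord]) -> tuple[float, float]:
    """Pearson correlation between cluster particle count and hull area."""
    if len(clusters) < 3:
        raise InsufficientParticlesError("correlation needs >= 3 clusters")
    counts = np.array([c.n_particles for c in clusters], float)
    areas = np.array([c.hull_area_nm2 for c in clusters], float)
    if np.ptp(counts) == 0 or np.ptp(areas) == 0:
        raise ValueError("zero variance in cluster counts or areas")
    r, p = stats.pearsonr(counts, areas)
    return float(r), float(p)
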