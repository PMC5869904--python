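"""On-disk formats: images, particle tables, ROI polygons, config, results.

Particle positions are stored in nanometres (not pixels) so downstream
analyses are scale-independent; detection converts pixel coordinates to nm
when it emits particles.

Formats
-------
images        TIFF or PNG, single channel or RGB (converted to luminance);
              intensities normalised to [0, 1].  The nm-per-pixel scale is
              read from a JSON sidecar ``<image>.scale.json`` containing
              ``{"scale_nm_per_px": <float>}`` unless overridden.
particles     CSV with the fixed header
              image_id,particle_id,x_nm,y_nm,radius_nm,size_class,source,confidence
ROIs          JSON: {"rois": [{"id", "compartment", "face",
              "vertices_nm": [[x, y], ...]}, ...]}
config        YAML mirroring :class:`AnalysisConfig`
results       CSV tables (nnd_summary, intercluster, clusters, densities)
              with deterministic row order and 6-significant-digit floats.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .core_model import (
    COMPARTMENTS,
    NM2_PER_UM2,
    ClusterRecord,
    CompartmentResult,
    Particle,
    ProfileROI,
    polygon_is_simple,
    shoelace_area_nm2,
)

PARTICLE_HEADER = [
    "image_id",
    "particle_id",
    "x_nm",
    "y_nm",
    "radius_nm",
    "size_class",
    "source",
    "confidence",
]

# Rec. 709 luminance weights, as used by scikit-image's rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults are the workflow's standard settings: 500 simulations per image,
    10 nm hard core, minimum cluster size 3, clustering threshold
    mean + 2 SD of the intra-type NNDs, two-tailed alpha 0.05, and a
    fitted-simulation similarity criterion of KS p >= 0.1.
    """

    n_sims: int = 500
    hard_core_nm: float = 10.0
    min_cluster_size: int = 3
    cluster_threshold_rule: str = "mean_plus_2sd"  # or "mean", "mean_plus_1sd", "fixed"
    fixed_nm: float | None = None
    alpha: float = 0.05
    ks_alpha: float = 0.1
    max_fit_iterations: int = 10_000
    max_attempts: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims <= 0 or self.hard_core_nm <= 0 or self.min_cluster_size <= 0:
            raise FormatError("n_sims, hard_core_nm and min_cluster_size must be positive")
        if not 0 < self.alpha < 1:
            raise FormatError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.ks_alpha < 1:
            raise FormatError(f"ks_alpha must be in (0, 1), got {self.ks_alpha}")
        if self.max_fit_iterations <= 0 or self.max_attempts <= 0:
            raise FormatError("iteration caps must be positive")


def read_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write the resolved config (run provenance) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# images


def read_image(
    path: str | Path, scale_nm_per_px: float | None = None
) -> tuple[np.ndarray, float]:
    """Read a TIFF/PNG micrograph as a [0, 1] grayscale array plus scale.

    The nm-per-pixel scale comes from the ``<image>.scale.json`` sidecar
    unless ``scale_nm_per_px`` overrides it; a missing scale is an error,
    never a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise FormatError(f"unsupported image format: {path.suffix}")

    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].astype(float) @ _LUMA
        if np.issubdtype(np.asarray(Image.open(path)).dtype, np.integer):
            arr = arr / np.iinfo(np.asarray(Image.open(path)).dtype).max
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    arr = np.clip(arr, 0.0, 1.0)

    if scale_nm_per_px is None:
        sidecar = path.with_suffix(path.suffix + ".scale.json")
        alt = path.parent / (path.stem + ".scale.json")
        meta_path = sidecar if sidecar.exists() else alt
        if not meta_path.exists():
            raise FormatError(
                f"no scale for {path.name}: provide scale_nm_per_px or a "
                f"sidecar {alt.name}"
            )
        with open(meta_path) as fh:
            scale_nm_per_px = float(json.load(fh)["scale_nm_per_px"])
    if scale_nm_per_px <= 0:
        raise FormatError(f"scale_nm_per_px must be > 0, got {scale_nm_per_px}")
    return arr, float(scale_nm_per_px)


def write_image(arr: np.ndarray, path: str | Path, scale_nm_per_px: float) -> None:
    """Write a [0, 1] array as 16-bit TIFF (or 8-bit PNG) plus scale sidecar."""
    path = Path(path)
    data = np.clip(arr, 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (data * 65535).round().astype(np.uint16))
    elif path.suffix.lower() == ".png":
        Image.fromarray((data * 255).round().astype(np.uint8)).save(path)
    else:
        raise FormatError(f"unsupported image format: {path.suffix}")
    with open(path.parent / (path.stem + ".scale.json"), "w") as fh:
        json.dump({"scale_nm_per_px": scale_nm_per_px}, fh)


# ---------------------------------------------------------------------------
# particle tables


def read_particles(path: str | Path) -> dict[str, list[Particle]]:
    """Read a particle CSV into per-image particle lists (row order kept)."""
    df = pd.read_csv(path, dtype={"image_id": str, "particle_id": str})
    if list(df.columns) != PARTICLE_HEADER:
        raise FormatError(
            f"bad particle header: expected {PARTICLE_HEADER}, got {list(df.columns)}"
        )
    out: dict[str, list[Particle]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        for field in ("x_nm", "y_nm", "radius_nm", "confidence"):
            value = getattr(row, field)
            if not np.isfinite(value):
                raise FormatError(f"row {i + 1}: non-numeric {field}")
        size_class = int(row.size_class)
        if size_class not in (5, 10):
            raise FormatError(f"row {i + 1}: unknown size_class {row.size_class}")
        if row.source not in ("real", "simulated"):
            raise FormatError(f"row {i + 1}: unknown source {row.source!r}")
        out.setdefault(row.image_id, []).append(
            Particle(
                id=str(row.particle_id),
                x_nm=float(row.x_nm),
                y_nm=float(row.y_nm),
                radius_nm=float(row.radius_nm),
                size_class=size_class,
                source=str(row.source),
                confidence=float(row.confidence),
            )
        )
    return out


def write_particles(particles_by_image: dict[str, Sequence[Particle]], path: str | Path) -> None:
    rows = [
        {
            "image_id": image_id,
            "particle_id": p.id,
            "x_nm": p.x_nm,
            "y_nm": p.y_nm,
            "radius_nm": p.radius_nm,
            "size_class": p.size_class,
            "source": p.source,
            "confidence": p.confidence,
        }
        for image_id, plist in particles_by_image.items()
        for p in plist
    ]
    pd.DataFrame(rows, columns=PARTICLE_HEADER).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROIs


def read_roi(path: str | Path) -> list[ProfileROI]:
    """Read profile ROI polygons from the repo's JSON dialect."""
    with open(path) as fh:
        raw = json.load(fh)
    rois = []
    for entry in raw["rois"]:
        vertices = [(float(x), float(y)) for x, y in entry["vertices_nm"]]
        if len(vertices) < 3:
            raise FormatError(f"ROI {entry.get('id')}: fewer than 3 vertices")
        if not polygon_is_simple(vertices):
            raise FormatError(f"ROI {entry.get('id')}: self-intersecting polygon")
        compartment = entry["compartment"]
        if compartment not in COMPARTMENTS:
            raise FormatError(f"ROI {entry.get('id')}: unknown compartment {compartment!r}")
        rois.append(
            ProfileROI(
                id=str(entry["id"]),
                polygon=vertices,
                compartment=compartment,
                face=entry.get("face", "P"),
                area_um2=shoelace_area_nm2(vertices) / NM2_PER_UM2,
            )
        )
    return rois


def write_roi(rois: Sequence[ProfileROI], path: str | Path) -> None:
    payload = {
        "rois": [
            {
                "id": r.id,
                "compartment": r.compartment,
                "face": r.face,
                "vertices_nm": [[float(x), float(y)] for x, y in r.polygon],
            }
            for r in rois
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# result tables


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def write_results(
    out_dir: str | Path,
    compartment_results: Iterable[CompartmentResult] = (),
    intercluster_rows: Iterable[dict] = (),
    clusters: Iterable[tuple[str, ClusterRecord]] = (),
    density_rows: Iterable[dict] = (),
) -> dict[str, Path]:
    """Write the four result tables; row order is deterministic.

    ``nnd_summary.csv`` is the per-compartment association summary
    (molecule pair, compartment, real and simulated NND mean +/- SD,
    adjusted p, %associated, %dissociated, N); ``intercluster.csv`` the
    nearest-cluster distance summary; plus raw cluster and density tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    nnd = pd.DataFrame(
        [
            {
                "molecule_pair": r.molecule_pair,
                "compartment": r.compartment,
                "real_mean_nm": r.real_mean_of_means,
                "real_sd_nm": r.real_sd_of_means,
                "sim_mean_nm": r.sim_mean_of_means,
                "sim_sd_nm": r.sim_sd_of_means,
                "t_statistic": r.t_statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "pct_associated": r.pct_associated,
                "pct_dissociated": r.pct_dissociated,
                "n_images": r.n_images,
            }
            for r in compartment_results
        ],
        columns=[
            "molecule_pair",
            "compartment",
            "real_mean_nm",
            "real_sd_nm",
            "sim_mean_nm",
            "sim_sd_nm",
            "t_statistic",
            "p_raw",
            "p_adjusted",
            "pct_associated",
            "pct_dissociated",
            "n_images",
        ],
    ).sort_values(["molecule_pair", "compartment"], kind="stable")
    paths["nnd_summary"] = out_dir / "nnd_summary.csv"
    _write_csv(nnd, paths["nnd_summary"])

    inter = pd.DataFrame(
        list(intercluster_rows),
        columns=["molecule_pair", "compartment", "mean_nm", "sd_nm", "n_clusters"],
    ).sort_values(["molecule_pair", "compartment"], kind="stable")
    paths["intercluster"] = out_dir / "intercluster.csv"
    _write_csv(inter, paths["intercluster"])

    cl = pd.DataFrame(
        [
            {
                "image_id": image_id,
                "size_class": c.size_class,
                "n_particles": c.n_particles,
                "hull_area_nm2": c.hull_area_nm2,
                "centroid_x_nm": c.centroid_nm[0],
                "centroid_y_nm": c.centroid_nm[1],
                "member_ids": ";".join(c.member_ids),
            }
            for image_id, c in clusters
        ],
        columns=[
            "image_id",
            "size_class",
            "n_particles",
            "hull_area_nm2",
            "centroid_x_nm",
            "centroid_y_nm",
            "member_ids",
        ],
    ).sort_values(["image_id", "size_class", "centroid_x_nm"], kind="stable")
    paths["clusters"] = out_dir / "clusters.csv"
    _write_csv(cl, paths["clusters"])

    dens = pd.DataFrame(
        list(density_rows),
        columns=[
            "image_id",
            "roi_id",
            "compartment",
            "size_class",
            "n_particles",
            "area_um2",
            "density_per_um2",
        ],
    ).sort_values(["image_id", "roi_id", "size_class"], kind="stable")
    paths["densities"] = out_dir / "densities.csv"
    _write_csv(dens, paths["densities"])
    return paths
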