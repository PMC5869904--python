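import numpy as np
import pytest

from igquant.detection import (
    CandidateCircle,
    ClassifierModel,
    DiameterTooSmallError,
    classify_candidates,
    detect_circles,
    detect_particles,
    extract_features,
    import_manual_particles,
    match_detections,
    refine_position,
    train_classifier,
)
from igquant.synthetic_data import PatternSpec, RenderSpec, gen_pattern, render_image

from conftest import make_particle


def _disk_image(size=64, cx=31.5, cy=31.5, r=5.0, fg=0.0, bg=1.0):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.full((size, size), bg)
    img[np.hypot(xx - cx, yy - cy) <= r] = fg
    return img


# ---------------------------------------------------------------------------
# circle detection


def test_blank_image_yields_no_candidates():
    assert detect_circles(np.full((64, 64), 0.5), 10.0, 1.0) == []


def test_single_noiseless_disk_detected_within_one_nm():
    record, _ = gen_pattern(
        PatternSpec(process="csr", width_nm=100, height_nm=100,
                    intensity_per_um2={10: 100.0}, seed=3)
    )
    particle = record.particles[0]
    spec = RenderSpec(width_px=100, height_px=100, texture_sd=0.0, noise_sd=0.0)
    img, _, _ = render_image([particle], spec, seed=0)
    candidates = detect_circles(img, 10.0, 0.5 if False else 1.0)
    assert len(candidates) == 1
    assert np.hypot(candidates[0].x_nm - particle.x_nm,
                    candidates[0].y_nm - particle.y_nm) <= 1.0


def test_too_small_diameter_directs_to_manual_mode():
    with pytest.raises(DiameterTooSmallError, match="manual"):
        detect_circles(np.zeros((32, 32)), 5.0, 2.0)  # 2.5 px < 4 px


def test_candidates_sorted_and_separated():
    record, _ = gen_pattern(
        PatternSpec(process="csr", width_nm=300, height_nm=300,
                    intensity_per_um2={10: 150.0}, seed=5)
    )
    img, _, _ = render_image(record.particles, RenderSpec(width_px=300, height_px=300), seed=5)
    candidates = detect_circles(img, 10.0, 1.0)
    scores = [c.hough_score for c in candidates]
    assert scores == sorted(scores, reverse=True)
    xy = np.array([[c.x_nm, c.y_nm] for c in candidates])
    from scipy.spatial.distance import pdist

    assert pdist(xy).min() >= 5.0  # one radius


def test_detection_is_translation_equivariant():
    """Shifting the image shifts every detection by the same amount."""
    record, _ = gen_pattern(
        PatternSpec(process="csr", width_nm=200, height_nm=200,
                    intensity_per_um2={10: 120.0}, seed=11)
    )
    img, _, _ = render_image(record.particles, RenderSpec(
        width_px=260, height_px=260, texture_sd=0.0, noise_sd=0.0), seed=0)
    shifted = np.roll(np.roll(img, 13, axis=0), 7, axis=1)
    base = detect_circles(img, 10.0, 1.0)
    moved = detect_circles(shifted, 10.0, 1.0)
    base_xy = sorted((round(c.x_nm, 3), round(c.y_nm, 3)) for c in base)
    moved_xy = sorted((round(c.x_nm - 7, 3), round(c.y_nm - 13, 3)) for c in moved)
    assert base_xy == moved_xy


# ---------------------------------------------------------------------------
# features


def test_ring_contrast_of_ideal_disk():
    img = _disk_image()
    cand = CandidateCircle(x_nm=32.0, y_nm=32.0, radius_nm=5.0, hough_score=1.0)
    fv = extract_features(img, cand, 1.0)
    assert fv.in_bounds
    names_to_values = dict(zip(
        ["interior_mean", "interior_sd", "ring_contrast", "radial_gradient",
         "circularity", "background_sd"], fv.values))
    assert names_to_values["ring_contrast"] == pytest.approx(1.0)
    assert names_to_values["interior_mean"] == pytest.approx(0.0)


def test_uniform_image_has_zero_contrast():
    img = np.full((64, 64), 0.7)
    cand = CandidateCircle(x_nm=32.0, y_nm=32.0, radius_nm=5.0, hough_score=1.0)
    fv = extract_features(img, cand, 1.0)
    assert fv.values[2] == pytest.approx(0.0)  # ring contrast


def test_border_candidate_is_flagged_not_thrown():
    img = np.full((64, 64), 0.5)
    cand = CandidateCircle(x_nm=3.0, y_nm=3.0, radius_nm=5.0, hough_score=1.0)
    assert not extract_features(img, cand, 1.0).in_bounds


def test_features_match_pixel_loop_oracle(rng):
    """Interior/annulus statistics vs an independent per-pixel loop."""
    img = rng.uniform(0, 1, (64, 64))
    cand = CandidateCircle(x_nm=30.0, y_nm=28.0, radius_nm=6.0, hough_score=1.0)
    fv = extract_features(img, cand, 1.0)
    cx, cy, r = 29.5, 27.5, 6.0
    interior, annulus = [], []
    for y in range(64):
        for x in range(64):
            d = np.hypot(x - cx, y - cy)
            if d <= r:
                interior.append(img[y, x])
            elif d <= 2 * r:
                annulus.append(img[y, x])
    assert fv.values[0] == pytest.approx(np.mean(interior), abs=1e-6)
    assert fv.values[1] == pytest.approx(np.std(interior), abs=1e-6)
    assert fv.values[2] == pytest.approx(np.mean(annulus) - np.mean(interior), abs=1e-6)
    assert fv.values[5] == pytest.approx(np.std(annulus), abs=1e-6)


# ---------------------------------------------------------------------------
# classifier


def test_decision_boundary_between_separated_classes(rng):
    x0 = rng.normal(0.0, 0.5, (100, 1))
    x1 = rng.normal(10.0, 0.5, (100, 1))
    model = train_classifier(
        np.vstack([x0, x1]), ["artefact"] * 100 + ["particle"] * 100
    )
    grid = np.linspace(0.0, 10.0, 201).reshape(-1, 1)
    post = model.posterior_particle(grid)
    assert post[0] < 0.01 and post[-1] > 0.99
    crossings = np.flatnonzero(np.diff(post >= 0.5))
    assert len(crossings) == 1  # single decision boundary, between the means
    assert 0.0 < grid[crossings[0], 0] < 10.0


def test_identical_classes_give_posterior_near_prior(rng):
    x = rng.normal(0.0, 1.0, (300, 2))
    labels = ["particle"] * 100 + ["artefact"] * 200
    model = train_classifier(x, labels)
    post = model.posterior_particle(np.zeros((1, 2)))
    assert post[0] == pytest.approx(1 / 3, abs=0.1)


def test_training_requires_ten_per_class(rng):
    x = rng.normal(0, 1, (15, 2))
    with pytest.raises(ValueError, match=">= 10"):
        train_classifier(x, ["particle"] * 12 + ["artefact"] * 3)


def test_posteriors_match_sklearn_gaussian_nb(rng):
    """Cross-check the hand-rolled model against scikit-learn's."""
    from sklearn.naive_bayes import GaussianNB

    x = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(2, 1.5, (80, 3))])
    y = np.array([0] * 60 + [1] * 80)
    labels = np.where(y == 0, "artefact", "particle").tolist()
    model = train_classifier(x, labels)
    ref = GaussianNB(var_smoothing=0.0).fit(x, y)
    grid = rng.normal(1, 2, (40, 3))
    assert model.posterior_particle(grid) == pytest.approx(
        ref.predict_proba(grid)[:, 1], abs=1e-8
    )


def test_classifier_json_roundtrip(tmp_path, rng):
    x = np.vstack([rng.normal(0, 1, (20, 6)), rng.normal(3, 1, (20, 6))])
    model = train_classifier(x, ["artefact"] * 20 + ["particle"] * 20)
    model.to_json(tmp_path / "model.json")
    back = ClassifierModel.from_json(tmp_path / "model.json")
    probe = rng.normal(1, 1, (10, 6))
    assert back.posterior_particle(probe) == pytest.approx(
        model.posterior_particle(probe), rel=1e-12
    )


def test_threshold_keeps_exact_half_posterior():
    # symmetric model: posterior at the origin is exactly 0.5 and is kept
    model = ClassifierModel(
        means=np.array([[-1.0] * 6, [1.0] * 6]),
        variances=np.ones((2, 6)),
        priors=np.array([0.5, 0.5]),
    )
    cand = CandidateCircle(x_nm=50.0, y_nm=50.0, radius_nm=5.0, hough_score=1.0)
    from igquant.detection import FeatureVector

    kept = classify_candidates([cand], [FeatureVector(np.zeros(6))], model, 10)
    assert len(kept) == 1 and kept[0].confidence == pytest.approx(0.5)
    low = classify_candidates([cand], [FeatureVector(np.full(6, -0.1))], model, 10)
    assert low == []


def test_classify_empty_candidates():
    assert classify_candidates([], [], ClassifierModel(), 10) == []


# ---------------------------------------------------------------------------
# refinement


def test_refine_centred_disk_does_not_move():
    img = _disk_image(cx=31.5, cy=31.5)
    p = make_particle(x=32.0, y=32.0)
    refined = refine_position(img, p, 1.0)
    assert refined.x_nm == pytest.approx(32.0, abs=1e-6)
    assert refined.y_nm == pytest.approx(32.0, abs=1e-6)


def test_refine_recovers_offset_click():
    truth = make_particle(x=32.0, y=32.0)
    img, _, _ = render_image(
        [truth], RenderSpec(width_px=64, height_px=64, texture_sd=0.0, noise_sd=0.0), seed=0
    )
    clicked = make_particle(x=34.0, y=32.5)  # ~2 nm off
    refined = refine_position(img, clicked, 1.0)
    assert np.hypot(refined.x_nm - 32.0, refined.y_nm - 32.0) <= 0.5


def test_refine_on_flat_region_is_identity():
    img = np.full((64, 64), 0.4)
    p = make_particle(x=30.0, y=25.0)
    refined = refine_position(img, p, 1.0)
    assert refined.x_nm == pytest.approx(30.0, abs=1e-9)
    assert refined.y_nm == pytest.approx(25.0, abs=1e-9)


def test_refine_displacement_capped_at_one_radius():
    img = _disk_image(cx=20.0, cy=31.5)
    p = make_particle(x=40.0, y=32.0)  # 20 nm from the disk
    refined = refine_position(img, p, 1.0)
    assert np.hypot(refined.x_nm - p.x_nm, refined.y_nm - p.y_nm) <= 5.0 + 1e-9


def test_manual_import_refines_clicks():
    truth = make_particle(x=32.0, y=32.0, cls=5)
    img, _, _ = render_image(
        [truth], RenderSpec(width_px=64, height_px=64, texture_sd=0.0, noise_sd=0.0), seed=0
    )
    (imported,) = import_manual_particles(img, [(33.5, 31.0)], 5, 1.0)
    assert imported.confidence == 1.0 and imported.source == "real"
    assert np.hypot(imported.x_nm - 32.0, imported.y_nm - 32.0) < 1.0


# ---------------------------------------------------------------------------
# pipeline


def test_pipeline_respects_hard_core(trained_model):
    record, _ = gen_pattern(
        PatternSpec(process="csr", width_nm=400, height_nm=400,
                    intensity_per_um2={10: 120.0}, seed=21)
    )
    img, _, _ = render_image(record.particles, RenderSpec(
        width_px=400, height_px=400, n_artifacts=5), seed=21)
    detected = detect_particles(img, 10.0, 1.0, trained_model)
    from scipy.spatial.distance import pdist

    xy = np.array([[p.x_nm, p.y_nm] for p in detected])
    assert len(xy) >= 2
    assert pdist(xy).min() >= 10.0


def test_pipeline_recall_precision_on_one_fixture(trained_model):
    record, _ = gen_pattern(
        PatternSpec(process="csr", width_nm=600, height_nm=600,
                    intensity_per_um2={10: 80.0}, seed=33)
    )
    img, truth, _ = render_image(record.particles, RenderSpec(n_artifacts=8), seed=33)
    detected = detect_particles(img, 10.0, 1.0, trained_model)
    det_xy = np.array([[p.x_nm, p.y_nm] for p in detected])
    tp, errors = match_detections(det_xy, truth[["x_nm", "y_nm"]].to_numpy())
    assert tp / len(truth) >= 0.9
    assert tp / len(det_xy) >= 0.9
    assert errors.mean() <= 2.0
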