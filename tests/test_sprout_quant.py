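import numpy as np
import pytest

from earwound.config import ConfigError
from earwound.imaging import place_rois, render_series
from earwound.sprouts import (detect_sprouts, measure_length, segment_vessels,
                              summarize_sprouts)

PX = 1000 / 256


def test_noise_only_image_gives_empty_mask():
    rng = np.random.default_rng(0)
    img = rng.normal(10, 1, size=(64, 64))
    with pytest.warns(UserWarning, match="blank"):
        mask = segment_vessels(np.clip(img, 0, None))
    # Otsu on pure noise splits the noise itself; the size filter and
    # opening must leave nothing coherent
    assert mask.sum() < 0.02 * mask.size


def test_segmentation_scale_invariance(scene, sprouts):
    s = render_series(scene, mode="anatomy", res=256, sprouts=sprouts,
                      dpt=6.5, seed=1, n_z=2, noise=False)
    img = s.frames["green"]
    m1 = segment_vessels(img)
    m2 = segment_vessels(2.0 * img)
    assert np.array_equal(m1, m2)


def test_segmentation_covers_vessels_excludes_veins(scene, sprouts):
    s = render_series(scene, mode="anatomy", res=256, sprouts=sprouts,
                      dpt=6.5, seed=2, n_z=2)
    mask = segment_vessels(s.frames["green"])
    px = PX
    for v in scene.gcamp_vessels():
        pts = np.asarray(v.polyline_um)
        mids = (pts[:-1] + pts[1:]) / 2
        for x, y in np.vstack([pts, mids]):
            r, c = int(np.clip(y / px, 0, 255)), int(np.clip(x / px, 0, 255))
            assert mask[r, c]
    vein = scene.veins[0]
    r = int(vein.polyline_um[0][1] / px)
    assert not mask[r, 50] and not mask[r, 200]


def test_detection_recovers_truth_sprouts(scene, sprouts, roi_set):
    """Rendered scene with moderate noise: counts and sides match truth."""
    # time points chosen so every live sprout is clearly above (or a
    # nascent bud clearly below) the ~1-radius detectability floor
    for dpt in (6.5, 7.0):
        truth = [s for s in sprouts if s.length_at(dpt) >= 10.0]
        series = render_series(scene, mode="anatomy", res=256, sprouts=sprouts,
                               dpt=dpt, seed=3, n_z=2)
        mask = segment_vessels(series.frames["green"])
        dets = detect_sprouts(mask, roi_set.region_masks, PX)
        assert len(dets) == len(truth)
        assert all(d.side == "distal" for d in dets)


def test_lengths_match_truth_on_noise_free_renders(scene, sprouts, roi_set):
    dpt = 7.0
    series = render_series(scene, mode="anatomy", res=256, sprouts=sprouts,
                           dpt=dpt, seed=4, n_z=2, noise=False)
    mask = segment_vessels(series.frames["green"])
    dets = detect_sprouts(mask, roi_set.region_masks, PX)
    truth = sorted(s.length_at(dpt) for s in sprouts if s.length_at(dpt) >= 10)
    got = sorted(d.length_um for d in dets)
    assert len(got) == len(truth)
    for g, t in zip(got, truth):
        assert abs(g - t) <= 2 * PX  # skeletonization end effects


def test_detection_monotone_in_min_length(scene, sprouts, roi_set):
    series = render_series(scene, mode="anatomy", res=256, sprouts=sprouts,
                           dpt=8.0, seed=5, n_z=2)
    mask = segment_vessels(series.frames["green"])
    counts = [len(detect_sprouts(mask, roi_set.region_masks, PX, min_length_um=m))
              for m in (5.0, 10.0, 20.0, 40.0, 80.0)]
    assert counts == sorted(counts, reverse=True)


def test_missing_region_masks_rejected(roi_set):
    with pytest.raises(ConfigError, match="wound"):
        detect_sprouts(np.ones((8, 8), bool),
                       {"proximal": np.ones((8, 8), bool)}, 1.0)


def test_measure_length_examples():
    path = np.array([[50, 10 + i] for i in range(10)])
    assert measure_length(path, 3.906) == pytest.approx(9 * 3.906)
    with pytest.warns(UserWarning, match="zero length"):
        assert measure_length(np.array([[3, 3]]), 3.906) == 0.0
    diag = np.array([[0, 0], [1, 1]])
    assert measure_length(diag, 1.0) == pytest.approx(np.sqrt(2))
    with pytest.raises(ValueError):
        measure_length(np.empty((0, 2)), 1.0)


def test_summarize_counts_and_mean():
    from earwound.sprouts import SproutMeasurement
    ms = [SproutMeasurement(f"s{i}", "distal", L, (0, 0), np.zeros((2, 2)))
          for i, L in enumerate([10.0, 20.0, 30.0])]
    df = summarize_sprouts(ms, "a0", 5.0)
    by = df.set_index("metric")["value"]
    assert by["sprout_count_distal"] == 3
    assert by["sprout_count_proximal"] == 0
    assert by["mean_length_um"] == pytest.approx(20.0)

    empty = summarize_sprouts([], "a0", 5.0)
    by = empty.set_index("metric")
    assert by.loc["sprout_count_distal", "value"] == 0
    assert np.isnan(by.loc["mean_length_um", "value"])
    assert by.loc["mean_length_um", "censored"] == 1
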