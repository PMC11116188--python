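"""Optical pipeline: every elementary operation against a hand oracle, plus
end-to-end extraction on synthetic runs with known ground truth."""

import math

import numpy as np
import pytest

from mmcyto import (
    AcquisitionConfig,
    ClassSpec,
    NoParticleError,
    SimulationParams,
    compute_background,
    compute_volume,
    difference_image,
    estimate_diameter,
    estimate_velocity,
    extract_optical_events,
    generate_run,
    locate_center,
    radial_profile,
    render_frame,
    segment_particles,
)
from mmcyto.optical import BackgroundModel


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def test_background_of_identical_frames():
    frames = np.full((60, 8, 8), 17.0)
    bg = compute_background(frames, anchor_index=55, window=50)
    assert np.array_equal(bg.image, frames[0])


def test_background_of_alternating_frames():
    """25 frames of 0 and 25 of 100 average to 50."""
    frames = np.zeros((60, 4, 4))
    frames[1::2] = 100.0
    bg = compute_background(frames, anchor_index=52, window=50)
    assert np.allclose(bg.image, 50.0)


def test_background_insufficient_history():
    frames = np.zeros((60, 4, 4))
    with pytest.raises(ValueError):
        compute_background(frames, anchor_index=3, window=50, min_window=10)
    with pytest.raises(ValueError):
        compute_background(frames, anchor_index=30, window=50, strict=True)
    # lenient mode accepts a shorter history
    bg = compute_background(frames, anchor_index=30, window=50)
    assert bg.window == 30


# ---------------------------------------------------------------------------
# difference image
# ---------------------------------------------------------------------------

def test_difference_identity_and_single_pixel():
    bg = BackgroundModel(np.full((5, 5), 3.0), 50, 50)
    assert np.array_equal(difference_image(np.full((5, 5), 3.0), bg), np.zeros((5, 5)))
    frame = np.full((5, 5), 3.0)
    frame[2, 3] += 10.0
    d = difference_image(frame, bg)
    assert d[2, 3] == 10.0
    assert d.sum() == 10.0


def test_difference_matches_elementwise_oracle(rng):
    frame = rng.uniform(0, 255, (16, 16))
    bg = BackgroundModel(rng.uniform(0, 255, (16, 16)), 50, 50)
    d = difference_image(frame, bg)
    for i in range(16):
        for j in range(16):
            assert d[i, j] == abs(frame[i, j] - bg.image[i, j])


def test_difference_shape_mismatch():
    with pytest.raises(ValueError):
        difference_image(np.zeros((4, 4)), BackgroundModel(np.zeros((5, 5)), 50, 50))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _flood_count(mask):
    """Pure-python 8-connectivity component count (oracle)."""
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    nr, nc = mask.shape
    for i in range(nr):
        for j in range(nc):
            if mask[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if 0 <= x < nr and 0 <= y < nc and mask[x, y] \
                                    and not seen[x, y]:
                                seen[x, y] = True
                                stack.append((x, y))
    return n


def test_segment_empty_and_two_disks():
    assert segment_particles(np.zeros((20, 20)), 1.0, (0, 0, 20, 20)) == []
    diff = np.zeros((30, 30))
    ii, jj = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
    diff[np.hypot(ii - 8, jj - 8) < 4] = 50.0
    diff[np.hypot(ii - 22, jj - 22) < 4] = 50.0
    masks = segment_particles(diff, 10.0, (0, 0, 30, 30))
    assert len(masks) == 2


def test_segment_checkerboard_matches_flood_fill_oracle():
    diff = np.zeros((12, 12))
    diff[::2, ::2] = 50.0   # diagonal connectivity joins everything
    masks = segment_particles(diff, 10.0, (0, 0, 12, 12), min_area_px=1)
    assert len(masks) == _flood_count(diff > 10.0)


def test_segment_threshold_monotonicity(rng):
    diff = rng.uniform(0, 100, (24, 24))
    prev = None
    for thr in (10.0, 30.0, 50.0, 70.0):
        masks = segment_particles(diff, thr, (0, 0, 24, 24), min_area_px=1)
        union = np.zeros((24, 24), dtype=bool)
        for m in masks:
            union |= m.mask
        if prev is not None:
            assert np.all(union <= prev)   # raising threshold never adds pixels
        prev = union


def test_segment_flags_roi_border():
    diff = np.zeros((20, 20))
    diff[5:9, 0:4] = 50.0
    masks = segment_particles(diff, 10.0, (0, 0, 20, 20))
    assert len(masks) == 1 and masks[0].touches_roi_border


# ---------------------------------------------------------------------------
# centroid
# ---------------------------------------------------------------------------

def test_locate_center_cases(rng):
    m = np.zeros((10, 12), dtype=bool)
    m[5, 7] = True
    assert locate_center(m) == (5.0, 7.0)

    ring = np.zeros((41, 41), dtype=bool)
    ii, jj = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
    d = np.hypot(ii - 20, jj - 20)
    ring[(d > 8) & (d < 10)] = True
    assert locate_center(ring) == pytest.approx((20.0, 20.0))

    m17 = np.zeros((16, 16), dtype=bool)
    flat = rng.choice(256, size=17, replace=False)
    m17[np.unravel_index(flat, (16, 16))] = True
    rows, cols = np.nonzero(m17)
    expect = (sum(rows) / 17, sum(cols) / 17)
    assert locate_center(m17) == pytest.approx(expect)

    with pytest.raises(ValueError):
        locate_center(np.zeros((4, 4), dtype=bool))


# ---------------------------------------------------------------------------
# radial profile
# ---------------------------------------------------------------------------

def test_radial_profile_uniform_and_single_pixel():
    img = np.full((21, 21), 7.5)
    prof = radial_profile(img, (10.0, 10.0), 8.0)
    vals = prof.mean_intensity[np.isfinite(prof.mean_intensity)]
    assert np.allclose(vals, 7.5)
    assert prof.radii_px[0] == 0.0
    assert np.all(np.diff(prof.radii_px) > 0)

    img = np.zeros((21, 21))
    img[10, 14] = 9.0   # distance 4 from centre
    prof = radial_profile(img, (10.0, 10.0), 8.0)
    nz = [i for i, v in enumerate(prof.mean_intensity) if np.isfinite(v) and v > 0]
    assert nz == [4]


def test_radial_profile_matches_bucketing_oracle(rng):
    img = rng.uniform(0, 10, (15, 15))
    center = (7.3, 6.8)
    prof = radial_profile(img, center, 6.0)
    buckets: dict[int, list[float]] = {}
    for i in range(15):
        for j in range(15):
            b = round(math.hypot(i - center[0], j - center[1]))
            if b < len(prof.radii_px):
                buckets.setdefault(b, []).append(img[i, j])
    for b, vals in buckets.items():
        assert prof.mean_intensity[b] == pytest.approx(sum(vals) / len(vals))


def test_radial_profile_rejects_bad_inputs():
    with pytest.raises(ValueError):
        radial_profile(np.zeros((5, 5)), (2.0, 2.0), 0.0)
    with pytest.raises(ValueError):
        radial_profile(np.zeros((5, 5)), (9.0, 2.0), 3.0)


# ---------------------------------------------------------------------------
# diameter and volume
# ---------------------------------------------------------------------------

def test_estimate_diameter_on_ideal_ring():
    bg = np.zeros((64, 64))
    out = render_frame(bg, [((32.0, 32.0), 14.0)], psf_sigma_px=1.0)
    prof = radial_profile(out, (32.0, 32.0), 20.0)
    d = estimate_diameter(prof, pixel_size_um=0.2)
    assert d == pytest.approx(2.8, abs=0.2)


def test_estimate_diameter_rejects_flat_profile():
    prof = radial_profile(np.zeros((21, 21)), (10.0, 10.0), 8.0)
    with pytest.raises(NoParticleError):
        estimate_diameter(prof, 0.2)


def test_compute_volume_closed_form():
    assert compute_volume(0.0) == 0.0
    assert compute_volume(2.0) == pytest.approx(4.0 / 3.0 * math.pi, rel=1e-12)
    total = compute_volume(2.0) + compute_volume(2.0)
    assert total == pytest.approx(8.0 / 3.0 * math.pi, rel=1e-12)
    with pytest.raises(ValueError):
        compute_volume(-1.0)


# ---------------------------------------------------------------------------
# velocity
# ---------------------------------------------------------------------------

def test_velocity_examples(rng):
    t = np.array([0.0, 1 / 125])
    track = np.array([[0.0, 0.0], [0.0, 10.0]])
    assert estimate_velocity(track, t, 0.2) == pytest.approx(250.0)

    track = np.array([[3.0, 4.0]] * 4)
    assert estimate_velocity(track, np.arange(4) / 125, 0.2) == 0.0

    steps = rng.normal(0, 2, size=(4, 2))
    track = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
    t = np.arange(5) / 125
    expect = np.mean([math.hypot(*s) for s in steps]) * 0.2 * 125
    assert estimate_velocity(track, t, 0.2) == pytest.approx(expect)

    with pytest.raises(ValueError):
        estimate_velocity(track, t[::-1], 0.2)
    with pytest.raises(ValueError):
        estimate_velocity(track[:1], t[:1], 0.2)


# ---------------------------------------------------------------------------
# end-to-end extraction
# ---------------------------------------------------------------------------

def test_extract_empty_run(config, unbiased_classes, clean_params):
    run = generate_run(config, unbiased_classes,
                       clean_params.replace(n_events_per_class=0, seed=2))
    assert extract_optical_events(run.frames, config,
                                  frame_times_s=run.frame_times_s) == []


def test_extract_single_bead(config, clean_params):
    params = clean_params.replace(n_events_per_class=1, seed=8)
    run = generate_run(config, [ClassSpec(1, "b", (2.8, 2.8))], params)
    events = [e for e in extract_optical_events(
        run.frames, config, frame_times_s=run.frame_times_s)
        if e.component_diameters_um]
    assert len(events) == 1
    assert events[0].component_diameters_um[0] == pytest.approx(2.8, abs=0.4)
    assert abs(events[0].time_s - run.truth[0].transit_time_s) < 0.05
    assert events[0].velocity_um_s == pytest.approx(
        run.truth[0].true_velocity_um_s, rel=0.25)


def test_extract_two_bead_aggregate(config, clean_params):
    params = clean_params.replace(
        n_events_per_class=1, aggregate_probability=1.0,
        aggregate_size_range=(2, 2), seed=4)
    run = generate_run(config, [ClassSpec(2, "b", (4.0, 4.5))], params)
    assert len(run.truth[0].component_diameters_um) == 2
    events = [e for e in extract_optical_events(
        run.frames, config, frame_times_s=run.frame_times_s)
        if e.component_diameters_um]
    assert len(events) == 1
    assert len(events[0].component_diameters_um) == 2
    assert "aggregate" in events[0].quality_flags
    assert events[0].total_volume_um3 == pytest.approx(
        sum(compute_volume(d) for d in events[0].component_diameters_um), rel=1e-9)


def test_extract_all_events_of_small_run(small_run, config):
    events = [e for e in extract_optical_events(
        small_run.frames, config, frame_times_s=small_run.frame_times_s)
        if e.component_diameters_um]
    assert len(events) == len(small_run.truth)
    # every truth transit has a matching optical event close in time
    for g in small_run.truth:
        assert min(abs(e.time_s - g.transit_time_s) for e in events) < 0.05


def test_recovered_diameters_cluster_on_pixel_grid(config, clean_params):
    """0.2 µm/px quantization: estimates land near the 0.2 µm grid."""
    params = clean_params.replace(n_events_per_class=12, seed=6)
    run = generate_run(config, [ClassSpec(1, "b", (2.0, 2.9))], params)
    events = [e for e in extract_optical_events(
        run.frames, config, frame_times_s=run.frame_times_s)
        if e.component_diameters_um]
    diams = np.array([e.component_diameters_um[0] for e in events])
    assert len(diams) >= 10
    offsets = np.abs(diams / 0.2 - np.rint(diams / 0.2)) * 0.2
    assert np.median(offsets) <= 0.05
    assert len(set(np.rint(diams / 0.2).astype(int))) >= 3


def test_extract_rejects_short_stack(config):
    with pytest.raises(ValueError):
        extract_optical_events(np.zeros((5, *config.frame_shape), dtype=np.uint8),
                               config)
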