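"""Optical sizing of particles from high-speed-camera frame stacks.

The diameter pipeline works on one frame at a time:

1. a *background* image is formed as the mean of the preceding 50 frames,
2. the *difference image* |frame - background| isolates the transiting
   particle, which appears as a bright ring against a near-zero background,
3. suprathreshold pixels are grouped into 8-connected components,
4. the particle centre is the unweighted mean of component pixel positions,
5. the *radial intensity profile* — mean difference intensity per 1-px
   distance bin from the centre — locates the particle edge,
6. the diameter is read off at the outer half-maximum crossing of that
   profile, and the sphere volume (π/6)·d³ follows.

Aggregates contribute one diameter per resolved component; the event
volume is the sum of component sphere volumes.  Velocity comes from the
frame-to-frame displacement of the tracked centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .config import AcquisitionConfig

__all__ = [
    "BackgroundModel",
    "RadialProfile",
    "OpticalEvent",
    "ParticleMask",
    "NoParticleError",
    "compute_background",
    "difference_image",
    "segment_particles",
    "locate_center",
    "radial_profile",
    "estimate_diameter",
    "compute_volume",
    "estimate_velocity",
    "extract_optical_events",
    "robust_threshold",
]


class NoParticleError(ValueError):
    """Raised when a radial profile has no peak above the noise floor."""


@dataclass(frozen=True)
class BackgroundModel:
    """Blank-channel image: mean of the ``window`` frames before ``anchor_index``."""

    image: np.ndarray
    window: int
    anchor_index: int


@dataclass(frozen=True)
class RadialProfile:
    """Mean difference-image intensity per radial bin around a sub-pixel centre.

    ``radii_px`` are the bin centres (0, bin_width, 2·bin_width, ...);
    empty bins hold NaN in ``mean_intensity`` and are skipped downstream.
    """

    radii_px: np.ndarray
    mean_intensity: np.ndarray
    center_px: tuple[float, float]


@dataclass
class OpticalEvent:
    """One particle transit as seen by the camera."""

    event_id: int
    frame_indices: list[int]
    center_track_px: np.ndarray          # (n_frames, 2) sub-pixel (row, col)
    component_diameters_um: list[float]  # one per resolved component, best frame
    total_volume_um3: float
    velocity_um_s: float                 # NaN for single-frame events
    time_s: float                        # mean timestamp of the tracked frames
    quality_flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class ParticleMask:
    """A connected component of suprathreshold difference pixels."""

    mask: np.ndarray                 # full-frame boolean
    area_px: int
    touches_roi_border: bool


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def compute_background(
    frames: np.ndarray,
    anchor_index: int,
    window: int = 50,
    *,
    min_window: int = 10,
    strict: bool = False,
) -> BackgroundModel:
    """Mean of the ``window`` frames preceding ``anchor_index``.

    In strict mode a full window of history is required; in the default
    lenient mode any history of at least ``min_window`` frames is averaged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    available = anchor_index
    if strict and available < window:
        raise ValueError(
            f"insufficient history: {available} frames before anchor, need {window}"
        )
    if available < min_window:
        raise ValueError(
            f"insufficient history: {available} frames before anchor, "
            f"need at least {min_window}"
        )
    w = min(window, available)
    block = np.asarray(frames[anchor_index - w:anchor_index], dtype=np.float64)
    return BackgroundModel(image=block.mean(axis=0), window=w, anchor_index=anchor_index)


def difference_image(frame: np.ndarray, background: BackgroundModel | np.ndarray) -> np.ndarray:
    """Pixelwise absolute difference between a frame and the blank image."""
    bg = background.image if isinstance(background, BackgroundModel) else np.asarray(background)
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != bg.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs background {bg.shape}")
    return np.abs(frame - bg)


def robust_threshold(diff: np.ndarray, k: float = 5.0) -> float:
    """median + k robust sigmas (1.4826·MAD) of the difference image."""
    flat = np.asarray(diff, dtype=np.float64).ravel()
    med = np.median(flat)
    mad = np.median(np.abs(flat - med))
    return float(med + k * 1.4826 * mad)


def segment_particles(
    diff: np.ndarray,
    threshold: float,
    roi: tuple[int, int, int, int],
    *,
    min_area_px: int = 4,
) -> list[ParticleMask]:
    """8-connected components of ``{pixel in roi : diff > threshold}``.

    Components with fewer than ``min_area_px`` pixels are discarded;
    components whose bounding box touches the ROI border are flagged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diff = np.asarray(diff, dtype=np.float64)
    r0, c0, r1, c1 = roi
    sub = diff[r0:r1, c0:c1] > threshold
    labels = measure.label(sub, connectivity=2)
    out: list[ParticleMask] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        rr0, cc0, rr1, cc1 = region.bbox
        touches = rr0 == 0 or cc0 == 0 or rr1 == sub.shape[0] or cc1 == sub.shape[1]
        full = np.zeros(diff.shape, dtype=bool)
        full[r0:r1, c0:c1][labels == region.label] = True
        out.append(ParticleMask(mask=full, area_px=int(region.area), touches_roi_border=touches))
    return out


def locate_center(
    mask: np.ndarray,
    diff: np.ndarray | None = None,
    *,
    weighted: bool = False,
) -> tuple[float, float]:
    """Sub-pixel particle centre: mean (row, col) of the marked pixels.

    The default is the unweighted coordinate average; an intensity-weighted
    variant is available but off by default.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    if weighted:
        if diff is None:
            raise ValueError("weighted centroid requires the difference image")
        w = np.asarray(diff, dtype=np.float64)[rows, cols]
        if w.sum() <= 0:
            raise ValueError("non-positive total weight")
        return float((rows * w).sum() / w.sum()), float((cols * w).sum() / w.sum())
    return float(rows.mean()), float(cols.mean())


def radial_profile(
    diff: np.ndarray,
    center: tuple[float, float],
    max_radius_px: float,
    bin_width_px: float = 1.0,
) -> RadialProfile:
    """Mean difference intensity per radial distance bin around ``center``.

    Pixel (i, j) lands in bin ``round(dist / bin_width)``; empty bins are
    NaN.  Distances are measured from the sub-pixel centre.
    """
    if max_radius_px <= 0:
        raise ValueError("max_radius_px must be positive")
    if bin_width_px <= 0:
        raise ValueError("bin_width_px must be positive")
    diff = np.asarray(diff, dtype=np.float64)
    nr, nc = diff.shape
    cr, cc = center
    if not (0 <= cr <= nr - 1 and 0 <= cc <= nc - 1):
        raise ValueError("center must lie inside the image")
    n_bins = int(math.floor(max_radius_px / bin_width_px)) + 1
    # local window: only pixels within max_radius can contribute
    i0 = max(0, int(math.floor(cr - max_radius_px)) - 1)
    i1 = min(nr, int(math.ceil(cr + max_radius_px)) + 2)
    j0 = max(0, int(math.floor(cc - max_radius_px)) - 1)
    j1 = min(nc, int(math.ceil(cc + max_radius_px)) + 2)
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    dist = np.hypot(ii - cr, jj - cc)
    bins = np.rint(dist / bin_width_px).astype(np.intp)
    keep = bins < n_bins
    sums = np.bincount(bins[keep], weights=diff[i0:i1, j0:j1][keep], minlength=n_bins)
    counts = np.bincount(bins[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = np.arange(n_bins, dtype=np.float64) * bin_width_px
    return RadialProfile(radii_px=radii, mean_intensity=means, center_px=(float(cr), float(cc)))


def estimate_diameter(
    profile: RadialProfile,
    pixel_size_um: float,
    *,
    min_peak_to_floor: float = 3.0,
) -> float:
    """Diameter from the outer half-maximum crossing of the radial profile.

    The particle edge radius is the first radius beyond the profile peak at
    which the intensity falls below half the peak value, linearly
    interpolated between bins; the diameter is twice that radius scaled to
    micrometres.  A profile whose peak does not exceed
    ``min_peak_to_floor`` times its median (the noise floor) is treated as
    containing no particle.
    """
    vals = np.asarray(profile.mean_intensity, dtype=np.float64)
    radii = np.asarray(profile.radii_px, dtype=np.float64)
    valid = np.isfinite(vals)
    if valid.sum() < 3:
        raise NoParticleError("profile has too few populated bins")
    peak_idx = int(np.nanargmax(vals))
    peak = vals[peak_idx]
    floor = float(np.nanmedian(vals))
    if peak <= 0 or peak < min_peak_to_floor * max(floor, 1e-12):
        raise NoParticleError("no peak above the noise floor")
    half = 0.5 * peak
    prev_i = peak_idx
    for i in range(peak_idx + 1, len(vals)):
        if not valid[i]:
            continue
        if vals[i] < half:
            r_lo, v_lo = radii[prev_i], vals[prev_i]
            r_hi, v_hi = radii[i], vals[i]
            if v_lo == v_hi:
                r_edge = r_hi
            else:
                r_edge = r_lo + (v_lo - half) / (v_lo - v_hi) * (r_hi - r_lo)
            return 2.0 * r_edge * pixel_size_um
        prev_i = i
    raise NoParticleError("profile never falls below half maximum")


def compute_volume(diameter_um: float) -> float:
    """Sphere volume (π/6)·d³ = (4/3)·π·r³ in µm³."""
    if diameter_um < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi / 6.0 * diameter_um ** 3


def estimate_velocity(
    center_track_px: np.ndarray,
    timestamps: np.ndarray,
    pixel_size_um: float,
) -> float:
    """Transit speed: mean frame-to-frame displacement scaled by pixel size and rate."""
    track = np.asarray(center_track_px, dtype=np.float64)
    t = np.asarray(timestamps, dtype=np.float64)
    if track.ndim != 2 or track.shape[0] != t.shape[0]:
        raise ValueError("center_track_px and timestamps must have matching lengths")
    if track.shape[0] < 2:
        raise ValueError("velocity needs at least 2 tracked frames")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError("timestamps must be strictly increasing")
    steps = np.hypot(*np.diff(track, axis=0).T)
    return float(steps.mean() * pixel_size_um / dts.mean())


# ---------------------------------------------------------------------------
# frame-stack orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Detection:
    frame: int
    centroid: tuple[float, float]
    area: int
    diameter_um: float | None
    touches_border: bool


def _measure_component(
    diff: np.ndarray,
    region,
    offset: tuple[int, int],
    pixel_size_um: float,
) -> _Detection:
    """Centroid + radial-profile diameter for one labelled component."""
    r0, c0 = offset
    cr = region.centroid[0] + r0
    cc = region.centroid[1] + c0
    rr0, cc0, rr1, cc1 = region.bbox
    corners = np.array([
        [rr0 + r0, cc0 + c0], [rr0 + r0, cc1 - 1 + c0],
        [rr1 - 1 + r0, cc0 + c0], [rr1 - 1 + r0, cc1 - 1 + c0],
    ], dtype=np.float64)
    r_max = float(np.hypot(corners[:, 0] - cr, corners[:, 1] - cc).max()) + 4.0
    try:
        prof = radial_profile(diff, (cr, cc), r_max)
        d_um = estimate_diameter(prof, pixel_size_um)
    except (NoParticleError, ValueError):
        d_um = None
    return _Detection(frame=-1, centroid=(float(cr), float(cc)), area=int(region.area),
                      diameter_um=d_um, touches_border=False)


def extract_optical_events(
    frames: np.ndarray,
    config: AcquisitionConfig,
    *,
    frame_times_s: np.ndarray | None = None,
    window: int = 50,
    min_window: int = 10,
    threshold: float | None = None,
    min_area_px: int = 4,
    max_gap_frames: int = 2,
    link_radius_px: float = 60.0,
    threshold_k: float = 5.0,
    peak_floor_k: float = 3.0,
) -> list[OpticalEvent]:
    """Run the full diameter pipeline over a frame stack.

    Detections in nearby frames (gap <= ``max_gap_frames``, centroid within
    ``link_radius_px``) are grouped into one event.  Diameters are taken
    from the event's best frame — the frame of largest total component area
    in which no component touches the ROI border — one diameter per
    component; the event volume is the sum of component sphere volumes.

    When ``threshold`` is None a single run-level threshold is estimated as
    median + ``threshold_k`` robust sigmas of the difference image, pooled
    over a spread of sampled frames.

    The rolling background keeps a memory of a departed particle for one
    window length, and the absolute difference renders that memory as a
    faint ghost (amplitude ~ visible-frames/window of the true ring).  A
    component is therefore only accepted as a particle if its peak
    difference intensity reaches ``peak_floor_k`` times the threshold,
    which ghosts at the configured transit rate never do.
    """
    frames = np.asarray(frames)
    n = frames.shape[0]
    if n < min_window + 1:
        raise ValueError(f"need at least {min_window + 1} frames, got {n}")
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, rows, cols) stack")
    if frames.shape[1:] != tuple(config.frame_shape):
        raise ValueError(
            f"frame shape {frames.shape[1:]} does not match config {config.frame_shape}"
        )
    if frame_times_s is None:
        frame_times_s = np.arange(n) / config.fps
    r0, c0, r1, c1 = config.roi

    # one run-level robust threshold, pooled over sampled frames
    if threshold is None:
        sample_idx = np.unique(np.linspace(min_window, n - 1, 16).astype(int))
        pooled = []
        for i in sample_idx:
            bg = compute_background(frames, i, window, min_window=min_window)
            pooled.append(difference_image(frames[i], bg).ravel()[::3])
        threshold = robust_threshold(np.concatenate(pooled), k=threshold_k)
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    # rolling-window background via a running sum
    acc = frames[:min_window].astype(np.float64).sum(axis=0)
    count = min_window
    detections: list[list[_Detection]] = []
    for i in range(min_window, n):
        bg = acc / count
        fr = frames[i].astype(np.float64)
        diff = np.abs(fr - bg)
        sub = diff[r0:r1, c0:c1] > threshold
        if np.count_nonzero(sub) >= min_area_px:
            labels = measure.label(sub, connectivity=2)
            dets = []
            for region in measure.regionprops(labels, intensity_image=diff[r0:r1, c0:c1]):
                if region.area < min_area_px:
                    continue
                if region.intensity_max < peak_floor_k * threshold:
                    continue  # rolling-background ghost, not a particle
                det = _measure_component(diff, region, (r0, c0), config.pixel_size_um)
                rr0, cc0, rr1, cc1 = region.bbox
                touches = rr0 == 0 or cc0 == 0 or rr1 == sub.shape[0] or cc1 == sub.shape[1]
                dets.append(_Detection(frame=i, centroid=det.centroid, area=det.area,
                                       diameter_um=det.diameter_um, touches_border=touches))
            if dets:
                detections.append(dets)
        # slide the window
        acc += fr
        count += 1
        if count > window:
            acc -= frames[i - window].astype(np.float64)
            count -= 1

    # group frame detections into events
    events: list[OpticalEvent] = []
    current: list[list[_Detection]] = []

    def _mean_centroid(dets: list[_Detection]) -> np.ndarray:
        return np.mean([d.centroid for d in dets], axis=0)

    def _flush(group: list[list[_Detection]]) -> None:
        if not group:
            return
        idxs = [g[0].frame for g in group]
        track = np.array([_mean_centroid(g) for g in group])
        flags: set[str] = set()
        # best frame: largest total area with no border contact and all sized
        best = None
        best_area = -1
        for g in group:
            if any(d.touches_border for d in g):
                continue
            if any(d.diameter_um is None for d in g):
                continue
            area = sum(d.area for d in g)
            if area > best_area:
                best_area = area
                best = g
        if best is None:
            flags.add("no_clean_frame")
            diameters: list[float] = []
        else:
            diameters = [float(d.diameter_um) for d in best]
            if len(best) > 1:
                flags.add("aggregate")
        if any(d.touches_border for g in group for d in g):
            flags.add("touched_roi_border")
        total_volume = float(sum(compute_volume(d) for d in diameters))
        times = frame_times_s[idxs]
        if len(idxs) >= 2:
            vel = estimate_velocity(track, times, config.pixel_size_um)
        else:
            vel = float("nan")
            flags.add("single_frame")
        events.append(OpticalEvent(
            event_id=len(events),
            frame_indices=list(idxs),
            center_track_px=track,
            component_diameters_um=diameters,
            total_volume_um3=total_volume,
            velocity_um_s=vel,
            time_s=float(times.mean()),
            quality_flags=flags,
        ))

    for dets in detections:
        if current:
            gap = dets[0].frame - current[-1][0].frame
            dist = float(np.hypot(*(_mean_centroid(dets) - _mean_centroid(current[-1]))))
            if gap <= max_gap_frames + 1 and dist <= link_radius_px + gap * link_radius_px:
                current.append(dets)
                continue
            _flush(current)
        current = [dets]
    _flush(current)
    return events
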