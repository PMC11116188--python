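"""Synthetic co-registered video + multi-frequency impedance runs.

The generator emulates the acquisition the analysis assumes: a monochrome
high-speed camera (125 fps, 0.2 µm/px, 8-bit-like grayscale) watching a
microfluidic sensing region, and a lock-in amplifier producing eight
amplitude channels at 899 S/s.  Each scheduled transit appears

* optically, as a bright ring (defocused-bead difference signature) of the
  correct pixel diameter, Gaussian-blurred and noisy, moving across the
  ROI over a handful of frames, and
* electrically, as a unipolar Gaussian pulse in every channel centred on
  the transit time with amplitude ``gain · run_gain · Σ V_i^b`` scaled by
  a per-class spectral tilt and log-normal event/channel scatter.

Aggregates are rendered as a vertical chain of resolvable rings and as a
single summed-amplitude impedance peak.  Everything derives from one seed,
so identical parameters give bit-identical runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import AcquisitionConfig, ClassSpec, SimulationParams, freq_label
from .electrical import ImpedanceTrace
from .optical import compute_volume

__all__ = [
    "GroundTruthEvent",
    "SyntheticRun",
    "render_frame",
    "synth_trace",
    "generate_run",
    "write_run",
    "read_trace_csv",
    "read_truth_csv",
]

_HALF_MAX = math.sqrt(2.0 * math.log(2.0))  # half-maximum offset in sigmas


@dataclass
class GroundTruthEvent:
    """Ground truth for one transit (single particle or aggregate)."""

    event_id: int
    class_id: int
    transit_time_s: float
    component_diameters_um: list[float]
    true_total_volume_um3: float
    trajectory: np.ndarray            # (n_vis, 3): time_s, row_px, col_px
    true_velocity_um_s: float
    # renderer bookkeeping (not part of the measured record)
    component_row_offsets_px: np.ndarray = field(default_factory=lambda: np.zeros(1))
    component_render_px: np.ndarray | None = None  # apparent diameters, pixels
    channel_amplitudes: np.ndarray | None = None  # per-frequency normalized peak height


@dataclass
class SyntheticRun:
    """One co-registered synthetic acquisition."""

    config: AcquisitionConfig
    frames: np.ndarray                # (n_frames, rows, cols) uint8
    frame_times_s: np.ndarray
    trace: ImpedanceTrace
    truth: list[GroundTruthEvent]
    run_id: str
    params: SimulationParams


# ---------------------------------------------------------------------------
# optical rendering
# ---------------------------------------------------------------------------

def _add_ring(layer: np.ndarray, center: tuple[float, float], radius_px: float,
              amplitude: float, ring_sigma_px: float, psf_sigma_px: float) -> None:
    """Draw one radial-Gaussian annulus into ``layer`` (pre-blur).

    The annulus is centred at ``radius - delta`` with ``delta`` chosen so
    that after the point-spread blur the *outer half-maximum* of the radial
    intensity profile sits at ``radius``: the half-max read-off of the
    sizing algorithm then recovers the nominal particle radius.
    """
    sigma_eff = math.hypot(ring_sigma_px, psf_sigma_px)
    r0 = max(radius_px - _HALF_MAX * sigma_eff, 0.3 * radius_px)
    cr, cc = center
    ext = radius_px + 4.0 * ring_sigma_px
    i0 = max(0, int(math.floor(cr - ext)))
    i1 = min(layer.shape[0], int(math.ceil(cr + ext)) + 1)
    j0 = max(0, int(math.floor(cc - ext)))
    j1 = min(layer.shape[1], int(math.ceil(cc + ext)) + 1)
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    dist = np.hypot(ii - cr, jj - cc)
    layer[i0:i1, j0:j1] += amplitude * np.exp(-((dist - r0) ** 2) / (2.0 * ring_sigma_px ** 2))


def render_frame(
    background: np.ndarray,
    particles: list[tuple[tuple[float, float], float]],
    psf_sigma_px: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    *,
    amplitude: float = 120.0,
    ring_sigma_px: float = 1.0,
) -> np.ndarray:
    """Background + ring-like particle profiles + Gaussian noise.

    ``particles`` is a list of ``(center_(row, col), diameter_px)``.  The
    whole disk of each particle must lie inside the frame; the input
    background is never modified.
    """
    bg = np.asarray(background, dtype=np.float64)
    nr, nc = bg.shape
    layer = np.zeros_like(bg)
    for (cr, cc), d_px in particles:
        if d_px <= 0:
            raise ValueError("particle diameter must be positive")
        r = d_px / 2.0
        if not (0 <= cr <= nr - 1 and 0 <= cc <= nc - 1):
            raise ValueError(f"particle center ({cr}, {cc}) outside frame")
        if cr - r < 0 or cr + r > nr - 1 or cc - r < 0 or cc + r > nc - 1:
            raise ValueError(f"particle at ({cr}, {cc}) extends beyond the frame")
        _add_ring(layer, (cr, cc), r, amplitude, ring_sigma_px, psf_sigma_px)
    if particles and psf_sigma_px > 0:
        layer = gaussian_filter(layer, psf_sigma_px)
    out = bg + layer
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out


def _make_background(config: AcquisitionConfig, params: SimulationParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Static blank-channel image: level + gentle gradient + fixed-pattern noise."""
    nr, nc = config.frame_shape
    rows = np.linspace(-1, 1, nr)[:, None]
    cols = np.linspace(-1, 1, nc)[None, :]
    base = params.background_level + 4.0 * rows + 2.0 * cols
    pattern = gaussian_filter(rng.normal(0.0, 3.0, size=(nr, nc)), 3.0)
    return np.clip(base + pattern, 0.0, 255.0)


# ---------------------------------------------------------------------------
# electrical synthesis
# ---------------------------------------------------------------------------

def _channel_tilt(config: AcquisitionConfig, params: SimulationParams,
                  spectral_tilt: float) -> np.ndarray:
    """Per-channel multiplier 1 + (tilt_base + class tilt) · u, u in [-1, 1]."""
    nf = config.n_frequencies
    u = np.linspace(-1.0, 1.0, nf) if nf > 1 else np.zeros(1)
    return 1.0 + (params.channel_tilt_base + spectral_tilt) * u


def synth_trace(
    events: list[GroundTruthEvent],
    config: AcquisitionConfig,
    params: SimulationParams,
    *,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> ImpedanceTrace:
    """Raw multi-frequency impedance trace containing the events' pulses.

    Each channel is ``Z0 · (1 + drift + Σ amp_e · kernel(t − t_e)) + noise``
    with a unipolar Gaussian kernel (FWHM ``pulse_fwhm_s``; a bipolar
    derivative-shaped dialect is available via ``bipolar_pulses``).  Events
    that carry pre-computed ``channel_amplitudes`` use them; otherwise the
    noise-free law ``gain · Σ V_i^b`` (zero class tilt) applies, so that
    with noise and drift disabled peak amplitude increases strictly with
    true volume.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if duration_s is None:
        last = max((e.transit_time_s for e in events), default=0.0)
        duration_s = last + params.warmup_s + 0.5
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    for e in events:
        if not (0.0 <= e.transit_time_s <= duration_s):
            raise ValueError(f"event {e.event_id} at {e.transit_time_s}s outside run duration")

    nf = config.n_frequencies
    sigma_p = params.pulse_fwhm_s / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    drift_phase = rng.uniform(0.0, 2.0 * math.pi)
    drift = params.baseline_drift_amp * np.sin(
        2.0 * math.pi * t / params.baseline_drift_period_s + drift_phase
    )
    rel = np.tile(1.0 + drift, (nf, 1))

    for e in events:
        if e.channel_amplitudes is not None:
            amps = np.asarray(e.channel_amplitudes, dtype=np.float64)
        else:
            # gain · Σ V_i^b, no tilt, no scatter
            base = params.impedance_gain * sum(
                compute_volume(d) ** params.pi_exponent for d in e.component_diameters_um
            )
            amps = np.full(nf, base)
        i0 = max(0, int((e.transit_time_s - 6 * sigma_p) * config.sample_rate_hz))
        i1 = min(n, int((e.transit_time_s + 6 * sigma_p) * config.sample_rate_hz) + 1)
        if i0 >= i1:
            continue
        dt = t[i0:i1] - e.transit_time_s
        if params.bipolar_pulses:
            kernel = -(dt / sigma_p) * np.exp(0.5 - dt ** 2 / (2 * sigma_p ** 2))
        else:
            kernel = np.exp(-(dt ** 2) / (2 * sigma_p ** 2))
        rel[:, i0:i1] += amps[:, None] * kernel[None, :]

    channels: dict[float, np.ndarray] = {}
    for ci, f in enumerate(config.frequencies_hz):
        z0 = 1000.0 * (1.0 + 0.02 * ci)
        noise = rng.normal(0.0, params.impedance_noise_sd * z0, size=n) \
            if params.impedance_noise_sd > 0 else 0.0
        channels[f] = z0 * rel[ci] + noise
    return ImpedanceTrace(time_s=t, channels=channels, normalized=False)


# ---------------------------------------------------------------------------
# run generation
# ---------------------------------------------------------------------------

def _plan_event(
    cid: int, spec: ClassSpec, t_nominal: float,
    config: AcquisitionConfig, params: SimulationParams,
    rng: np.random.Generator, event_id: int,
) -> GroundTruthEvent:
    """Geometry + kinematics for one transit; amplitudes are filled in later."""
    nr, nc = config.frame_shape
    r0, c0, r1, c1 = config.roi
    lo, hi = spec.diameter_range_um

    n_p = 1
    if rng.uniform() < params.aggregate_probability:
        a_lo, a_hi = params.aggregate_size_range
        n_p = int(rng.integers(a_lo, a_hi + 1))
    diams = rng.uniform(lo, hi, size=n_p)
    # apparent optical size: product-specific halo bias plus defocus
    # jitter, then the camera pixel grid
    apparent = diams + spec.optical_bias_um \
        + rng.normal(0.0, params.sizing_jitter_um, size=n_p)
    apparent = np.maximum(apparent, 0.5 * diams)

    margin = 3.0 * params.psf_sigma_px + 2.0
    avail_rows = (r1 - r0) - 2.0 * margin

    def chain_geometry(ds: np.ndarray):
        # camera-grid quantization: rendered diameter snaps to whole pixels
        radii = np.round(ds / config.pixel_size_um) / 2.0
        offs = [0.0]
        for a, b in zip(radii[:-1], radii[1:]):
            offs.append(offs[-1] + a + b + params.aggregate_gap_px)
        offs = np.asarray(offs) - np.mean(offs)
        extent = (offs[-1] + radii[-1]) - (offs[0] - radii[0])
        return radii, offs, extent

    radii_px, offsets, extent = chain_geometry(apparent)
    while len(diams) > 1 and extent > avail_rows:
        diams = diams[:-1]
        apparent = apparent[:-1]
        radii_px, offsets, extent = chain_geometry(apparent)

    r_max = float(radii_px.max())
    # vertical placement: whole chain inside the ROI with margin
    row_lo = r0 + margin - offsets[0] + radii_px[0]
    row_hi = r1 - margin - offsets[-1] - radii_px[-1]
    if row_hi < row_lo:
        row_c = 0.5 * (r0 + r1)
    else:
        mid = 0.5 * (row_lo + row_hi)
        half = 0.5 * (row_hi - row_lo)
        row_c = mid + np.clip(rng.normal(0.0, 2.0), -half, half)

    speed = rng.uniform(*params.velocity_band_um_s)
    step_px = speed / (config.pixel_size_um * config.fps)
    col_lo = c0 + margin + r_max
    col_hi = c1 - margin - r_max
    span = max(col_hi - col_lo, step_px)
    n_vis = max(2, min(int(span // step_px) + 1, 24))
    start_lo = col_lo
    start_hi = max(col_lo, col_hi - step_px * (n_vis - 1))
    start = rng.uniform(start_lo, start_hi)
    cols = start + step_px * np.arange(n_vis)
    cols = np.clip(cols, col_lo, col_hi)
    if rng.uniform() < 0.5:
        cols = cols[::-1].copy()

    f_mid = int(round(t_nominal * config.fps))
    mid = (n_vis - 1) // 2
    frame_idx = f_mid - mid + np.arange(n_vis)
    times = frame_idx / config.fps
    traj = np.column_stack([times, np.full(n_vis, row_c), cols])
    total_v = float(sum(compute_volume(d) for d in diams))
    return GroundTruthEvent(
        event_id=event_id,
        class_id=cid,
        transit_time_s=float(f_mid / config.fps),
        component_diameters_um=[float(d) for d in diams],
        true_total_volume_um3=total_v,
        trajectory=traj,
        true_velocity_um_s=float(speed),
        component_row_offsets_px=offsets,
        component_render_px=2.0 * radii_px,
        channel_amplitudes=None,
    )


def generate_run(
    config: AcquisitionConfig,
    classes: list[ClassSpec],
    params: SimulationParams,
    run_id: str = "run-000",
) -> SyntheticRun:
    """Generate one co-registered synthetic run.

    Transits are scheduled on a jittered grid (one slot every
    ``event_spacing_s``) after a ``warmup_s`` lead-in, so the 50-frame
    rolling background rarely overlaps a neighbouring transit.  Identical
    ``(config, classes, params)`` give a bit-identical run.
    """
    ids = [c.class_id for c in classes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate class_id in classes")
    by_id = {c.class_id: c for c in classes}

    root = np.random.default_rng(params.seed)
    r_sched, r_geom, r_amp, r_frames, r_trace = root.spawn(5)

    n_ev = params.n_events_per_class * len(classes)
    duration = 2.0 * params.warmup_s + n_ev * params.event_spacing_s
    if duration <= 0:
        raise ValueError("run duration must be positive")
    n_frames = int(round(duration * config.fps))
    frame_times = np.arange(n_frames) / config.fps

    class_seq = np.repeat(ids, params.n_events_per_class)
    r_sched.shuffle(class_seq)
    jitter = r_sched.uniform(-params.spacing_jitter_s, params.spacing_jitter_s, size=n_ev)
    t_nominal = params.warmup_s + np.arange(n_ev) * params.event_spacing_s + jitter

    events: list[GroundTruthEvent] = []
    for k in range(n_ev):
        events.append(_plan_event(int(class_seq[k]), by_id[int(class_seq[k])],
                                  float(t_nominal[k]), config, params, r_geom, k))
    events.sort(key=lambda e: e.transit_time_s)
    for k, e in enumerate(events):
        e.event_id = k

    # electrical amplitudes: gain · run_gain · Σ V_i^b · tilt · scatter
    run_gain = float(np.exp(r_amp.normal(0.0, params.gain_drift_sd)))
    for e in events:
        v_tot = sum(compute_volume(d) for d in e.component_diameters_um)
        base = params.impedance_gain * run_gain * sum(
            compute_volume(d) ** params.pi_exponent for d in e.component_diameters_um
        )
        tilt = _channel_tilt(config, params, by_id[e.class_id].spectral_tilt)
        # noise-floor scaling: smaller pulses scatter more (in log units)
        rel = params.pi_noise_ref_volume_um3 / max(v_tot, 1e-12)
        f_ev = min(params.pi_noise_factor_cap, rel ** params.pi_event_noise_exp)
        f_ch = min(params.pi_noise_factor_cap, rel ** params.pi_channel_noise_exp)
        shared = 10.0 ** r_amp.normal(0.0, params.pi_event_noise_sd * f_ev)
        per_chan = 10.0 ** r_amp.normal(0.0, params.pi_channel_noise_sd * f_ch,
                                        size=config.n_frequencies)
        e.channel_amplitudes = base * shared * tilt * per_chan

    # frames
    base_img = _make_background(config, params, r_frames)
    frames = np.empty((n_frames, *config.frame_shape), dtype=np.uint8)
    visible: dict[int, list[tuple[tuple[float, float], float]]] = {}
    for e in events:
        for tt, rr, cc in e.trajectory:
            fi = int(round(tt * config.fps))
            if not (0 <= fi < n_frames):
                continue
            render_px = e.component_render_px
            if render_px is None:
                render_px = np.round(
                    np.asarray(e.component_diameters_um) / config.pixel_size_um)
            for d_px, o in zip(render_px, e.component_row_offsets_px):
                visible.setdefault(fi, []).append(((rr + o, cc), float(d_px)))
    for i in range(n_frames):
        out = render_frame(
            base_img, visible.get(i, []),
            psf_sigma_px=params.psf_sigma_px,
            noise_sd=params.optical_noise_sd,
            seed=r_frames,
            amplitude=params.optical_amplitude,
            ring_sigma_px=params.ring_sigma_px,
        )
        frames[i] = np.clip(np.rint(out), 0, 255).astype(np.uint8)

    trace = synth_trace(events, config, params, duration_s=duration, rng=r_trace)
    return SyntheticRun(config=config, frames=frames, frame_times_s=frame_times,
                        trace=trace, truth=events, run_id=run_id, params=params)


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def write_run(run: SyntheticRun, outdir: str | Path) -> None:
    """Write frames (multi-page TIFF + timestamp CSV), trace CSV, truth CSV, manifest."""
    import pandas as pd
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "frames.tif", run.frames)
    pd.DataFrame({"frame": np.arange(run.frames.shape[0]),
                  "time_s": run.frame_times_s}).to_csv(outdir / "frame_times.csv", index=False)
    cols = {"time_s": run.trace.time_s}
    for f in run.config.frequencies_hz:
        cols[f"amp_{freq_label(f)}"] = run.trace.channels[f]
    pd.DataFrame(cols).to_csv(outdir / "trace.csv", index=False)
    rows = []
    for e in run.truth:
        rows.append({
            "event_id": e.event_id,
            "class_id": e.class_id,
            "transit_time_s": e.transit_time_s,
            "component_diameters_um": ";".join(f"{d:.6f}" for d in e.component_diameters_um),
            "true_total_volume_um3": e.true_total_volume_um3,
            "true_velocity_um_s": e.true_velocity_um_s,
        })
    pd.DataFrame(rows).to_csv(outdir / "truth.csv", index=False)
    manifest = {
        "run_id": run.run_id,
        "config": run.config.to_dict(),
        "params": run.params.to_dict(),
        "n_frames": int(run.frames.shape[0]),
        "n_events": len(run.truth),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_trace_csv(path: str | Path, config: AcquisitionConfig) -> ImpedanceTrace:
    """Read a trace CSV (time_s + one amp_* column per carrier)."""
    import pandas as pd

    df = pd.read_csv(path)
    channels = {}
    for f in config.frequencies_hz:
        col = f"amp_{freq_label(f)}"
        if col not in df.columns:
            raise ValueError(f"trace file missing column {col}")
        channels[f] = df[col].to_numpy(dtype=np.float64)
    return ImpedanceTrace(time_s=df["time_s"].to_numpy(dtype=np.float64),
                          channels=channels, normalized=False)


def read_truth_csv(path: str | Path) -> list[GroundTruthEvent]:
    """Read the ground-truth table written by :func:`write_run`."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        diams = [float(x) for x in str(row["component_diameters_um"]).split(";") if x]
        out.append(GroundTruthEvent(
            event_id=int(row["event_id"]),
            class_id=int(row["class_id"]),
            transit_time_s=float(row["transit_time_s"]),
            component_diameters_um=diams,
            true_total_volume_um3=float(row["true_total_volume_um3"]),
            trajectory=np.zeros((0, 3)),
            true_velocity_um_s=float(row["true_velocity_um_s"]),
        ))
    return out
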