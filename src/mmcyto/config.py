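"""Shared acquisition and simulation configuration.

All physical and acquisition constants used by both the synthetic-data
generator and the extraction modules live here, so that simulator and
analysis can never silently disagree about frame rate, pixel size,
sampling rate or the carrier-frequency set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = [
    "DEFAULT_FREQUENCIES_HZ",
    "AcquisitionConfig",
    "ClassSpec",
    "SimulationParams",
    "default_classes",
    "freq_label",
]

#: The eight lock-in carrier frequencies, in Hz, lowest first.
DEFAULT_FREQUENCIES_HZ: tuple[float, ...] = (
    100e3, 250e3, 500e3, 750e3, 1.0e6, 1.25e6, 1.5e6, 1.75e6,
)


def freq_label(frequency_hz: float) -> str:
    """Column-name label for a carrier frequency, e.g. ``500kHz``, ``1750kHz``."""
    return f"{frequency_hz / 1e3:g}kHz"


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition constants shared by the simulator and the extractors.

    Parameters
    ----------
    fps : float
        Camera frame rate in frames per second.
    exposure_s : float
        Camera exposure time in seconds (metadata only; the renderer does
        not model motion blur).
    pixel_size_um : float
        Physical size of one camera pixel in micrometres.
    frame_shape : (int, int)
        Frame size in pixels, ``(rows, cols)``.
    roi : (int, int, int, int)
        Region of interest ``(row0, col0, row1, col1)``, half-open, in pixel
        coordinates; must lie within ``frame_shape``.
    sample_rate_hz : float
        Impedance sampling rate in samples per second.
    frequencies_hz : tuple of float
        Strictly increasing carrier frequencies of the amplitude channels.
    """

    fps: float = 125.0
    exposure_s: float = 63.75e-6
    pixel_size_um: float = 0.2
    frame_shape: tuple[int, int] = (104, 128)
    roi: tuple[int, int, int, int] = (1, 1, 103, 127)
    sample_rate_hz: float = 899.0
    frequencies_hz: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if len(self.frame_shape) != 2 or any(s <= 0 for s in self.frame_shape):
            raise ValueError("frame_shape must be two positive integers")
        freqs = tuple(float(f) for f in self.frequencies_hz)
        if len(freqs) < 1:
            raise ValueError("frequencies_hz must have length >= 1")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("frequencies_hz must be strictly increasing")
        object.__setattr__(self, "frequencies_hz", freqs)
        r0, c0, r1, c1 = self.roi
        nr, nc = self.frame_shape
        if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
            raise ValueError("roi must be a non-empty rectangle inside frame_shape")

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies_hz)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        d["roi"] = list(self.roi)
        d["frequencies_hz"] = list(self.frequencies_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        d["frame_shape"] = tuple(d["frame_shape"])
        d["roi"] = tuple(d["roi"])
        d["frequencies_hz"] = tuple(d["frequencies_hz"])
        return cls(**d)


@dataclass(frozen=True)
class ClassSpec:
    """One particle class: three bead products plus a cancer-cell line.

    ``spectral_tilt`` is a dimensionless per-class linear tilt of the
    impedance response across the carrier set: the amplitude at channel
    ``c`` is scaled by ``1 + (tilt_base + spectral_tilt) * u_c`` with
    ``u_c`` running linearly from -1 (lowest carrier) to +1 (highest).
    It models material-dependent dispersion — polystyrene beads and cells
    do not perturb the impedance identically at every frequency — which is
    what makes the multi-frequency channel set informative beyond size.

    ``optical_bias_um`` is a systematic offset of the *apparent* optical
    diameter for this particle product (imaging halo / defocus signature).
    The bead products do not image identically: a product whose apparent
    size is inflated leaks optically into the next size class one-sidedly,
    while its impedance still follows the true volume — which is precisely
    the failure mode the fused classifier exists to repair.
    """

    class_id: int
    name: str
    diameter_range_um: tuple[float, float]
    spectral_tilt: float = 0.0
    optical_bias_um: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi):
            raise ValueError("diameter_range_um must satisfy 0 < low <= high")
        if not (1 <= int(self.class_id)):
            raise ValueError("class_id must be a positive integer")
        object.__setattr__(self, "diameter_range_um", (float(lo), float(hi)))


def default_classes() -> list[ClassSpec]:
    """The study's four classes: three bead sizes and MDA-MB-231 cells."""
    return [
        ClassSpec(1, "bead_2um", (2.0, 2.9), spectral_tilt=-0.15),
        ClassSpec(2, "bead_4um", (4.0, 4.5), spectral_tilt=0.0, optical_bias_um=0.5),
        ClassSpec(3, "bead_5um", (5.0, 5.9), spectral_tilt=+0.15),
        ClassSpec(4, "mda_mb_231", (15.0, 17.0), spectral_tilt=-0.22),
    ]


@dataclass(frozen=True)
class SimulationParams:
    """Tunable knobs of the synthetic acquisition.

    The defaults define the study conditions emulated by the generator:
    sparse transits (~2 events/s so the 50-frame rolling background stays
    clean), 8-bit-like optics at 0.2 µm/px with Gaussian read noise, and a
    volume-proportional impedance response PI = gain · V^b with run-level
    gain drift (device-to-device variability) and per-event log-normal
    scatter calibrated so the per-frequency log–log R² of volume against
    peak intensity lands in the high-0.8/low-0.9 band.

    Attributes
    ----------
    n_events_per_class : int
        Transits generated per particle class.
    aggregate_probability : float
        Probability that a transit is a multi-particle aggregate.
    aggregate_size_range : (int, int)
        Inclusive range of the number of particles in an aggregate.
    optical_noise_sd : float
        Gaussian camera read noise, grayscale units (0–255 scale).
    psf_sigma_px : float
        Gaussian blur sigma applied to rendered particles, pixels.
    impedance_noise_sd : float
        Additive trace noise relative to the channel baseline.
    impedance_gain : float
        Run-independent proportionality between V^b (µm³) and normalized
        peak height ΔZ/Z0.
    gain_drift_sd : float
        Sigma of the log-normal run-level gain multiplier, sampled once per
        run (device-to-device / day-to-day variation).
    baseline_drift_amp : float
        Relative amplitude of the slow sinusoidal baseline drift.
    pi_exponent : float
        Exponent b in PI ∝ V^b.
    sizing_jitter_um : float
        Per-component scatter of the *apparent* optical diameter (defocus
        and illumination variability), applied before the camera-grid
        quantization; the electrical amplitude always follows the true
        volume.  This is what blurs the optically hardest class boundary
        (4.0-4.5 vs 5.0-5.9 µm beads) without touching the impedance.
    pi_event_noise_sd : float
        Per-event multiplicative scatter of the peak height, log10 units,
        shared across channels, at the reference volume
        ``pi_noise_ref_volume_um3``.
    pi_channel_noise_sd : float
        Additional per-channel multiplicative scatter, log10 units, at the
        reference volume.
    pi_event_noise_exp, pi_channel_noise_exp : float
        The measurement noise floor makes small pulses relatively noisier:
        each scatter component is scaled by ``(V_ref / V)**exp`` (capped at
        ``pi_noise_factor_cap``), so the smallest beads carry large PI
        scatter while big particles are measured cleanly.  The event-level
        component falls off steeply (pulse-shape/readout error), the
        channel-level component mildly (independent electronics noise).
    seed : int
        Seed for every random draw the generator makes.
    """

    n_events_per_class: int = 50
    aggregate_probability: float = 0.10
    aggregate_size_range: tuple[int, int] = (2, 3)
    optical_noise_sd: float = 2.0
    psf_sigma_px: float = 1.0
    impedance_noise_sd: float = 2e-5
    impedance_gain: float = 2e-4
    gain_drift_sd: float = 0.12
    baseline_drift_amp: float = 0.001
    pi_exponent: float = 1.0
    sizing_jitter_um: float = 0.35
    pi_event_noise_sd: float = 0.48
    pi_channel_noise_sd: float = 0.12
    pi_event_noise_exp: float = 0.3
    pi_channel_noise_exp: float = 0.0
    pi_noise_ref_volume_um3: float = 8.0
    pi_noise_factor_cap: float = 1.7
    seed: int = 0
    # acquisition-geometry details
    event_spacing_s: float = 0.45
    spacing_jitter_s: float = 0.05
    warmup_s: float = 0.6
    velocity_band_um_s: tuple[float, float] = (150.0, 350.0)
    optical_amplitude: float = 120.0
    ring_sigma_px: float = 1.0
    background_level: float = 30.0
    pulse_fwhm_s: float = 0.02
    bipolar_pulses: bool = False
    baseline_drift_period_s: float = 8.0
    channel_tilt_base: float = 0.05
    aggregate_gap_px: float = 6.0

    def __post_init__(self) -> None:
        if self.n_events_per_class < 0:
            raise ValueError("n_events_per_class must be >= 0")
        if not (0.0 <= self.aggregate_probability <= 1.0):
            raise ValueError("aggregate_probability must lie in [0, 1]")
        lo, hi = self.aggregate_size_range
        if not (1 <= lo <= hi):
            raise ValueError("aggregate_size_range must satisfy 1 <= min <= max")
        for name in (
            "optical_noise_sd", "impedance_noise_sd", "gain_drift_sd",
            "baseline_drift_amp", "pi_event_noise_sd", "pi_channel_noise_sd",
            "sizing_jitter_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pi_exponent <= 0:
            raise ValueError("pi_exponent must be positive")
        if self.impedance_gain <= 0:
            raise ValueError("impedance_gain must be positive")
        if self.event_spacing_s <= 0 or self.pulse_fwhm_s <= 0:
            raise ValueError("event spacing and pulse width must be positive")

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aggregate_size_range"] = list(self.aggregate_size_range)
        d["velocity_band_um_s"] = list(self.velocity_band_um_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        d["aggregate_size_range"] = tuple(d["aggregate_size_range"])
        d["velocity_band_um_s"] = tuple(d["velocity_band_um_s"])
        return cls(**d)
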