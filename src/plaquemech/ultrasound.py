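"""Linear-array RF simulation of scatterer fields.

A convolutional point-spread-function model: every RF line is the sum over
scatterers of reflectivity x lateral Gaussian beam weight x Gaussian-
modulated cosine pulse centered at the scatterer depth.  This produces
fully developed speckle (Rayleigh envelope statistics) at sufficient
scatterer density, which is what the displacement tracker needs; it does
not model beamforming, attenuation or nonlinear propagation.

Depth-sample convention: sample i of a line sits at depth
y = i * axial_step with axial_step = c / (2 fs); the RF carrier has depth
wavelength c / (2 f0) (pulse-echo round trip).

Defaults emulate a ~40 MHz high-frequency linear array; the sampling rate
(154 MHz) and line pitch (11 µm) are chosen so that the tracker's physical
kernel sizes quantize to exact integer sample counts: the axial step is
exactly 5 µm and the 715 / 935 µm lateral kernels are exactly 65 / 85 lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit
from scipy.signal import hilbert

from plaquemech.phantom import ScattererField

__all__ = ["TransducerSpec", "FieldOfView", "RFFrame", "simulate_rf",
           "displace_scatterers", "bmode", "write_bmode_pgm",
           "write_rf", "read_rf"]


@dataclass(frozen=True)
class TransducerSpec:
    """Linear-array acquisition parameters.

    center_frequency_mhz: pulse carrier (default 40 MHz).
    sampling_frequency_mhz: RF sampling rate (>= 3x carrier).
    line_pitch_um: lateral spacing of RF lines.
    pulse_bandwidth: fractional -6 dB bandwidth of the Gaussian pulse.
    speed_of_sound_m_s: assumed sound speed.
    lateral_beam_sigma_um: Gaussian beam-profile sigma.
    """

    center_frequency_mhz: float = 40.0
    sampling_frequency_mhz: float = 154.0
    line_pitch_um: float = 11.0
    pulse_bandwidth: float = 0.5
    speed_of_sound_m_s: float = 1540.0
    lateral_beam_sigma_um: float = 45.0

    def __post_init__(self):
        vals = (self.center_frequency_mhz, self.sampling_frequency_mhz,
                self.line_pitch_um, self.pulse_bandwidth,
                self.speed_of_sound_m_s, self.lateral_beam_sigma_um)
        if any(v <= 0 for v in vals):
            raise ValueError("all transducer parameters must be positive")
        if self.sampling_frequency_mhz < 3 * self.center_frequency_mhz:
            # Nyquist for the upper band edge of a 50%-bandwidth pulse is
            # 2 x 1.25 f0; 3x leaves comfortable margin.
            raise ValueError("sampling frequency must be at least 3x the carrier")

    @property
    def axial_step_um(self) -> float:
        """Depth step per RF sample, c / (2 fs), in µm."""
        # m/s divided by MHz is µm; 1540 / (2 * 154) = 5 µm
        return self.speed_of_sound_m_s / (2.0 * self.sampling_frequency_mhz)

    @property
    def carrier_wavelength_um(self) -> float:
        """Pulse-echo carrier wavelength in depth, c / (2 f0), µm."""
        return self.speed_of_sound_m_s / (2.0 * self.center_frequency_mhz)

    @property
    def axial_pulse_sigma_um(self) -> float:
        """Gaussian pulse envelope sigma in depth, from the fractional
        -6 dB bandwidth of a Gaussian spectrum."""
        f0 = self.center_frequency_mhz * 1e6
        sigma_t = np.sqrt(8 * np.log(2)) / (2 * np.pi * self.pulse_bandwidth * f0)
        return 0.5 * self.speed_of_sound_m_s * sigma_t * 1e6


@dataclass(frozen=True)
class FieldOfView:
    """Imaged region: lateral extent [x_min, x_max] mm, depth [0, depth] mm."""

    x_min_mm: float = -4.0
    x_max_mm: float = 4.0
    depth_mm: float = 10.0

    def __post_init__(self):
        if self.x_max_mm <= self.x_min_mm or self.depth_mm <= 0:
            raise ValueError("empty field of view")


@dataclass
class RFFrame:
    """RF samples (axial sample x line) plus acquisition metadata."""

    samples: np.ndarray
    axial_step_um: float
    line_pitch_um: float
    x0_mm: float
    transducer: TransducerSpec

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 2:
            raise ValueError("RF samples must be a 2D (sample x line) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    def axial_positions_mm(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.axial_step_um * 1e-3

    def lateral_positions_mm(self) -> np.ndarray:
        return self.x0_mm + np.arange(self.n_lines) * self.line_pitch_um * 1e-3


@njit(cache=True)
def _accumulate_rf(out, xs_um, ys_um, amps, x_lines_um, axial_step_um,
                   sigma_lat_um, sigma_ax_um, wavelength_um):
    n_samples, n_lines = out.shape
    two_pi = 2.0 * np.pi
    for s in range(xs_um.shape[0]):
        x, y, a = xs_um[s], ys_um[s], amps[s]
        j_lo = int(np.floor((x - 4.0 * sigma_lat_um - x_lines_um[0])
                            / (x_lines_um[1] - x_lines_um[0])))
        j_hi = int(np.ceil((x + 4.0 * sigma_lat_um - x_lines_um[0])
                           / (x_lines_um[1] - x_lines_um[0])))
        i_lo = int(np.floor((y - 4.0 * sigma_ax_um) / axial_step_um))
        i_hi = int(np.ceil((y + 4.0 * sigma_ax_um) / axial_step_um))
        if j_hi < 0 or j_lo >= n_lines or i_hi < 0 or i_lo >= n_samples:
            continue
        j_lo, j_hi = max(j_lo, 0), min(j_hi, n_lines - 1)
        i_lo, i_hi = max(i_lo, 0), min(i_hi, n_samples - 1)
        for j in range(j_lo, j_hi + 1):
            dx = x_lines_um[j] - x
            wl = np.exp(-0.5 * dx * dx / (sigma_lat_um * sigma_lat_um))
            if wl < 1e-8:
                continue
            for i in range(i_lo, i_hi + 1):
                dy = i * axial_step_um - y
                out[i, j] += (a * wl
                              * np.exp(-0.5 * dy * dy / (sigma_ax_um * sigma_ax_um))
                              * np.cos(two_pi * dy / wavelength_um))


def simulate_rf(scatterers: ScattererField,
                transducer: TransducerSpec | None = None,
                field_of_view: FieldOfView | None = None,
                noise_snr_db: float | None = None,
                seed: int | None = None) -> RFFrame:
    """Simulate one RF frame of a scatterer field.

    Optional additive white Gaussian noise at ``noise_snr_db`` relative to
    the RMS of the simulated RF; deterministic for a fixed seed.
    Raises on an empty scatterer field.
    """
    if len(scatterers) == 0:
        raise ValueError("empty scatterer field")
    t = transducer or TransducerSpec()
    fov = field_of_view or FieldOfView()
    pitch = t.line_pitch_um
    n_lines = int(np.floor((fov.x_max_mm - fov.x_min_mm) * 1e3 / pitch)) + 1
    n_samples = int(np.floor(fov.depth_mm * 1e3 / t.axial_step_um)) + 1
    x_lines = fov.x_min_mm * 1e3 + np.arange(n_lines) * pitch

    out = np.zeros((n_samples, n_lines))
    _accumulate_rf(out,
                   np.ascontiguousarray(scatterers.positions[:, 0] * 1e3),
                   np.ascontiguousarray(scatterers.positions[:, 1] * 1e3),
                   np.ascontiguousarray(scatterers.amplitudes),
                   x_lines, t.axial_step_um,
                   t.lateral_beam_sigma_um, t.axial_pulse_sigma_um,
                   t.carrier_wavelength_um)
    if noise_snr_db is not None:
        rms = np.sqrt(np.mean(out ** 2))
        if rms > 0:
            rng = np.random.default_rng(seed)
            out = out + rng.normal(0.0, rms * 10 ** (-noise_snr_db / 20.0),
                                   size=out.shape)
    return RFFrame(out, t.axial_step_um, pitch, fov.x_min_mm, t)


def displace_scatterers(scatterers: ScattererField, displacement) -> ScattererField:
    """Move scatterers by a displacement field (mm), amplitudes unchanged.

    ``displacement`` is a callable mapping (N, 2) positions to (N, 2)
    displacement vectors, or a precomputed (N, 2) array.  Raises when the
    field is undefined (NaN) at any scatterer position.
    """
    if callable(displacement):
        disp = np.asarray(displacement(scatterers.positions), float)
    else:
        disp = np.asarray(displacement, float)
    if disp.shape != scatterers.positions.shape:
        raise ValueError("displacement shape does not match scatterer positions")
    if not np.all(np.isfinite(disp)):
        raise ValueError("displacement field undefined at some scatterer positions")
    return ScattererField(scatterers.positions + disp,
                          scatterers.amplitudes.copy(), seed=scatterers.seed)


def bmode(rf: RFFrame, dynamic_range_db: float = 50.0) -> np.ndarray:
    """Log-compressed envelope image, values in [0, 1].

    Envelope by analytic-signal magnitude per line, normalized to the frame
    maximum, compressed to the stated dynamic range.
    """
    env = np.abs(hilbert(rf.samples, axis=0))
    peak = env.max()
    if peak == 0:
        return np.zeros_like(env)
    db = 20.0 * np.log10(np.maximum(env / peak, 1e-12))
    return np.clip((db + dynamic_range_db) / dynamic_range_db, 0.0, 1.0)


def write_bmode_pgm(image: np.ndarray, path, max_value: int = 255) -> None:
    """Write a [0, 1] grayscale image as a plain-text portable graymap."""
    img = np.asarray(image, float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    quant = np.rint(img * max_value).astype(int)
    lines = ["P2", f"{img.shape[1]} {img.shape[0]}", str(max_value)]
    lines += [" ".join(map(str, row)) for row in quant]
    Path(path).write_text("\n".join(lines) + "\n")


def write_rf(frame: RFFrame, path_prefix) -> None:
    """Write a frame as <prefix>.npy plus a JSON metadata sidecar."""
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), frame.samples)
    meta = {"axial_step_um": frame.axial_step_um,
            "line_pitch_um": frame.line_pitch_um,
            "x0_mm": frame.x0_mm,
            "transducer": asdict(frame.transducer)}
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def read_rf(path_prefix) -> RFFrame:
    prefix = Path(path_prefix)
    samples = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return RFFrame(samples, meta["axial_step_um"], meta["line_pitch_um"],
                   meta["x0_mm"], TransducerSpec(**meta["transducer"]))
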