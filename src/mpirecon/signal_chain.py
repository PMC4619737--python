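"""Idealized 1D x-space signal chain.

Models the acquisition upstream of DC recovery: the field-free region
(FFR) sweeps the 1D image with a sinusoidal drive excursion superposed on
a slow linear shift; the received voltage is proportional to the native
image sampled at the instantaneous FFR position times the FFR velocity,
plus direct feedthrough at the drive fundamental.  Processing then
mirrors the scanner chain: harmonic band filtering (which also removes
feedthrough), velocity compensation, and gridding of each drive traversal
into one partial FOV with per-line DC filtered to zero.

Hardware filter-chain phase correction is a no-op here: no hardware phase
distortion is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry

__all__ = [
    "DriveTrajectory",
    "RawSignal",
    "synthesize_signal_1d",
    "remove_fundamental",
    "velocity_compensate",
    "grid_to_partial_fovs",
    "make_trajectory",
    "process_chain",
]


@dataclass
class DriveTrajectory:
    """Sinusoidal drive superposed on a linear shift, all in pixel units.

    drive_frequency : Hz.
    drive_amplitude : peak-to-peak FFR excursion in pixels — the pFOV
        width minus one (the FFR visits pixels 0..p-1 of each pFOV).
    shift_rate : mean slow-shift speed in pixels/s.
    sample_rate : Hz; must be at least 20x the drive frequency.
    duration : s.
    shift_mode : "linear" for a continuously ramping shift field (the
        sinusoid-on-a-ramp trajectory), or "stepped" for a shift field
        that steps once per full drive period, so the forward and return
        sweeps of a period retrace the same pFOV window (one station per
        period).  Station scanning makes the signal exactly periodic per
        station, which is what confines the hardware-filtered content to
        the pFOV DC; under a linear shift the two sweeps cover slightly
        different windows and the filter also nibbles real signal.
    """

    drive_frequency: float
    drive_amplitude: float
    shift_rate: float
    sample_rate: float
    duration: float
    shift_mode: str = "linear"

    def __post_init__(self) -> None:
        if self.sample_rate < 20.0 * self.drive_frequency:
            raise ValueError("sample_rate must be >= 20x drive_frequency")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.shift_mode not in ("linear", "stepped"):
            raise ValueError(f"unknown shift_mode {self.shift_mode!r}")

    def times(self) -> np.ndarray:
        n = int(round(self.sample_rate * self.duration))
        return np.arange(n) / self.sample_rate

    def positions(self, t: np.ndarray) -> np.ndarray:
        # one traversal (half drive period) sweeps 0 .. amplitude
        osc = 0.5 * self.drive_amplitude * (1.0 - np.cos(2.0 * np.pi * self.drive_frequency * t))
        if self.shift_mode == "stepped":
            per_period = self.shift_rate / self.drive_frequency
            base = per_period * np.floor(self.drive_frequency * t)
        else:
            base = self.shift_rate * t
        return base + osc

    def velocities(self, t: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * self.drive_frequency
        v = 0.5 * self.drive_amplitude * w * np.sin(w * t)
        if self.shift_mode == "linear":
            v = v + self.shift_rate
        # stepped: the shift jump happens at the turnaround, where the
        # velocity floor masks samples anyway
        return v

    @property
    def shift_per_traversal(self) -> float:
        """Slow-shift advance per drive half-period, in pixels."""
        return self.shift_rate / (2.0 * self.drive_frequency)


@dataclass
class RawSignal:
    samples: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    trajectory: DriveTrajectory

    def __post_init__(self) -> None:
        if not (len(self.samples) == len(self.positions) == len(self.velocities)):
            raise ValueError("samples, positions and velocities must align")


def synthesize_signal_1d(native: np.ndarray, traj: DriveTrajectory,
                         feedthrough_amp: float = 0.0) -> RawSignal:
    """Simulate the received signal for a 1D native image.

    samples(t) = native(x(t)) · ẋ(t) + feedthrough·cos(2π f₀ t), with the
    native image linearly interpolated at the FFR position.
    """
    native = np.asarray(native, dtype=float).reshape(-1)
    t = traj.times()
    x = traj.positions(t)
    if x.min() < -0.5 or x.max() > native.size - 0.5:
        raise ValueError(
            f"FFR trajectory [{x.min():.2f}, {x.max():.2f}] exits the image "
            f"extent [0, {native.size - 1}]"
        )
    v = traj.velocities(t)
    vals = np.interp(x, np.arange(native.size), native)
    samples = vals * v + feedthrough_amp * np.cos(2.0 * np.pi * traj.drive_frequency * t)
    return RawSignal(samples=samples, positions=x, velocities=v, trajectory=traj)


def remove_fundamental(signal: RawSignal, n_harmonics: int = 15) -> RawSignal:
    """Zero the DC-to-fundamental band and everything above the passband.

    The Fourier mask keeps |f| in (1.5 f₀, (n_harmonics + ½) f₀]; applied
    symmetrically, so the filter is zero-phase.  Filtering is done one
    drive period at a time: a period holds exactly one feedthrough cycle
    and an integer count of every harmonic, so the mask lands on exact
    FFT bins and the feedthrough tone is removed without leakage.  A
    trailing partial period is zero-padded to a full one and truncated
    back.
    """
    if n_harmonics < 2:
        raise ValueError("n_harmonics must be >= 2")
    f0 = signal.trajectory.drive_frequency
    fs = signal.trajectory.sample_rate
    if (n_harmonics + 0.5) * f0 > 0.5 * fs:
        raise ValueError("harmonic band exceeds the Nyquist frequency")
    block = int(round(fs / f0))  # samples per drive period
    x = signal.samples
    n = x.size
    n_blocks = -(-n // block)
    padded = np.zeros(n_blocks * block)
    padded[:n] = x
    spec = np.fft.rfft(padded.reshape(n_blocks, block), axis=1)
    freqs = np.fft.rfftfreq(block, d=1.0 / fs)
    mask = (freqs > 1.5 * f0) & (freqs <= (n_harmonics + 0.5) * f0)
    out = np.fft.irfft(spec * mask, n=block, axis=1).reshape(-1)[:n]
    return RawSignal(samples=out, positions=signal.positions,
                     velocities=signal.velocities, trajectory=signal.trajectory)


def velocity_compensate(signal: RawSignal, velocity_floor: float = 0.05
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Normalize samples by the instantaneous FFR speed.

    Samples where |ẋ| < velocity_floor · max|ẋ| (the drive turnarounds)
    are masked invalid.  Returns (values, valid mask).
    """
    if velocity_floor <= 0:
        raise ValueError("velocity_floor must be positive")
    v = signal.velocities
    vmax = np.abs(v).max()
    mask = np.abs(v) >= velocity_floor * vmax
    if not mask.any():
        raise ValueError("degenerate trajectory: no samples above the velocity floor")
    values = np.zeros_like(signal.samples)
    values[mask] = signal.samples[mask] / v[mask]
    return values, mask


def _traversal_index(positions: np.ndarray) -> np.ndarray:
    """Label each sample with its drive-traversal number.

    A traversal boundary is a sign change of the position increment (the
    FFR turning around).
    """
    dx = np.diff(positions)
    sign = np.sign(dx)
    # carry the previous sign through zero increments
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.concatenate([[False], sign[1:] != sign[:-1]])
    idx = np.concatenate([[0], np.cumsum(flips)])
    return idx


def grid_to_partial_fovs(values: np.ndarray, mask: np.ndarray,
                         positions: np.ndarray, geometry: ScanGeometry,
                         return_counts: bool = False):
    """Bin velocity-compensated samples into per-traversal pFOV images.

    Each drive traversal becomes one pFOV; valid samples are binned to the
    nearest pixel and bin-averaged (averaging redundant samples improves
    SNR).  Pixels left empty by turnaround masking or the alternating
    sweep direction are flagged and filled by linear interpolation within
    the line; per-line means are then removed, matching the DC loss of
    the hardware chain.  Raises if any pFOV receives no valid samples.

    Returns the pFOV stack; with ``return_counts=True`` also returns the
    per-pixel sample counts (0 marks a filled, not measured, pixel).
    """
    if len(geometry.image_shape) != 1:
        raise ValueError("gridding implemented for 1D geometries")
    values = np.asarray(values, dtype=float).reshape(-1)
    mask = np.asarray(mask, dtype=bool).reshape(-1)
    positions = np.asarray(positions, dtype=float).reshape(-1)
    N, p, d = geometry.n_pfov, geometry.pfov_width, geometry.shift

    trav = _traversal_index(positions)
    n_trav = int(trav.max()) + 1
    if n_trav < N:
        raise ValueError(f"only {n_trav} traversals for {N} pFOVs")
    # several traversals may dwell on one station (e.g. one full period,
    # or repeated averaging passes); assign them evenly in order
    per_pfov = max(int(round(n_trav / N)), 1)
    pfov_of = np.minimum(trav // per_pfov, N - 1)
    sums = np.zeros((N, p))
    counts = np.zeros((N, p))
    pix = np.round(positions).astype(int)
    for k in range(N):
        sel = (pfov_of == k) & mask
        local = pix[sel] - k * d
        ok = (local >= 0) & (local < p)
        np.add.at(sums[k], local[ok], values[sel][ok])
        np.add.at(counts[k], local[ok], 1.0)
        if counts[k].sum() == 0:
            raise ValueError(f"pFOV {k} received no valid samples")
    grid = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
    for k in range(N):
        filled = counts[k] > 0
        if not filled.all():
            grid[k] = np.interp(np.arange(p), np.flatnonzero(filled),
                                grid[k][filled])
    grid -= grid.mean(axis=1, keepdims=True)
    stack = grid.reshape(geometry.stack_shape)
    if return_counts:
        return stack, counts.reshape(geometry.stack_shape)
    return stack


def make_trajectory(geometry: ScanGeometry, drive_frequency: float = 25.0,
                    samples_per_traversal: int = 400,
                    shift_mode: str = "stepped") -> DriveTrajectory:
    """Build a drive trajectory consistent with a 1D scan geometry.

    With the default stepped shift, one full drive period dwells on each
    pFOV station: the excursion spans the pFOV width, the station advances
    one shift per period, and both sweeps of period k cover exactly the
    window of pFOV k.  With a linear shift the excursion is narrowed so
    the trajectory stays inside the image; each half-period is then one
    pFOV and backward traversals undercover their windows.
    """
    if len(geometry.image_shape) != 1:
        raise ValueError("make_trajectory expects a 1D geometry")
    p, d, N = geometry.pfov_width, geometry.shift, geometry.n_pfov
    amplitude = float(p - 1) if shift_mode == "stepped" else float(p - 1 - d)
    if amplitude <= 0:
        raise ValueError("pfov_width too small for the requested shift_mode")
    f = float(drive_frequency)
    sample_rate = samples_per_traversal * 2.0 * f
    if shift_mode == "stepped":
        shift_rate = d * f          # one shift per full period
        duration = N / f            # N stations
    else:
        shift_rate = d * 2.0 * f    # one shift per half-period
        duration = N / (2.0 * f)
    return DriveTrajectory(drive_frequency=f, drive_amplitude=amplitude,
                           shift_rate=shift_rate, sample_rate=sample_rate,
                           duration=duration, shift_mode=shift_mode)


def process_chain(native: np.ndarray, traj: DriveTrajectory,
                  geometry: ScanGeometry, feedthrough_amp: float = 0.0,
                  n_harmonics: int = 15, velocity_floor: float = 0.05
                  ) -> np.ndarray:
    """Full chain: synthesize → filter → velocity-compensate → grid."""
    raw = synthesize_signal_1d(native, traj, feedthrough_amp)
    filt = remove_fundamental(raw, n_harmonics)
    values, mask = velocity_compensate(filt, velocity_floor)
    return grid_to_partial_fovs(values, mask, raw.positions, geometry)
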