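"""Signal conditioning: band-pass filter, decimate to 25 Hz, integrate.

The conditioning chain is: zero-phase 4th-order Butterworth band-pass
(0.1-12 Hz) on the raw tri-axial acceleration, decimation to 25 Hz, then
velocity by cumulative trapezoidal integration followed by the same
band-pass (which removes integration drift).  The 0.1 Hz high-pass edge
removes gravity; the 12 Hz low-pass edge sits below the 12.5 Hz Nyquist of
the 25 Hz target rate, so decimation needs no extra anti-alias filter.

Filtering is forward-backward (``sosfiltfilt``), so the effective amplitude
response is the squared magnitude of the designed filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate as _integrate
from scipy import signal as _signal

TARGET_FS = 25.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification."""

    low_hz: float = 0.1
    high_hz: float = 12.0
    order: int = 4

    def sos(self, fs: float):
        if not 0 < self.low_hz < self.high_hz < fs / 2:
            raise ValueError(
                f"band [{self.low_hz}, {self.high_hz}] Hz invalid for fs={fs} Hz"
            )
        return _signal.butter(
            self.order, [self.low_hz, self.high_hz], btype="band", fs=fs, output="sos"
        )


@dataclass
class KinematicsPair:
    """Filtered acceleration and band-passed velocity at 25 Hz."""

    acc: np.ndarray  # (n, 3) m/s^2
    vel: np.ndarray  # (n, 3) m/s
    fs: float = TARGET_FS

    def __post_init__(self) -> None:
        if self.acc.shape != self.vel.shape:
            raise ValueError("acc and vel must have identical shape")


def _min_length(spec: FilterSpec) -> int:
    # sosfiltfilt needs > 3 * (number of taps) samples per section chain
    sos = np.atleast_2d(_signal.butter(spec.order, [0.1, 0.4], btype="band", output="sos"))
    return 3 * (sos.shape[0] * 2 + 1) + 1


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase band-pass along axis 0; output length equals input length."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    min_n = _min_length(spec)
    if n < min_n:
        raise ValueError(
            f"signal too short for zero-phase filtering: {n} < minimum {min_n} samples"
        )
    return _signal.sosfiltfilt(spec.sos(fs), x, axis=0)


def downsample(x: np.ndarray, fs_in: float, fs_out: float = TARGET_FS) -> np.ndarray:
    """Plain decimation: keep every (fs_in/fs_out)-th sample from index 0.

    Assumes the signal is already low-passed below fs_out/2 (the band-pass
    runs first in this pipeline).  Output length is ceil(n / factor).
    """
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"fs_in={fs_in} is not an integer multiple of fs_out={fs_out}; "
            "resample the signal first"
        )
    return np.asarray(x)[:: int(round(factor))]


def integrate_velocity(
    acc: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Velocity per axis: trapezoidal integration then the same band-pass.

    Integration starts from zero velocity; the re-applied band-pass removes
    the low-frequency drift an accelerometer offset would otherwise
    integrate into a ramp.
    """
    acc = np.asarray(acc, dtype=float)
    vel = _integrate.cumulative_trapezoid(acc, dx=1.0 / fs, axis=0, initial=0.0)
    return bandpass(vel, fs, spec)


def preprocess(
    acc_raw: np.ndarray, fs_raw: float, spec: FilterSpec = FilterSpec()
) -> KinematicsPair:
    """Full conditioning chain: band-pass, decimate to 25 Hz, velocity."""
    filt = bandpass(acc_raw, fs_raw, spec)
    acc25 = downsample(filt, fs_raw, TARGET_FS)
    vel25 = integrate_velocity(acc25, TARGET_FS, spec)
    return KinematicsPair(acc=acc25, vel=vel25)


def downsample_labels(labels: np.ndarray, fs_in: float, fs_out: float = TARGET_FS) -> np.ndarray:
    """Decimate a per-sample label track in lockstep with :func:`downsample`."""
    return downsample(labels, fs_in, fs_out)
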