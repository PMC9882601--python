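"""Patient head/eye motion simulation.

Generates continuous 3D globe-position trajectories on the OCT axes
(temporal-nasal, superior-inferior, anterior-posterior) for two patient
profiles:

``healthy``
    band-limited drift (Ornstein-Uhlenbeck) plus a slow postural sway
    sinusoid, calibrated so the median per-axis excursion over a 4.14 s
    three-volume acquisition window is (1.5, 0.7, 2.1) mm.

``tremor``
    the healthy process plus a 4-6 Hz rest-tremor oscillation with
    randomised frequency, phase and amplitude, calibrated to a median
    excursion of (2.5, 1.0, 3.4) mm over the same window.

Calibration constants are derived once per (duration-window, dt) by internal
Monte-Carlo on the unit-amplitude process with a fixed internal seed, so the
mapping from clinical target ranges to process amplitudes is reproducible and
independent of the caller's seed.

A slow, independent 2D gaze-drift walk is carried alongside the globe
position; it models fixation wander, which the alignment system does not
track and which therefore shifts the imaged field of view.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "MotionTrajectory",
    "simulate_motion",
    "motion_range",
    "resample",
    "HEALTHY_RANGE_MM",
    "TREMOR_RANGE_MM",
]

#: clinical calibration targets: median per-axis (max - min) excursion in mm
#: over the reference 4.14 s acquisition window
HEALTHY_RANGE_MM = (1.5, 0.7, 2.1)
TREMOR_RANGE_MM = (2.5, 1.0, 3.4)

REFERENCE_WINDOW_S = 4.14
TREMOR_BAND_HZ = (4.0, 6.0)

_OU_THETA = 0.7          # 1/s, drift mean-reversion rate
_SWAY_REL_AMP = 0.35     # sway amplitude relative to OU stationary sd
_SWAY_BAND_HZ = (0.15, 0.35)
_GAZE_SD_MM = 0.12       # stationary sd of the gaze-drift walk
_CAL_SEED = 20230109     # internal seed for calibration Monte-Carlo only
_CAL_REPS = 64


@dataclass(frozen=True)
class MotionTrajectory:
    """Time-indexed globe position and gaze drift.

    ``times`` is a uniform grid (s); ``globe_position`` is (N, 3) mm on
    (T-N, S-I, A-P) axes; ``gaze_offset`` is (N, 2) mm of lateral fixation
    drift.
    """

    times: np.ndarray
    globe_position: np.ndarray
    gaze_offset: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("times must be a non-empty 1D array")
        if len(t) > 1:
            dts = np.diff(t)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6):
                raise ValueError("times must be uniformly spaced")
        if not (np.all(np.isfinite(self.globe_position))
                and np.all(np.isfinite(self.gaze_offset))):
            raise ValueError("trajectory contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.times,
                "x_mm": self.globe_position[:, 0],
                "y_mm": self.globe_position[:, 1],
                "z_mm": self.globe_position[:, 2],
                "gx_mm": self.gaze_offset[:, 0],
                "gy_mm": self.gaze_offset[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MotionTrajectory":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            times=df["t_s"].to_numpy(),
            globe_position=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            gaze_offset=df[["gx_mm", "gy_mm"]].to_numpy(),
        )


def _ou_path(rng: np.random.Generator, n: int, dt: float, theta: float) -> np.ndarray:
    """Unit-stationary-sd Ornstein-Uhlenbeck path starting at equilibrium."""
    from scipy.signal import lfilter

    a = np.exp(-theta * dt)
    b = np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    drive = b * eps
    drive[0] = eps[0]  # x[0] ~ stationary N(0, 1)
    # x[i] = a*x[i-1] + drive[i] is a first-order IIR filter
    return lfilter([1.0], [1.0, -a], drive)


def _unit_axis_process(rng: np.random.Generator, t: np.ndarray, dt: float) -> np.ndarray:
    """OU drift + slow sway, unit drift sd; the calibrated building block."""
    x = _ou_path(rng, len(t), dt, _OU_THETA)
    f = rng.uniform(*_SWAY_BAND_HZ)
    phase = rng.uniform(0, 2 * np.pi)
    return x + _SWAY_REL_AMP * np.sin(2 * np.pi * f * t + phase)


def _tremor_wave(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Unit-amplitude tremor oscillation with randomised frequency/phase and
    a +/-20% amplitude jitter."""
    f = rng.uniform(*TREMOR_BAND_HZ)
    phase = rng.uniform(0, 2 * np.pi)
    jitter = rng.uniform(0.8, 1.2)
    return jitter * np.sin(2 * np.pi * f * t + phase)


@lru_cache(maxsize=8)
def _healthy_scales(dt: float) -> tuple[float, ...]:
    """Per-axis amplitude so median unit-process range hits the targets."""
    n = int(round(REFERENCE_WINDOW_S / dt)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(_CAL_SEED)
    ranges = [np.ptp(_unit_axis_process(rng, t, dt)) for _ in range(_CAL_REPS)]
    unit_median = float(np.median(ranges))
    return tuple(r / unit_median for r in HEALTHY_RANGE_MM)


@lru_cache(maxsize=8)
def _tremor_amplitudes(dt: float) -> tuple[float, ...]:
    """Per-axis tremor amplitude (mm) found by bisection so the combined
    process median range hits the tremor targets."""
    n = int(round(REFERENCE_WINDOW_S / dt)) + 1
    t = np.arange(n) * dt
    scales = _healthy_scales(dt)

    def median_range(axis: int, amp: float) -> float:
        rng = np.random.default_rng(_CAL_SEED + 1 + axis)
        r = []
        for _ in range(_CAL_REPS):
            base = scales[axis] * _unit_axis_process(rng, t, dt)
            r.append(np.ptp(base + amp * _tremor_wave(rng, t)))
        return float(np.median(r))

    amps = []
    for axis, target in enumerate(TREMOR_RANGE_MM):
        lo, hi = 0.0, target  # range contribution of a sinusoid is <= 2*amp
        for _ in range(24):
            mid = 0.5 * (lo + hi)
            if median_range(axis, mid) < target:
                lo = mid
            else:
                hi = mid
        amps.append(0.5 * (lo + hi))
    return tuple(amps)


def simulate_motion(
    profile: str,
    duration: float,
    dt: float = 1e-3,
    seed: int = 0,
    amplitude_scale: float = 1.0,
) -> MotionTrajectory:
    """Simulate a globe-motion trajectory.

    Parameters
    ----------
    profile : {"healthy", "tremor"}
    duration : seconds (> 0)
    dt : grid step, seconds (> 0; default 1 ms so both the 120 FPS pupil
        tracker and the 100 kHz scanner can be driven by interpolation)
    seed : reproducibility seed; identical seeds give identical trajectories
    amplitude_scale : global multiplier on all motion amplitudes (0 gives a
        perfectly still patient)
    """
    if profile not in ("healthy", "tremor"):
        raise ValueError(f"unknown motion profile {profile!r}")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    scales = _healthy_scales(dt)
    pos = np.column_stack(
        [scales[ax] * _unit_axis_process(rng, t, dt) for ax in range(3)]
    )
    if profile == "tremor":
        amps = _tremor_amplitudes(dt)
        pos += np.column_stack(
            [amps[ax] * _tremor_wave(rng, t) for ax in range(3)]
        )
    gaze = np.column_stack(
        [_GAZE_SD_MM * _ou_path(rng, n, dt, 0.3) for _ in range(2)]
    )
    pos *= amplitude_scale
    gaze *= amplitude_scale
    pos -= pos[0]  # session origin at the first sample
    gaze -= gaze[0]
    return MotionTrajectory(times=t, globe_position=pos, gaze_offset=gaze)


def motion_range(traj: MotionTrajectory) -> np.ndarray:
    """Per-axis (max - min) excursion of the globe position, mm."""
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    return np.ptp(traj.globe_position, axis=0)


def resample(traj: MotionTrajectory, query_times) -> np.ndarray:
    """Linear interpolation of globe position at ``query_times`` (s)."""
    q = np.atleast_1d(np.asarray(query_times, float))
    t0, t1 = traj.times[0], traj.times[-1]
    eps = 1e-9 * max(1.0, abs(t1))
    if np.any(q < t0 - eps) or np.any(q > t1 + eps):
        raise ValueError("query time outside trajectory support")
    return np.column_stack(
        [np.interp(q, traj.times, traj.globe_position[:, k]) for k in range(3)]
    )


def resample_gaze(traj: MotionTrajectory, query_times) -> np.ndarray:
    q = np.atleast_1d(np.asarray(query_times, float))
    return np.column_stack(
        [np.interp(q, traj.times, traj.gaze_offset[:, k]) for k in range(2)]
    )
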