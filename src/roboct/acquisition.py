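"""Motion-distorted OCT volume acquisition from a retina phantom.

The scanner raster-samples the phantom A-scan by A-scan.  At each A-scan
timestamp the uncompensated residual motion (from a :class:`CompensationLog`)
displaces the beam laterally and shifts the tissue axially; untracked gaze
drift additionally shifts the whole field of view.  Depth profiles are the
phantom reflectivity sampled on the pixel grid, multiplied by unit-mean
exponential speckle and summed with a Gaussian noise floor.

Default scan patterns: a 30 x 30 degree volume of 900 A-scans x 125 B-scans
at a 100 kHz A-scan rate (1.125 s active; flyback chosen so three sequential
volumes span 4.14 s) and a 30 degree repeated B-scan of 2000 A-scans x 100
frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .motion import simulate_motion
from .phantom import RetinalPhantom
from .tracking import CompensationLog, ControllerConfig, run_alignment

__all__ = [
    "ScanPattern",
    "OCTVolume",
    "NoiseConfig",
    "make_scan_pattern",
    "angle_to_retina_mm",
    "acquire",
    "acquire_triplicate",
    "write_volume",
    "read_volume",
]

MM_PER_DEGREE = 0.288          # retinal arc length per degree, emmetropic eye
N_G_RETINA = 1.37              # group refractive index of retina
DEFAULT_A_SCAN_RATE = 100_000.0
DEFAULT_DEPTH_PX = 1024
DEFAULT_DEPTH_RANGE_AIR_MM = 3.8
#: flyback such that one volume cycle is 4.14/3 s: 1.125*(1+f) = 1.38
DEFAULT_FLYBACK_FRACTION = (4.14 / 3 - 1.125) / 1.125


def angle_to_retina_mm(angle_deg, mm_per_degree: float = MM_PER_DEGREE):
    """Small-angle scan-angle to retinal-position conversion (mm)."""
    return np.asarray(angle_deg, float) * mm_per_degree


@dataclass(frozen=True)
class ScanPattern:
    """Raster scan timing and angles; per-sample arrays are flattened in
    acquisition order (fast axis innermost)."""

    kind: str
    n_ascans_per_bscan: int
    n_bscans: int
    fov_degrees: tuple[float, float]
    a_scan_rate: float = DEFAULT_A_SCAN_RATE
    flyback_fraction: float = DEFAULT_FLYBACK_FRACTION

    @property
    def n_samples(self) -> int:
        return self.n_ascans_per_bscan * self.n_bscans

    @property
    def active_duration(self) -> float:
        return self.n_samples / self.a_scan_rate

    @property
    def duration(self) -> float:
        """Full cycle including per-B-scan flyback gaps."""
        per_bscan = self.n_ascans_per_bscan * (1.0 + self.flyback_fraction)
        return per_bscan * self.n_bscans / self.a_scan_rate

    def sample_times(self) -> np.ndarray:
        """(n_ascans, n_bscans) timestamps in seconds from pattern start."""
        n_a, n_b = self.n_ascans_per_bscan, self.n_bscans
        n_fly = n_a * self.flyback_fraction
        i = np.arange(n_a)[:, None]
        b = np.arange(n_b)[None, :]
        return (b * (n_a + n_fly) + i) / self.a_scan_rate

    def angles(self) -> tuple[np.ndarray, np.ndarray]:
        """(fast, slow) scan angles in degrees, each (n_ascans, n_bscans)."""
        n_a, n_b = self.n_ascans_per_bscan, self.n_bscans
        fov_f, fov_s = self.fov_degrees
        fast = np.linspace(-fov_f / 2, fov_f / 2, n_a)[:, None]
        if n_b > 1 and fov_s > 0:
            slow = np.linspace(-fov_s / 2, fov_s / 2, n_b)[None, :]
        else:
            slow = np.zeros((1, n_b))
        return (np.broadcast_to(fast, (n_a, n_b)).copy(),
                np.broadcast_to(slow, (n_a, n_b)).copy())


def make_scan_pattern(kind: str = "volume", **overrides) -> ScanPattern:
    """Build a scan pattern: ``volume`` (900 x 125, 30 x 30 deg) or
    ``repeated_bscan`` (2000 x 100, 30 deg width)."""
    if kind == "volume":
        defaults = dict(n_ascans_per_bscan=900, n_bscans=125,
                        fov_degrees=(30.0, 30.0))
    elif kind == "repeated_bscan":
        defaults = dict(n_ascans_per_bscan=2000, n_bscans=100,
                        fov_degrees=(30.0, 0.0))
    else:
        raise ValueError(f"unknown scan pattern kind {kind!r}")
    defaults.update(overrides)
    p = ScanPattern(kind=kind, **defaults)
    if p.n_ascans_per_bscan <= 0 or p.n_bscans <= 0:
        raise ValueError("scan counts must be positive")
    return p


@dataclass(frozen=True)
class NoiseConfig:
    speckle: bool = True
    noise_floor_sd: float = 0.01


@dataclass
class OCTVolume:
    """Acquired intensity volume with its own simulation ground truth.

    ``intensity`` is (n_depth, n_ascans, n_bscans), linear arbitrary units.
    ``residual_trace`` is the per-A-scan 3-vector (mm) of lateral/axial
    displacement that was actually applied during rendering — the volume
    carries its own motion ground truth.
    """

    intensity: np.ndarray
    depth_pixel_pitch_air_um: float
    fov_degrees: tuple[float, float]
    timestamps: np.ndarray               # (n_ascans, n_bscans), s
    laterality: str = "OD"
    residual_trace: np.ndarray | None = None   # (n_ascans, n_bscans, 3), mm
    z_reference_px: float = 150.0
    mm_per_degree: float = MM_PER_DEGREE
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.depth_pixel_pitch_air_um <= 0:
            raise ValueError("depth pixel pitch must be positive")
        flat = self.timestamps.T.ravel()
        if np.any(np.diff(flat) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[0]

    @property
    def shape(self):
        return self.intensity.shape

    @property
    def depth_pixel_pitch_tissue_um(self) -> float:
        return self.depth_pixel_pitch_air_um / N_G_RETINA

    def lateral_pitch_mm(self) -> tuple[float, float]:
        """(mm per A-scan step, mm per B-scan step)."""
        n_d, n_a, n_b = self.intensity.shape
        fov_f, fov_s = self.fov_degrees
        da = fov_f * self.mm_per_degree / max(n_a - 1, 1)
        db = fov_s * self.mm_per_degree / max(n_b - 1, 1)
        return da, db


def _render_chunk(phantom, x_mm, y_mm, resid_z_mm, n_depth, pitch_air, z_ref_px):
    """Noiseless reflectivity for a chunk of A-scans: (n_depth, chunk)."""
    px = np.arange(n_depth, dtype=float)[:, None]
    z_tissue = ((px - z_ref_px) * pitch_air - resid_z_mm[None, :] * 1000.0) / N_G_RETINA
    return phantom.reflectivity(x_mm[None, :], y_mm[None, :], z_tissue)


def acquire(
    phantom: RetinalPhantom,
    compensation_log: CompensationLog | None,
    pattern: ScanPattern,
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    n_depth: int = DEFAULT_DEPTH_PX,
    depth_range_air_mm: float = DEFAULT_DEPTH_RANGE_AIR_MM,
    laterality: str = "OD",
    time_offset: float | None = None,
    chunk: int = 4096,
) -> OCTVolume:
    """Sample the phantom along ``pattern`` with residual motion applied.

    ``compensation_log=None`` renders a perfectly still eye.  With a log, the
    pattern is placed ``time_offset`` seconds into the log (default: so the
    scan occupies the *end* of the log, after the alignment settles), and the
    per-A-scan residual error plus untracked gaze drift displace each beam.
    """
    pitch_air = depth_range_air_mm * 1000.0 / n_depth
    times = pattern.sample_times()
    n_a, n_b = times.shape
    flat_t = times.T.ravel()  # acquisition order

    if compensation_log is not None:
        log_span = compensation_log.times[-1] - compensation_log.times[0]
        if pattern.duration > log_span + 1e-9:
            raise ValueError("compensation log shorter than the scan pattern")
        if time_offset is None:
            time_offset = log_span - pattern.duration
        tq = compensation_log.times[0] + time_offset + flat_t
        resid = np.column_stack([
            np.interp(tq, compensation_log.times, compensation_log.residual_error[:, k])
            for k in range(3)
        ])
        gaze = np.column_stack([
            np.interp(tq, compensation_log.times, compensation_log.gaze_offset[:, k])
            for k in range(2)
        ])
        disp = np.column_stack([
            resid[:, 0] + gaze[:, 0], resid[:, 1] + gaze[:, 1], resid[:, 2]
        ])
    else:
        disp = np.zeros((n_a * n_b, 3))

    fast, slow = pattern.angles()
    sign = -1.0 if laterality == "OS" else 1.0   # mirror x for left eyes
    x0 = sign * angle_to_retina_mm(fast.T.ravel(), MM_PER_DEGREE)
    y0 = angle_to_retina_mm(slow.T.ravel(), MM_PER_DEGREE)
    x = np.clip(x0 + disp[:, 0], -phantom.lateral_extent / 2, phantom.lateral_extent / 2)
    y = np.clip(y0 + disp[:, 1], -phantom.lateral_extent / 2, phantom.lateral_extent / 2)

    rng = np.random.default_rng(seed)
    z_ref = 150.0 * (n_depth / DEFAULT_DEPTH_PX)
    out = np.empty((n_depth, n_a * n_b), dtype=np.float32)
    for s in range(0, n_a * n_b, chunk):
        e = min(s + chunk, n_a * n_b)
        block = _render_chunk(phantom, x[s:e], y[s:e], disp[s:e, 2],
                              n_depth, pitch_air, z_ref)
        if noise.speckle:
            block = block * rng.exponential(1.0, block.shape)
        if noise.noise_floor_sd > 0:
            block = block + noise.noise_floor_sd * rng.standard_normal(block.shape)
        out[:, s:e] = np.clip(block, 0.0, None)

    intensity = out.reshape(n_depth, n_b, n_a).transpose(0, 2, 1)
    trace = disp.reshape(n_b, n_a, 3).transpose(1, 0, 2)
    return OCTVolume(
        intensity=intensity,
        depth_pixel_pitch_air_um=pitch_air,
        fov_degrees=pattern.fov_degrees,
        timestamps=times,
        laterality=laterality,
        residual_trace=trace,
        z_reference_px=z_ref,
        meta={
            "pattern_kind": pattern.kind,
            "a_scan_rate": pattern.a_scan_rate,
            "seed": seed,
            "compensated": compensation_log is not None,
        },
    )


def acquire_triplicate(
    phantom: RetinalPhantom,
    motion_profile: str,
    gains: ControllerConfig | None,
    pattern: ScanPattern,
    seeds,
    noise: NoiseConfig = NoiseConfig(),
    settle_s: float = 1.0,
    mode: str = "full",
    **acquire_kwargs,
) -> list[OCTVolume]:
    """Three independent captures, each preceded by a fresh engage/align run
    (fresh motion realisation and controller settling), emulating the
    robot-disengage protocol between repeats."""
    seeds = list(seeds)
    if len(seeds) != 3 or len(set(seeds)) != 3:
        raise ValueError("need 3 distinct seeds")
    vols = []
    for s in seeds:
        traj = simulate_motion(motion_profile, settle_s + pattern.duration,
                               dt=1e-3, seed=s)
        log = run_alignment(traj, gains, seed=s, mode=mode)
        vols.append(
            acquire(phantom, log, pattern, noise=noise, seed=s, **acquire_kwargs)
        )
    return vols


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF (one page per B-scan) + JSON sidecar, or .npz

def write_volume(volume: OCTVolume, path_base) -> tuple[Path, Path]:
    """Write ``<base>.tiff`` (pages = B-scans) and ``<base>.json`` sidecar."""
    import tifffile

    base = Path(path_base)
    tiff_path = base.with_suffix(".tiff")
    json_path = base.with_suffix(".json")
    pages = np.moveaxis(volume.intensity, 2, 0)  # (n_bscans, depth, n_ascans)
    tifffile.imwrite(tiff_path, pages.astype(np.float32), photometric="minisblack")
    sidecar = {
        "depth_pixel_pitch_air_um": volume.depth_pixel_pitch_air_um,
        "fov_degrees": list(volume.fov_degrees),
        "laterality": volume.laterality,
        "z_reference_px": volume.z_reference_px,
        "mm_per_degree": volume.mm_per_degree,
        "timestamps": volume.timestamps.tolist(),
        "residual_trace": (
            volume.residual_trace.tolist() if volume.residual_trace is not None else None
        ),
        "meta": volume.meta,
    }
    json_path.write_text(json.dumps(sidecar))
    return tiff_path, json_path


def read_volume(path_base) -> OCTVolume:
    import tifffile

    base = Path(path_base)
    pages = tifffile.imread(base.with_suffix(".tiff"))
    side = json.loads(base.with_suffix(".json").read_text())
    trace = side["residual_trace"]
    return OCTVolume(
        intensity=np.moveaxis(np.asarray(pages), 0, 2),
        depth_pixel_pitch_air_um=side["depth_pixel_pitch_air_um"],
        fov_degrees=tuple(side["fov_degrees"]),
        timestamps=np.asarray(side["timestamps"]),
        laterality=side["laterality"],
        residual_trace=np.asarray(trace) if trace is not None else None,
        z_reference_px=side["z_reference_px"],
        mm_per_degree=side["mm_per_degree"],
        meta=side["meta"],
    )


def save_npz(volume: OCTVolume, path) -> None:
    np.savez_compressed(
        path,
        intensity=volume.intensity,
        timestamps=volume.timestamps,
        residual_trace=(volume.residual_trace if volume.residual_trace is not None
                        else np.zeros(0)),
        header=json.dumps({
            "depth_pixel_pitch_air_um": volume.depth_pixel_pitch_air_um,
            "fov_degrees": list(volume.fov_degrees),
            "laterality": volume.laterality,
            "z_reference_px": volume.z_reference_px,
            "mm_per_degree": volume.mm_per_degree,
            "meta": volume.meta,
        }),
    )


def load_npz(path) -> OCTVolume:
    d = np.load(path, allow_pickle=False)
    header = json.loads(str(d["header"]))
    trace = d["residual_trace"]
    return OCTVolume(
        intensity=d["intensity"],
        timestamps=d["timestamps"],
        residual_trace=None if trace.size == 0 else trace,
        depth_pixel_pitch_air_um=header["depth_pixel_pitch_air_um"],
        fov_degrees=tuple(header["fov_degrees"]),
        laterality=header["laterality"],
        z_reference_px=header["z_reference_px"],
        mm_per_degree=header["mm_per_degree"],
        meta=header["meta"],
    )
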