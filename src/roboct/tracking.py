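"""Two-tiered autonomous alignment: open-loop face tracking driving a
rate-limited robot, and closed-loop pupil tracking driving fast opto-mechanic
actuators.

Tier 1 (open loop): a face tracker supplies noisy 3D globe-position
estimates at ~14 FPS; the robot end effector is commanded toward them with a
maximum translation speed and a command latency, without feedback from the
imaging path.

Tier 2 (closed loop): three calibrated pupil cameras around the imaging axis
view the eye at 120 FPS.  Each image is segmented by binary morphology to a
pupil centroid; centroids from >= 2 cameras are triangulated to the residual
eye position relative to the scanner.  A proportional loop sends the fast
lateral component to a 2D scan mirror and the fast axial component to a
voice-coil reference-arm motor (VCM), while a low-passed copy of the fast
actuator offsets is offloaded to the robot so the limited-range actuators
re-center.

A small state machine gates acquisition: imaging is allowed only while the
pupil is locked (>= 2 centroids for N consecutive frames).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .motion import MotionTrajectory, resample, resample_gaze

__all__ = [
    "CameraModel",
    "FaceTrackEstimate",
    "PupilObservation",
    "ActuatorState",
    "AlignmentState",
    "ControllerConfig",
    "CompensationLog",
    "default_pupil_cameras",
    "observe_face",
    "render_pupil_image",
    "segment_pupil_centroid",
    "triangulate",
    "step_controller",
    "update_alignment_state",
    "run_alignment",
]

PUPIL_FPS = 120.0
FACE_FPS = 14.0
WORKING_DISTANCE_MM = 86.0


# ---------------------------------------------------------------------------
# cameras

@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera. ``rotation`` maps world vectors into the camera frame
    (camera +z is the viewing direction); pixel coordinates are (col, row)
    with the principal point at the image centre."""

    position: tuple[float, float, float]
    rotation: np.ndarray            # (3, 3), world -> camera
    focal_length_mm: float = 12.0
    pixel_pitch_mm: float = 0.01
    resolution: tuple[int, int] = (200, 200)   # (width, height)

    @property
    def principal_point(self) -> np.ndarray:
        w, h = self.resolution
        return np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    def project(self, point_mm) -> tuple[np.ndarray, float]:
        """World point -> (pixel (col,row), camera depth mm)."""
        p = np.asarray(point_mm, float) - np.asarray(self.position)
        pc = self.rotation @ p
        depth = pc[2]
        if depth <= 1e-9:
            return np.array([np.nan, np.nan]), depth
        uv = self.focal_length_mm * pc[:2] / depth / self.pixel_pitch_mm
        return self.principal_point + uv, depth

    def back_project(self, pixel) -> tuple[np.ndarray, np.ndarray]:
        """Pixel -> (ray origin, unit ray direction) in world frame."""
        uv = (np.asarray(pixel, float) - self.principal_point) * self.pixel_pitch_mm
        d_cam = np.array([uv[0], uv[1], self.focal_length_mm])
        d = self.rotation.T @ d_cam
        return np.asarray(self.position, float), d / np.linalg.norm(d)

    def in_frame(self, pixel, margin: float = 0.0) -> bool:
        w, h = self.resolution
        return bool(
            np.all(np.isfinite(pixel))
            and -margin <= pixel[0] <= w - 1 + margin
            and -margin <= pixel[1] <= h - 1 + margin
        )


def _look_at(position, target) -> np.ndarray:
    """Rotation (world->camera) for a camera at ``position`` viewing ``target``."""
    z = np.asarray(target, float) - np.asarray(position, float)
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(up, z)) > 0.99:
        up = np.array([1.0, 0.0, 0.0])
    x = np.cross(up, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z])


def default_pupil_cameras(
    working_distance_mm: float = WORKING_DISTANCE_MM,
    ring_radius_mm: float = 30.0,
    n_cameras: int = 3,
) -> list[CameraModel]:
    """Pupil-camera rig: ``n_cameras`` pinhole cameras on a ring around the
    imaging axis at the scanner working distance, all aimed at the nominal
    eye position (the world origin)."""
    cams = []
    for k in range(n_cameras):
        th = 2 * np.pi * k / n_cameras
        pos = (
            ring_radius_mm * np.cos(th),
            ring_radius_mm * np.sin(th),
            -working_distance_mm,
        )
        cams.append(CameraModel(position=pos, rotation=_look_at(pos, (0, 0, 0))))
    return cams


# ---------------------------------------------------------------------------
# observations

@dataclass(frozen=True)
class FaceTrackEstimate:
    time: float
    globe_estimate: np.ndarray   # (3,) mm
    valid: bool = True


@dataclass(frozen=True)
class PupilObservation:
    time: float
    centroids: tuple                  # per-camera pixel (col,row) or None
    residual_3d: np.ndarray | None    # (3,) mm, None when < 2 centroids
    images: tuple = ()

    @property
    def n_centroids(self) -> int:
        return sum(c is not None for c in self.centroids)


def observe_face(
    true_globe,
    time: float,
    noise_sd: float,
    rng: np.random.Generator,
    dropout_prob: float = 0.0,
) -> FaceTrackEstimate:
    """One face-tracker sample: truth plus isotropic Gaussian noise; with
    probability ``dropout_prob`` the estimate is marked invalid."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    est = np.asarray(true_globe, float) + noise_sd * rng.standard_normal(3)
    valid = bool(rng.random() >= dropout_prob) if dropout_prob > 0 else True
    return FaceTrackEstimate(time=time, globe_estimate=est, valid=valid)


# ---------------------------------------------------------------------------
# pupil image rendering and segmentation

@dataclass(frozen=True)
class PupilRenderConfig:
    pupil_radius_mm: float = 2.0
    iris_radius_mm: float = 6.0
    background_level: float = 0.45
    iris_level: float = 0.60
    pupil_level: float = 0.08
    glint_level: float = 0.95
    glint_offset_mm: float = 0.8
    noise_sd: float = 0.02


def render_pupil_image(
    eye_position_mm,
    camera: CameraModel,
    config: PupilRenderConfig = PupilRenderConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a grayscale pupil-camera frame: dark pupil disc on a brighter
    iris, optional specular glint, additive Gaussian noise.  The projected
    pupil centre follows the pinhole projection of the 3D eye position; if
    the eye is outside the camera frustum the frame contains no pupil."""
    w, h = camera.resolution
    img = np.full((h, w), config.background_level)
    pix, depth = camera.project(eye_position_mm)
    if depth > 0 and camera.in_frame(pix, margin=40):
        scale = camera.focal_length_mm / (depth * camera.pixel_pitch_mm)  # px/mm
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        d = np.hypot(cols - pix[0], rows - pix[1])
        img[d < config.iris_radius_mm * scale] = config.iris_level
        img[d < config.pupil_radius_mm * scale] = config.pupil_level
        # specular glint near the pupil margin
        gx = pix[0] + config.glint_offset_mm * scale * 0.5
        gy = pix[1] - config.glint_offset_mm * scale * 0.5
        dg = np.hypot(cols - gx, rows - gy)
        img[dg < 0.15 * scale] = config.glint_level
    if rng is not None and config.noise_sd > 0:
        img = img + config.noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def segment_pupil_centroid(
    image: np.ndarray,
    area_bounds_px: tuple[float, float] = (80.0, 20000.0),
    opening_radius: int = 2,
) -> np.ndarray | None:
    """Dark-object pupil segmentation by binary morphology.

    Otsu threshold, opening then closing with a small disc, largest connected
    component within area bounds, intensity-weighted (darkness-weighted)
    centroid as (col, row).  Returns None when no acceptable component is
    found."""
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops
    from skimage.morphology import closing, disk, opening

    img = np.asarray(image, float)
    if np.ptp(img) < 1e-6:
        return None
    thr = threshold_otsu(img)
    mask = img < thr
    se = disk(opening_radius)
    mask = closing(opening(mask, se), se)
    lab = label(mask)
    props = regionprops(lab)
    if not props:
        return None
    props = [p for p in props if area_bounds_px[0] <= p.area <= area_bounds_px[1]]
    if not props:
        return None
    best = max(props, key=lambda p: p.area)
    rr, cc = np.nonzero(lab == best.label)
    wgt = np.clip(thr - img[rr, cc], 0.0, None) + 1e-12
    return np.array([np.sum(cc * wgt) / np.sum(wgt), np.sum(rr * wgt) / np.sum(wgt)])


class DegenerateRaysError(ValueError):
    """Triangulation rays are near-parallel; the 3D point is unresolvable."""


def triangulate(
    centroids, cameras, min_eigenvalue: float = 1e-3
) -> tuple[np.ndarray, float]:
    """Least-squares intersection of back-projected camera rays.

    ``centroids`` aligns with ``cameras``; entries may be None.  Returns the
    3D point (mm) and the RMS point-to-ray distance.  Raises ``ValueError``
    when fewer than two centroids are available and ``DegenerateRaysError``
    when the rays are near-parallel.
    """
    rays = [
        cam.back_project(c)
        for c, cam in zip(centroids, cameras)
        if c is not None and np.all(np.isfinite(c))
    ]
    if len(rays) < 2:
        raise ValueError("triangulation requires >= 2 centroids")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for o, d in rays:
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ o
    w = np.linalg.eigvalsh(A)
    if w[0] < min_eigenvalue:
        raise DegenerateRaysError("near-parallel rays")
    p = np.linalg.solve(A, b)
    resid = [np.linalg.norm((np.eye(3) - np.outer(d, d)) @ (p - o)) for o, d in rays]
    return p, float(np.sqrt(np.mean(np.square(resid))))


# ---------------------------------------------------------------------------
# controller

@dataclass(frozen=True)
class ControllerConfig:
    """Gains, limits and latencies of the two-tier controller.

    The printed system description names the actuators and loop structure but
    not the control law; these defaults are documented design choices.
    """

    robot_max_speed_mm_s: float = 50.0
    robot_latency_s: float = 0.05
    mirror_range_mm: float = 2.0
    vcm_range_mm: float = 3.0
    kp_fast: float = 0.8             # per-tick proportional gain, fast loop
    offload_tau_s: float = 0.4       # low-pass constant for robot offloading
    recenter_threshold_mm: float = 0.2
    face_noise_sd_mm: float = 0.4
    face_dropout_prob: float = 0.02
    pupil_centroid_noise_px: float = 0.3
    lock_frames: int = 5             # N consecutive pupil frames to lock
    loss_frames: int = 12            # M missed frames to drop the lock
    dt_s: float = 1.0 / PUPIL_FPS


@dataclass(frozen=True)
class ActuatorState:
    robot_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mirror_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    vcm_offset: float = 0.0
    offload_lp: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def validate(self, cfg: ControllerConfig) -> None:
        if np.any(np.abs(self.mirror_offset) > cfg.mirror_range_mm + 1e-9):
            raise AssertionError("mirror offset outside range")
        if abs(self.vcm_offset) > cfg.vcm_range_mm + 1e-9:
            raise AssertionError("VCM offset outside range")


@dataclass(frozen=True)
class AlignmentState:
    """Alignment state machine: searching_face -> approaching ->
    pupil_locked (-> imaging); imaging is reachable only from pupil_locked."""

    state: str = "searching_face"
    pupil_streak: int = 0
    loss_streak: int = 0
    imaging_aborted: bool = False

    @property
    def can_image(self) -> bool:
        return self.state in ("pupil_locked", "imaging")


def update_alignment_state(
    st: AlignmentState,
    face_est: FaceTrackEstimate | None,
    pupil_obs: PupilObservation | None,
    cfg: ControllerConfig = ControllerConfig(),
) -> AlignmentState:
    """Advance the alignment state machine by one pupil-camera frame."""
    pupil_ok = pupil_obs is not None and pupil_obs.residual_3d is not None
    streak = st.pupil_streak + 1 if pupil_ok else 0
    loss = 0 if pupil_ok else st.loss_streak + 1

    state = st.state
    aborted = False
    if state == "searching_face":
        if face_est is not None and face_est.valid:
            state = "approaching"
    elif state == "approaching":
        if streak >= cfg.lock_frames:
            state = "pupil_locked"
    elif state in ("pupil_locked", "imaging"):
        if loss >= cfg.loss_frames:
            aborted = state == "imaging"
            state = "approaching"
    return AlignmentState(
        state=state, pupil_streak=streak, loss_streak=loss,
        imaging_aborted=st.imaging_aborted or aborted,
    )


def begin_imaging(st: AlignmentState) -> AlignmentState:
    if st.state != "pupil_locked":
        raise ValueError("imaging may start only from pupil_locked")
    return replace(st, state="imaging")


def step_controller(
    state: ActuatorState,
    face_est: FaceTrackEstimate | None,
    pupil_obs: PupilObservation | None,
    dt: float,
    cfg: ControllerConfig,
    robot_target_delayed: np.ndarray | None = None,
) -> ActuatorState:
    """One controller tick.

    Without a pupil residual the robot moves open-loop toward the face
    estimate.  With a residual, the fast actuators track its lateral (mirror)
    and axial (VCM) components proportionally, and a low-passed copy of the
    fast-actuator offsets is offloaded to the robot target so the mirror and
    VCM re-center.  ``robot_target_delayed`` is the latency-delayed command
    actually reaching the robot this tick (defaults to the fresh target).
    All range and speed limits are enforced by clipping.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    robot = state.robot_position.copy()
    mirror = state.mirror_offset.copy()
    vcm = state.vcm_offset
    lp = state.offload_lp.copy()

    have_pupil = pupil_obs is not None and pupil_obs.residual_3d is not None
    if have_pupil:
        est_eye = pupil_obs.residual_3d     # absolute eye estimate
        r = est_eye - robot                 # residual seen by the OCT path
        mirror = mirror + cfg.kp_fast * (r[:2] - mirror)
        mirror = np.clip(mirror, -cfg.mirror_range_mm, cfg.mirror_range_mm)
        vcm = vcm + cfg.kp_fast * (r[2] - vcm)
        vcm = float(np.clip(vcm, -cfg.vcm_range_mm, cfg.vcm_range_mm))
        # the robot slowly tracks the low-passed eye position, which drains
        # the DC component out of the limited-range fast actuators
        alpha = min(dt / cfg.offload_tau_s, 1.0)
        lp = lp + alpha * (est_eye - lp)
        target = lp
    elif face_est is not None and face_est.valid:
        target = face_est.globe_estimate
        lp = target.copy()
    else:
        target = robot

    cmd = robot_target_delayed if robot_target_delayed is not None else target
    step = cmd - robot
    max_step = cfg.robot_max_speed_mm_s * dt
    norm = np.linalg.norm(step)
    if norm > max_step:
        step = step * (max_step / norm)
    robot = robot + step

    new = ActuatorState(
        robot_position=robot, mirror_offset=mirror, vcm_offset=vcm, offload_lp=lp
    )
    new.validate(cfg)
    # stash the fresh target for the caller's latency queue
    object.__setattr__(new, "_fresh_target", target)
    return new


# ---------------------------------------------------------------------------
# full simulation

@dataclass
class CompensationLog:
    """Per-tick record of the alignment simulation.

    ``residual_error = true - robot - (mirror_x, mirror_y, vcm)`` is the
    motion left uncompensated in the OCT image.  ``gaze_offset`` is the
    untracked fixation drift carried through for the acquisition stage.
    """

    times: np.ndarray
    true_position: np.ndarray    # (N, 3)
    robot_position: np.ndarray   # (N, 3)
    mirror_offset: np.ndarray    # (N, 2)
    vcm_offset: np.ndarray       # (N,)
    residual_error: np.ndarray   # (N, 3)
    gaze_offset: np.ndarray      # (N, 2)
    states: list

    def __post_init__(self):
        n = len(self.times)
        for arr in (self.true_position, self.robot_position, self.mirror_offset,
                    self.vcm_offset, self.residual_error, self.gaze_offset):
            if len(arr) != n:
                raise ValueError("log arrays must share length")
        if not np.all(np.isfinite(self.residual_error)):
            raise ValueError("non-finite residual")

    def residual_rms(self, after_s: float = 0.0) -> np.ndarray:
        sel = self.times >= self.times[0] + after_s
        return np.sqrt(np.mean(self.residual_error[sel] ** 2, axis=0))

    def open_loop_residual(self) -> np.ndarray:
        """Residual ignoring the fast actuators (robot-only compensation)."""
        return self.true_position - self.robot_position

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.times,
            "true_x": self.true_position[:, 0],
            "true_y": self.true_position[:, 1],
            "true_z": self.true_position[:, 2],
            "robot_x": self.robot_position[:, 0],
            "robot_y": self.robot_position[:, 1],
            "robot_z": self.robot_position[:, 2],
            "mirror_x": self.mirror_offset[:, 0],
            "mirror_y": self.mirror_offset[:, 1],
            "vcm_z": self.vcm_offset,
            "resid_x": self.residual_error[:, 0],
            "resid_y": self.residual_error[:, 1],
            "resid_z": self.residual_error[:, 2],
            "gaze_x": self.gaze_offset[:, 0],
            "gaze_y": self.gaze_offset[:, 1],
            "state": self.states,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _synthetic_pupil_observation(
    eye_rel, t, cameras, noise_px, rng
) -> PupilObservation:
    """Project the eye through each camera and perturb the centroids with
    pixel noise; geometry identical to the rendered-image path."""
    centroids = []
    for cam in cameras:
        pix, depth = cam.project(eye_rel)
        if depth <= 0 or not cam.in_frame(pix, margin=20):
            centroids.append(None)
        else:
            centroids.append(pix + noise_px * rng.standard_normal(2))
    residual = None
    if sum(c is not None for c in centroids) >= 2:
        try:
            residual, _ = triangulate(centroids, cameras)
        except ValueError:
            residual = None
    return PupilObservation(time=t, centroids=tuple(centroids), residual_3d=residual)


def _rendered_pupil_observation(
    eye_rel, t, cameras, rng, render_cfg: PupilRenderConfig
) -> PupilObservation:
    images, centroids = [], []
    for cam in cameras:
        img = render_pupil_image(eye_rel, cam, render_cfg, rng)
        images.append(img)
        centroids.append(segment_pupil_centroid(img))
    residual = None
    if sum(c is not None for c in centroids) >= 2:
        try:
            residual, _ = triangulate(centroids, cameras)
        except ValueError:
            residual = None
    return PupilObservation(
        time=t, centroids=tuple(centroids), residual_3d=residual, images=tuple(images)
    )


def run_alignment(
    traj: MotionTrajectory,
    gains: ControllerConfig | None = None,
    seed: int = 0,
    mode: str = "full",
    render_images: bool = False,
    initial_offset_mm=(3.0, 2.0, 4.0),
) -> CompensationLog:
    """Simulate the full two-tier alignment loop over a motion trajectory.

    ``mode``: "full" (both tiers), "open_loop" (face tracking + robot only),
    or "off" (no compensation at all; residual equals raw motion).  Pupil
    observations use the camera-projection path by default; with
    ``render_images=True`` each 120 FPS frame is rendered and segmented,
    which is slower but exercises the imaging pipeline end to end.
    """
    cfg = gains or ControllerConfig()
    if mode not in ("full", "open_loop", "off"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    cameras = default_pupil_cameras()
    render_cfg = PupilRenderConfig()

    dt = cfg.dt_s
    n = max(int(np.floor(traj.duration / dt)) + 1, 1)
    times = traj.times[0] + np.arange(n) * dt
    start = resample(traj, times[0])[0]
    if mode == "off":
        # no compensation: scanner parked at the session origin so the
        # residual trace is exactly the raw motion
        act = ActuatorState(robot_position=start)
    else:
        act = ActuatorState(robot_position=start + np.asarray(initial_offset_mm))
    st = AlignmentState()
    latency_ticks = max(int(round(cfg.robot_latency_s / dt)), 0)
    cmd_queue: deque = deque(maxlen=latency_ticks + 1)

    face_period = 1.0 / FACE_FPS
    next_face_t = times[0]
    face_est: FaceTrackEstimate | None = None

    truth = resample(traj, times)
    gaze = resample_gaze(traj, times)
    robot_log = np.zeros((n, 3))
    mirror_log = np.zeros((n, 2))
    vcm_log = np.zeros(n)
    resid_log = np.zeros((n, 3))
    states = []

    for i, t in enumerate(times):
        true = truth[i]
        if t >= next_face_t - 1e-9:
            face_est = observe_face(
                true, t, cfg.face_noise_sd_mm, rng, cfg.face_dropout_prob
            )
            next_face_t += face_period

        if mode == "full":
            if render_images:
                obs = _rendered_pupil_observation(
                    true - act.robot_position, t, cameras, rng, render_cfg
                )
            else:
                obs = _synthetic_pupil_observation(
                    true - act.robot_position, t, cameras,
                    cfg.pupil_centroid_noise_px, rng,
                )
            if obs.residual_3d is not None:
                # camera residual is relative to the scanner; controller wants
                # the absolute eye estimate
                obs = replace(obs, residual_3d=obs.residual_3d + act.robot_position)
        else:
            obs = None

        st = update_alignment_state(st, face_est, obs, cfg)
        if mode != "off":
            delayed = cmd_queue[0] if len(cmd_queue) > latency_ticks else None
            act = step_controller(act, face_est, obs, dt, cfg, delayed)
            cmd_queue.append(getattr(act, "_fresh_target"))

        robot_log[i] = act.robot_position
        if mode == "full":
            mirror_log[i] = act.mirror_offset
            vcm_log[i] = act.vcm_offset
        comp = np.array([mirror_log[i, 0], mirror_log[i, 1], vcm_log[i]])
        resid_log[i] = true - act.robot_position - comp
        states.append(st.state)

    return CompensationLog(
        times=times,
        true_position=truth,
        robot_position=robot_log,
        mirror_offset=mirror_log,
        vcm_offset=vcm_log,
        residual_error=resid_log,
        gaze_offset=gaze,
        states=states,
    )
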