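"""Hierarchical registration and averaging of repeated B-scan stacks.

Repeated-frame stacks (default 100 frames at one retinal location) are
averaged in two stages: consecutive frames are grouped (default groups of
four), each group is registered to its first frame and averaged; groups whose
registration fails quality control (e.g. a blink or large eye motion) are
dropped; the surviving group-averages are then registered to the first
survivor and averaged again.

Pairwise registration is feature-based: scale-space keypoints with binary
descriptors (ORB), robust affine fitting by RANSAC, then sub-pixel
translation refinement by upsampled phase correlation.  The similarity score
is the normalised cross-correlation after warping; quality control keeps a
registration iff it converged and its similarity clears a threshold — the
automated surrogate for manual inspection of the averaged groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, EuclideanTransform, warp

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "group_frames",
    "register_pair",
    "qc_accept",
    "hierarchical_average",
]


@dataclass(frozen=True)
class RegistrationConfig:
    n_keypoints: int = 200
    min_inliers: int = 5
    ransac_residual_px: float = 2.0
    min_similarity: float = 0.2
    phase_upsample: int = 50
    max_shift_px: float = 30.0
    deadband_px: float = 0.2
    model: str = "affine"      # "affine" or "euclidean"


@dataclass
class RegistrationResult:
    transform: AffineTransform
    similarity: float
    converged: bool
    n_inliers: int = 0

    @property
    def translation(self) -> np.ndarray:
        """(dx, dy) in pixels, x = column shift."""
        return np.asarray(self.transform.translation)

    def is_identity(self, tol: float = 1e-3) -> bool:
        return bool(np.allclose(self.transform.params, np.eye(3), atol=tol))


def group_frames(stack: np.ndarray, group_size: int = 4) -> list[np.ndarray]:
    """Split a frame stack into consecutive, non-overlapping index groups.

    A trailing partial group of >= 2 frames is kept; a trailing singleton is
    dropped.  100 frames at the default group size of 4 give 25 groups.
    """
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    n = len(stack)
    if n < 2:
        raise ValueError("stack must hold at least 2 frames")
    groups = []
    for s in range(0, n, group_size):
        idx = np.arange(s, min(s + group_size, n))
        if len(idx) >= 2:
            groups.append(idx)
    return groups


def _ncc(a: np.ndarray, b: np.ndarray, smooth_sigma: float = 1.5) -> float:
    """Normalised cross-correlation on lightly smoothed frames.

    Smoothing suppresses the uncorrelated fully-developed speckle so the
    score reflects structural agreement rather than the speckle floor."""
    from scipy.ndimage import gaussian_filter

    if smooth_sigma > 0:
        a = gaussian_filter(np.asarray(a, float), smooth_sigma)
        b = gaussian_filter(np.asarray(b, float), smooth_sigma)
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-12:
        return 0.0
    return float(np.clip(np.dot(a, b) / denom, -1.0, 1.0))


def _warp(moving: np.ndarray, tf: AffineTransform) -> np.ndarray:
    if np.allclose(tf.params, np.eye(3), atol=1e-12):
        return moving
    return warp(moving, tf.inverse, order=1, mode="edge", preserve_range=True)


def register_pair(
    reference: np.ndarray,
    moving: np.ndarray,
    config: RegistrationConfig = RegistrationConfig(),
) -> RegistrationResult:
    """Estimate the warp taking ``moving`` onto ``reference``.

    Keypoint matching + RANSAC affine, refined by upsampled phase
    correlation for sub-pixel translation.  ``converged=False`` when too few
    inlier matches are found or the post-warp similarity is too low.
    """
    ref = np.asarray(reference, float)
    mov = np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving frames must share a shape")
    identity = AffineTransform()
    if np.array_equal(ref, mov):
        return RegistrationResult(identity, 1.0, True, n_inliers=0)

    tf = None
    n_inliers = 0
    try:
        orb_r = ORB(n_keypoints=config.n_keypoints)
        orb_r.detect_and_extract(ref)
        orb_m = ORB(n_keypoints=config.n_keypoints)
        orb_m.detect_and_extract(mov)
        matches = match_descriptors(
            orb_r.descriptors, orb_m.descriptors, cross_check=True
        )
        if len(matches) >= 3:
            src = orb_m.keypoints[matches[:, 1]][:, ::-1]  # (x, y)
            dst = orb_r.keypoints[matches[:, 0]][:, ::-1]
            model_cls = (AffineTransform if config.model == "affine"
                         else EuclideanTransform)
            model, inliers = ransac(
                (src, dst),
                model_cls,
                min_samples=3,
                residual_threshold=config.ransac_residual_px,
                max_trials=300,
                rng=0,
            )
            if model is not None and inliers is not None:
                n_inliers = int(inliers.sum())
                if n_inliers >= config.min_inliers:
                    tf = AffineTransform(matrix=model.params)
                    if np.allclose(tf.params[:2, :2], np.eye(2), atol=0.02):
                        # translation-dominated: drop the (noise-fitted)
                        # linear part so phase refinement can reach sub-pixel
                        tf = AffineTransform(translation=tf.translation)
                    if np.any(np.abs(tf.translation) > config.max_shift_px):
                        # outside the plausible motion budget: spurious
                        # matches on noise, not geometry
                        tf = None
                        n_inliers = 0
    except (RuntimeError, ValueError):
        tf = None

    # coarse-to-fine translation refinement: iterate upsampled phase
    # correlation on the warped frame until the update is sub-pixel stable.
    # A light pre-smooth keeps speckle from biasing the correlation peak.
    from scipy.ndimage import gaussian_filter

    # Hann window: without it, strong off-centre structure (e.g. the optic
    # nerve head near a frame edge) biases the sub-pixel correlation peak
    hann = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    ref_sm = gaussian_filter(ref, 1.0) * hann

    def _refined(tf0: AffineTransform) -> AffineTransform:
        t = tf0
        for _ in range(3):
            w = warp(mov, t.inverse, order=3, mode="edge", preserve_range=True)
            shift, _, _ = phase_cross_correlation(
                ref_sm, gaussian_filter(w, 1.0) * hann,
                upsample_factor=config.phase_upsample, normalization=None,
            )
            # shift is (row, col); positive: warped must move down/right
            step = AffineTransform(translation=(shift[1], shift[0]))
            t = AffineTransform(matrix=step.params @ t.params)
            if np.hypot(*shift) < 0.5 / config.phase_upsample:
                break
        if (np.allclose(t.params[:2, :2], np.eye(2), atol=1e-6)
                and np.hypot(*t.translation) < config.deadband_px):
            # noise-level micro-shift: snap to identity so already-aligned
            # frames are not blurred by interpolation
            t = AffineTransform()
        return t

    # race the translation-only candidate against the feature-based one;
    # translation wins ties, keeping noise-fitted affine terms out of
    # translation-dominated stacks
    tf_best = _refined(AffineTransform())
    sim = _ncc(ref, _warp(mov, tf_best))
    if tf is not None:
        tf_feat = _refined(tf)
        sim_feat = _ncc(ref, _warp(mov, tf_feat))
        if sim_feat > sim + 0.005:
            tf_best, sim = tf_feat, sim_feat
    tf = tf_best
    warped = _warp(mov, tf)
    converged = bool(
        (n_inliers >= config.min_inliers or _small_transform(tf))
        and sim >= config.min_similarity
    )
    return RegistrationResult(tf, sim, converged, n_inliers=n_inliers)


def _small_transform(tf: AffineTransform, max_px: float = 30.0) -> bool:
    """Translation-dominated transform within a plausible motion budget."""
    lin_ok = np.allclose(tf.params[:2, :2], np.eye(2), atol=0.05)
    return bool(lin_ok and np.all(np.abs(tf.translation) <= max_px))


def qc_accept(results: list[RegistrationResult], threshold: float = 0.5) -> list[bool]:
    """Keep a registration iff it converged and its post-warp similarity is
    at least ``threshold``."""
    return [bool(r.converged and r.similarity >= threshold) for r in results]


def hierarchical_average(
    stack: np.ndarray,
    config: RegistrationConfig = RegistrationConfig(),
    group_size: int = 4,
    qc_threshold: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Two-stage registered average of a repeated B-scan stack.

    Stage 1 registers each group's frames to the group's first frame and
    averages them; a group is kept only if every within-group registration
    passes QC.  Stage 2 registers surviving group-averages to the first
    survivor and averages those that pass QC.  Returns the final average and
    a provenance dict recording kept/dropped groups.
    """
    stack = np.asarray(stack, float)
    groups = group_frames(stack, group_size)
    averages = []
    provenance = {"groups": [], "group_size": group_size}
    for idx in groups:
        ref = stack[idx[0]]
        results = [register_pair(ref, stack[i], config) for i in idx[1:]]
        keep = qc_accept(results, qc_threshold)
        ok = all(keep)
        rec = {
            "frames": idx.tolist(),
            "similarities": [r.similarity for r in results],
            "kept": bool(ok),
        }
        provenance["groups"].append(rec)
        if ok:
            frames = [ref] + [_warp(stack[i], r.transform)
                              for i, r in zip(idx[1:], results)]
            averages.append(np.mean(frames, axis=0))
    if not averages:
        raise ValueError("no group survived registration QC")

    ref = averages[0]
    stage2 = [ref]
    kept2 = [True]
    for av in averages[1:]:
        r = register_pair(ref, av, config)
        ok = qc_accept([r], qc_threshold)[0]
        kept2.append(ok)
        if ok:
            stage2.append(_warp(av, r.transform))
    provenance["stage2_kept"] = kept2
    provenance["n_groups_kept"] = len(stage2)
    provenance["n_frames_averaged"] = int(
        sum(len(g["frames"]) for g, k in zip(provenance["groups"], kept2_iter(provenance))
            if k)
    )
    return np.mean(stage2, axis=0), provenance


def kept2_iter(provenance: dict):
    """Stage-2 keep flags aligned with the stage-1 kept groups."""
    it = iter(provenance["stage2_kept"])
    for g in provenance["groups"]:
        if g["kept"]:
            yield next(it)
        else:
            yield False
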