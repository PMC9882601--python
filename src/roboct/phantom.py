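"""Synthetic layered retina phantoms with exact ground-truth geometry.

The phantom is a continuous (analytic) model of the posterior retina as seen
by a macular OCT raster: two height fields in tissue-depth coordinates — the
inner limiting membrane (ILM) and the retinal pigment epithelium (RPE) — plus
an optic nerve head (ONH) disc where the RPE terminates, a foveal pit, and
optional focal pathology (macular hole, cystoid edema, epiretinal traction).
Retinal thickness is defined throughout as ``z_RPE - z_ILM`` (microns), the
ILM-to-RPE convention used by clinical macular thickness maps.

Coordinates: ``x`` is temporal-nasal (mm, nasal positive), ``y`` is
superior-inferior (mm), ``z`` is depth into tissue (um) increasing away from
the vitreous.  The fovea sits at the lateral origin; for left eyes the
renderer mirrors ``x`` at acquisition time, the phantom itself is always
right-eye oriented.

Everything is vectorised over lateral position so that an acquisition module
can render hundreds of thousands of A-scans without per-point Python loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "PhantomConfig",
    "PathologySpec",
    "RetinalPhantom",
    "build_phantom",
    "add_pathology",
    "reflectivity_profile",
    "ground_truth_thickness",
]

PathologyKind = Literal["macular_hole", "cystoid_edema", "epiretinal_traction"]

#: half-thickness of the rendered hyper-reflective RPE band (um).  The RPE
#: surface height field runs through the band centre, so a segmenter that
#: returns the brightest-band centre measures the ground-truth surface.
RPE_BAND_HALF_UM = 10.0

# reflectivity bands between ILM and the top of the RPE band, as
# (start_fraction, end_fraction, reflectivity).  NFL-like bright band at the
# top, two darker plexiform/nuclear-like bands below; cosmetic and
# configurable via PhantomConfig.inner_bands.
DEFAULT_INNER_BANDS: tuple[tuple[float, float, float], ...] = (
    (0.00, 0.15, 0.55),
    (0.15, 0.55, 0.30),
    (0.55, 1.00, 0.18),
)

RPE_REFLECTIVITY = 0.90
VITREOUS_REFLECTIVITY = 0.02
CHOROID_REFLECTIVITY = 0.12
ONH_CUP_REFLECTIVITY = 0.25
CAVITY_REFLECTIVITY = 0.03


@dataclass(frozen=True)
class PathologySpec:
    """A focal retinal lesion.

    Parameters
    ----------
    kind :
        ``macular_hole`` — full-thickness defect of lumen diameter ``extent``
        whose residual walls have ground-truth thickness ``magnitude``.
        ``cystoid_edema`` — Gaussian retinal thickening (ILM elevation) of
        peak ``magnitude`` um and FWHM ``extent`` mm, with embedded
        hypo-reflective fluid cavities.
        ``epiretinal_traction`` — low-amplitude surface rippling.
    center :
        Lateral position ``(x, y)`` in mm.
    extent :
        Lateral size in mm (> 0).
    magnitude :
        Thickness change / wall thickness in um.
    """

    kind: PathologyKind
    center: tuple[float, float]
    extent: float
    magnitude: float

    def __post_init__(self) -> None:
        if self.extent <= 0:
            raise ValueError("pathology extent must be > 0 mm")
        if self.kind == "macular_hole" and self.magnitude < 10.0:
            raise ValueError("macular hole wall thickness must be >= 10 um")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the healthy baseline phantom.

    Defaults give a central foveal thickness of ``foveal_thickness_um``
    (280 um) and a peripapillary thickness peak of ``peripapillary_peak_um``
    (450 um) at the ONH rim, with the ONH centred 4 mm nasal to the fovea.
    """

    lateral_extent_mm: float = 10.0
    min_extent_mm: float = 8.64          # 30 deg FOV footprint at 0.288 mm/deg
    baseline_thickness_um: float = 330.0
    foveal_thickness_um: float = 280.0
    foveal_pit_fwhm_mm: float = 1.6
    foveal_pit_order: int = 6     # super-Gaussian: flat-bottomed central pit
    peripapillary_peak_um: float = 450.0
    peripapillary_sigma_mm: float = 0.8
    onh_center_mm: tuple[float, float] = (4.0, 0.0)
    onh_radius_mm: float = 0.9
    onh_cup_depth_um: float = 300.0
    rpe_depth_um: float = 360.0
    rpe_bowl_um_per_mm2: float = 1.5
    undulation_amplitude_um: float = 2.0
    inner_bands: tuple[tuple[float, float, float], ...] = DEFAULT_INNER_BANDS


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _make_undulation(seed: int, amplitude: float, extent: float):
    """Seeded band-limited 2D cosine field, analytic and vectorised."""
    rng = np.random.default_rng(seed)
    n_modes = 6
    kx = rng.uniform(0.2, 0.8, n_modes) * 2 * np.pi  # cycles/mm range 0.2-0.8
    ky = rng.uniform(0.2, 0.8, n_modes) * 2 * np.pi
    phase = rng.uniform(0, 2 * np.pi, n_modes)
    amp = amplitude * rng.uniform(0.3, 1.0, n_modes) / np.sqrt(n_modes)

    def f(x, y):
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        return np.sum(amp * np.cos(kx * x + ky * y + phase), axis=-1)

    return f


@dataclass(frozen=True)
class RetinalPhantom:
    """Continuous retina model with exact ground truth.

    All surface queries accept scalars or broadcastable arrays of lateral
    position in mm and return um.
    """

    config: PhantomConfig
    seed: int
    pathologies: tuple[PathologySpec, ...] = ()
    _undulation: Callable = field(repr=False, compare=False, default=None)

    # -- lateral helper fields -------------------------------------------

    @property
    def lateral_extent(self) -> float:
        return self.config.lateral_extent_mm

    @property
    def onh_center(self) -> tuple[float, float]:
        return self.config.onh_center_mm

    @property
    def onh_radius(self) -> float:
        return self.config.onh_radius_mm

    @property
    def fovea_center(self) -> tuple[float, float]:
        return (0.0, 0.0)

    def _check_inside(self, x, y) -> None:
        half = self.config.lateral_extent_mm / 2.0
        if np.any(np.abs(np.asarray(x)) > half) or np.any(np.abs(np.asarray(y)) > half):
            raise ValueError("lateral position outside phantom extent")

    def _d_onh(self, x, y):
        cx, cy = self.config.onh_center_mm
        return np.hypot(np.asarray(x, float) - cx, np.asarray(y, float) - cy)

    # -- thickness field --------------------------------------------------

    def _pit_depth(self) -> float:
        # solve so that thickness at the exact fovea centre is the configured
        # value, including the (tiny) peripapillary contribution there
        c = self.config
        d = np.hypot(*c.onh_center_mm)
        peri = (c.peripapillary_peak_um - c.baseline_thickness_um) * np.exp(
            -((d - c.onh_radius_mm) ** 2) / (2 * c.peripapillary_sigma_mm**2)
        )
        return c.baseline_thickness_um + peri - c.foveal_thickness_um

    def _healthy_thickness(self, x, y):
        c = self.config
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        t = np.full(np.broadcast(x, y).shape, c.baseline_thickness_um)
        # nerve-fiber-layer thickening peaking at the ONH rim
        d_onh = self._d_onh(x, y)
        t = t + (c.peripapillary_peak_um - c.baseline_thickness_um) * np.exp(
            -((d_onh - c.onh_radius_mm) ** 2) / (2 * c.peripapillary_sigma_mm**2)
        )
        # inverted super-Gaussian foveal pit: flat-bottomed, so the central
        # 1 mm subfield mean essentially equals the pit-floor thickness
        p = c.foveal_pit_order
        scale = (c.foveal_pit_fwhm_mm / 2.0) / np.log(2.0) ** (1.0 / p)
        d_fov = np.hypot(x, y)
        t = t - self._pit_depth() * np.exp(-((d_fov / scale) ** p))
        return t

    def thickness(self, x, y):
        """Ground-truth thickness in um; NaN where full-thickness defects or
        the ONH disc interrupt the retina (see :meth:`mask`)."""
        t = self._healthy_thickness(x, y)
        for p in self.pathologies:
            t = self._apply_pathology_thickness(t, p, x, y)
        return np.where(self.mask(x, y), np.nan, t)

    def _apply_pathology_thickness(self, t, p: PathologySpec, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        d = np.hypot(x - p.center[0], y - p.center[1])
        if p.kind == "cystoid_edema":
            sigma = _fwhm_to_sigma(p.extent)
            return t + p.magnitude * np.exp(-(d**2) / (2 * sigma**2))
        if p.kind == "epiretinal_traction":
            sigma = _fwhm_to_sigma(p.extent)
            ripple = np.cos(2 * np.pi * d / max(p.extent / 2, 1e-6))
            return t + p.magnitude * ripple * np.exp(-(d**2) / (2 * sigma**2))
        if p.kind == "macular_hole":
            lumen = p.extent / 2.0
            wall = 0.15          # mm of constant-thickness residual wall
            ramp = 0.30          # mm smooth return to ambient thickness
            s = _smoothstep((d - lumen - wall) / ramp)
            return np.where(
                d < lumen + wall, p.magnitude, p.magnitude + s * (t - p.magnitude)
            )
        raise ValueError(f"unknown pathology kind {p.kind!r}")

    def mask(self, x, y):
        """True where thickness is undefined: ONH disc and hole lumens."""
        m = self._d_onh(x, y) < self.config.onh_radius_mm
        for p in self.pathologies:
            if p.kind == "macular_hole":
                d = np.hypot(
                    np.asarray(x, float) - p.center[0],
                    np.asarray(y, float) - p.center[1],
                )
                m = m | (d < p.extent / 2.0)
        return m

    # -- surfaces ---------------------------------------------------------

    def rpe(self, x, y):
        """RPE surface depth (um): gentle bowl plus seeded undulation."""
        c = self.config
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z = c.rpe_depth_um + c.rpe_bowl_um_per_mm2 * (x**2 + y**2)
        if self._undulation is not None:
            z = z + self._undulation(x, y)
        return np.broadcast_to(z, np.broadcast(x, y).shape).copy()

    def ilm(self, x, y):
        """ILM surface depth (um); continues as the cup floor inside the ONH."""
        t = self.thickness(x, y)
        z = self.rpe(x, y) - np.where(np.isnan(t), 0.0, t)
        d = self._d_onh(x, y)
        c = self.config
        in_onh = d < c.onh_radius_mm
        if np.any(in_onh):
            cup = c.onh_cup_depth_um * (1.0 - (d / c.onh_radius_mm) ** 2)
            z = np.where(in_onh, self.rpe(x, y) + np.clip(cup, 0, None), z)
        return z

    # -- rendering --------------------------------------------------------

    def _edema_cavities(self) -> list[tuple[float, float, float, float]]:
        """(cx, cy, lateral radius mm, depth fraction) for each fluid cavity."""
        out = []
        rng = np.random.default_rng(self.seed + 7919)
        for p in self.pathologies:
            if p.kind != "cystoid_edema" or p.magnitude <= 0:
                continue
            n = 3
            r = rng.uniform(0.15, 0.45, n) * p.extent / 2
            th = rng.uniform(0, 2 * np.pi, n)
            for ri, ti in zip(r, th):
                out.append(
                    (
                        p.center[0] + ri * np.cos(ti),
                        p.center[1] + ri * np.sin(ti),
                        0.2 * p.extent,
                        rng.uniform(0.3, 0.6),
                    )
                )
        return out

    def reflectivity(self, x, y, z_um):
        """Reflectivity in [0, 1] at tissue depth ``z_um``.

        ``x, y`` and ``z_um`` broadcast; typical acquisition use is
        ``x, y`` of shape (n,) against ``z_um`` of shape (m, 1).
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z = np.asarray(z_um, float)
        ilm = self.ilm(x, y)
        rpe = self.rpe(x, y)
        in_onh = self._d_onh(x, y) < self.config.onh_radius_mm
        hole = np.zeros(np.broadcast(x, y).shape, bool)
        for p in self.pathologies:
            if p.kind == "macular_hole":
                d = np.hypot(x - p.center[0], y - p.center[1])
                hole = hole | (d < p.extent / 2.0)

        refl = np.full(np.broadcast(x, y, z).shape, VITREOUS_REFLECTIVITY)
        inner_top = ilm
        inner_bot = rpe - RPE_BAND_HALF_UM
        span = np.maximum(inner_bot - inner_top, 1e-6)
        frac = (z - inner_top) / span
        for f0, f1, r in self.config.inner_bands:
            refl = np.where((frac >= f0) & (frac < f1), r, refl)
        in_rpe_band = (z >= rpe - RPE_BAND_HALF_UM) & (z <= rpe + RPE_BAND_HALF_UM)
        refl = np.where(in_rpe_band, RPE_REFLECTIVITY, refl)
        refl = np.where(z > rpe + RPE_BAND_HALF_UM, CHOROID_REFLECTIVITY, refl)

        if np.any(in_onh):
            # deep cup: moderate tissue below the cup floor, no RPE band
            cup_refl = np.where(
                z >= ilm, ONH_CUP_REFLECTIVITY, VITREOUS_REFLECTIVITY
            )
            refl = np.where(in_onh, cup_refl, refl)
        if np.any(hole):
            # lumen is fluid; residual wall tissue sits on the RPE
            wall_refl = np.where(
                in_rpe_band,
                RPE_REFLECTIVITY,
                np.where(
                    z > rpe + RPE_BAND_HALF_UM,
                    CHOROID_REFLECTIVITY,
                    VITREOUS_REFLECTIVITY,
                ),
            )
            refl = np.where(hole & ~in_onh, wall_refl, refl)
        for cx, cy, cr, zf in self._edema_cavities():
            d = np.hypot(x - cx, y - cy)
            in_cav = (
                (d < cr)
                & (frac > zf - 0.15)
                & (frac < zf + 0.15)
                & ~in_onh
                & ~hole
            )
            refl = np.where(in_cav, CAVITY_REFLECTIVITY, refl)
        return refl


def build_phantom(config: PhantomConfig | None = None, seed: int = 0) -> RetinalPhantom:
    """Construct a healthy phantom from ``config``; deterministic in ``seed``.

    Raises ``ValueError`` if the lateral extent cannot cover the scan FOV
    footprint (``config.min_extent_mm``).
    """
    config = config or PhantomConfig()
    if config.lateral_extent_mm < config.min_extent_mm:
        raise ValueError(
            f"lateral_extent_mm={config.lateral_extent_mm} smaller than the "
            f"scan FOV footprint ({config.min_extent_mm} mm)"
        )
    und = (
        _make_undulation(seed, config.undulation_amplitude_um, config.lateral_extent_mm)
        if config.undulation_amplitude_um > 0
        else None
    )
    return RetinalPhantom(config=config, seed=seed, _undulation=und)


def add_pathology(phantom: RetinalPhantom, spec: PathologySpec) -> RetinalPhantom:
    """Return a new phantom with ``spec`` applied; ground truth stays exact."""
    half = phantom.config.lateral_extent_mm / 2.0
    if abs(spec.center[0]) > half or abs(spec.center[1]) > half:
        raise ValueError("pathology center outside phantom extent")
    cx, cy = phantom.config.onh_center_mm
    d = np.hypot(spec.center[0] - cx, spec.center[1] - cy)
    if d < spec.extent / 2.0 + phantom.config.onh_radius_mm:
        raise ValueError("pathology overlaps the ONH disc")
    return replace(phantom, pathologies=phantom.pathologies + (spec,))


def reflectivity_profile(phantom: RetinalPhantom, x: float, y: float):
    """Depth profile at one lateral position: callable ``z_um -> reflectivity``."""
    phantom._check_inside(x, y)
    return lambda z_um: phantom.reflectivity(x, y, z_um)


def ground_truth_thickness(phantom: RetinalPhantom, x, y):
    """ILM-to-RPE thickness in um as a masked array (masked inside the ONH
    disc and full-thickness defects)."""
    phantom._check_inside(x, y)
    t = np.ma.masked_invalid(phantom.thickness(x, y))
    if t.ndim == 0:
        return np.ma.masked if t.mask else float(t)
    return t


def export_truth_grid(
    phantom: RetinalPhantom, n: int = 101
) -> "np.ndarray":
    """Ground-truth thickness on an n x n grid as structured rows
    (x_mm, y_mm, thickness_um, masked) suitable for CSV export."""
    half = phantom.config.lateral_extent_mm / 2.0
    xs = np.linspace(-half, half, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    t = ground_truth_thickness(phantom, xx, yy)
    rows = np.zeros(xx.size, dtype=[("x_mm", float), ("y_mm", float),
                                    ("thickness_um", float), ("masked", int)])
    rows["x_mm"] = xx.ravel()
    rows["y_mm"] = yy.ravel()
    rows["thickness_um"] = np.where(t.mask.ravel(), np.nan, t.filled(np.nan).ravel())
    rows["masked"] = t.mask.ravel().astype(int)
    return rows
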