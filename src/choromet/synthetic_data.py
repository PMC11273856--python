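"""Ground-truthed synthetic SS-OCT volumes and RR-interval series.

The generator emulates the posterior segment of a (by default left) eye as
seen by a wide-field swept-source OCT raster: a mid-RPE surface lying on a
sphere cap (the posterior curvature), a retina of configurable thickness with
a Gaussian foveal pit in the ILM, and a choroid bounded below by the
choroid-scleral interface.  Volumes are rendered from the surfaces as banded
reflectivity profiles (vitreous dark, retina moderate, RPE brightest, choroid
textured, sclera dim) with depth-dependent exponential attenuation and
unit-mean gamma multiplicative speckle.  A stress effect thickens the choroid
(CSI displaced posteriorly) and moves the whole geometry by a small rigid
transform, mimicking between-session repositioning.  RR series are generated
as first-order autoregressive gaussian interval sequences with acquisition-end
event markers.

Every generator is a pure function of (config, seed): fixed seeds give
bit-identical output.  Default geometry is a reduced 64 x 64 x 256 grid over
the full 12 mm x 12 mm x 4.5 mm physical extents; the full 512 x 512 x 1920
acquisition grid is configuration only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import SurfaceSet
from .volume import OCTVolume

__all__ = [
    "EyeGeometryConfig",
    "NoiseConfig",
    "StressEffectConfig",
    "GroundTruth",
    "generate_eye",
    "render_volume",
    "apply_stress_effect",
    "generate_rr_series",
    "generate_stress_session_rr",
]

# band reflectivities (relative backscatter), anterior to posterior
REFLECTIVITY = {
    "vitreous": 0.05,
    "retina": 0.40,
    "rpe": 0.95,
    "choroid": 0.30,
    "sclera": 0.12,
}
RPE_BAND_UM = 30.0  # full thickness of the bright RPE band


@dataclass
class EyeGeometryConfig:
    """Geometry of one synthetic eye.

    Thickness fields are ``(mean_um, slope_um_per_mm)`` pairs evaluated as
    ``mean + slope * r`` with ``r`` the en-face distance (mm) from the fovea.
    ``posterior_radius_mm`` is the radius of the sphere cap the mid-RPE lies
    on, centered en-face at the fovea.
    """

    n_bscans: int = 64
    n_ascans: int = 64
    depth_px: int = 256
    transverse_extent_mm: float = 12.0
    axial_extent_mm: float = 4.5
    axial_length_mm: float = 24.0
    fovea_position: tuple[int, int] | None = None  # defaults to grid center
    pit_depth_um: float = 100.0
    pit_radius_mm: float = 0.6
    retina_thickness_um: tuple[float, float] = (315.0, 0.0)
    choroid_thickness_um: tuple[float, float] = (283.0, 0.0)
    posterior_radius_mm: float = 19.0
    rpe_depth_at_fovea_mm: float = 1.3
    undulation_um: float = 4.0
    disc_offset_mm: tuple[float, float] = (0.0, 4.0)  # (b, a-nasal) from fovea
    disc_radius_mm: float = 0.75
    disc_cup_depth_um: float = 80.0  # shallower than the foveal pit, so the
    # pit stays the unique global ILM depression
    n_vessels: int = 10
    vessel_width_um: float = 150.0
    vessel_shadow: float = 0.45
    orientation: str = "left"

    def __post_init__(self) -> None:
        if min(self.n_bscans, self.n_ascans, self.depth_px) < 8:
            raise ValueError("all grid counts must be >= 8")
        if min(self.transverse_extent_mm, self.axial_extent_mm) <= 0:
            raise ValueError("physical extents must be positive")
        if self.retina_thickness_um[0] <= 0 or self.choroid_thickness_um[0] <= 0:
            raise ValueError("thickness means must be positive")
        if self.pit_radius_mm > self.transverse_extent_mm / 2:
            raise ValueError("pit_radius exceeds half the transverse extent")
        if self.fovea_position is None:
            self.fovea_position = (self.n_bscans // 2, self.n_ascans // 2)
        fb, fa = self.fovea_position
        if not (0 <= fb < self.n_bscans and 0 <= fa < self.n_ascans):
            raise ValueError("fovea_position outside the grid")

    @property
    def bscan_pitch_mm(self) -> float:
        return self.transverse_extent_mm / self.n_bscans

    @property
    def ascan_pitch_mm(self) -> float:
        return self.transverse_extent_mm / self.n_ascans

    @property
    def axial_pitch_mm(self) -> float:
        return self.axial_extent_mm / self.depth_px


@dataclass
class NoiseConfig:
    """Rendering noise: gamma speckle, per-mm attenuation, intensity floor.

    ``speckle_shape`` is the gamma shape per speckle resolution cell (4
    corresponds to 4-frame compounding of exponential intensity speckle).
    Because a rendered voxel integrates every resolution cell it covers, the
    per-voxel shape is ``speckle_shape`` times the number of cells per voxel,
    computed from the optical resolution (``lateral_resolution_um``,
    ``axial_resolution_um``) and the grid pitches — so a reduced grid over
    the same physical extents shows the correspondingly smoother speckle a
    real downsampled scan would.
    """

    speckle_shape: float = 4.0
    attenuation_coeff: float = 0.5
    background_level: float = 0.02
    lateral_resolution_um: float = 20.0
    axial_resolution_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation_coeff must be non-negative")

    def cells_per_voxel(self, lateral_pitch_um: float, axial_pitch_um: float) -> float:
        return max(1.0, lateral_pitch_um / self.lateral_resolution_um) * max(
            1.0, axial_pitch_um / self.axial_resolution_um
        )


@dataclass
class StressEffectConfig:
    """Between-session effect: choroidal thickening plus a small rigid move.

    ``rigid_shift_px`` is (dz, db, da) in pixels; ``rigid_rot_deg`` rotates the
    en-face plane about the depth axis (|angle| < 5 degrees).
    """

    delta_ct_um: float = 3.3
    rigid_shift_px: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rigid_rot_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.rigid_rot_deg) >= 5:
            raise ValueError("|rigid_rot_deg| must be < 5")


@dataclass
class GroundTruth:
    """Generator output: surfaces, the choroidal-thickness map and bookkeeping.

    ``disc_map`` (optic-nerve-head footprint) and ``texture_map`` (en-face
    choroidal vasculature modulation) are anatomy: they are fixed per eye and
    move with the geometry under the stress-effect rigid transform, so two
    renders of the same eye differ only in speckle.
    """

    surfaces: SurfaceSet
    ct_map_um: np.ndarray
    fovea: tuple[int, int]
    config: EyeGeometryConfig
    disc_map: np.ndarray | None = None
    texture_map: np.ndarray | None = None
    vessel_map: np.ndarray | None = None
    applied_transform: dict | None = None
    applied_delta_ct_um: float = 0.0


def _radial_mm(config: EyeGeometryConfig) -> np.ndarray:
    fb, fa = config.fovea_position
    b = (np.arange(config.n_bscans) - fb) * config.bscan_pitch_mm
    a = (np.arange(config.n_ascans) - fa) * config.ascan_pitch_mm
    return np.sqrt(b[:, None] ** 2 + a[None, :] ** 2)


def _disc_profile(config: EyeGeometryConfig) -> np.ndarray:
    """En-face gaussian footprint of the optic nerve head, peak 1 at its center.

    The disc sits ``disc_offset_mm`` from the fovea, with the second component
    measured toward the nasal side (+a for a left eye, -a for a right eye).
    """
    fb, fa = config.fovea_position
    nasal = 1.0 if config.orientation == "left" else -1.0
    db_mm, da_mm = config.disc_offset_mm
    b = (np.arange(config.n_bscans) - fb) * config.bscan_pitch_mm - db_mm
    a = (np.arange(config.n_ascans) - fa) * config.ascan_pitch_mm - nasal * da_mm
    r2 = b[:, None] ** 2 + a[None, :] ** 2
    return np.exp(-r2 / (config.disc_radius_mm**2))


def _disc_center_mm(config: EyeGeometryConfig) -> tuple[float, float]:
    nasal = 1.0 if config.orientation == "left" else -1.0
    return (config.disc_offset_mm[0], nasal * config.disc_offset_mm[1])


def _vessel_map(config: EyeGeometryConfig, rng: np.random.Generator) -> np.ndarray:
    """En-face retinal-vessel mask (peak 1 on vessel axes).

    Vessels emanate radially from the optic disc at seeded angles, drawn as
    gaussian-profile rays of ``vessel_width_um`` full width.  Their shadows
    give registration its high-contrast rotational anchors, as real retinal
    vessels do.
    """
    fb, fa = config.fovea_position
    db_mm, da_mm = _disc_center_mm(config)
    b = (np.arange(config.n_bscans) - fb) * config.bscan_pitch_mm - db_mm
    a = (np.arange(config.n_ascans) - fa) * config.ascan_pitch_mm - da_mm
    bb, aa = np.meshgrid(b, a, indexing="ij")
    sigma = config.vessel_width_um / 1000.0 / 2.355  # FWHM -> sigma, mm
    out = np.zeros_like(bb)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=config.n_vessels)
    for theta in angles:
        ub, ua = np.cos(theta), np.sin(theta)
        along = bb * ub + aa * ua
        perp = -bb * ua + aa * ub
        ray = np.exp(-(perp**2) / (2.0 * sigma**2)) * (along > 0)
        out = np.maximum(out, ray)
    return out


def _smooth_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field with max |value| = amplitude (zero if amplitude 0)."""
    if amplitude == 0:
        return np.zeros(shape)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0, mode="reflect")
    peak = np.max(np.abs(f))
    return f * (amplitude / peak) if peak > 0 else f


def generate_eye(config: EyeGeometryConfig, seed: int = 0) -> GroundTruth:
    """Build the ground-truth surfaces of one eye.

    The mid-RPE lies on a sphere cap of ``posterior_radius_mm``; the ILM sits
    one retina-thickness above it with a Gaussian pit of ``pit_depth_um`` at
    the fovea; the CSI one choroid-thickness below.  A small seeded smooth
    undulation (``undulation_um``) perturbs both thickness fields.
    """
    rng = np.random.default_rng(seed)
    r = _radial_mm(config)
    R = config.posterior_radius_mm
    if np.max(r) >= R:
        raise ValueError("posterior_radius_mm too small for the scan extent")
    ax = config.axial_pitch_mm

    rpe_mm = config.rpe_depth_at_fovea_mm + R - np.sqrt(R * R - r * r)

    ret_mean, ret_slope = config.retina_thickness_um
    cho_mean, cho_slope = config.choroid_thickness_um
    ret_um = ret_mean + ret_slope * r + _smooth_field(r.shape, config.undulation_um, rng)
    cho_um = cho_mean + cho_slope * r + _smooth_field(r.shape, config.undulation_um, rng)
    pit_um = config.pit_depth_um * np.exp(-((r / config.pit_radius_mm) ** 2))
    cup_um = config.disc_cup_depth_um * _disc_profile(config)  # optic-disc cup

    ilm_mm = rpe_mm - (ret_um - pit_um - cup_um) / 1000.0
    csi_mm = rpe_mm + cho_um / 1000.0
    if np.min(ilm_mm) <= 0 or np.max(csi_mm) >= config.axial_extent_mm:
        raise ValueError("surfaces leave the depth range; adjust geometry")

    surfaces = SurfaceSet(
        ilm_mm / ax, rpe_mm / ax, csi_mm / ax, np.ones(r.shape, dtype=bool)
    )
    # en-face choroidal vasculature surrogate: smooth random modulation field
    texture = ndimage.gaussian_filter(rng.standard_normal(r.shape), sigma=1.5, mode="reflect")
    peak = np.max(np.abs(texture))
    if peak > 0:
        texture /= peak
    return GroundTruth(
        surfaces=surfaces,
        ct_map_um=cho_um.copy(),
        fovea=tuple(config.fovea_position),
        config=config,
        disc_map=_disc_profile(config),
        texture_map=texture,
        vessel_map=_vessel_map(config, rng),
    )


def render_volume(truth: GroundTruth, noise: NoiseConfig | None = None) -> OCTVolume:
    """Render a volume from ground-truth surfaces.

    Per A-scan column the reflectivity profile is a stack of sigmoid band
    transitions (edge width 0.75 px, so boundary positions survive sampling at
    sub-pixel precision), scaled by ``exp(-attenuation_coeff * z_mm)``,
    multiplied by unit-mean gamma speckle, offset by the background floor and
    clipped to [0, 1].
    """
    noise = noise or NoiseConfig()
    cfg = truth.config
    s = truth.surfaces
    depth = cfg.depth_px
    if np.min(s.ilm_px) < 0 or np.max(s.csi_px) >= depth:
        raise ValueError("surfaces outside the depth range")
    z = np.arange(depth, dtype=np.float64)[None, :, None]
    w = 0.75  # sigmoid edge width, px

    def edge(surface_px: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(z - surface_px[:, None, :]) / w))

    half_band = 0.5 * RPE_BAND_UM / 1000.0 / cfg.axial_pitch_mm
    refl = REFLECTIVITY
    profile = (
        refl["vitreous"]
        + (refl["retina"] - refl["vitreous"]) * edge(s.ilm_px)
        + (refl["rpe"] - refl["retina"]) * edge(s.midrpe_px - half_band)
        + (refl["choroid"] - refl["rpe"]) * edge(s.midrpe_px + half_band)
        + (refl["sclera"] - refl["choroid"]) * edge(s.csi_px)
    )

    rng = np.random.default_rng(noise.seed)
    # choroidal vasculature: en-face anatomy modulating the choroid band
    if truth.texture_map is not None:
        choroid_window = edge(s.midrpe_px + half_band) - edge(s.csi_px)
        profile = profile * (1.0 + 0.25 * truth.texture_map[:, None, :] * choroid_window)

    # optic-disc dropout of the bright RPE band (the nerve head interrupts it)
    if truth.disc_map is not None:
        rpe_window = edge(s.midrpe_px - half_band) - edge(s.midrpe_px + half_band)
        profile = profile * (1.0 - 0.6 * truth.disc_map[:, None, :] * rpe_window)

    # retinal-vessel shadows: everything below the ILM is dimmed under a vessel
    if truth.vessel_map is not None and cfg.vessel_shadow > 0:
        shadow = cfg.vessel_shadow * truth.vessel_map[:, None, :]
        profile = profile * (1.0 - shadow * edge(s.ilm_px + 1.0))

    # attenuation accrues with depth in tissue (below the ILM); the vitreous
    # is optically transparent
    tissue_mm = np.maximum(0.0, z - s.ilm_px[:, None, :]) * cfg.axial_pitch_mm
    atten = np.exp(-noise.attenuation_coeff * tissue_mm)
    shape_eff = noise.speckle_shape * noise.cells_per_voxel(
        cfg.ascan_pitch_mm * 1000.0, cfg.axial_pitch_mm * 1000.0
    )
    speckle = rng.gamma(shape_eff, 1.0 / shape_eff, size=profile.shape)
    intensities = np.clip(profile * atten * speckle + noise.background_level, 0.0, 1.0)
    return OCTVolume(
        intensities,
        transverse_mm_per_px=cfg.ascan_pitch_mm,
        axial_mm_per_px=cfg.axial_pitch_mm,
        axial_length_mm=cfg.axial_length_mm,
        orientation=cfg.orientation,
    )


def _rigid_move_surface(
    surface_px: np.ndarray, effect: StressEffectConfig, cfg: EyeGeometryConfig
) -> np.ndarray:
    """Move a depth surface by the configured en-face rotation + translation.

    The new surface value at (b, a) is the old surface sampled at the
    inverse-transformed en-face position, plus the depth shift.  Rotation is
    about the depth axis through the en-face grid center.
    """
    dz, db, da = effect.rigid_shift_px
    theta = np.deg2rad(effect.rigid_rot_deg)
    nb, na = surface_px.shape
    cb, ca = (nb - 1) / 2.0, (na - 1) / 2.0
    bb, aa = np.meshgrid(np.arange(nb, dtype=float), np.arange(na, dtype=float), indexing="ij")
    # inverse map: undo translation, then rotate by -theta about the center
    b0 = bb - db - cb
    a0 = aa - da - ca
    cos_t, sin_t = np.cos(-theta), np.sin(-theta)
    src_b = cos_t * b0 - sin_t * a0 + cb
    src_a = sin_t * b0 + cos_t * a0 + ca
    moved = ndimage.map_coordinates(
        surface_px, [src_b, src_a], order=1, mode="nearest"
    )
    return moved + dz


def apply_stress_effect(truth: GroundTruth, effect: StressEffectConfig) -> GroundTruth:
    """Thicken the choroid and rigidly move the geometry.

    The CSI is displaced posteriorly by ``delta_ct_um`` (the retina is left
    untouched), then the whole geometry is translated/rotated.  Both the
    applied thickening and the transform are recorded for downstream checks.
    """
    cfg = truth.config
    s = truth.surfaces
    ax_um = cfg.axial_pitch_mm * 1000.0
    csi = s.csi_px + effect.delta_ct_um / ax_um
    if np.max(csi) >= cfg.depth_px or np.min(csi) < 0:
        raise ValueError("thickened CSI leaves the depth range")
    if np.any(csi < s.midrpe_px):
        raise ValueError("negative choroidal thickness after thinning")

    ilm = _rigid_move_surface(s.ilm_px, effect, cfg)
    rpe = _rigid_move_surface(s.midrpe_px, effect, cfg)
    csi = _rigid_move_surface(csi, effect, cfg)
    if np.max(csi) >= cfg.depth_px or np.min(ilm) < 0:
        raise ValueError("rigid move pushes surfaces outside the depth range")
    enface = StressEffectConfig(  # en-face anatomy shifts without the depth offset
        delta_ct_um=0.0,
        rigid_shift_px=(0.0, effect.rigid_shift_px[1], effect.rigid_shift_px[2]),
        rigid_rot_deg=effect.rigid_rot_deg,
    )
    disc = None if truth.disc_map is None else _rigid_move_surface(truth.disc_map, enface, cfg)
    texture = (
        None if truth.texture_map is None else _rigid_move_surface(truth.texture_map, enface, cfg)
    )
    vessels = (
        None if truth.vessel_map is None else _rigid_move_surface(truth.vessel_map, enface, cfg)
    )

    surfaces = SurfaceSet(ilm, rpe, csi, np.ones_like(ilm, dtype=bool))
    transform = {
        "shift_px": tuple(float(v) for v in effect.rigid_shift_px),
        "rot_deg": float(effect.rigid_rot_deg),
    }
    return GroundTruth(
        surfaces=surfaces,
        ct_map_um=(csi - rpe) * ax_um,
        fovea=truth.fovea,
        config=cfg,
        disc_map=disc,
        texture_map=texture,
        vessel_map=vessels,
        applied_transform=transform,
        applied_delta_ct_um=truth.applied_delta_ct_um + effect.delta_ct_um,
    )


def generate_rr_series(
    mean_rr_ms: float,
    sd_rr_ms: float,
    n_beats: int,
    events: dict[str, float] | None = None,
    seed: int = 0,
    ar_coeff: float = 0.7,
):
    """First-order autoregressive gaussian RR series with event markers.

    The stationary SD equals ``sd_rr_ms``; ``ar_coeff`` (default 0.7) sets the
    beat-to-beat correlation.  RMSSD of an AR(1) series is
    ``sd * sqrt(2 * (1 - ar_coeff))``, so any coefficient above 0.5 keeps
    RMSSD below SDRR as in real recordings.
    Requires ``mean_rr_ms > 3 * sd_rr_ms`` so intervals stay positive.
    """
    from .hrv import RRSeries

    if mean_rr_ms <= 3 * sd_rr_ms:
        raise ValueError("require mean_rr_ms > 3 * sd_rr_ms")
    if not (0 <= ar_coeff < 1):
        raise ValueError("ar_coeff must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    innov_sd = sd_rr_ms * np.sqrt(1.0 - ar_coeff**2)
    x = np.empty(n_beats)
    prev = rng.normal(0.0, sd_rr_ms) if sd_rr_ms > 0 else 0.0
    for i in range(n_beats):
        prev = ar_coeff * prev + rng.normal(0.0, innov_sd) if sd_rr_ms > 0 else 0.0
        x[i] = prev
    rr = mean_rr_ms + x
    return RRSeries(rr, dict(events or {}))


def generate_stress_session_rr(
    baseline_mean_rr_ms: float = 779.0,
    baseline_sd_rr_ms: float = 48.0,
    stress_mean_rr_ms: float = 692.0,
    stress_sd_rr_ms: float = 33.0,
    segment_s: float = 120.0,
    seed: int = 0,
    ar_coeff: float = 0.7,
):
    """A two-segment session: baseline beats then stress beats, with one
    acquisition-end event at the end of each segment.

    Defaults place the segments at ~77 bpm and ~87 bpm with the stress
    segment's variability reduced, the qualitative stress signature (HR up,
    RMSSD down).
    """
    from .hrv import RRSeries

    n_base = int(np.ceil(segment_s * 1000.0 / baseline_mean_rr_ms)) + 2
    n_stress = int(np.ceil(segment_s * 1000.0 / stress_mean_rr_ms)) + 2
    base = generate_rr_series(baseline_mean_rr_ms, baseline_sd_rr_ms, n_base, seed=seed, ar_coeff=ar_coeff)
    stress = generate_rr_series(stress_mean_rr_ms, stress_sd_rr_ms, n_stress, seed=seed + 1, ar_coeff=ar_coeff)
    rr = np.concatenate([base.rr_ms, stress.rr_ms])
    # compute event times with the same summation order the series uses, so
    # the final event stays inside the recording span to the last ulp
    t_end = np.cumsum(rr)
    events = {
        "baseline_end": float(t_end[base.rr_ms.size - 1]),
        "stress_end": float(rr.sum()),
    }
    return RRSeries(rr, events)
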