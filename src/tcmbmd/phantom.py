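"""Synthetic CT phantoms: forward model, geometry rasterizer, builtin scenes.

The forward model maps a bone volume fraction to a CT number.  In
*calibrated* mode it is the exact affine inverse of the TCM inversion,
``CTN = bvf * (ctn_cor - ctn_mar) + ctn_mar``; in *attenuation* mode it is
built from spectrum-weighted linear attenuation coefficients,
``CTN = (mu_mix / mu_water - 1) * 1000`` with
``mu_mix = bvf * mu_a + (1 - bvf) * mu_b``.  Both are affine in the volume
fraction, which is what makes the pixel-wise inversion linear.

Scenes are declarative: an ordered list of shape primitives with nominal
volumetric BMD (or explicit HU), rendered at a supersampled resolution and
box-averaged down so boundary pixels carry realistic partial-volume mixing,
optionally degraded by a radial beam-hardening (cupping) deficit inside
dense shapes, then corrupted with i.i.d. Gaussian HU noise from a seeded
generator.

Builtin scenes emulate the validation phantoms of the reference protocol:

``seven_vials``
    A row of seven 20 mm K2HPO4 vials at 0.135-0.467 g/cm^3.
``forearm_qrm``
    A 6 cm water-equivalent forearm phantom: four hydroxyapatite sections
    (0.194, 0.103, 0.054, 0 g/cm^3), each in a 1.2 mm wall of
    0.800 g/cm^3, stacked on the left, two water inserts on the right.
``toy_femur``
    A schematic femoral-neck cross-section: 0.800 g/cm^3 cortical shell,
    trabecular interior near 0.17 g/cm^3, optional central nonosseous void.

Per-kVp default noise SDs (41.4, 27.2, 16.4 HU at 80/100/120 kVp) are the
cortical-phantom ROI standard deviations of the reference calibration scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import ROISpec
from .core import CalibrationEntry, default_calibration
from .image_io import CTImage

__all__ = [
    "Annulus",
    "Disk",
    "FlattenedDisk",
    "ForwardModel",
    "PhantomError",
    "PhantomSpec",
    "Rect",
    "Shape",
    "builtin_specs",
    "forward_ctn",
    "forearm_insert_rois",
    "render_phantom",
    "seven_vial_rois",
    "toy_femur_volume",
    "NOISE_SD_BY_KVP",
    "SEVEN_VIAL_DENSITIES",
    "FOREARM_SECTION_DENSITIES",
]

#: cortical-scan ROI noise (HU) by tube voltage, used as image noise defaults
NOISE_SD_BY_KVP = {80: 41.4, 100: 27.2, 120: 16.4}

SEVEN_VIAL_DENSITIES = (0.135, 0.202, 0.267, 0.300, 0.344, 0.401, 0.467)
FOREARM_SECTION_DENSITIES = (0.194, 0.103, 0.054, 0.0)
FOREARM_WALL_DENSITY = 0.800
FOREARM_WALL_THICKNESS_MM = 1.2


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass(frozen=True)
class ForwardModel:
    """Maps bone volume fraction to CT number (HU).

    Exactly one of the two parameterizations is active: a calibration entry
    (affine mode, the default) or attenuation coefficients in 1/cm.
    ``rho_cor`` converts nominal vBMD to volume fraction; in calibrated mode
    it comes from the entry.
    """

    calibration: CalibrationEntry | None = None
    mu_a: float | None = None
    mu_b: float | None = None
    mu_water: float | None = None
    rho_cor: float | None = None

    @classmethod
    def from_calibration(cls, entry: CalibrationEntry) -> "ForwardModel":
        return cls(calibration=entry, rho_cor=entry.rho_cor)

    @classmethod
    def from_attenuation(
        cls, mu_a: float, mu_b: float, mu_water: float, rho_cor: float = 0.533
    ) -> "ForwardModel":
        if mu_water <= 0:
            raise PhantomError(f"mu_water must be positive, got {mu_water}")
        return cls(mu_a=mu_a, mu_b=mu_b, mu_water=mu_water, rho_cor=rho_cor)

    def ctn(self, bvf):
        """CT number of a mixture with the given bone volume fraction."""
        bvf = np.asarray(bvf, dtype=float)
        if self.calibration is not None:
            c = self.calibration
            out = bvf * (c.ctn_cor - c.ctn_mar) + c.ctn_mar
        else:
            if self.mu_water is None or self.mu_water <= 0:
                raise PhantomError("attenuation mode requires mu_water > 0")
            mu_mix = bvf * self.mu_a + (1.0 - bvf) * self.mu_b
            out = (mu_mix / self.mu_water - 1.0) * 1000.0
        return out if out.ndim else float(out)

    def ctn_from_vbmd(self, vbmd: float) -> float:
        if self.rho_cor is None or self.rho_cor <= 0:
            raise PhantomError("rho_cor required to map vBMD to volume fraction")
        return self.ctn(vbmd / self.rho_cor)


def forward_ctn(bvf, model: ForwardModel):
    """Functional form of :meth:`ForwardModel.ctn`."""
    return model.ctn(bvf)


# ---------------------------------------------------------------------------
# shape primitives (all dimensions in mm, (row, col) order)

@dataclass(frozen=True)
class Shape:
    center_mm: tuple[float, float]
    vbmd: float | None = None
    ctn: float | None = None

    def contains(self, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def bounds_mm(self) -> tuple[float, float, float, float]:
        """(rmin, rmax, cmin, cmax) in mm."""
        raise NotImplementedError

    def cupping_radius_mm(self) -> float:
        """Characteristic radius for the radial cupping deficit."""
        b = self.bounds_mm()
        return max(b[1] - b[0], b[3] - b[2]) / 2.0


@dataclass(frozen=True)
class Disk(Shape):
    radius_mm: float = 1.0

    def contains(self, rr, cc):
        r0, c0 = self.center_mm
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius_mm**2

    def bounds_mm(self):
        r0, c0 = self.center_mm
        return (r0 - self.radius_mm, r0 + self.radius_mm,
                c0 - self.radius_mm, c0 + self.radius_mm)


@dataclass(frozen=True)
class Annulus(Shape):
    r_inner_mm: float = 0.5
    r_outer_mm: float = 1.0

    def contains(self, rr, cc):
        r0, c0 = self.center_mm
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        return (d2 <= self.r_outer_mm**2) & (d2 > self.r_inner_mm**2)

    def bounds_mm(self):
        r0, c0 = self.center_mm
        return (r0 - self.r_outer_mm, r0 + self.r_outer_mm,
                c0 - self.r_outer_mm, c0 + self.r_outer_mm)


@dataclass(frozen=True)
class Rect(Shape):
    """Axis-aligned (optionally rounded) rectangle."""

    height_mm: float = 1.0
    width_mm: float = 1.0
    corner_radius_mm: float = 0.0

    def contains(self, rr, cc):
        r0, c0 = self.center_mm
        hr, hc = self.height_mm / 2, self.width_mm / 2
        if self.corner_radius_mm <= 0:
            return (np.abs(rr - r0) <= hr) & (np.abs(cc - c0) <= hc)
        k = self.corner_radius_mm
        dr = np.maximum(np.abs(rr - r0) - (hr - k), 0.0)
        dc = np.maximum(np.abs(cc - c0) - (hc - k), 0.0)
        return dr**2 + dc**2 <= k**2

    def bounds_mm(self):
        r0, c0 = self.center_mm
        return (r0 - self.height_mm / 2, r0 + self.height_mm / 2,
                c0 - self.width_mm / 2, c0 + self.width_mm / 2)


@dataclass(frozen=True)
class FlattenedDisk(Shape):
    """Cylinder cross-section with two parallel chord flats (top/bottom)."""

    radius_mm: float = 1.0
    flatten_mm: float = 0.0  # material removed from each flat side

    def contains(self, rr, cc):
        r0, c0 = self.center_mm
        in_disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius_mm**2
        return in_disk & (np.abs(rr - r0) <= self.radius_mm - self.flatten_mm)

    def bounds_mm(self):
        r0, c0 = self.center_mm
        h = self.radius_mm - self.flatten_mm
        return (r0 - h, r0 + h, c0 - self.radius_mm, c0 + self.radius_mm)


@dataclass
class PhantomSpec:
    """Declarative scene plus rendering parameters.

    Shapes are painted in order (later shapes overwrite earlier ones).
    ``cupping_amplitude`` (HU, >= 0) scales a multiplicative radial deficit
    ``CTN * (1 - a * (1 - r/R))`` with ``a = amplitude / 1000`` inside
    shapes whose CT number exceeds ``cupping_hu_threshold`` -- a minimal
    stand-in for the beam-hardening cupping seen in dense objects.
    """

    canvas_px: tuple[int, int]
    pixel_spacing: tuple[float, float]
    shapes: list[Shape] = field(default_factory=list)
    background_ctn: float = 0.0
    noise_sd: float = 0.0
    cupping_amplitude: float = 0.0
    cupping_hu_threshold: float = 400.0
    supersample: int = 8
    seed: int = 0
    kvp: int = 120
    slice_thickness: float = 3.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.supersample < 1:
            raise PhantomError(f"supersample must be >= 1, got {self.supersample}")
        if self.noise_sd < 0:
            raise PhantomError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.cupping_amplitude < 0:
            raise PhantomError("cupping_amplitude must be >= 0")

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (
            self.canvas_px[0] * self.pixel_spacing[0],
            self.canvas_px[1] * self.pixel_spacing[1],
        )


def render_phantom(spec: PhantomSpec, model: ForwardModel) -> CTImage:
    """Rasterize a scene into a noisy CT slice.

    Pipeline: supersampled painting -> per-shape cupping -> box average to
    the canvas grid (partial volume) -> additive Gaussian noise.
    """
    rows, cols = spec.canvas_px
    if rows <= 0 or cols <= 0:
        raise PhantomError(f"canvas must be non-empty, got {spec.canvas_px}")
    height_mm, width_mm = spec.extent_mm
    for shape in spec.shapes:
        rmin, rmax, cmin, cmax = shape.bounds_mm()
        if rmin < 0 or cmin < 0 or rmax > height_mm or cmax > width_mm:
            raise PhantomError(
                f"shape {shape} exceeds canvas extent {height_mm} x {width_mm} mm"
            )
    s = spec.supersample
    sr, sc = spec.pixel_spacing
    rr = (np.arange(rows * s) + 0.5) * (sr / s)
    cc = (np.arange(cols * s) + 0.5) * (sc / s)
    RR, CC = np.meshgrid(rr, cc, indexing="ij", copy=False)
    ctn_field = np.full((rows * s, cols * s), float(spec.background_ctn))
    for shape in spec.shapes:
        if shape.ctn is not None:
            base = float(shape.ctn)
        elif shape.vbmd is not None:
            base = model.ctn_from_vbmd(shape.vbmd)
        else:
            raise PhantomError(f"shape {shape} has neither vbmd nor explicit ctn")
        mask = shape.contains(RR, CC)
        if spec.cupping_amplitude > 0 and base >= spec.cupping_hu_threshold:
            a = spec.cupping_amplitude / 1000.0
            radius = shape.cupping_radius_mm()
            r = np.hypot(RR - shape.center_mm[0], CC - shape.center_mm[1])
            factor = 1.0 - a * np.clip(1.0 - r / radius, 0.0, 1.0)
            ctn_field[mask] = base * factor[mask]
        else:
            ctn_field[mask] = base
    img = ctn_field.reshape(rows, s, cols, s).mean(axis=(1, 3))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return CTImage(
        voxels=img,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        kvp=spec.kvp,
        orientation_label="axial",
        provenance=f"synthetic:{spec.name}:seed={spec.seed}",
    )


# ---------------------------------------------------------------------------
# builtin scenes (geometry constants in mm)

_VIAL_RADIUS = 10.0
_VIAL_ROW = 20.0
_VIAL_COLS = tuple(18.0 + 24.0 * i for i in range(7))
_VIAL_SPACING = 0.5  # mm/px

_FOREARM_SPACING = 0.25
_FOREARM_BODY = dict(center=(40.0, 40.0), height=60.0, width=60.0)
_FOREARM_SECTION_ROWS = (19.0, 33.0, 47.0, 61.0)
_FOREARM_SECTION_COL = 26.0
_FOREARM_SECTION_H = 14.0
_FOREARM_SECTION_W = 20.0
_FOREARM_WATER = ((33.0, 42.0), (62.0, 14.0))  # (row center, height)
_FOREARM_WATER_COL = 54.0
_FOREARM_WATER_W = 16.0

_FEMUR_SPACING = 0.5
_FEMUR_CENTER = (50.0, 50.0)
_FEMUR_SHELL_OUTER = 25.0
_FEMUR_SHELL_INNER = 23.0
_FEMUR_VOID_RADIUS = 5.0


def _default_noise(kvp: int) -> float:
    return NOISE_SD_BY_KVP.get(kvp, NOISE_SD_BY_KVP[120])


def _seven_vials_spec(kvp, noise_sd, seed) -> PhantomSpec:
    shapes = [
        Disk(center_mm=(_VIAL_ROW, col), vbmd=v, radius_mm=_VIAL_RADIUS)
        for col, v in zip(_VIAL_COLS, SEVEN_VIAL_DENSITIES)
    ]
    return PhantomSpec(
        canvas_px=(80, 360),
        pixel_spacing=(_VIAL_SPACING, _VIAL_SPACING),
        shapes=shapes,
        noise_sd=noise_sd,
        seed=seed,
        kvp=kvp,
        name="seven_vials",
    )


def _forearm_spec(kvp, noise_sd, seed) -> PhantomSpec:
    b = _FOREARM_BODY
    t = FOREARM_WALL_THICKNESS_MM
    shapes: list[Shape] = [
        Rect(center_mm=b["center"], vbmd=0.0, height_mm=b["height"], width_mm=b["width"])
    ]
    for row, dens in zip(_FOREARM_SECTION_ROWS, FOREARM_SECTION_DENSITIES):
        shapes.append(
            Rect(
                center_mm=(row, _FOREARM_SECTION_COL),
                vbmd=FOREARM_WALL_DENSITY,
                height_mm=_FOREARM_SECTION_H,
                width_mm=_FOREARM_SECTION_W + 2 * t,
            )
        )
        shapes.append(
            Rect(
                center_mm=(row, _FOREARM_SECTION_COL),
                vbmd=dens,
                height_mm=_FOREARM_SECTION_H - 2 * t,
                width_mm=_FOREARM_SECTION_W,
            )
        )
    for row, height in _FOREARM_WATER:
        shapes.append(
            Rect(
                center_mm=(row, _FOREARM_WATER_COL),
                vbmd=FOREARM_WALL_DENSITY,
                height_mm=height,
                width_mm=_FOREARM_WATER_W + 2 * t,
            )
        )
        shapes.append(
            Rect(
                center_mm=(row, _FOREARM_WATER_COL),
                vbmd=0.0,
                height_mm=height - 2 * t,
                width_mm=_FOREARM_WATER_W,
            )
        )
    return PhantomSpec(
        canvas_px=(320, 320),
        pixel_spacing=(_FOREARM_SPACING, _FOREARM_SPACING),
        shapes=shapes,
        noise_sd=noise_sd,
        seed=seed,
        kvp=kvp,
        name="forearm_qrm",
    )


def _toy_femur_shapes(
    interior_vbmd: float = 0.17,
    void: bool = True,
    outer_radius: float = _FEMUR_SHELL_OUTER,
) -> list[Shape]:
    shell_thickness = _FEMUR_SHELL_OUTER - _FEMUR_SHELL_INNER
    inner = outer_radius - shell_thickness
    shapes: list[Shape] = [
        Disk(center_mm=_FEMUR_CENTER, vbmd=FOREARM_WALL_DENSITY, radius_mm=outer_radius),
        Disk(center_mm=_FEMUR_CENTER, vbmd=interior_vbmd, radius_mm=inner),
    ]
    if void:
        shapes.append(
            Disk(center_mm=_FEMUR_CENTER, vbmd=0.0, radius_mm=_FEMUR_VOID_RADIUS)
        )
    return shapes


def _toy_femur_spec(kvp, noise_sd, seed) -> PhantomSpec:
    return PhantomSpec(
        canvas_px=(200, 200),
        pixel_spacing=(_FEMUR_SPACING, _FEMUR_SPACING),
        shapes=_toy_femur_shapes(),
        noise_sd=noise_sd,
        seed=seed,
        kvp=kvp,
        name="toy_femur",
    )


_BUILTINS = {
    "seven_vials": _seven_vials_spec,
    "forearm_qrm": _forearm_spec,
    "toy_femur": _toy_femur_spec,
}


def builtin_specs(
    name: str, kvp: int = 120, noise_sd: float | None = None, seed: int = 0
) -> PhantomSpec:
    """Return a fully parameterized builtin scene.

    ``noise_sd`` defaults to the per-kVp cortical-scan SD
    (:data:`NOISE_SD_BY_KVP`).
    """
    if name not in _BUILTINS:
        raise PhantomError(
            f"unknown phantom {name!r}; valid names: {', '.join(sorted(_BUILTINS))}"
        )
    if noise_sd is None:
        noise_sd = _default_noise(kvp)
    return _BUILTINS[name](kvp, noise_sd, seed)


def toy_femur_volume(
    n_slices: int = 7,
    interior_vbmd: float = 0.17,
    void: bool = False,
    kvp: int = 120,
    noise_sd: float | None = None,
    seed: int = 0,
    peak_slice: int | None = None,
    model: ForwardModel | None = None,
) -> CTImage:
    """Stack of toy-femur slices whose neck cross-section peaks mid-volume.

    The outer shell radius tapers by 2 mm per slice away from ``peak_slice``
    (default: the middle slice), so VOI slice selection has an unambiguous
    maximum-area slice.  Each slice uses an independent noise substream.
    """
    if n_slices < 1:
        raise PhantomError("volume needs at least one slice")
    if peak_slice is None:
        peak_slice = n_slices // 2
    if model is None:
        model = ForwardModel.from_calibration(default_calibration()[kvp])
    if noise_sd is None:
        noise_sd = _default_noise(kvp)
    slabs = []
    for i in range(n_slices):
        radius = _FEMUR_SHELL_OUTER - 2.0 * abs(i - peak_slice)
        radius = max(radius, _FEMUR_SHELL_OUTER - _FEMUR_SHELL_INNER + 4.0)
        spec = PhantomSpec(
            canvas_px=(200, 200),
            pixel_spacing=(_FEMUR_SPACING, _FEMUR_SPACING),
            shapes=_toy_femur_shapes(interior_vbmd, void, outer_radius=radius),
            noise_sd=noise_sd,
            seed=seed + i,
            kvp=kvp,
            name=f"toy_femur[{i}]",
        )
        slabs.append(render_phantom(spec, model).voxels)
    return CTImage(
        voxels=np.stack(slabs),
        pixel_spacing=(_FEMUR_SPACING, _FEMUR_SPACING),
        slice_thickness=3.0,
        kvp=kvp,
        orientation_label="coronal",
        provenance=f"synthetic:toy_femur_volume:seed={seed}",
    )


# ---------------------------------------------------------------------------
# landmark ROIs for the builtin scenes

def _mm_to_px(mm: float, spacing: float) -> float:
    return mm / spacing - 0.5


def seven_vial_rois(diameter_mm: float = 12.0) -> list[ROISpec]:
    """Circular ROIs centered on each vial of the ``seven_vials`` scene."""
    return [
        ROISpec(
            shape="circle",
            center=(_mm_to_px(_VIAL_ROW, _VIAL_SPACING), _mm_to_px(col, _VIAL_SPACING)),
            extent_mm=diameter_mm,
        )
        for col in _VIAL_COLS
    ]


def forearm_insert_rois(margin_mm: float = 2.0) -> list[ROISpec]:
    """Interior-eroded rectangular ROIs for the four forearm sections.

    Returned in section order (0.194, 0.103, 0.054, 0 g/cm^3); the erosion
    margin keeps partial-volume wall pixels out.
    """
    t = FOREARM_WALL_THICKNESS_MM
    rois = []
    for row in _FOREARM_SECTION_ROWS:
        extent = min(
            _FOREARM_SECTION_H - 2 * t - 2 * margin_mm,
            _FOREARM_SECTION_W - 2 * margin_mm,
        )
        rois.append(
            ROISpec(
                shape="rectangle",
                center=(
                    _mm_to_px(row, _FOREARM_SPACING),
                    _mm_to_px(_FOREARM_SECTION_COL, _FOREARM_SPACING),
                ),
                extent_mm=extent,
            )
        )
    return rois
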