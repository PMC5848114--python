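"""Two-compartment model (TCM) inversion of CT numbers.

A voxel is modelled as a two-material mixture of cortical-bone-equivalent
material (a K2HPO4 aqueous solution in the reference calibration) and
marrow-equivalent material (water).  Because the CT number of a mixture is
affine in the volume fraction of either compartment, the bone volume
fraction (BVF) follows from a single linear inversion::

    BVF  = (CTN_mix - CTN_mar) / (CTN_cor - CTN_mar)
    vBMD = BVF * rho_cor

``CTN_mar`` and ``CTN_cor`` are reference CT numbers (HU) measured on a
water vial and on the cortical-equivalent calibration phantom at the same
tube voltage as the image being converted; ``rho_cor`` is the phantom's
mineral-equivalent density in g/cm^3 (the K2HPO4 mass per solution volume,
not the physical mass density -- the mixture-density terms cancel in the
inversion, so it is never needed).

The canonical internal unit for density is g/cm^3; mg/cm^3 appears only at
the diagnostic-classification boundary, converted by an exact factor 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterator, Mapping, Union

import numpy as np
import yaml

__all__ = [
    "CalibrationEntry",
    "CalibrationError",
    "CalibrationTable",
    "DensityMap",
    "DiagnosticClass",
    "classify_acr",
    "ctn_to_bvf_vbmd",
    "default_calibration",
    "volume_fraction",
    "weight_fraction",
    "OSTEOPOROSIS_THRESHOLD_MG",
    "OSTEOPENIA_THRESHOLD_MG",
]

#: ACR diagnostic cut-offs for volumetric BMD, mg/cm^3.
OSTEOPOROSIS_THRESHOLD_MG = 80.0
OSTEOPENIA_THRESHOLD_MG = 120.0


class CalibrationError(ValueError):
    """Raised for degenerate or unusable calibration data."""


@dataclass(frozen=True)
class CalibrationEntry:
    """Per-kVp TCM calibration: the parameters of the linear inversion.

    Parameters
    ----------
    kvp:
        Peak tube voltage the references were measured at.
    ctn_mar, ctn_cor:
        Mean CT numbers (HU) of the marrow surrogate (water) and of the
        cortical-bone-equivalent phantom.
    rho_cor:
        Mineral-equivalent density of the cortical calibration phantom,
        g/cm^3.
    ctn_mar_sd, ctn_cor_sd:
        ROI standard deviations of the reference scans (HU); informational,
        not used by the inversion itself.
    """

    kvp: int
    ctn_mar: float
    ctn_cor: float
    rho_cor: float = 0.533
    ctn_mar_sd: float = 0.0
    ctn_cor_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.ctn_mar, self.ctn_cor, self.rho_cor]).all():
            raise CalibrationError("calibration values must be finite")
        if self.ctn_cor <= self.ctn_mar:
            raise CalibrationError(
                f"degenerate calibration at {self.kvp} kVp: "
                f"CTN_cor ({self.ctn_cor}) must exceed CTN_mar ({self.ctn_mar})"
            )
        if self.rho_cor <= 0:
            raise CalibrationError(f"rho_cor must be positive, got {self.rho_cor}")
        if self.ctn_mar_sd < 0 or self.ctn_cor_sd < 0:
            raise CalibrationError("reference SDs must be non-negative")


@dataclass
class CalibrationTable:
    """Collection of :class:`CalibrationEntry` keyed by tube voltage."""

    entries: dict[int, CalibrationEntry] = field(default_factory=dict)

    def add(self, entry: CalibrationEntry) -> None:
        self.entries[entry.kvp] = entry

    def __getitem__(self, kvp: int) -> CalibrationEntry:
        try:
            return self.entries[kvp]
        except KeyError:
            available = ", ".join(str(k) for k in sorted(self.entries)) or "none"
            raise CalibrationError(
                f"no calibration entry for {kvp} kVp (available: {available})"
            ) from None

    def __contains__(self, kvp: int) -> bool:
        return kvp in self.entries

    def __iter__(self) -> Iterator[CalibrationEntry]:
        return iter(self.entries[k] for k in sorted(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    # -- serialization ----------------------------------------------------

    def to_yaml(self, stream: Union[str, IO[str], None] = None):
        """Serialize to YAML; returns the string when ``stream`` is None."""
        doc = {
            "calibration": {
                int(e.kvp): {
                    "ctn_mar": float(e.ctn_mar),
                    "ctn_mar_sd": float(e.ctn_mar_sd),
                    "ctn_cor": float(e.ctn_cor),
                    "ctn_cor_sd": float(e.ctn_cor_sd),
                    "rho_cor": float(e.rho_cor),
                }
                for e in self
            }
        }
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                yaml.safe_dump(doc, fh, sort_keys=True)
            return None
        return yaml.safe_dump(doc, stream, sort_keys=True)

    @classmethod
    def from_yaml(cls, source: Union[str, IO[str]]) -> "CalibrationTable":
        """Load from a YAML path, YAML string, or open stream."""
        if isinstance(source, str):
            try:
                with open(source) as fh:
                    doc = yaml.safe_load(fh)
            except (FileNotFoundError, OSError):
                doc = yaml.safe_load(source)
        else:
            doc = yaml.safe_load(source)
        if not isinstance(doc, Mapping) or "calibration" not in doc:
            raise CalibrationError("calibration file must have a 'calibration' mapping")
        table = cls()
        for kvp, block in doc["calibration"].items():
            table.add(CalibrationEntry(kvp=int(kvp), **block))
        return table


def default_calibration() -> CalibrationTable:
    """Reference calibration measured on a 16-slice scanner at 80/100/120 kVp.

    Water vial means were -11.1, 2.1 and 8.7 HU and the 0.533 g/cm^3
    cortical-equivalent phantom read 982.2, 830.0 and 739.5 HU respectively.
    """
    table = CalibrationTable()
    table.add(CalibrationEntry(80, -11.1, 982.2, 0.533, 30.3, 41.4))
    table.add(CalibrationEntry(100, 2.1, 830.0, 0.533, 23.7, 27.2))
    table.add(CalibrationEntry(120, 8.7, 739.5, 0.533, 13.8, 16.4))
    return table


def volume_fraction(ctn_mix, ctn_a: float, ctn_b: float):
    """Volume fraction of material *a* in a two-material mixture.

    The defining ratio is between linear attenuation coefficients,
    ``(CTN/1000 + 1)`` each; the offsets cancel, leaving
    ``(ctn_mix - ctn_b) / (ctn_a - ctn_b)``.  The raw (unclamped) value is
    returned; fractions outside [0, 1] indicate a voxel outside the
    calibrated density range and are the caller's to handle.
    """
    ctn_mix = np.asarray(ctn_mix, dtype=float)
    if not (np.isfinite(ctn_mix).all() and np.isfinite([ctn_a, ctn_b]).all()):
        raise ValueError("CT numbers must be finite")
    if ctn_a == ctn_b:
        raise CalibrationError(
            f"unusable calibration: reference CT numbers coincide ({ctn_a} HU)"
        )
    out = (ctn_mix - ctn_b) / (ctn_a - ctn_b)
    return out if out.ndim else float(out)


def weight_fraction(v_a, rho_a: float, rho_mix: float):
    """Weight fraction of material *a*: ``v_a * rho_a / rho_mix``."""
    if rho_a <= 0 or rho_mix <= 0:
        raise ValueError(f"densities must be positive (rho_a={rho_a}, rho_mix={rho_mix})")
    v_a = np.asarray(v_a, dtype=float)
    out = v_a * rho_a / rho_mix
    return out if out.ndim else float(out)


@dataclass
class DensityMap:
    """Per-voxel BVF and vBMD aligned with the source CT array.

    ``bvf`` is dimensionless, ``vbmd`` in g/cm^3; ``clamped_mask`` is True
    exactly where the raw BVF fell outside [0, 1] (all False when clamping
    was not requested).
    """

    bvf: np.ndarray
    vbmd: np.ndarray
    clamped_mask: np.ndarray
    calibration: CalibrationEntry

    @property
    def vbmd_scalar(self) -> float:
        """The vBMD as a float, valid for scalar (0-d) conversions."""
        return float(self.vbmd)


def ctn_to_bvf_vbmd(
    ctn_mix, calib: CalibrationEntry, clamp: bool = False
) -> DensityMap:
    """Convert CT numbers to BVF and vBMD maps via the TCM inversion.

    Element-wise and affine in ``ctn_mix``: converting an ROI mean is
    identical to averaging a converted ROI.  With ``clamp`` the BVF is
    clipped to [0, 1] and offending voxels recorded in ``clamped_mask``;
    by default raw values are kept (voxels denser than the calibration
    phantom legitimately yield BVF > 1).
    """
    bvf = np.asarray(
        volume_fraction(ctn_mix, calib.ctn_cor, calib.ctn_mar), dtype=float
    )
    clamped = (bvf < 0.0) | (bvf > 1.0)
    if clamp:
        bvf = np.clip(bvf, 0.0, 1.0)
    vbmd = bvf * calib.rho_cor
    return DensityMap(bvf=bvf, vbmd=vbmd, clamped_mask=clamped, calibration=calib)


@dataclass(frozen=True)
class DiagnosticClass:
    """ACR-threshold bone-density class for a volumetric BMD value."""

    label: str  # normal | osteopenia | osteoporosis
    vbmd_mg_cm3: float


def classify_acr(vbmd: float) -> DiagnosticClass:
    """Classify a vBMD (g/cm^3) against the ACR QCT cut-offs.

    Osteoporosis below 80 mg/cm^3 (strict), osteopenia on the closed
    interval [80, 120] mg/cm^3, normal above.
    """
    vbmd = float(vbmd)
    if not np.isfinite(vbmd) or vbmd < 0:
        raise ValueError(f"vBMD must be finite and non-negative, got {vbmd}")
    mg = vbmd * 1000.0
    if mg < OSTEOPOROSIS_THRESHOLD_MG:
        label = "osteoporosis"
    elif mg <= OSTEOPENIA_THRESHOLD_MG:
        label = "osteopenia"
    else:
        label = "normal"
    return DiagnosticClass(label=label, vbmd_mg_cm3=mg)
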