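"""Domain types: phantom, detector, beam, exposure and the Image container.

Units are canonical throughout the package: lengths in mm (pixel pitch is
carried in um because that is how detector data sheets quote it), dose in
mGy, tube loading in mAs, signal in detector counts.

Coordinate convention (enforced package-wide): axis 0 (rows) runs from the
chest-wall edge (row 0) toward the nipple side; axis 1 (cols) is lateral.
All ROIs are 0-based and half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError, GeometryError

__all__ = [
    "Insert",
    "PhantomSpec",
    "HeelProfile",
    "DetectorSpec",
    "BeamSpec",
    "ExposureSettings",
    "Image",
]


@dataclass(frozen=True)
class Insert:
    """A thin radiopaque plate resting on the PMMA slab.

    The rectangle is centred at (center_row_mm, center_col_mm) in detector
    coordinates and may be rotated by a few degrees so its edges can serve
    as slanted edges for presampled-MTF estimation.
    """

    material: str
    height_mm: float  # extent along the chest-wall -> nipple axis (rows)
    width_mm: float   # lateral extent (cols)
    thickness_mm: float
    center_row_mm: float
    center_col_mm: float
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.height_mm <= 0 or self.width_mm <= 0 or self.thickness_mm <= 0:
            raise GeometryError(f"{self.material} insert dimensions must be positive")

    def corners_mm(self) -> np.ndarray:
        """Corner coordinates (4, 2) as (row_mm, col_mm) after rotation."""
        h2, w2 = self.height_mm / 2.0, self.width_mm / 2.0
        local = np.array([[-h2, -w2], [-h2, w2], [h2, w2], [h2, -w2]])
        a = math.radians(self.rotation_deg)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        return local @ rot.T + np.array([self.center_row_mm, self.center_col_mm])

    def contains(self, row_mm: np.ndarray, col_mm: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (rotated) rectangle."""
        a = math.radians(self.rotation_deg)
        dr = np.asarray(row_mm) - self.center_row_mm
        dc = np.asarray(col_mm) - self.center_col_mm
        u = dr * math.cos(a) + dc * math.sin(a)     # along height
        v = -dr * math.sin(a) + dc * math.cos(a)    # along width
        return (np.abs(u) <= self.height_mm / 2.0) & (np.abs(v) <= self.width_mm / 2.0)


@dataclass(frozen=True)
class PhantomSpec:
    """The QC phantom: a uniform PMMA slab optionally carrying Cu and Al plates.

    The reference design is a 24 x 30 cm^2, 4.5 cm thick PMMA plate with a
    5 x 5 cm^2 / 1 mm Cu square (implant surrogate) and a 1 x 1 cm^2 /
    0.2 mm Al square (microcalcification-contrast target). The desk-scale
    default shrinks the lateral layout while preserving the pixel footprint
    of every analysis ROI.
    """

    pmma_thickness_mm: float
    lateral_size_mm: tuple[float, float]  # (rows extent, cols extent)
    cu: Optional[Insert] = None
    al: Optional[Insert] = None

    def __post_init__(self) -> None:
        if self.pmma_thickness_mm <= 0:
            raise GeometryError("PMMA thickness must be positive")
        if any(s <= 0 for s in self.lateral_size_mm):
            raise GeometryError("lateral extent must be positive")
        for ins in self.inserts:
            c = ins.corners_mm()
            if (c[:, 0].min() < 0 or c[:, 1].min() < 0
                    or c[:, 0].max() > self.lateral_size_mm[0]
                    or c[:, 1].max() > self.lateral_size_mm[1]):
                raise GeometryError(
                    f"{ins.material} insert extends outside the phantom lateral extent")
        if self.cu is not None and self.al is not None:
            if _rectangles_overlap(self.cu, self.al):
                raise GeometryError("Cu and Al inserts overlap")

    @property
    def inserts(self) -> tuple[Insert, ...]:
        return tuple(i for i in (self.cu, self.al) if i is not None)

    def without_inserts(self) -> "PhantomSpec":
        return replace(self, cu=None, al=None)


def _rectangles_overlap(a: Insert, b: Insert) -> bool:
    # Conservative separating-axis test on the corner hulls.
    ca, cb = a.corners_mm(), b.corners_mm()
    for rect in (a, b):
        ang = math.radians(rect.rotation_deg)
        for axis in (np.array([math.cos(ang), math.sin(ang)]),
                     np.array([-math.sin(ang), math.cos(ang)])):
            pa, pb = ca @ axis, cb @ axis
            if pa.max() <= pb.min() or pb.max() <= pa.min():
                return False
    return True


@dataclass(frozen=True)
class HeelProfile:
    """Multiplicative field non-uniformity along the chest-wall -> nipple axis.

    The axial profile is a sequence of flat ``plateaus`` — (t_start, t_end,
    level) in row-fraction coordinates — joined by C^1 smoothstep
    transitions, a stylised anode-heel shape: the intensity is locally flat
    where the uniformity ROIs sit and the drop toward the nipple side is
    concentrated between them (so ROI statistics measure noise, not the
    deterministic ramp). ``tilt_chest``/``tilt_nipple`` add a small lateral
    gradient interpolating linearly between the two image ends. The field
    is normalised so its maximum is exactly 1, keeping the multiplier in
    (0, 1] everywhere.
    """

    plateaus: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.15, 1.112), (0.42, 0.60, 1.0), (0.85, 1.0, 0.54))
    tilt_chest: float = 0.058
    tilt_nipple: float = 0.087
    amplitude: float = 1.0  # 0 disables the profile (uniform field)

    def axial(self, t: np.ndarray) -> np.ndarray:
        """Plateau-and-smoothstep axial profile at row fractions ``t``."""
        t = np.asarray(t, dtype=np.float64)
        out = np.empty_like(t)
        p = self.plateaus
        out[t <= p[0][1]] = p[0][2]
        out[t >= p[-1][0]] = p[-1][2]
        for t0, t1, v in p:
            out[(t >= t0) & (t <= t1)] = v
        for (t0, t1, v0), (t2, t3, v1) in zip(p[:-1], p[1:]):
            sel = (t > t1) & (t < t2)
            u = (t[sel] - t1) / (t2 - t1)
            out[sel] = v0 + (v1 - v0) * u * u * (3.0 - 2.0 * u)
        return out

    def field(self, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate the normalised heel multiplier on an (n_rows, n_cols) grid."""
        n_rows, n_cols = shape
        t = np.linspace(0.0, 1.0, n_rows)[:, None]
        c = np.linspace(0.0, 1.0, n_cols)[None, :]
        tilt = self.tilt_chest + (self.tilt_nipple - self.tilt_chest) * t
        f = self.axial(t) * (1.0 + tilt * (c - 0.5))
        f = f / f.max()
        # amplitude scales the deviation from flatness, not the field itself
        f = 1.0 + self.amplitude * (f - 1.0)
        if f.min() <= 0:
            raise ConfigurationError("heel profile multiplier must stay positive")
        return f


@dataclass(frozen=True)
class DetectorSpec:
    """Amorphous-selenium flat-panel model (linear gain + blur + noise).

    quantum_gain is the variance-per-signal factor of the quantum noise
    branch: Var_q = quantum_gain * (mean - dc_offset). electronic_noise_sd
    is the additive read-noise sigma in counts. psf_sigma_mm is the Gaussian
    presampling blur of the mean signal.
    """

    area_mm: tuple[float, float] = (44.8, 35.84)  # (rows extent, cols extent)
    pitch_um: float = 70.0
    dc_offset: float = 50.0
    gain: float = 84.0                 # counts per mAs at unit transmission
    quantum_gain: float = 0.16
    electronic_noise_sd: float = 2.0
    psf_sigma_mm: float = 0.04
    heel: HeelProfile = field(default_factory=HeelProfile)

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ConfigurationError("pixel pitch must be positive")
        if self.gain <= 0:
            raise ConfigurationError("gain must be positive")
        if self.dc_offset < 0:
            raise ConfigurationError("DC offset must be non-negative")
        if self.quantum_gain < 0 or self.electronic_noise_sd < 0:
            raise ConfigurationError("noise parameters must be non-negative")

    @property
    def pitch_mm(self) -> float:
        return self.pitch_um / 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        return (int(round(self.area_mm[0] / self.pitch_mm)),
                int(round(self.area_mm[1] / self.pitch_mm)))

    @property
    def nyquist_mm(self) -> float:
        """Nyquist frequency in cycles/mm (7.14 mm^-1 at 70 um pitch)."""
        return 1.0 / (2.0 * self.pitch_mm)


@dataclass(frozen=True)
class BeamSpec:
    """Monoenergetic-equivalent beam: effective attenuation per material.

    mu maps material name -> effective linear attenuation in mm^-1. These
    are *effective* values chosen so the realised image contrast and the
    AEC compensation behaviour match a clinical W/Rh mammography beam; they
    are deliberately far from narrow-beam monoenergetic coefficients
    (beam hardening and scatter strongly reduce effective contrast).
    """

    kvp: float = 28.0
    target_filter: str = "W/Rh"
    mu: dict = field(default_factory=lambda: {"PMMA": 0.060, "Cu": 0.654, "Al": 0.60})
    tube_output_mgy_per_mas: float = 0.0185  # air kerma at 1 m per mAs
    hvl_mm_al: float = 0.53
    source_to_detector_mm: float = 700.0
    breast_support_mm: float = 25.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.mu.values()):
            raise ConfigurationError("attenuation coefficients must be non-negative")
        if self.tube_output_mgy_per_mas <= 0 or self.hvl_mm_al <= 0:
            raise ConfigurationError("tube output and HVL must be positive")

    def mu_of(self, material: str) -> float:
        try:
            return self.mu[material]
        except KeyError:
            raise ConfigurationError(f"no attenuation coefficient for material {material!r}")


@dataclass(frozen=True)
class ExposureSettings:
    """kVp/mAs/mode triple; aec_position is set iff mode == 'automatic'."""

    kvp: float
    mas: float
    mode: str = "manual"  # "automatic" | "manual"
    aec_position: Optional[int] = None
    mas_reduction_level: int = 0

    def __post_init__(self) -> None:
        if self.mas < 0:
            raise ConfigurationError("mAs must be non-negative")
        if self.mode not in ("automatic", "manual"):
            raise ConfigurationError(f"unknown exposure mode {self.mode!r}")
        if self.mode == "automatic":
            if self.aec_position is None or not 1 <= int(self.aec_position) <= 7:
                raise ConfigurationError("automatic mode requires an AEC position in 1..7")
        elif self.aec_position is not None:
            raise ConfigurationError("manual mode must not carry an AEC position")
        if self.mas_reduction_level < 0:
            raise ConfigurationError("mas_reduction_level must be >= 0")


@dataclass
class Image:
    """A linear 'for processing' acquisition: pixel grid + acquisition metadata."""

    pixels: np.ndarray
    pitch_um: float
    dc_offset: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise GeometryError("Image pixels must be a 2D grid")
        if self.pixels.min() < 0:
            raise GeometryError("Image pixels must be non-negative")
        if self.pitch_um <= 0:
            raise ConfigurationError("pixel pitch must be positive")

    @property
    def pitch_mm(self) -> float:
        return self.pitch_um / 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
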