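"""Run configuration: default phantom/detector/beam layouts and YAML loading.

Two built-in scales exist. "test" is the desk-scale default: a 640 x 512
pixel frame (44.8 x 35.84 mm at 70 um pitch) whose insert layout is shrunk
from the reference phantom while preserving the *pixel* footprint of every
analysis ROI, so that ROI statistics transfer between scales. "full" is the
24 x 29 cm detector at 70 um pitch with the reference phantom geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import ConfigurationError
from .specs import BeamSpec, DetectorSpec, HeelProfile, Insert, PhantomSpec

__all__ = ["AecConfig", "AnalysisGeometry", "RunConfig", "default_config", "load_config"]


@dataclass(frozen=True)
class AecConfig:
    """AEC servo parameters: sensor footprint table, target signal, quanta.

    Sensor footprints are rectangles on the chest-wall -> nipple axis; the
    servo is flat-field calibrated per position (the heel profile is divided
    out of the sensor reading), which is what makes a uniform phantom yield
    the same mAs at every position, as a clinical unit does.
    """

    target_counts: float = 500.0        # target mean signal above DC offset
    mas_quantum: float = 0.5
    mas_cap: float = 500.0
    sensor_row_centers_mm: tuple[float, ...] = (3.0, 8.0, 13.0, 18.0, 23.0, 28.0, 33.0)
    sensor_height_mm: float = 3.2
    sensor_width_mm: float = 4.6
    sensor_col_center_mm: float = 17.92
    # kVp by compressed thickness: (upper bound mm inclusive, kVp); 28 kVp for
    # the 40-50 mm band, stepping up beyond it.
    kvp_table: tuple[tuple[float, float], ...] = (
        (30.0, 26.0), (40.0, 27.0), (50.0, 28.0), (60.0, 29.0),
        (70.0, 31.0), (200.0, 32.0))

    def kvp_for_thickness(self, thickness_mm: float) -> float:
        for upper, kvp in self.kvp_table:
            if thickness_mm <= upper:
                return kvp
        raise ConfigurationError(f"thickness {thickness_mm} mm outside kVp table")

    def sensor_bounds_mm(self, position: int) -> tuple[float, float, float, float]:
        """(row0, row1, col0, col1) of the footprint for a 1-based position."""
        if not 1 <= int(position) <= len(self.sensor_row_centers_mm):
            raise ConfigurationError(f"AEC position must be in 1..7, got {position}")
        rc = self.sensor_row_centers_mm[int(position) - 1]
        cc = self.sensor_col_center_mm
        return (rc - self.sensor_height_mm / 2, rc + self.sensor_height_mm / 2,
                cc - self.sensor_width_mm / 2, cc + self.sensor_width_mm / 2)


@dataclass(frozen=True)
class AnalysisGeometry:
    """Where the analysis ROIs and edge/noise regions sit, in mm.

    al_roi / bg_roi are (center_row, center_col, side) squares; the edge
    bands bracket the interior Cu edges; nps_region is (row0, col0, size)
    of the homogeneous square used for the noise power spectrum.
    """

    al_roi_mm: tuple[float, float, float]
    bg_roi_mm: tuple[float, float, float]
    h_edge_band_mm: tuple[float, float, float, float]  # row0, row1, col0, col1
    v_edge_band_mm: tuple[float, float, float, float]
    nps_region_mm: tuple[float, float, float]
    corner_roi_px: int       # standard five-ROI size in pixels
    corner_margin_px: int = 16
    nps_roi_px: int = 64     # NPS sub-ROI size (stride is half of this)


@dataclass(frozen=True)
class RunConfig:
    scale: str
    phantom: PhantomSpec
    detector: DetectorSpec
    beam: BeamSpec
    aec: AecConfig
    geometry: AnalysisGeometry
    supersample: int = 4
    recommended_mas: float = 120.0      # manufacturer's manual setting, 4-6 cm
    mas_reduction_fraction: float = 0.13  # first console reduction level
    flat_field_pmma_mm: float = 40.0
    reference_aec_position: int = 4

    def with_heel_amplitude(self, amplitude: float) -> "RunConfig":
        det = replace(self.detector, heel=replace(self.detector.heel, amplitude=amplitude))
        return replace(self, detector=det)


def _test_scale() -> RunConfig:
    detector = DetectorSpec()
    phantom = PhantomSpec(
        pmma_thickness_mm=45.0,
        lateral_size_mm=detector.area_mm,
        cu=Insert("Cu", height_mm=13.0, width_mm=24.0, thickness_mm=1.0,
                  center_row_mm=7.2, center_col_mm=18.0, rotation_deg=3.0),
        al=Insert("Al", height_mm=6.0, width_mm=6.0, thickness_mm=0.2,
                  center_row_mm=24.0, center_col_mm=11.0),
    )
    geometry = AnalysisGeometry(
        al_roi_mm=(24.0, 11.0, 4.48),
        bg_roi_mm=(24.0, 22.0, 4.48),
        h_edge_band_mm=(11.0, 16.5, 9.0, 27.0),
        v_edge_band_mm=(2.0, 12.0, 3.5, 9.0),
        nps_region_mm=(30.0, 13.44, 8.96),
        corner_roi_px=64,
        nps_roi_px=64,
    )
    return RunConfig(scale="test", phantom=phantom, detector=detector,
                     beam=BeamSpec(), aec=AecConfig(), geometry=geometry)


def _full_scale() -> RunConfig:
    detector = DetectorSpec(area_mm=(290.0, 240.0))
    phantom = PhantomSpec(
        pmma_thickness_mm=45.0,
        lateral_size_mm=(300.0, 240.0),
        cu=Insert("Cu", height_mm=50.0, width_mm=50.0, thickness_mm=1.0,
                  center_row_mm=27.0, center_col_mm=120.0, rotation_deg=3.0),
        al=Insert("Al", height_mm=10.0, width_mm=10.0, thickness_mm=0.2,
                  center_row_mm=150.0, center_col_mm=90.0),
    )
    aec = AecConfig(
        sensor_row_centers_mm=(12.0, 30.0, 48.0, 66.0, 84.0, 102.0, 120.0),
        sensor_height_mm=20.0, sensor_width_mm=30.0, sensor_col_center_mm=120.0)
    geometry = AnalysisGeometry(
        al_roi_mm=(150.0, 90.0, 8.96),
        bg_roi_mm=(150.0, 150.0, 8.96),
        h_edge_band_mm=(48.0, 58.0, 100.0, 140.0),
        v_edge_band_mm=(6.0, 46.0, 90.0, 100.0),
        nps_region_mm=(180.0, 102.0, 35.84),
        corner_roi_px=256,
        nps_roi_px=256,
    )
    return RunConfig(scale="full", phantom=phantom, detector=detector,
                     beam=BeamSpec(), aec=aec, geometry=geometry,
                     supersample=1)


def default_config(scale: str = "test") -> RunConfig:
    """Built-in configuration at the requested scale ("test" or "full")."""
    if scale == "test":
        return _test_scale()
    if scale == "full":
        return _full_scale()
    raise ConfigurationError(f"unknown scale {scale!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML override file on top of the built-in defaults.

    The file may set ``scale`` plus any subset of the block fields
    (phantom, detector, beam, aec, run); unspecified values keep their
    defaults. Seeds never live in the config; they are explicit arguments.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    cfg = default_config(raw.get("scale", "test"))
    if "detector" in raw:
        det = raw["detector"]
        heel = det.pop("heel", None)
        detector = replace(cfg.detector, **det)
        if heel is not None:
            if "plateaus" in heel:
                heel["plateaus"] = tuple(tuple(a) for a in heel["plateaus"])
            detector = replace(detector, heel=replace(detector.heel, **heel))
        cfg = replace(cfg, detector=detector)
    if "beam" in raw:
        cfg = replace(cfg, beam=replace(cfg.beam, **raw["beam"]))
    if "phantom" in raw:
        ph = dict(raw["phantom"])
        for key in ("cu", "al"):
            if key in ph and ph[key] is not None:
                ph[key] = Insert(**ph[key])
        if "lateral_size_mm" in ph:
            ph["lateral_size_mm"] = tuple(ph["lateral_size_mm"])
        cfg = replace(cfg, phantom=replace(cfg.phantom, **ph))
    if "aec" in raw:
        aec = dict(raw["aec"])
        for key in ("sensor_row_centers_mm", "kvp_table"):
            if key in aec:
                aec[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                                 for x in aec[key])
        cfg = replace(cfg, aec=replace(cfg.aec, **aec))
    if "run" in raw:
        cfg = replace(cfg, **raw["run"])
    return cfg
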