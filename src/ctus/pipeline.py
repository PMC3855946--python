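"""End-to-end simulation: enhance -> slice -> rectangle -> propagate ->
integrate -> sector -> scale -> write.

Each stage is an importable library call; `simulate` only chains them,
derives per-module seeds from the master seed, and reports per-stage wall
times at high verbosity.  Stage errors propagate with the stage name
attached.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import acoustic_model, sector_geometry, transducer_array, vessel_enhance
from .config import SimulationConfig
from .sector_geometry import ScanlineSet, SliceImage
from .volume_io import CTVolume, UltrasoundImage, read_volume, write_image, write_volume

__all__ = ["simulate", "simulate_volume", "SimulationResult"]

log = logging.getLogger("ctus")


@dataclass
class SimulationResult:
    """Final frame plus the intermediates useful for inspection."""

    image: UltrasoundImage
    rect: Optional[ScanlineSet] = None
    echo: Optional[np.ndarray] = None
    integrated: Optional[np.ndarray] = None
    vesselness_rect: Optional[np.ndarray] = None
    enhanced: Optional[vessel_enhance.EnhancedVolume] = None
    slice_image: Optional[SliceImage] = None
    timings: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """Wraps an exception with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


class _Stage:
    def __init__(self, name: str, timings: dict, verbosity: int):
        self.name = name
        self.timings = timings
        self.verbosity = verbosity

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.timings[self.name] = dt
        if self.verbosity > 0:
            print(f"[ctus] {self.name}: {dt:.3f} s", file=sys.stderr)
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(self.name, exc) from exc
        return False


def simulate_volume(volume: CTVolume, config: SimulationConfig) -> SimulationResult:
    """Run the full chain on an in-memory volume; deterministic per seed."""
    cfg = config.with_derived_seeds()
    timings: dict = {}
    v = cfg.verbosity

    with _Stage("enhance", timings, v):
        if cfg.enhance:
            enhanced = vessel_enhance.enhance_volume(
                volume, cfg.vesselness, cfg.blend_weight, cfg.vessel_intensity_shift
            )
            work = enhanced.blended
            # anechoic rendering uses the regularized modulation field
            nu_vol = volume.copy_with(enhanced.modulation, unit_tag="raw")
        else:
            enhanced = None
            work = volume
            nu_vol = None

    with _Stage("slice", timings, v):
        slice_img = sector_geometry.extract_sector_slice(
            work, cfg.pose, cfg.geometry, pitch=cfg.slice_pitch
        )
        geometry = slice_img.geometry  # apex at (0, 0) in slice frame
        nu_slice = None
        if nu_vol is not None:
            nu_slice = sector_geometry.extract_sector_slice(
                nu_vol, cfg.pose, cfg.geometry, pitch=cfg.slice_pitch, background=0.0
            )

    with _Stage("tps", timings, v):
        forward, inverse = sector_geometry.fit_sector_transforms(
            geometry, control=cfg.control_lattice, lambda_reg=cfg.tps_lambda
        )

    with _Stage("rectangle", timings, v):
        rect = sector_geometry.resample_to_rectangle(slice_img, geometry, forward)
        nu_rect = None
        if nu_slice is not None:
            nu_rect = np.clip(
                sector_geometry.resample_to_rectangle(
                    nu_slice, geometry, forward, cval=0.0
                ).rect,
                0.0, 1.0,
            )

    with _Stage("propagate", timings, v):
        echo = acoustic_model.propagate_all(rect, nu_rect, cfg.acoustics)

    with _Stage("integrate", timings, v):
        integrated = transducer_array.integrate_elements(echo, cfg.array)
        integrated = transducer_array.radial_blur(integrated, cfg.array.radial_blur_len)

    with _Stage("sector", timings, v):
        sector_img, mask, origin, pitch = sector_geometry.map_to_sector(
            integrated, geometry, inverse, pitch=cfg.sector_pitch
        )

    with _Stage("scale", timings, v):
        pixels = transducer_array.linear_scale_256(sector_img)
        pixels[~mask] = 0
        image = UltrasoundImage(
            pixels=pixels, geometry=geometry, mask=mask,
            origin=origin, pitch=pitch,
            meta={"seed": cfg.seed, "frequency_mhz": cfg.frequency_mhz},
        )

    return SimulationResult(
        image=image, rect=rect, echo=echo, integrated=integrated,
        vesselness_rect=nu_rect, enhanced=enhanced, slice_image=slice_img,
        timings=timings,
    )


def simulate(config: SimulationConfig, dump_intermediates: bool = False) -> UltrasoundImage:
    """File-to-file entry point: read input, run the chain, write the PNG."""
    if config.input is None:
        raise ValueError("config.input must point at a CT volume")
    volume = read_volume(config.input)
    result = simulate_volume(volume, config)
    if config.output:
        write_image(result.image, config.output)
        if dump_intermediates:
            from pathlib import Path

            stem = Path(config.output)
            base = stem.with_suffix("")
            np.save(f"{base}_rect.npy", result.rect.rect)
            np.save(f"{base}_echo.npy", result.echo)
            np.save(f"{base}_integrated.npy", result.integrated)
    return result.image
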