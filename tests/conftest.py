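"""Shared fixtures: phantoms and one full abdominal simulation per session."""

import dataclasses

import numpy as np
import pytest

import ctus
from ctus.config import abdominal_simulation_config
from ctus import sector_geometry as sg


@pytest.fixture(scope="session")
def abdominal():
    """(volume, masks) of the canonical abdominal phantom, seed 0."""
    return ctus.make_abdominal_phantom(seed=0)


@pytest.fixture(scope="session")
def abdominal_sim(abdominal):
    """Full simulation of the abdominal phantom plus rect-domain truth masks."""
    vol, masks = abdominal
    cfg = abdominal_simulation_config(seed=1)
    result = ctus.simulate_volume(vol, cfg)
    geometry = result.slice_image.geometry
    forward, inverse = sg.fit_sector_transforms(geometry, control=cfg.control_lattice)

    def rect_mask(name):
        mvol = vol.copy_with(masks[name].astype(float), unit_tag="raw")
        sl = sg.extract_sector_slice(
            mvol, cfg.pose, cfg.geometry, pitch=cfg.slice_pitch, background=0.0
        )
        return sg.resample_to_rectangle(sl, geometry, forward, cval=0.0).rect > 0.5

    rect_masks = {k: rect_mask(k) for k in ("vessel", "liver", "bone")}
    return {
        "volume": vol,
        "masks": masks,
        "config": cfg,
        "result": result,
        "rect_masks": rect_masks,
        "inverse": inverse,
    }


@pytest.fixture(scope="session")
def abdominal_sim_off(abdominal, abdominal_sim):
    """Same acquisition with vessel enhancement disabled."""
    vol, _ = abdominal
    cfg = dataclasses.replace(abdominal_sim["config"], enhance=False)
    return ctus.simulate_volume(vol, cfg)


@pytest.fixture(scope="session")
def cylinder_fixture():
    """Noise-free radius-4 mm tube along z in a 64^3 volume."""
    return ctus.make_cylinder_volume(
        dims=(64, 64, 64), radius=4.0, axis="z", inside_val=100.0, outside_val=0.0
    )
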