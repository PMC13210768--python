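"""Shared fixtures: small, fast synthetic scenes for pipeline tests."""

import math

import numpy as np
import pytest

from fibersense import detect, synth


@pytest.fixture
def criteria():
    return detect.CountingCriteria()


def make_fiber(x, y, length=10.0, width=1.0, orientation=0.0, z=6.0, intensity=150.0,
               curvature=0.0):
    return synth.FiberTruth(
        centroid_xy=(x, y), length=length, width=width, orientation=orientation,
        curvature=curvature, z_depth=z, intensity=intensity,
    )


def quiet_scene(fibers=(), particles=(), field=(100.0, 80.0), pixel_size=0.5,
                background=20.0, noise=True, seed=0):
    """Scene with controlled objects; noise can be switched off entirely."""
    return synth.SceneSpec(
        field_size_xy=field,
        pixel_size=pixel_size,
        fibers=list(fibers),
        particles=list(particles),
        background_level=background,
        background_texture_scale=5.0 if background > 0 else 0.0,
        gaussian_sd=0.4 if noise else 0.0,
        poisson_gain=1.0 if noise else 0.0,
        seed=seed,
    )


def recovery_params(pixel_size=0.66):
    """High-SNR full-field conditions with clearly countable fiber geometry."""
    return synth.SceneParams(
        expected_fibers=10.0,
        expected_particles=30.0,
        field_size_xy=(660.0, 440.0),
        pixel_size=pixel_size,
        fiber_length_log_mean=math.log(11.0),
        fiber_length_log_sd=0.28,
        fiber_width_log_mean=math.log(1.0),
        fiber_width_log_sd=0.2,
        fiber_intensity_log_mean=math.log(150.0),
        fiber_intensity_log_sd=0.2,
        particle_intensity_log_mean=math.log(100.0),
        particle_intensity_log_sd=0.3,
    )


@pytest.fixture
def small_stack_spec():
    return synth.StackSpec(n_planes=9, z_step=2.0)
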