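"""Shared fixtures: phantom renders at several scales.

Expensive renders are session-scoped and shared across test modules; the
full-length default sequence is only built when a test requests it.
"""

from __future__ import annotations

import numpy as np
import pytest

from ustongue.contour import track_sequence
from ustongue.phantom import DeformationModel, ImagingConfig, PhantomGeometry, render_sequence
from ustongue.protocol import MotionProtocol


@pytest.fixture(scope="session")
def small_run():
    """Short compression + one small stroke; ~200 frames."""
    proto = MotionProtocol(compression_amplitude=5.0, shear_amplitudes=(2.0,), rest_duration=0.5)
    stack, truth, forces = render_sequence(
        proto, DeformationModel(), ImagingConfig(seed=2), density=6.0
    )
    return proto, stack, truth, forces


@pytest.fixture(scope="session")
def small_table(small_run):
    _, stack, _, _ = small_run
    return track_sequence(stack)


@pytest.fixture(scope="session")
def stickslip_run():
    """Reduced-amplitude stick-slip sequence; ~470 frames."""
    proto = MotionProtocol(compression_amplitude=6.0, shear_amplitudes=(3.0, 3.0), rest_duration=1.0)
    model = DeformationModel(static_friction_threshold=1.2)
    stack, truth, forces = render_sequence(proto, model, ImagingConfig(seed=5))
    return proto, model, stack, truth, forces


@pytest.fixture(scope="session")
def static_run():
    """Zero-amplitude protocol: nothing moves."""
    proto = MotionProtocol(compression_amplitude=0.0, shear_amplitudes=(), rest_duration=1.0)
    stack, truth, forces = render_sequence(
        proto, DeformationModel(), ImagingConfig(seed=7), density=6.0
    )
    return proto, stack, truth, forces


@pytest.fixture(scope="session")
def default_run():
    """The full default sequence with ground truth (expensive; acceptance)."""
    proto = MotionProtocol()
    model = DeformationModel()
    stack, truth, forces = render_sequence(proto, model, ImagingConfig(seed=11))
    return proto, model, stack, truth, forces


@pytest.fixture(scope="session")
def default_table(default_run):
    _, _, stack, _, _ = default_run
    return track_sequence(stack)
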