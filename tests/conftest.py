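"""Shared fixtures: small synthetic phantom scenes for fast pipeline tests."""

from __future__ import annotations

import numpy as np
import pytest

from cdqa.io import FrameStack, extract_us_image
from cdqa.phantom import ArtifactSpec, FlowSpec, PhantomSpec, simulate_bmode, simulate_cd_video
from cdqa.preprocess import make_average_images


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Horizontal-vessel scene at reduced resolution (fast to render)."""
    return PhantomSpec(
        vessel_depth_mm=15.0,
        vessel_angle_deg=0.0,
        fov_cm=5.0,
        image_shape=(240, 320),
        fr_duplex=10.0,
        fr_bmode=40.0,
    )


@pytest.fixture(scope="session")
def diag_spec() -> PhantomSpec:
    """Deeper-field scene used for the velocity parameters."""
    return PhantomSpec(
        vessel_depth_mm=40.0,
        vessel_angle_deg=0.0,
        fov_cm=12.0,
        image_shape=(480, 640),
    )


def masked_stack(stack) -> FrameStack:
    layout = stack.meta.layout
    frames = [extract_us_image(f, layout) for f in stack.frames]
    return FrameStack(frames=frames, frame_period=stack.frame_period, meta=stack.meta)


def averages(stack, N=6, M=None, th_sat=0.35):
    base = masked_stack(stack)
    M = M or base.n_fr // N
    return make_average_images(base, N, M, th_sat=th_sat, color_only=True)


@pytest.fixture(scope="session")
def clean_video(small_spec):
    """Artifact-free constant-flow video + ground truth."""
    return simulate_cd_video(small_spec, FlowSpec(Q=6.0), ArtifactSpec(), n_fr=30, seed=101)


@pytest.fixture(scope="session")
def blind_zone_video(small_spec):
    return simulate_cd_video(
        small_spec,
        FlowSpec(Q=6.0),
        ArtifactSpec(blind_zone_width_mm=3.0),
        n_fr=30,
        seed=102,
    )


@pytest.fixture(scope="session")
def bleed_video(small_spec):
    return simulate_cd_video(
        small_spec,
        FlowSpec(Q=6.0),
        ArtifactSpec(bleed_rate=0.4),
        n_fr=30,
        seed=103,
    )


@pytest.fixture(scope="session")
def bmode_image(small_spec):
    return simulate_bmode(small_spec, seed=104)
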