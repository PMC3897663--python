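"""Shared fixtures: small synthetic stacks and deterministic RNGs."""

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tubeorient as to
from tubeorient.synthetic import NoiseModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(**overrides):
    """A fast, small synthetic spec used across unit tests."""
    base = dict(
        field_size_px=(192, 192),
        n_slices=60,
        seed=7,
    )
    base.update(overrides)
    return dataclasses.replace(to.preset_scenarios()["ureter_like"], **base)


@pytest.fixture
def clean_spec():
    """Noiseless, clutter-free, all-elongated spec (detection oracle)."""
    return small_spec(
        noise=NoiseModel(0.0, 0.0),
        clutter_count_per_slice=0,
        round_nucleus_fraction=0.0,
    )


@pytest.fixture(scope="session")
def ureter_stacks():
    """Twelve simulated stacks of the gradually dispersing scenario.

    The orientation dispersion rises linearly from 25 deg at the
    adventitial side to 32 deg at the proprial side; the field is the
    default 512 px (256 µm) so each depth window holds enough independent
    nuclei for stable per-stack dispersion estimates.
    """
    results, truths = [], []
    for seed in range(1, 13):
        spec = dataclasses.replace(
            to.preset_scenarios()["ureter_like"], seed=seed
        )
        stack, truth = to.generate_stack(spec)
        stack.stack_id = f"ureter-{seed}"
        res = to.analyze_stack(stack, lm_thickness_um=spec.wall_thickness_um)
        results.append(res)
        truths.append(truth)
    return results, truths


@pytest.fixture(scope="session")
def intestine_stacks():
    """Three simulated stacks of the two-layer (gut-like) control scenario."""
    results, truths = [], []
    for seed in range(21, 24):
        spec = dataclasses.replace(
            to.preset_scenarios()["intestine_like"], seed=seed
        )
        stack, truth = to.generate_stack(spec)
        stack.stack_id = f"intestine-{seed}"
        res = to.analyze_stack(stack, lm_thickness_um=spec.wall_thickness_um)
        results.append(res)
        truths.append(truth)
    return results, truths
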