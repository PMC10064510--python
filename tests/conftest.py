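import numpy as np
import pytest

import stomakit as sk


@pytest.fixture(scope="session")
def p400():
    return sk.get_profile("400x")


@pytest.fixture(scope="session")
def p100():
    return sk.get_profile("100x")


@pytest.fixture(scope="session")
def dicot_scene(p400):
    """One moderate-noise scattered-archetype scene with ground truth."""
    spec = sk.make_scene_spec("400x", "dicot", target_density_mm2=100, seed=11)
    image, gt = sk.render_scene(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def clean_dicot_scene(p400):
    """Artifact-free scattered scene (no noise, gradient or bubbles)."""
    spec = sk.make_scene_spec(
        "400x", "dicot", target_density_mm2=100, seed=7,
        noise_sd=0.0, illumination_gradient=0.0, bubble_count=0,
    )
    image, gt = sk.render_scene(spec)
    return spec, image, gt


def single_stoma_scene(openness_mean, seed=3, archetype="dicot", profile="400x",
                       noise_sd=0.0):
    """Scene sized to hold exactly one stoma, with controllable openness."""
    arch = sk.ARCHETYPES[archetype]
    arch = sk.SpeciesArchetype(
        name="custom", arrangement="scattered", shape=arch.shape,
        complex_length_um=arch.complex_length_um,
        complex_width_um=arch.complex_width_um,
        aperture_openness=(openness_mean, 0.0),
        min_spacing_um=arch.min_spacing_um,
    )
    prof = sk.get_profile(profile)
    side = int(3 * arch.complex_length_um[0] * prof.px_per_mm / 1000)
    area_mm2 = (side / prof.px_per_mm) ** 2
    spec = sk.SceneSpec(
        profile=prof, image_size_px=(side, side),
        target_density_mm2=1.0 / area_mm2, archetype=arch,
        noise_sd=noise_sd, illumination_gradient=0.0, bubble_count=0, seed=seed,
    )
    return spec
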