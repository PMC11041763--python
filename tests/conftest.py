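import numpy as np
import pytest
from hypothesis import settings

import aggrescope as ag

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_scene_config(**overrides) -> ag.SceneConfig:
    """A compact noise-free scene the whole suite shares: 1 mm particle,
    10 µm pixels, 10 hourly frames, 5 colonies already past their (zero) lag."""
    defaults = dict(
        particle_radius_um=1000.0,
        pixel_size_um=10.0,
        n_frames=10,
        n_colonies=5,
        n_diatoms=6,
        noise_sd=0.0,
        rng_seed=3,
        growth_law=ag.DiauxicGrowthParams(
            mu1=0.05, lag_start_h=6.0, lag_duration_h=0.0,
            mu2=0.04, area0_um2=3000.0,
        ),
    )
    defaults.update(overrides)
    return ag.SceneConfig(**defaults)


@pytest.fixture(scope="session")
def scene():
    """(config, stack, calibration frames, ground truth) of the shared scene."""
    config = small_scene_config()
    stack, cal, truth = ag.render_frames(config)
    return config, stack, cal, truth


@pytest.fixture(scope="session")
def scene_pipeline(scene):
    """The full pipeline run on the shared scene, from the detected geometry."""
    config, stack, cal, truth = scene
    geom = ag.detect_particle(stack.brightfield[0],
                              pixel_size_um=config.pixel_size_um)
    model = ag.fit_calibration(cal.anoxic, cal.air, geom,
                               o2_saturation_umol_L=config.o2_saturation_umol_L)
    diatoms = ag.mask_diatoms(stack.brightfield[0], geom)
    label_stack, obs_by_frame, o2_fields = [], [], []
    for i, t in enumerate(stack.times_h):
        o2 = ag.fluorescence_to_oxygen(stack.sensor[i], model, geom)
        labels, obs = ag.segment_colonies(stack.brightfield[i], geom, diatoms,
                                          o2, frame_index=i, time_h=float(t))
        label_stack.append(labels)
        obs_by_frame.append(obs)
        o2_fields.append(o2)
    tracks, qc = ag.backtrack(np.stack(label_stack), obs_by_frame,
                              pixel_size_um=config.pixel_size_um)
    return {
        "geometry": geom, "model": model, "diatom_mask": diatoms,
        "labels": np.stack(label_stack), "observations": obs_by_frame,
        "o2": np.stack(o2_fields), "tracks": tracks, "qc": qc,
    }


@pytest.fixture(scope="session")
def disk_geometry():
    """Full-size (1.5 mm) particle geometry straight from an analytic mask."""
    shape = (340, 340)
    yy, xx = np.indices(shape)
    c = (shape[0] - 1) / 2
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= 150.0 ** 2
    return ag.geometry_from_mask(mask, pixel_size_um=10.0)
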