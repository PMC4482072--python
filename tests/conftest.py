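import numpy as np
import pytest

from frit.calibration import default_calibration
from frit.event_kinetics import ReleaseEvent
from frit.pipeline import PipelineConfig, process_frame
from frit.roi_stats import compartment_traces
from frit.simulate import SimulationConfig, generate_timeseries


@pytest.fixture(scope="session")
def curve():
    """Default anchored calibration curve (built once per session)."""
    return default_calibration()


@pytest.fixture(scope="session")
def noise_free_movie():
    """Small noise-free dual-gain movie with one step-like scripted release.

    Two cells in a 160x160 field, 2 z-slices, 2-min frames over 120 min; the
    scripted event is a clean step (no rise ramp, instantaneous fading, no
    perinuclear accumulation) so trace detection can recover it exactly.
    """
    config = SimulationConfig(
        image_size=(160, 160),
        z_slices=2,
        cells_per_field=2,
        frame_interval=2.0,
        duration=120.0,
        shot_noise=False,
        read_noise_sd=0.0,
        release_spread=0.0,
        perinuclear_intensity=0.0,
        seed=5,
    )
    event = ReleaseEvent(cell_id=0, onset=40.0, persistence=30.0, depletion_duration=0.0)
    stack, truth = generate_timeseries(config, 5, events=[event], return_integrity=True)
    return config, stack, truth


@pytest.fixture(scope="session")
def processed_movie(noise_free_movie):
    """The noise-free movie run through gain fusion + ratio imaging."""
    config, stack, truth = noise_free_movie
    pc = PipelineConfig(
        gain_ratio=config.gain_ratio, saturation_level=config.saturation, background=0.0
    )
    T, Z, _, H, W = stack.shape
    ratio = np.empty((T, Z, H, W))
    donor = np.empty_like(ratio)
    fret = np.empty_like(ratio)
    for t in range(T):
        for z in range(Z):
            masked, d, f = process_frame(stack[t, z], pc)
            ratio[t, z] = masked.values
            donor[t, z] = d
            fret[t, z] = f
    return ratio, donor, fret, truth


@pytest.fixture(scope="session")
def cytosol_trace(processed_movie):
    ratio, donor, fret, truth = processed_movie
    traces = compartment_traces(truth["times"], donor, fret, ratio, truth["rois"][0])
    return truth["times"], traces
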