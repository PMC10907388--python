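"""Shared fixtures: synthetic stimuli and model-cell recordings.

Session-scoped fixtures keep the expensive generator outputs (spot
movies, per-type response maps, a reference set for classification)
shared across test modules.
"""

from dataclasses import replace

import numpy as np
import pytest

from onbc import celltyping as ct
from onbc import imaging as im
from onbc import spots as sp
from onbc import synthetic as syn


@pytest.fixture(scope="session")
def spot_movie():
    """Full seven-size spot protocol, five repeats, 10 fps."""
    return syn.generate_spot_stimulus(repeats=5, frame_rate=10.0, seed=1)


@pytest.fixture(scope="session")
def cell_params():
    return syn.default_cell_params()


def epoch_single_trace(trace, rate, log, baseline_s=0.5):
    """Wrap a 1-D trace as a one-pixel recording and epoch it."""
    series = im.ImageSeries(np.asarray(trace)[:, None, None], rate, 1.0)
    roi_map = im.ROIMap(np.ones((1, 1), np.int32), [(0, 0)])
    return im.extract_epoched_traces(series, roi_map, log, baseline_s=baseline_s)


def spot_map_for_cell(cell, movie, noise_sd=0.0, seed=0):
    cell = replace(cell, noise_sd=noise_sd)
    trace = syn.simulate_cell_response(cell, movie, sampling_rate=9.5, seed=seed)
    epoched = epoch_single_trace(trace, 9.5, movie.log)
    return sp.SpotResponseMap.from_epoched(epoched, 1)


@pytest.fixture(scope="session")
def type_spot_maps(spot_movie, cell_params):
    """Noise-free spot-response maps for all seven model types."""
    return {lbl: spot_map_for_cell(c, spot_movie) for lbl, c in cell_params.items()}


@pytest.fixture(scope="session")
def reference_set(spot_movie, cell_params):
    """Five noisy exemplars per type, as a classification reference."""
    rng = np.random.default_rng(7)
    responses, labels, depths = [], [], []
    for lbl, cell in cell_params.items():
        for _ in range(5):
            jittered = replace(
                cell,
                noise_sd=0.04,
                center_radius=cell.center_radius * rng.uniform(0.9, 1.1),
                ipl_depth=float(np.clip(cell.ipl_depth + rng.normal(0, 0.02), 0, 1)),
            )
            trace = syn.simulate_cell_response(
                jittered, spot_movie, 9.5, seed=int(rng.integers(2**31))
            )
            epoched = epoch_single_trace(trace, 9.5, spot_movie.log)
            m = sp.SpotResponseMap.from_epoched(epoched, 1)
            responses.append(m.mean_traces.ravel())
            labels.append(lbl)
            depths.append(jittered.ipl_depth)
    return ct.ReferenceSet(np.asarray(responses), np.asarray(labels), np.asarray(depths))


@pytest.fixture(scope="session")
def depth_profiles():
    return ct.default_depth_profiles()
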