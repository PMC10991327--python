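"""Shared fixtures: one moderately sized synthetic recording, decomposed once."""

import numpy as np
import pytest

from cortexwaves import cpca, fcanalysis, preprocess, synthdata


@pytest.fixture(scope="session")
def small_truth():
    """Default 3-wave fixture at reduced scale (20×20, 100 s @ 30 Hz)."""
    return synthdata.default_truth(seed=1, grid_shape=(20, 20), duration=100.0)


@pytest.fixture(scope="session")
def small_run(small_truth):
    """Full preprocessing + decomposition of the small fixture, shared."""
    movie, mask = synthdata.simulate_movie(small_truth)
    m = preprocess.flatten_movie(movie, mask, small_truth.sampling_rate)
    m = preprocess.bandpass(m, preprocess.FrequencyBand(0.1, 14.5))
    m = preprocess.zscore(m)
    analytic = cpca.analytic_signal(m)
    decomposition = cpca.cpca_decompose(analytic, n_components=10)
    return {
        "truth": small_truth,
        "movie": movie,
        "mask": mask,
        "matrix": m,
        "analytic": analytic,
        "decomposition": decomposition,
        "fc": fcanalysis.fc_matrix(m),
        "recovery": synthdata.recovery_report(small_truth, decomposition),
    }


def make_component(loading, score, pixel_index=None, grid_shape=None, rate=30.0):
    """Hand-built WaveComponent for oracle tests (normalized, gauge left as given)."""
    loading = np.asarray(loading, dtype=complex)
    score = np.asarray(score, dtype=complex)
    d = float(np.linalg.norm(score))
    if pixel_index is None:
        n = loading.size
        pixel_index = np.stack([np.zeros(n, dtype=int), np.arange(n)], axis=1)
        grid_shape = (1, n)
    return cpca.WaveComponent(
        loading=loading / np.linalg.norm(loading),
        score=score,
        eigenvalue=d,
        variance_fraction=1.0,
        pixel_index=pixel_index,
        grid_shape=grid_shape,
        sampling_rate=rate,
    )
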