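import numpy as np
import pytest

import aortahemo as ah


@pytest.fixture(scope="session")
def subjects():
    """Per-subject hemodynamic inputs (D, T, Qmean, Qpeak) for the cohort."""
    return ah.make_subject_table().set_index("subject")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ts2_waveform():
    """Synthetic waveform matching the TS2 inputs (T=0.57 s, 90/294 ml/s)."""
    return ah.make_waveform(ah.WaveformTemplate(T=0.57, Qmean=90.0, Qpeak=294.0))


def random_smooth_series(rng, mesh, n_time=100, period=1.0, n_modes=4):
    """Band-limited random tangential WSS series on a mesh (test helper).

    Uses a few Fourier modes per component so that periodic trapezoid
    integration of derived quantities is spectrally accurate, making dense
    quadrature a valid independent oracle.
    """
    times = period * np.arange(n_time) / n_time
    V = mesh.n_vertices
    tau = np.zeros((n_time, V, 3))
    for k in range(n_modes + 1):
        amp = rng.normal(size=(1, V, 3)) / (k + 1)
        phase = rng.uniform(0, 2 * np.pi, size=(1, V, 3))
        tau += amp * np.cos(2 * np.pi * k * times[:, None, None] / period + phase)
    # project onto the tangent plane so the series is a valid wall shear
    n = mesh.vertex_normals
    tau -= np.einsum("tvk,vk->tv", tau, n)[:, :, None] * n[None, :, :]
    return ah.WSSVectorSeries(mesh, times, tau, period)
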