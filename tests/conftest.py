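import numpy as np
import pytest

from vepscope import CONTROL, DKO, SyntheticConfig


@pytest.fixture()
def noiseless_config() -> SyntheticConfig:
    """50 kHz acquisition with no noise and no stimulus artifact."""
    return SyntheticConfig(seed=0, noise_sd_uv=0.0, artifact_amp_uv=0.0)


@pytest.fixture(params=["control", "dko"])
def preset(request):
    return {"control": CONTROL, "dko": DKO}[request.param]


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-configuration pipeline run, shared across tests."""
    from vepscope.pipeline import run_pipeline

    return run_pipeline({"seed": 1})


def grid_search_naka_rushton(
    intensity: np.ndarray,
    response: np.ndarray,
    log10_i50_range=(2.0, 8.0),
    slope_range=(0.05, 3.0),
    n_grid: int = 400,
    n_zoom: int = 2,
):
    """Brute-force RSS grid search oracle, refined by successive zooming.

    Independent of the package fitter: evaluates the Naka-Rushton RSS on
    an explicit (log10 i50, slope) grid and narrows the grid around the
    best cell.  Returns (i50, slope, rss).
    """
    log_i = np.log(np.asarray(intensity, dtype=float))
    r = np.asarray(response, dtype=float)
    lo_l, hi_l = log10_i50_range
    lo_s, hi_s = slope_range
    ln10 = np.log(10.0)
    for _ in range(n_zoom + 1):
        l_grid = np.linspace(lo_l, hi_l, n_grid)
        s_grid = np.linspace(lo_s, hi_s, n_grid)
        pred = 1.0 / (
            1.0
            + np.exp(
                s_grid[None, :, None] * (l_grid[:, None, None] * ln10 - log_i[None, None, :])
            )
        )
        rss = np.sum((pred - r[None, None, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        dl = (hi_l - lo_l) / (n_grid - 1)
        ds = (hi_s - lo_s) / (n_grid - 1)
        best = (l_grid[i], s_grid[j], rss[i, j])
        lo_l, hi_l = l_grid[i] - 2 * dl, l_grid[i] + 2 * dl
        lo_s, hi_s = max(s_grid[j] - 2 * ds, 1e-6), s_grid[j] + 2 * ds
    return 10.0 ** best[0], best[1], float(best[2])
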