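import numpy as np
import pytest

from rbcdeform import render_field
from rbcdeform.presets import load_preset


@pytest.fixture(scope="session")
def fresh_preset():
    return load_preset("fresh-donor")


@pytest.fixture(scope="session")
def study_preset():
    return load_preset("study")


@pytest.fixture(scope="session")
def clean_field(fresh_preset):
    """A small noise-free rendered field with its ground truth."""
    spec = fresh_preset.field_spec(
        seed=101, n_cells=50, width_px=640, height_px=480,
        noise_sd=0.0, background_gradient=0.0,
    )
    image, truths = render_field(spec)
    return spec, image, truths


def flood_fill_components(binary: np.ndarray) -> int:
    """Independent 4-connected component counter (iterative BFS)."""
    visited = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    count = 0
    for sy, sx in zip(*np.nonzero(binary)):
        if visited[sy, sx]:
            continue
        count += 1
        stack = [(sy, sx)]
        visited[sy, sx] = True
        while stack:
            y, x = stack.pop()
            for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not visited[ny, nx]:
                    visited[ny, nx] = True
                    stack.append((ny, nx))
    return count
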