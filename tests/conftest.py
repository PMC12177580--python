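from __future__ import annotations

import numpy as np
import pytest

from loosenrate.geometry import Box


def rand_box(
    rng: np.random.Generator,
    frame: float = 1000.0,
    min_size: float = 1.0,
    max_size: float = 300.0,
    integer: bool = False,
) -> Box:
    """Uniform random valid box inside a square frame."""
    w = rng.uniform(min_size, max_size)
    h = rng.uniform(min_size, max_size)
    x1 = rng.uniform(0, frame - w)
    y1 = rng.uniform(0, frame - h)
    if integer:
        x1, y1 = np.floor(x1), np.floor(y1)
        w, h = max(1, round(w)), max(1, round(h))
    return Box(float(x1), float(y1), float(x1 + w), float(y1 + h))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
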