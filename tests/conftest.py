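import numpy as np
import pytest

from spioquant import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A 64x64 8-bit image with a loosely bimodal intensity mix."""
    dark = rng.normal(70, 15, size=(64, 64))
    light = rng.normal(190, 12, size=(64, 64))
    choose = rng.uniform(size=(64, 64)) < 0.3
    px = np.clip(np.where(choose, dark, light), 0, 255).astype(np.uint8)
    return GrayImage(pixels=px, pixel_size_nm=0.97)


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Independent Otsu oracle: scan all T, variances from raw pixel lists."""
    values = np.asarray(pixels).ravel().astype(float)
    n = values.size
    best_t, best_obj = None, np.inf
    for t in range(1, 256):
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        obj = (lo.size * lo.var() + hi.size * hi.var()) / n
        if obj < best_obj - 1e-9:
            best_obj, best_t = obj, t
    if best_t is None:
        raise ValueError("degenerate image")
    return best_t


def flood_fill_components(fg: np.ndarray) -> list[set]:
    """Independent 8-connected component oracle by BFS flood fill."""
    fg = np.asarray(fg, dtype=bool)
    seen = np.zeros_like(fg)
    comps = []
    h, w = fg.shape
    for r in range(h):
        for c in range(w):
            if fg[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (
                                0 <= nr < h and 0 <= nc < w
                                and fg[nr, nc] and not seen[nr, nc]
                            ):
                                seen[nr, nc] = True
                                stack.append((nr, nc))
                comps.append(comp)
    return comps
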