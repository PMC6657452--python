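import numpy as np
import pytest

from catqol.irt import ItemBank, PcmItem


@pytest.fixture
def small_bank() -> ItemBank:
    """Ten 3-category items in one domain, centers spread over [-2, 2]."""
    items = []
    centers = np.linspace(-2, 2, 10)
    for i, c in enumerate(centers, 1):
        items.append(
            PcmItem(item_id=f"it{i:02d}", domain_id="physical", thresholds=(c - 0.5, c + 0.5))
        )
    return ItemBank(items=tuple(items))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def grid_search_mle(responses, bounds=(-4.0, 4.0), step=1e-4) -> float:
    """Independent exhaustive-grid argmax of the PCM log-likelihood."""
    lo, hi = bounds
    grid = np.arange(lo, hi + step / 2, step)
    ll = np.zeros_like(grid)
    for item, k in responses:
        b = np.asarray(item.thresholds)
        csum = np.concatenate(([0.0], np.cumsum(b)))
        m = len(b)
        a = grid[:, None] * np.arange(m + 1)[None, :] - csum[None, :]
        amax = a.max(axis=1, keepdims=True)
        logz = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
        ll += a[:, k] - logz
    return float(grid[np.argmax(ll)])
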