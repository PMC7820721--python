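import numpy as np
import pytest

from runsit.geo_context import GeoContextStack
from runsit.synthetic_world import make_landscape


@pytest.fixture(scope="session")
def world():
    """A small patchy landscape with all 9 classes present."""
    return make_landscape(seed=7, width_cells=40, height_cells=40)


@pytest.fixture(scope="session")
def stack(world):
    raster, hoods = world
    return GeoContextStack.build(raster, hoods)


@pytest.fixture(scope="session")
def bins(stack):
    return stack.fit_bins()


def brute_force_distance(classes: np.ndarray, code: int, cell_size: float) -> np.ndarray:
    """O(cells^2) nearest-class-cell scan (independent oracle)."""
    h, w = classes.shape
    targets = np.argwhere(classes == code)
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            d2 = (targets[:, 0] - r) ** 2 + (targets[:, 1] - c) ** 2
            out[r, c] = np.sqrt(d2.min()) * cell_size
    return out


def brute_force_coverage(classes: np.ndarray, code: int, row: int, col: int, window: int = 10) -> float:
    """Explicit window count (independent oracle); window rows [r-5, r+4]."""
    h, w = classes.shape
    half = window // 2
    total = 0
    hits = 0
    for r in range(row - half, row + window - half):
        for c in range(col - half, col + window - half):
            if 0 <= r < h and 0 <= c < w:
                total += 1
                if classes[r, c] == code:
                    hits += 1
    return 100.0 * hits / total


def reference_dtw(a, b) -> float:
    """Independently coded full-matrix DTW DP (oracle)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = abs(a[i - 1] - b[j - 1]) + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    return float(acc[n, m])


def enumerate_dtw(a, b) -> float:
    """DTW by exhaustive enumeration of all warping paths (tiny inputs only)."""
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = min(best[0], cost)
            return
        if i + 1 < len(a):
            walk(i + 1, j, cost)
        if j + 1 < len(b):
            walk(i, j + 1, cost)
        if i + 1 < len(a) and j + 1 < len(b):
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def brute_force_mine(itemlists, weights, sigma, max_len):
    """All non-empty subsets of surviving items with |support| >= sigma (oracle).

    Direct subset enumeration over per-item transaction masks, independent of
    the FP-tree implementation.
    """
    from itertools import combinations

    weights = np.asarray(weights, dtype=float)
    sup = {}
    for t, w in zip(itemlists, weights):
        for i in t:
            sup[i] = sup.get(i, 0.0) + w
    surviving = sorted(i for i, s in sup.items() if abs(s) >= sigma)
    masks = {
        i: np.fromiter((i in t for t in itemlists), dtype=bool, count=len(itemlists))
        for i in surviving
    }
    sets = {}
    limit = max_len if max_len is not None else len(surviving)
    for L in range(1, limit + 1):
        for combo in combinations(surviving, L):
            m = masks[combo[0]].copy()
            for i in combo[1:]:
                m &= masks[i]
            w = float(weights[m].sum())
            if abs(w) >= sigma:
                sets[frozenset(combo)] = (w, int(m.sum()))
    return sets


def random_instance(rng, n_items=10, n_tx=100, tx_len=4):
    """A random small weighted transaction set over items a..j."""
    alphabet = [chr(ord("a") + i) for i in range(n_items)]
    itemlists = []
    for _ in range(n_tx):
        k = rng.integers(1, min(tx_len, n_items) + 1)
        itemlists.append(tuple(sorted(rng.choice(alphabet, size=k, replace=False))))
    weights = rng.uniform(-1, 1, size=n_tx)
    return itemlists, weights
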