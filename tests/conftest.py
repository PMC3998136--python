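"""Shared fixtures: the four-sequence worked example and seeded panel grids."""

import numpy as np
import pytest

from pbwtkit import CopyingModelParams, HaplotypePanel, simulate_copying_panel

# x0=0101, x1=1100, x2=0010, x3=1101 — small enough to verify by hand,
# rich enough to exercise every match class.
P4_ROWS = ["0101", "1100", "0010", "1101"]


@pytest.fixture
def p4() -> HaplotypePanel:
    return HaplotypePanel(P4_ROWS)


def random_panel(seed: int, max_m: int = 40, max_n: int = 80) -> HaplotypePanel:
    """IID panel with a per-site allele frequency drawn uniformly."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, max_m + 1))
    n = int(rng.integers(2, max_n + 1))
    freqs = rng.random(n)
    return HaplotypePanel((rng.random((m, n)) < freqs).astype(np.uint8))


def copying_panel(seed: int, m: int = 30, n: int = 70) -> HaplotypePanel:
    return simulate_copying_panel(
        CopyingModelParams(M=m, N=n, founders=max(2, m // 5), seed=seed)
    )


def panel_grid(n_panels: int, offset: int = 0):
    """Alternating IID and copying-model panels, all seeded."""
    for t in range(n_panels):
        seed = offset + t
        yield random_panel(seed) if t % 2 == 0 else copying_panel(seed)


def brute_prefix_order(X: np.ndarray, k: int) -> list[int]:
    """Stable sort of reversed prefixes at k (the construction oracle)."""
    rev = ["".join(map(str, X[i, :k][::-1])) for i in range(X.shape[0])]
    return sorted(range(X.shape[0]), key=lambda i: (rev[i], i))


def brute_divergence(X: np.ndarray, order: list[int], k: int) -> list[int]:
    """Neighbour match starts by direct backwards comparison."""
    d = [k]
    for i in range(1, len(order)):
        x1, x2 = X[order[i - 1]], X[order[i]]
        j = k
        while j > 0 and x1[j - 1] == x2[j - 1]:
            j -= 1
        d.append(j)
    return d
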