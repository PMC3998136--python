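"""Synthetic haplotype panels with linkage-disequilibrium structure.

The built-in generator is a Li–Stephens-style copying model: a small set
of founder haplotypes is drawn from a 1/f-weighted allele-frequency
spectrum (mimicking a neutral site-frequency spectrum), and every later
haplotype is a mosaic copy of previously generated ones, switching
template at a per-site rate and flipping alleles at a per-site mutation
rate.  Template switching at low rates produces exactly the long shared
segments — and hence the long PBWT runs — that linkage disequilibrium
produces in real panels, in a few dozen lines and with no external
simulator.  Coalescent simulations (used for scaled headline numbers)
enter through :func:`coalescent_panel_adapter`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PanelError
from .panel import HaplotypePanel, default_sites


@dataclass(frozen=True)
class CopyingModelParams:
    """Parameters of the copying-model generator.

    switch_rate and mut_rate are the per-site template-switch and allele
    flip probabilities for the first copied haplotype; as in the
    Li-Stephens model both scale down as founders/m for the m-th
    haplotype, since a larger panel offers closer templates.  This
    scaling is what makes the per-column run count — and hence PBWT
    payload per site — grow sublinearly in M, the behaviour real
    LD-structured panels show.  site_spacing is the mean base-pair gap
    between adjacent sites (exponential).
    """

    M: int
    N: int
    founders: int = 20
    switch_rate: float = 0.02
    mut_rate: float = 0.002
    site_spacing: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.M < 1 or self.N < 1:
            raise PanelError("M and N must be positive")
        if not 1 <= self.founders <= self.M:
            raise PanelError("founders must be in [1, M]")
        for name in ("switch_rate", "mut_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise PanelError(f"{name} must be in [0, 1]")
        if self.site_spacing <= 0:
            raise PanelError("site_spacing must be positive")


def simulate_copying_panel(params: CopyingModelParams) -> HaplotypePanel:
    """Generate a seeded, reproducible LD-structured panel."""
    p = params
    rng = np.random.default_rng(p.seed)
    F, M, N = p.founders, p.M, p.N
    X = np.empty((M, N), dtype=np.uint8)

    # founders: per-site derived-allele count j drawn with P(j) ~ 1/j
    if F >= 2:
        counts = np.arange(1, F)
        weights = 1.0 / counts
        weights /= weights.sum()
        js = rng.choice(counts, size=N, p=weights)
        founder_block = np.zeros((F, N), dtype=np.uint8)
        for k in range(N):
            founder_block[rng.choice(F, size=js[k], replace=False), k] = 1
    else:
        founder_block = np.zeros((1, N), dtype=np.uint8)
    X[: min(F, M)] = founder_block[: min(F, M)]

    # mosaic copies with Li-Stephens-style founders/m rate scaling
    for m in range(F, M):
        scale = F / m
        switches = rng.random(N) < min(1.0, p.switch_rate * scale)
        switches[0] = True
        cuts = np.flatnonzero(switches)
        templates = rng.integers(0, m, size=cuts.shape[0])
        row = np.empty(N, dtype=np.uint8)
        bounds = np.append(cuts, N)
        for t in range(cuts.shape[0]):
            row[bounds[t] : bounds[t + 1]] = X[templates[t], bounds[t] : bounds[t + 1]]
        flips = rng.random(N) < min(1.0, p.mut_rate * scale)
        row[flips] ^= 1
        X[m] = row

    gaps = rng.exponential(p.site_spacing, size=N)
    pos = np.maximum(1, np.round(gaps)).cumsum().astype(np.int64)
    return HaplotypePanel(X, sites=default_sites(pos))


def plant_shared_segment(
    panel: HaplotypePanel, members, interval: tuple[int, int], donor: int
) -> HaplotypePanel:
    """Overwrite [start, end) in each member with the donor's alleles,
    guaranteeing a known identical segment.  Returns a modified copy."""
    start, end = interval
    if not 0 <= start < end <= panel.N:
        raise PanelError(f"interval {interval} out of range for N={panel.N}")
    if not 0 <= donor < panel.M:
        raise PanelError(f"donor index {donor} out of range")
    X = panel.alleles.copy()
    for m in members:
        if not 0 <= m < panel.M:
            raise PanelError(f"member index {m} out of range")
        X[m, start:end] = X[donor, start:end]
    return HaplotypePanel(X, sites=panel.sites, sample_names=panel.sample_names)


def coalescent_panel_adapter(source, region_length: float = 2e7) -> HaplotypePanel:
    """Load site-major output of any coalescent simulator.

    The canonical acceptance configuration follows scaled mutation and
    recombination rates of 0.001 per base pair over a 2e7 bp region.
    Simulators that report positions on the unit interval are rescaled
    to base pairs using ``region_length``.
    """
    import io as _io

    from .panel_io import _read_lines, read_sitemajor_text

    lines = _read_lines(source)
    if not lines:
        raise PanelError("empty simulation output")
    panel = read_sitemajor_text(_io.StringIO("\n".join(lines)))
    if panel.N == 0 or panel.M == 0:
        raise PanelError("empty simulation output")

    raw: list[float] | None = []
    for line in lines:
        tokens = line.split()
        if raw is not None and len(tokens) >= 2:
            try:
                raw.append(float(tokens[-2]))
            except ValueError:
                raw = None
        else:
            raw = None
    if raw is not None:
        pos = np.asarray(raw, dtype=float)
        if pos.size and 0.0 <= pos.min() and pos.max() <= 1.0:
            pos = pos * region_length
        bp = np.round(pos).astype(np.int64)
        # force strict increase after rounding (collisions bump forward)
        n = bp.shape[0]
        bp = np.maximum.accumulate(bp - np.arange(n)) + np.arange(n)
        panel = HaplotypePanel(
            panel.alleles, sites=default_sites(bp), sample_names=panel.sample_names
        )
    return panel
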