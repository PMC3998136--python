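"""Positional prefix and divergence arrays, and the compact PBWT index.

The central object of the sweep is the pair (a_k, d_k):

* ``a_k`` lists the sequences so that their reversed prefixes up to site
  k-1 are sorted (ties broken by original index), and
* ``d_k[i]`` is the smallest j such that sorted neighbours i-1 and i
  agree on every site in [j, k), with the sentinel d_k[0] = k.

Both are maintained in a single O(NM) forward pass.  The alleles of
column k read in a_k order form the PBWT column y_k, which is highly
run-length compressible under linkage disequilibrium; a
:class:`PBWTIndex` stores only those compressed columns plus periodic
(a, d) checkpoints, from which any intermediate state can be replayed.

Coordinates are 0-based and all intervals are half-open [k1, k2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._kernels import step_a_d
from .codec import rle_decode, rle_encode, rle_tokens
from .errors import IntegrityError, PanelError
from .panel import HaplotypePanel

DEFAULT_CHECKPOINT = 64


def _as_column(column, M: int) -> np.ndarray:
    col = np.asarray(column)
    if col.shape != (M,):
        raise PanelError(f"column has length {col.shape}, expected ({M},)")
    if col.size and not np.isin(col, (0, 1)).all():
        raise PanelError("column contains non-binary values")
    return col.astype(np.uint8, copy=False)


@dataclass
class SweepState:
    """Sweep position k with prefix array a, divergence array d and,
    once the column at k has been seen, its rank arrays u, v and zero
    total c used by the extension function."""

    k: int
    a: np.ndarray
    d: np.ndarray | None = None
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    c: int | None = None

    @classmethod
    def initial(cls, M: int) -> "SweepState":
        """State at k = 0: identity permutation, all-zero divergences
        (every empty prefix ties; ties break by sequence index)."""
        return cls(k=0, a=np.arange(M, dtype=np.int32), d=np.zeros(M, dtype=np.int32))

    @property
    def M(self) -> int:
        return self.a.shape[0]

    def set_column(self, column) -> None:
        """Attach the rank arrays of the column at site k (enables extend)."""
        self.u, self.v, self.c = compute_column_ranks(_as_column(column, self.M))

    def extend(self, i: int, allele: int) -> int:
        return extend(self, i, allele)

    def sorted_column(self, panel_column) -> np.ndarray:
        """Reorder an original-order column into a_k order (y_k)."""
        return _as_column(panel_column, self.M)[self.a]


def compute_column_ranks(column) -> tuple[np.ndarray, np.ndarray, int]:
    """Cumulative zero/one counts of a sorted column.

    u[i] (resp. v[i]) is the number of 0 (resp. 1) alleles among the
    first i entries, so u[i] + v[i] = i and c = u[M] is the column's
    zero total.
    """
    col = np.asarray(column)
    if col.size and not np.isin(col, (0, 1)).all():
        raise PanelError("column contains non-binary values")
    col = col.astype(np.int64, copy=False)
    v = np.concatenate(([0], np.cumsum(col)))
    u = np.arange(col.shape[0] + 1) - v
    return u, v, int(u[-1])


def extend(state: SweepState, i: int, allele: int) -> int:
    """Map sorted boundary i at k to the boundary at k+1 after ``allele``.

    Returns u[i] for allele 0 and c + v[i] for allele 1 — the position
    at k+1 of the boundary before the i-th sorted prefix extended by
    that allele.  Requires the column ranks (``set_column`` or a
    divergence step) to be present on the state.
    """
    if state.u is None:
        raise PanelError("column ranks not set; call set_column() first")
    if not 0 <= i <= state.M:
        raise PanelError(f"sorted index {i} out of range [0, {state.M}]")
    if allele == 0:
        return int(state.u[i])
    if allele == 1:
        return state.c + int(state.v[i])
    raise PanelError(f"allele must be 0 or 1, got {allele!r}")


def build_prefix_step(state: SweepState, column) -> SweepState:
    """Advance only the prefix array: stable partition by the allele at k."""
    col = _as_column(column, state.M)
    zeros = col == 0
    a2 = np.concatenate((state.a[zeros], state.a[~zeros]))
    state.set_column(col)
    return SweepState(k=state.k + 1, a=a2.astype(np.int32))


def build_prefix_divergence_step(state: SweepState, column) -> SweepState:
    """Advance prefix and divergence arrays together (one sweep step)."""
    if state.d is None:
        raise PanelError("state has no divergence array")
    col = _as_column(column, state.M)
    a2 = np.empty(state.M, dtype=np.int32)
    d2 = np.empty(state.M, dtype=np.int32)
    c = step_a_d(
        state.a.astype(np.int32, copy=False),
        state.d.astype(np.int32, copy=False),
        col,
        state.k,
        a2,
        d2,
    )
    state.set_column(col)
    assert c == state.c
    return SweepState(k=state.k + 1, a=a2, d=d2)


def sweep(panel: HaplotypePanel) -> Iterator[SweepState]:
    """Yield SweepState at k = 0 .. N; state k has its column ranks set
    for k < N."""
    st = SweepState.initial(panel.M)
    for k in range(panel.N):
        yield st
        st = build_prefix_divergence_step(st, panel.alleles[st.a, k])
    yield st


# ---------------------------------------------------------------------------
# the compact index
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class _ColumnRuns:
    """Per-column run structure answering rank/select in O(log runs)."""

    values: np.ndarray  # uint8, per maximal run
    lengths: np.ndarray  # int64
    ends: np.ndarray  # cumulative lengths (exclusive end of each run)
    zero_ends: np.ndarray  # cumulative zero counts after each run
    c: int

    @classmethod
    def from_payload(cls, payload: bytes, M: int, k: int) -> "_ColumnRuns":
        try:
            values, lengths = rle_tokens(payload)
        except Exception as exc:
            raise IntegrityError(f"column {k}: {exc}") from exc
        if int(lengths.sum()) != M:
            raise IntegrityError(
                f"column {k}: payload decodes to {int(lengths.sum())} alleles, "
                f"expected {M}"
            )
        # merge adjacent tokens with the same value into maximal runs
        if values.size:
            keep = np.concatenate(([True], values[1:] != values[:-1]))
            grp = np.cumsum(keep) - 1
            lengths = np.bincount(grp, weights=lengths).astype(np.int64)
            values = values[keep]
        ends = np.cumsum(lengths)
        zero_ends = np.cumsum(np.where(values == 0, lengths, 0))
        return cls(
            values=values,
            lengths=lengths,
            ends=ends,
            zero_ends=zero_ends,
            c=int(zero_ends[-1]) if zero_ends.size else 0,
        )

    def rank(self, allele: int, i: int) -> int:
        """Occurrences of ``allele`` among the first i entries."""
        if i <= 0:
            return 0
        t = int(np.searchsorted(self.ends, i, side="left"))
        zeros_before = int(self.zero_ends[t - 1]) if t > 0 else 0
        start = int(self.ends[t - 1]) if t > 0 else 0
        zeros = zeros_before + (i - start if self.values[t] == 0 else 0)
        return zeros if allele == 0 else i - zeros

    def select(self, allele: int, r: int) -> int:
        """Position of the (r+1)-th occurrence of ``allele`` (0-based r)."""
        if allele == 0:
            cum = self.zero_ends
        else:
            cum = self.ends - self.zero_ends
        t = int(np.searchsorted(cum, r, side="right"))
        before = int(cum[t - 1]) if t > 0 else 0
        start = int(self.ends[t - 1]) if t > 0 else 0
        return start + (r - before)

    def value_at(self, i: int) -> int:
        t = int(np.searchsorted(self.ends, i, side="right"))
        return int(self.values[t])

    def decode(self) -> np.ndarray:
        return np.repeat(self.values, self.lengths)


@dataclass(eq=False)
class PBWTIndex:
    """Run-length-compressed PBWT columns plus (a, d) checkpoints.

    Checkpoints are stored at every k that is a multiple of the
    checkpoint interval C and at k = N, so any intermediate sweep state
    is at most C replay steps away.
    """

    M: int
    N: int
    checkpoint_interval: int
    c: np.ndarray  # per-column zero totals
    payloads: list
    a_checkpoints: dict
    d_checkpoints: dict
    sites: pd.DataFrame | None = None
    _runs_cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- column access ---------------------------------------------------

    def column_runs(self, k: int) -> _ColumnRuns:
        runs = self._runs_cache.get(k)
        if runs is None:
            runs = _ColumnRuns.from_payload(self.payloads[k], self.M, k)
            if runs.c != int(self.c[k]):
                raise IntegrityError(
                    f"column {k}: zero count {runs.c} != stored c_k {int(self.c[k])}"
                )
            if len(self._runs_cache) > 4096:
                self._runs_cache.clear()
            self._runs_cache[k] = runs
        return runs

    def column(self, k: int) -> np.ndarray:
        """PBWT column y_k (alleles of site k in a_k order)."""
        return self.column_runs(k).decode()

    def extend_boundary(self, k: int, i: int, allele: int) -> int:
        """FM-style extension w_k(i, allele): boundary at k -> boundary at k+1."""
        if not 0 <= i <= self.M:
            raise PanelError(f"sorted index {i} out of range [0, {self.M}]")
        runs = self.column_runs(k)
        if allele == 0:
            return runs.rank(0, i)
        if allele == 1:
            return runs.c + runs.rank(1, i)
        raise PanelError(f"allele must be 0 or 1, got {allele!r}")

    def allele_in_sorted(self, k: int, j: int) -> int:
        """y_k[j]: the allele at site k of the j-th sorted sequence."""
        return self.column_runs(k).value_at(j)

    def step_back(self, k: int, j: int) -> tuple[int, int]:
        """Invert the extension: the sequence at sorted position j at k
        sat at position p at k-1 and carried ``allele`` at site k-1.
        Returns (p, allele)."""
        runs = self.column_runs(k - 1)
        if j < runs.c:
            return runs.select(0, j), 0
        return runs.select(1, j - runs.c), 1

    def seq_id_at(self, k: int, j: int) -> int:
        """Original index a_k[j], resolved by walking forward to the
        next stored a checkpoint (at most C extension steps)."""
        cp = self._next_checkpoint(k)
        t, h = k, j
        while t < cp:
            allele = self.allele_in_sorted(t, h)
            h = self.extend_boundary(t, h, allele)
            t += 1
        return int(self.a_checkpoints[cp][h])

    def _next_checkpoint(self, k: int) -> int:
        C = self.checkpoint_interval
        cp = min(((k + C - 1) // C) * C, self.N)
        while cp not in self.a_checkpoints:
            cp = min(cp + C, self.N)
            if cp > self.N:
                raise IntegrityError("no checkpoint at or after requested position")
        return cp

    def _prev_checkpoint(self, k: int) -> int:
        C = self.checkpoint_interval
        cp = (k // C) * C
        while cp not in self.a_checkpoints:
            cp -= C
            if cp < 0:
                raise IntegrityError("no checkpoint at or before requested position")
        return cp

    # -- reconstruction ---------------------------------------------------

    def state_at(self, k: int) -> SweepState:
        """Reconstruct (a_k, d_k) from the nearest checkpoint at or
        before k by replaying at most C columns; equal to the value an
        uninterrupted sweep would produce."""
        if not 0 <= k <= self.N:
            raise PanelError(f"position {k} out of range [0, {self.N}]")
        if k in self.a_checkpoints and k in self.d_checkpoints:
            return SweepState(
                k=k, a=self.a_checkpoints[k].copy(), d=self.d_checkpoints[k].copy()
            )
        cp = self._prev_checkpoint(k)
        if cp in self.d_checkpoints:
            d0 = self.d_checkpoints[cp].copy()
        elif cp == 0:
            d0 = np.zeros(self.M, dtype=np.int32)
        else:
            raise IntegrityError(f"no divergence checkpoint at or before {k}")
        st = SweepState(k=cp, a=self.a_checkpoints[cp].copy(), d=d0)
        for t in range(cp, k):
            st = build_prefix_divergence_step(st, self.column(t))
        return st

    def decode_panel(self) -> HaplotypePanel:
        """Invert the transform: scatter each PBWT column back through
        its permutation.  Lossless by construction."""
        X = np.empty((self.M, self.N), dtype=np.uint8)
        a = np.arange(self.M, dtype=np.int32)
        d = np.zeros(self.M, dtype=np.int32)
        a2 = np.empty_like(a)
        d2 = np.empty_like(d)
        for k in range(self.N):
            y = self.column(k)
            X[a, k] = y
            step_a_d(a, d, y, k, a2, d2)
            a, a2 = a2, a
            d, d2 = d2, d
        if self.N and self.N in self.a_checkpoints:
            if not np.array_equal(a, self.a_checkpoints[self.N]):
                raise IntegrityError("replayed final prefix array != stored checkpoint")
        return HaplotypePanel(X, sites=self.sites)


def build_index(
    panel: HaplotypePanel, checkpoint_interval: int = DEFAULT_CHECKPOINT
) -> PBWTIndex:
    """Single forward sweep producing all RLE columns, zero totals and
    (a, d) checkpoints.  Empty panels yield an explicit empty index."""
    if checkpoint_interval < 1:
        raise PanelError("checkpoint interval must be >= 1")
    M, N = panel.M, panel.N
    C = checkpoint_interval
    a = np.arange(M, dtype=np.int32)
    d = np.zeros(M, dtype=np.int32)
    a2 = np.empty_like(a)
    d2 = np.empty_like(d)
    c = np.zeros(N, dtype=np.int64)
    payloads: list[bytes] = []
    a_cp: dict[int, np.ndarray] = {}
    d_cp: dict[int, np.ndarray] = {}
    X = panel.alleles
    for k in range(N):
        if k % C == 0:
            a_cp[k] = a.copy()
            d_cp[k] = d.copy()
        y = X[a, k]
        payloads.append(rle_encode(y))
        if M:
            c[k] = step_a_d(a, d, y, k, a2, d2)
            a, a2 = a2, a
            d, d2 = d2, d
    a_cp[N] = a.copy()
    d_cp[N] = d.copy()
    return PBWTIndex(
        M=M,
        N=N,
        checkpoint_interval=C,
        c=c,
        payloads=payloads,
        a_checkpoints=a_cp,
        d_checkpoints=d_cp,
        sites=panel.sites,
    )


def state_at(index: PBWTIndex, k: int) -> SweepState:
    """Module-level convenience wrapper for :meth:`PBWTIndex.state_at`."""
    return index.state_at(k)


def decode_panel(index: PBWTIndex) -> HaplotypePanel:
    """Module-level convenience wrapper for :meth:`PBWTIndex.decode_panel`."""
    return index.decode_panel()
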