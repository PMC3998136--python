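"""Exact haplotype match discovery on PBWT-sorted panels.

Three match classes are supported, all on half-open 0-based site
intervals [start, end):

* **long matches** — every locally maximal match between two panel
  sequences of length >= L sites, found by block-scanning positions
  where the divergence value drops to start <= k - L;
* **set-maximal matches** — for each sequence, its locally maximal
  matches not contained in a longer match to anyone else, found by a
  bounded neighbour scan in sorted order;
* **query matches** — set-maximal matches of a new sequence against an
  indexed panel, maintained with FM-style extension and backward
  rebasing, without touching every panel sequence per site.

The ``naive_*`` functions implement the match definitions literally by
pairwise scanning; they are the correctness oracles for everything else.
Matches are emitted ordered by ending position, then by sorted-block
position; consumers must not rely on more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from ._kernels import setmax_stats_step, step_a_d
from .core import PBWTIndex, SweepState, build_prefix_divergence_step
from .errors import PanelError
from .panel import HaplotypePanel


class Match(NamedTuple):
    """A shared segment: sequences ``seq_a`` and ``seq_b`` agree on every
    site in [start, end).  For panel-vs-panel set-maximal matches
    ``seq_a`` is the target sequence; for query matches it is the query
    id."""

    seq_a: int
    seq_b: int
    start: int
    end: int


@dataclass
class OpCounter:
    """Instrumentation hook: counts elementary sweep and scan operations
    so the O(NM) behaviour can be asserted empirically."""

    sweep_ops: int = 0
    scan_ops: int = 0
    reported: int = 0

    @property
    def total(self) -> int:
        return self.sweep_ops + self.scan_ops


def _validate_query(z, N: int) -> np.ndarray:
    if isinstance(z, str):
        z = [int(ch) for ch in z]
    z = np.asarray(z)
    if z.ndim == 2 and z.shape[0] == 1:
        z = z[0]
    if z.shape != (N,):
        raise PanelError(f"query has {z.shape} alleles, panel has {N} sites")
    if z.size and not np.isin(z, (0, 1)).all():
        raise PanelError("query contains non-binary alleles")
    return z.astype(np.uint8, copy=False)


# ---------------------------------------------------------------------------
# long matches (>= L sites, locally maximal)
# ---------------------------------------------------------------------------


def long_matches(
    panel: HaplotypePanel, L: int, counter: OpCounter | None = None
) -> Iterator[Match]:
    """Every locally maximal match of length >= L sites between distinct
    panel sequences, each exactly once, emitted at the site where it ends."""
    if not 1 <= L <= panel.N:
        raise PanelError(f"L must be in [1, {panel.N}], got {L}")
    return long_matches_stream(panel.iter_columns(), panel.M, panel.N, L, counter)


def long_matches_stream(
    columns: Iterable, M: int, N: int, L: int, counter: OpCounter | None = None
) -> Iterator[Match]:
    """Streaming variant: consumes original-order columns one at a time,
    holding only O(M) working state."""
    if not 1 <= L <= N:
        raise PanelError(f"L must be in [1, {N}], got {L}")
    a = np.arange(M, dtype=np.int32)
    d = np.zeros(M, dtype=np.int32)
    a2 = np.empty_like(a)
    d2 = np.empty_like(d)
    k = 0
    for column in columns:
        col = np.asarray(column, dtype=np.uint8)[a]
        if k >= L:
            yield from _long_matches_at(a, d, col, k, L, final=False, counter=counter)
        if M:
            step_a_d(a, d, col, k, a2, d2)
            a, a2 = a2, a
            d, d2 = d2, d
        if counter is not None:
            counter.sweep_ops += M
        k += 1
    if k != N:
        raise PanelError(f"column stream ended at {k}, expected {N} columns")
    if N >= L:
        yield from _long_matches_at(a, d, None, N, L, final=True, counter=counter)


def _long_matches_at(a, d, col, k, L, final, counter=None):
    """Report matches ending at k: maximal blocks with divergence
    <= k - L, pairing opposite alleles (or all pairs at the final flush)."""
    M = a.shape[0]
    thresh = k - L
    start = 0
    for i in range(1, M + 1):
        if i < M and d[i] <= thresh:
            continue
        # block [start, i)
        if i - start >= 2:
            for q in range(start + 1, i):
                run = int(d[q])
                for p in range(q - 1, start - 1, -1):
                    if counter is not None:
                        counter.scan_ops += 1
                    if final or col[p] != col[q]:
                        sa, sb = int(a[p]), int(a[q])
                        if sa > sb:
                            sa, sb = sb, sa
                        yield Match(sa, sb, run, k)
                    if int(d[p]) > run:
                        run = int(d[p])
        start = i


# ---------------------------------------------------------------------------
# set-maximal matches within the panel
# ---------------------------------------------------------------------------


def set_maximal_matches(
    panel: HaplotypePanel, counter: OpCounter | None = None
) -> Iterator[Match]:
    """Every set-maximal match of each panel sequence to the rest of the
    panel, emitted at its ending position (ties to several partners give
    one match per partner)."""
    if panel.M < 2:
        raise PanelError("set-maximal matching needs at least two sequences")
    return set_maximal_stream(panel.iter_columns(), panel.M, panel.N, counter)


def set_maximal_stream(
    columns: Iterable, M: int, N: int, counter: OpCounter | None = None
) -> Iterator[Match]:
    if M < 2:
        raise PanelError("set-maximal matching needs at least two sequences")
    a = np.arange(M, dtype=np.int32)
    d = np.zeros(M, dtype=np.int32)
    a2 = np.empty_like(a)
    d2 = np.empty_like(d)
    k = 0
    for column in columns:
        col = np.asarray(column, dtype=np.uint8)[a]
        yield from _set_maximal_at(a, d, col, k, interior=True, counter=counter)
        step_a_d(a, d, col, k, a2, d2)
        a, a2 = a2, a
        d, d2 = d2, d
        if counter is not None:
            counter.sweep_ops += M
        k += 1
    if k != N:
        raise PanelError(f"column stream ended at {k}, expected {N} columns")
    yield from _set_maximal_at(a, d, None, N, interior=False, counter=counter)


def _set_maximal_at(a, d, col, k, interior, counter=None):
    """Neighbour scan at sweep position k (Python reference of the
    compiled statistics kernel; yields the actual Match records)."""
    M = a.shape[0]
    for i in range(M):
        di = int(d[i])
        di1 = int(d[i + 1]) if i + 1 < M else k
        e = min(di, di1)
        if e >= k:
            continue
        ok = True
        m = i - 1
        n = i + 1
        if di <= di1:
            while m >= 0 and d[m + 1] <= di:
                if counter is not None:
                    counter.scan_ops += 1
                if interior and col[m] == col[i]:
                    ok = False
                    break
                m -= 1
        if ok and di >= di1:
            while n < M and d[n] <= di1:
                if counter is not None:
                    counter.scan_ops += 1
                if interior and col[n] == col[i]:
                    ok = False
                    break
                n += 1
        if not ok:
            continue
        tgt = int(a[i])
        if di <= di1:
            for j in range(m + 1, i):
                yield Match(tgt, int(a[j]), di, k)
                if counter is not None:
                    counter.reported += 1
        if di1 <= di:
            for j in range(i + 1, n):
                yield Match(tgt, int(a[j]), di1, k)
                if counter is not None:
                    counter.reported += 1


@dataclass
class MatchLengthStats:
    """Aggregate set-maximal match statistics from the compiled sweep.

    ``n_matches`` counts Match records (one per tied partner);
    ``n_intervals`` counts distinct set-maximal intervals per target
    (a block of tied partners is one event).  The headline "average
    set-maximal match length" is the per-interval mean: a target's
    match to a block of identical partners is one shared segment, not
    one segment per partner.
    """

    n_matches: int
    total_sites: float
    total_bp: float
    n_intervals: int = 0
    interval_sites: float = 0.0
    interval_bp: float = 0.0

    @property
    def mean_sites(self) -> float:
        return self.interval_sites / self.n_intervals if self.n_intervals else 0.0

    @property
    def mean_bp(self) -> float:
        return self.interval_bp / self.n_intervals if self.n_intervals else 0.0

    @property
    def mean_bp_per_record(self) -> float:
        return self.total_bp / self.n_matches if self.n_matches else 0.0


def set_maximal_length_stats(
    columns: Iterable, M: int, N: int, positions=None
) -> MatchLengthStats:
    """Count and total length of all set-maximal matches, computed with
    the compiled kernel in a single streaming sweep (the scalable route
    for panels with thousands of haplotypes; cross-checked against
    :func:`set_maximal_matches` on small panels)."""
    if positions is None:
        pos = np.arange(N, dtype=np.float64)
    else:
        pos = np.asarray(positions, dtype=np.float64)
        if pos.shape != (N,):
            raise PanelError("positions length must equal N")
    a = np.arange(M, dtype=np.int32)
    d = np.zeros(M, dtype=np.int32)
    a2 = np.empty_like(a)
    d2 = np.empty_like(d)
    acc = np.zeros(6, dtype=np.float64)
    k = 0
    for column in columns:
        col = np.asarray(column, dtype=np.uint8)[a]
        pos_end = pos[k - 1] if k > 0 else pos[0]
        setmax_stats_step(a, d, col, k, 1, pos, pos_end, acc)
        step_a_d(a, d, col, k, a2, d2)
        a, a2 = a2, a
        d, d2 = d2, d
        k += 1
    if k != N:
        raise PanelError(f"column stream ended at {k}, expected {N} columns")
    dummy = np.zeros(max(M, 1), dtype=np.uint8)
    setmax_stats_step(a, d, dummy, N, 0, pos, pos[N - 1] if N else 0.0, acc)
    return MatchLengthStats(
        n_matches=int(acc[0]),
        total_sites=float(acc[1]),
        total_bp=float(acc[2]),
        n_intervals=int(acc[3]),
        interval_sites=float(acc[4]),
        interval_bp=float(acc[5]),
    )


# ---------------------------------------------------------------------------
# query matching against an index
# ---------------------------------------------------------------------------


def _match_start_backward(index: PBWTIndex, z, t: int, j: int) -> int:
    """Smallest s such that the sorted sequence at position j at sweep
    position t agrees with z on [s, t), found by walking the inverse
    extension map backwards."""
    h = j
    s = t
    while s > 0:
        h, allele = index.step_back(s, h)
        if allele != z[s - 1]:
            break
        s -= 1
    return s


def query_set_maximal(
    index: PBWTIndex, z, query_id: int = 0
) -> Iterator[Match]:
    """Set-maximal matches of a new sequence z against an indexed panel.

    Maintains the current longest-match state (e, f, g): all sorted
    sequences in [f, g) match z on [e, k).  The interval advances by
    rank lookups; when it empties, the matches ending at k are reported
    and the state rebases at the better-matching sorted neighbour of
    z's insertion point, stepping e back by direct comparison."""
    M, N = index.M, index.N
    z = _validate_query(z, N)
    if M == 0 or N == 0:
        return
    e, f, g = 0, 0, M
    for k in range(N):
        zk = int(z[k])
        f1 = index.extend_boundary(k, f, zk)
        g1 = index.extend_boundary(k, g, zk)
        if f1 < g1:
            f, g = f1, g1
            continue
        if k > e:
            for h in range(f, g):
                yield Match(query_id, index.seq_id_at(k, h), e, k)
        i = f1  # z's insertion boundary at k+1
        s_above = s_below = k + 1
        if i > 0:
            s_above = _match_start_backward(index, z, k + 1, i - 1)
        if i < M:
            s_below = _match_start_backward(index, z, k + 1, i)
        e = min(s_above, s_below)
        f = g = i
        if e <= k:  # at least one neighbour matches; expand the tied block
            if s_above == e:
                f = i - 1
                while f > 0 and _match_start_backward(index, z, k + 1, f - 1) <= e:
                    f -= 1
            if s_below == e:
                g = i + 1
                while g < M and _match_start_backward(index, z, k + 1, g) <= e:
                    g += 1
    if N > e:
        for h in range(f, g):
            yield Match(query_id, index.seq_id_at(N, h), e, N)


def query_batch(
    panel: HaplotypePanel, queries: Sequence, counter: OpCounter | None = None
) -> Iterator[Match]:
    """Joint sweep over panel and queries, reporting only query-vs-panel
    set-maximal matches.  Output multiset equals the union of
    :func:`query_set_maximal` over each query; memory is O(M + Q)."""
    M, N = panel.M, panel.N
    qlist = [_validate_query(q, N) for q in queries]
    Q = len(qlist)
    if Q == 0:
        return
    if M == 0 or N == 0:
        return

    def columns():
        for k in range(N):
            yield np.concatenate(
                [panel.alleles[:, k], [q[k] for q in qlist]]
            ).astype(np.uint8)

    T = M + Q
    a = np.arange(T, dtype=np.int32)
    d = np.zeros(T, dtype=np.int32)
    a2 = np.empty_like(a)
    d2 = np.empty_like(d)
    k = 0
    for column in columns():
        col = column[a]
        yield from _query_batch_at(a, d, col, k, M, interior=True, counter=counter)
        step_a_d(a, d, col, k, a2, d2)
        a, a2 = a2, a
        d, d2 = d2, d
        if counter is not None:
            counter.sweep_ops += T
        k += 1
    yield from _query_batch_at(a, d, None, k, M, interior=False, counter=counter)


def _query_batch_at(a, d, col, k, M, interior, counter=None):
    """Neighbour scan for query targets only, skipping other queries
    when locating the nearest panel partners."""
    T = a.shape[0]
    for i in range(T):
        if a[i] < M:
            continue  # panel sequence: not a query target
        qid = int(a[i]) - M
        # nearest panel neighbour above, tracking the running divergence max
        m = i - 1
        run_up = int(d[i])
        while m >= 0 and a[m] >= M:
            run_up = max(run_up, int(d[m]))
            m -= 1
            if counter is not None:
                counter.scan_ops += 1
        s_above = run_up if m >= 0 else k + 1
        n = i + 1
        run_dn = int(d[n]) if n < T else k
        while n < T and a[n] >= M:
            n += 1
            run_dn = max(run_dn, int(d[n]) if n < T else k)
            if counter is not None:
                counter.scan_ops += 1
        s_below = run_dn if n < T else k + 1
        e = min(s_above, s_below)
        if e >= k:
            continue
        ok = True
        up_partners: list[int] = []
        dn_partners: list[int] = []
        if s_above == e:
            j = i - 1
            run = int(d[i])
            while j >= 0 and run <= e:
                if counter is not None:
                    counter.scan_ops += 1
                if a[j] < M:
                    if interior and col[j] == col[i]:
                        ok = False
                        break
                    up_partners.append(int(a[j]))
                run = max(run, int(d[j]))
                j -= 1
        if ok and s_below == e:
            j = i + 1
            run = int(d[j]) if j < T else k
            while j < T and run <= e:
                if counter is not None:
                    counter.scan_ops += 1
                if a[j] < M:
                    if interior and col[j] == col[i]:
                        ok = False
                        break
                    dn_partners.append(int(a[j]))
                nxt = int(d[j + 1]) if j + 1 < T else k
                run = max(run, nxt)
                j += 1
        if not ok:
            continue
        for p in up_partners:
            yield Match(qid, p, e, k)
        for p in dn_partners:
            yield Match(qid, p, e, k)
        if counter is not None:
            counter.reported += len(up_partners) + len(dn_partners)


# ---------------------------------------------------------------------------
# centered blocks (bidirectional L/2 variant)
# ---------------------------------------------------------------------------


def centered_blocks(
    index: PBWTIndex, k: int, half_length: int
) -> Iterator[tuple[tuple[int, int], frozenset]]:
    """Maximal groups of sequences pairwise identical on the window
    [k - L2, k + L2), read off the divergence array at sweep position
    k + L2 without splitting by the current allele."""
    L2 = half_length
    if L2 < 1:
        raise PanelError("half_length must be >= 1")
    if not L2 <= k <= index.N - L2:
        raise PanelError(
            f"window centre {k} out of range [{L2}, {index.N - L2}] for L2={L2}"
        )
    st = index.state_at(k + L2)
    a, d = st.a, st.d
    thresh = k - L2
    interval = (k - L2, k + L2)
    start = 0
    for i in range(1, index.M + 1):
        if i < index.M and d[i] <= thresh:
            continue
        yield interval, frozenset(int(a[j]) for j in range(start, i))
        start = i


# ---------------------------------------------------------------------------
# naive oracles: the definitions, implemented literally
# ---------------------------------------------------------------------------


def _pair_maximal_intervals(x: np.ndarray, y: np.ndarray):
    """Locally maximal agreement intervals between two equal-length
    sequences (mismatch-or-boundary at both ends, nonempty)."""
    N = x.shape[0]
    mismatches = np.flatnonzero(x != y)
    bounds = np.concatenate(([-1], mismatches, [N]))
    for t in range(bounds.shape[0] - 1):
        s, e = int(bounds[t]) + 1, int(bounds[t + 1])
        if e > s:
            yield s, e


def naive_long_matches(panel: HaplotypePanel, L: int) -> Iterator[Match]:
    """All-pairs scan for locally maximal matches of length >= L."""
    if not 1 <= L <= panel.N:
        raise PanelError(f"L must be in [1, {panel.N}], got {L}")
    X = panel.alleles
    for i in range(panel.M):
        for j in range(i + 1, panel.M):
            for s, e in _pair_maximal_intervals(X[i], X[j]):
                if e - s >= L:
                    yield Match(i, j, s, e)


def _set_maximal_filter(cands: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Keep (partner, s, e) candidates not properly contained in a longer
    candidate interval (to any partner)."""
    kept = []
    for p, s, e in cands:
        contained = any(
            (e2 - s2 > e - s) and s2 <= s and e2 >= e for _, s2, e2 in cands
        )
        if not contained:
            kept.append((p, s, e))
    return kept


def naive_set_maximal(panel: HaplotypePanel) -> Iterator[Match]:
    """Per-target all-pairs scan followed by the containment filter that
    defines set-maximality."""
    if panel.M < 2:
        raise PanelError("set-maximal matching needs at least two sequences")
    X = panel.alleles
    for i in range(panel.M):
        cands = []
        for j in range(panel.M):
            if j == i:
                continue
            for s, e in _pair_maximal_intervals(X[i], X[j]):
                cands.append((j, s, e))
        for j, s, e in _set_maximal_filter(cands):
            yield Match(i, j, s, e)


def naive_query(panel: HaplotypePanel, z, query_id: int = 0) -> Iterator[Match]:
    """All-panel scan of a query sequence with the containment filter."""
    z = _validate_query(z, panel.N)
    cands = []
    for j in range(panel.M):
        for s, e in _pair_maximal_intervals(z, panel.alleles[j]):
            cands.append((j, s, e))
    for j, s, e in _set_maximal_filter(cands):
        yield Match(query_id, j, s, e)
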