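"""Positional Burrows-Wheeler Transform over a binary haplotype panel.

The PBWT keeps, at each marker m, the haplotypes sorted by their
*reverse prefix* (alleles read backwards from m to the window start).
One column is live at a time: ``advance_column`` maps the order at
marker m-1 to the order at m with a stable counting sort, updating

* ``A`` -- positional prefix array (permutation of haplotype ids),
* ``Y`` -- the panel column in previous-A order (the PBWT column),
* rank structures (``c`` and cumulative counts, the FM-index), and
* ``D`` -- divergence array: ``D[n]`` is the start of the maximal
  reverse-prefix match between the haplotypes at A-ranks n-1 and n,
  with the sentinel ``D[0] = m + 1`` (no match possible).

The start of the maximal match ending at m between the haplotypes at
A-ranks i < j is ``max(D[i+1..j])``, which is what state selection
exploits.  Target haplotypes are located in the reference order with an
O(1)-per-marker FM-index update, independent of the panel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PbwtColumn:
    """PBWT state after processing typed marker ``m``.

    ``cum0[n]`` counts 0-symbols in ``Y[0:n]`` (exclusive prefix sums,
    length N+1), so both the inclusive rank convention and insertion-slot
    lookups fall out without special cases.
    """

    m: int
    A: np.ndarray  # (N,) int32, reverse-prefix order after marker m
    Y: np.ndarray  # (N,) uint8, panel column m in A_{m-1} order
    D: np.ndarray  # (N,) int32, divergence (match starts), D[0] = m+1
    cum0: np.ndarray  # (N+1,) int32 exclusive zero counts over Y

    @property
    def n(self) -> int:
        return len(self.A)

    @property
    def c(self) -> int:
        """Number of 0 symbols in the column."""
        return int(self.cum0[-1])

    def rank(self, b: int, n: int) -> int:
        """Number of ``b`` symbols in ``Y[0..n]`` inclusive.

        Inclusive counting makes the identity
        ``rank(0, n) + rank(1, n) == n + 1`` hold at every position.
        """
        if not 0 <= n < self.n:
            raise IndexError(f"rank position {n} out of range")
        r0 = int(self.cum0[n + 1])
        return r0 if b == 0 else (n + 1) - r0

    def max_match_start(self, i: int, j: int) -> int:
        """Start of the maximal reverse-prefix match (ending at this
        marker) between the haplotypes at A-ranks ``i < j``."""
        if i >= j:
            raise ValueError("max_match_start requires i < j")
        return int(self.D[i + 1 : j + 1].max())


def initial_column(n: int) -> PbwtColumn:
    """Virtual state before any marker: identity order, empty prefixes."""
    return PbwtColumn(
        m=-1,
        A=np.arange(n, dtype=np.int32),
        Y=np.zeros(n, dtype=np.uint8),
        D=np.zeros(n, dtype=np.int32),
        cum0=np.arange(n + 1, dtype=np.int32),
    )


def _class_divergence(d_scan: np.ndarray, idx: np.ndarray, sentinel: int) -> np.ndarray:
    """Divergence values for one symbol class after the counting sort.

    ``idx`` are the (previous-order) positions holding this symbol; the
    new divergence of the k-th of them is the running maximum of the old
    divergences seen since the previous one (Durbin's one-pass sweep),
    and the first one gets the no-match sentinel.
    """
    k = len(idx)
    out = np.empty(k, dtype=np.int32)
    if k == 0:
        return out
    out[0] = sentinel
    if k > 1:
        # segments (idx[j-1], idx[j]] are contiguous; reduceat over the
        # slice ending at idx[-1] gives exact segment maxima.
        out[1:] = np.maximum.reduceat(d_scan[: idx[-1] + 1], idx[:-1] + 1)
    return out


def advance_column(prev: PbwtColumn | None, column_alleles: np.ndarray) -> PbwtColumn:
    """Advance the PBWT by one marker.

    ``column_alleles`` is the raw panel column ``H[:, m]`` indexed by
    haplotype id.  Runs in O(N) with vectorized counting sort.
    """
    h = np.asarray(column_alleles)
    if h.ndim != 1:
        raise ValueError("column must be a 1-D allele vector")
    if h.size and h.max(initial=0) > 1:
        raise ValueError("non-binary symbol in panel column")
    n = len(h)
    if prev is None:
        prev = initial_column(n)
    m = prev.m + 1
    y = np.ascontiguousarray(h[prev.A], dtype=np.uint8)
    zero_mask = y == 0
    idx0 = np.nonzero(zero_mask)[0]
    idx1 = np.nonzero(~zero_mask)[0]
    A = np.concatenate([prev.A[idx0], prev.A[idx1]])
    sentinel = m + 1
    d0 = _class_divergence(prev.D, idx0, sentinel)
    d1 = _class_divergence(prev.D, idx1, sentinel)
    D = np.concatenate([d0, d1])
    cum0 = np.zeros(n + 1, dtype=np.int32)
    np.cumsum(zero_mask, out=cum0[1:])
    return PbwtColumn(m=m, A=A.astype(np.int32), Y=y, D=D, cum0=cum0)


def recover_column(col: PbwtColumn, prev_A: np.ndarray) -> np.ndarray:
    """Invert the transform: rebuild ``H[:, m]`` from (Y, A at m-1)."""
    h = np.empty(col.n, dtype=np.uint8)
    h[prev_A] = col.Y
    return h


@dataclass
class TargetTrace:
    """Insertion state of one target haplotype swept along the PBWT.

    ``f`` is the slot (0..N) where the target's reverse prefix would be
    inserted in A-order, i.e. the number of reference reverse prefixes
    lexicographically smaller than the target's.
    """

    target_id: int
    f: int = 0
    history: list = None

    def __post_init__(self):
        if self.history is None:
            self.history = []


def insert_step(f: int, col: PbwtColumn, t_allele: int) -> int:
    """One FM-index update of the insertion slot (O(1), N-independent).

    With ``t=0`` the new slot counts the 0-symbols among the first ``f``
    entries of Y; with ``t=1`` it is ``c`` plus the 1-symbols among the
    first ``f`` entries.  ``f`` may be N (below every reference prefix),
    handled by the exclusive prefix counts.
    """
    z = int(col.cum0[f])
    if t_allele == 0:
        return z
    return col.c + (f - z)


def insert_step_many(f: np.ndarray, col: PbwtColumn, t_alleles: np.ndarray) -> np.ndarray:
    """Vectorized :func:`insert_step` for many targets at once."""
    z = col.cum0[f]
    return np.where(t_alleles == 0, z, col.c + (f - z)).astype(np.int64)


def insert_target(trace: TargetTrace, col: PbwtColumn, t_allele: int) -> TargetTrace:
    """Advance a target's trace past one marker, recording the slot."""
    trace.f = insert_step(trace.f, col, int(t_allele))
    trace.history.append(trace.f)
    return trace


def match_start_vs_reference(
    ref_typed: np.ndarray, hap_id: int, target_alleles: np.ndarray, m: int
) -> int:
    """Start of the maximal reverse-prefix match (ending at marker m)
    between a target and reference haplotype ``hap_id``, by direct scan."""
    mism = ref_typed[hap_id, : m + 1] != target_alleles[: m + 1]
    nz = np.nonzero(mism)[0]
    return 0 if nz.size == 0 else int(nz[-1]) + 1
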