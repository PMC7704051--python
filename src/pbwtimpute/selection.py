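"""Copying-state selection in the PBWT neighbourhood of each target.

At a sparse set of *selection markers* (every ``interval_cm``
centimorgans along the typed markers) each target haplotype's insertion
slot ``f`` in the reference PBWT is inspected and ``L`` nearby reference
haplotypes are harvested:

* *divergence selection* expands two pointers away from ``f`` and always
  takes the side whose running maximal-match start is older (i.e. the
  longer reverse-prefix match), maintained as prefix maxima of the
  divergence array;
* *neighbour selection* simply takes ceil(L/2) ranks above and
  floor(L/2) ranks below ``f``; near the ends of the prefix array fewer
  than L states are returned.  An optional mismatch guard skips
  neighbours whose allele at the current marker differs from the
  target's when the opposite side can still supply matching ones.

Events are merged per target into one deduplicated copying-state list
used as the HMM state space for the whole window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .pbwt import (
    PbwtColumn,
    advance_column,
    insert_step_many,
    match_start_vs_reference,
)

_INF = np.iinfo(np.int64).max


@dataclass
class SelectionConfig:
    """Knobs of the state-selection pass.

    ``L`` states are harvested per event (default 4; accuracy saturates
    around there), every ``interval_cm`` centimorgans (default 0.02;
    0.002 is the better choice on simulated constant-rate maps, whose
    typed markers are much more regular than real chips).
    """

    L: int = 4
    interval_cm: float = 0.02
    method: str = "neighbour"  # or "divergence"
    mismatch_guard: bool = True

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.interval_cm <= 0:
            raise ValueError("selection interval must be > 0 cM")
        if self.method not in ("neighbour", "divergence"):
            raise ValueError(f"unknown selection method {self.method!r}")


@dataclass
class StateList:
    """Merged copying states for one target haplotype."""

    target_id: int
    states: np.ndarray  # sorted unique reference haplotype ids
    event_counts: Counter = field(default_factory=Counter)

    def __len__(self):
        return len(self.states)


def selection_markers(cm: np.ndarray, interval_cm: float) -> np.ndarray:
    """Greedy left-to-right pick of typed-marker indices at least
    ``interval_cm`` apart; first and last typed markers always included."""
    cm = np.asarray(cm, dtype=float)
    t = len(cm)
    sel = [0]
    last = cm[0]
    for m in range(1, t):
        if cm[m] - last >= interval_cm:
            sel.append(m)
            last = cm[m]
    if sel[-1] != t - 1:
        sel.append(t - 1)
    return np.asarray(sel, dtype=np.intp)


def divergence_select(
    f: int, col: PbwtColumn, L: int, d_up: int, d_dn: int
) -> np.ndarray:
    """Pick the ``L`` longest reverse-prefix matches around slot ``f``.

    ``d_up`` / ``d_dn`` are the match starts between the target and its
    immediate PBWT neighbours (A-ranks f-1 and f); expanding outward the
    running match start of a candidate is the prefix maximum of the
    divergence array, so each step is O(1).  Smaller match start means a
    longer match; ties prefer the upper side.
    """
    n = col.n
    sel = []
    i, j = f - 1, f
    ru = d_up if i >= 0 else _INF
    rd = d_dn if j < n else _INF
    want = min(L, n)
    while len(sel) < want:
        if i >= 0 and (j >= n or ru <= rd):
            sel.append(col.A[i])
            i -= 1
            ru = max(ru, int(col.D[i + 1])) if i >= 0 else _INF
        else:
            sel.append(col.A[j])
            j += 1
            rd = max(rd, int(col.D[j])) if j < n else _INF
    return np.asarray(sel, dtype=np.int64)


def neighbour_select(
    f: int,
    col: PbwtColumn,
    L: int,
    t_allele: int | None = None,
    mismatch_guard: bool = True,
) -> np.ndarray:
    """Take the ranks adjacent to slot ``f``: ceil(L/2) above and
    floor(L/2) below, clipped at the prefix-array borders (fewer than L
    states near a border, never shifted).

    With the mismatch guard, neighbours whose allele at the current
    marker differs from the target's are skipped and their quota moves
    to the matching side.  After the counting sort the column is split
    into a 0-block and a 1-block, so on each side the mismatching
    neighbours are exactly those beyond the target's own block; the
    guard therefore never discards a longer match.
    """
    n = col.n
    up_quota = -(-L // 2)
    dn_quota = L // 2
    win_lo = max(0, f - up_quota)
    win_hi = min(n, f + dn_quota)
    if not mismatch_guard or t_allele is None:
        return col.A[win_lo:win_hi].astype(np.int64)
    c = col.c
    blk_lo, blk_hi = (0, c) if t_allele == 0 else (c, n)
    # window slots outside the target's allele block mismatch at this
    # marker; move their quota to the matching side where possible
    take_lo = max(win_lo, blk_lo)
    take_hi = min(win_hi, blk_hi)
    want = win_hi - win_lo
    if take_lo < take_hi:
        spare = want - (take_hi - take_lo)
        ext = min(spare, take_lo - blk_lo)
        take_lo -= ext
        spare -= ext
        take_hi += min(spare, blk_hi - take_hi)
    else:  # block empty in the window: nothing matches, keep the window
        take_lo, take_hi = win_lo, win_hi
    # quota the matching block could not absorb falls back to the
    # nearest mismatching neighbours (upper side first)
    while take_hi - take_lo < want and (take_lo > 0 or take_hi < n):
        if take_lo > 0:
            take_lo -= 1
        else:
            take_hi += 1
    return col.A[take_lo:take_hi].astype(np.int64)


def run_selection(
    ref_typed: np.ndarray,
    target_typed: np.ndarray,
    cm: np.ndarray,
    cfg: SelectionConfig,
) -> list[StateList]:
    """One left-to-right sweep building every target's copying list.

    ``ref_typed`` is the reference restricted to typed markers (N x T),
    ``target_typed`` the K target haplotypes at the same markers.  The
    PBWT column is advanced once per marker, every target's slot is
    updated with the O(1) FM-index step, and the configured selector
    fires at the selection markers; per-target events are unioned.
    """
    ref_typed = np.ascontiguousarray(ref_typed, dtype=np.uint8)
    target_typed = np.atleast_2d(np.asarray(target_typed, dtype=np.uint8))
    n, t = ref_typed.shape
    k = target_typed.shape[0]
    if t == 0:
        raise ValueError("no typed markers: selection undefined")
    if target_typed.shape[1] != t:
        raise ValueError("reference and targets disagree on typed markers")
    sel_at = np.zeros(t, dtype=bool)
    sel_at[selection_markers(cm, cfg.interval_cm)] = True
    counts = [Counter() for _ in range(k)]
    f = np.zeros(k, dtype=np.int64)
    col = None
    for m in range(t):
        col = advance_column(col, ref_typed[:, m])
        f = insert_step_many(f, col, target_typed[:, m])
        if not sel_at[m]:
            continue
        for q in range(k):
            fq = int(f[q])
            if cfg.method == "neighbour":
                picked = neighbour_select(
                    fq, col, cfg.L, int(target_typed[q, m]), cfg.mismatch_guard
                )
            else:
                d_up = (
                    match_start_vs_reference(
                        ref_typed, int(col.A[fq - 1]), target_typed[q], m
                    )
                    if fq > 0
                    else _INF
                )
                d_dn = (
                    match_start_vs_reference(
                        ref_typed, int(col.A[fq]), target_typed[q], m
                    )
                    if fq < n
                    else _INF
                )
                picked = divergence_select(fq, col, cfg.L, d_up, d_dn)
            counts[q].update(int(s) for s in picked)
    return [
        StateList(q, np.asarray(sorted(counts[q]), dtype=np.int64), counts[q])
        for q in range(k)
    ]
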